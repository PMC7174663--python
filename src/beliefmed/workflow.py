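"""The recommended end-to-end analysis.

Steps: (a) a participant-level paired t-test gate — does the cue
significantly shift the global belief predictions?  Regressing a
replicated participant-level prediction at the item level understates
its sampling variance, so mediation through beliefs should only be
attempted when the gate passes; (b) group-mean centering of the cue and
mediator(s); (c) the multilevel mediation fit, with the moderation
model and the mediation/moderation equivalence check and an optional
BIC comparison of the random-belief-slope outcome models bundled in.
Under ``gate_policy="enforce"`` a failed gate stops the workflow with a
structured report; under ``"warn"`` the mediation proceeds and the
warning is recorded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .data import ExclusionPolicy, TrialTable, apply_exclusions, group_mean_center, paired_t_test, read_trials, summarize_participants
from .exceptions import BeliefmedError, BeliefStructureError, DegenerateDesignError, UndefinedStatisticError
from .mediation import MediationConfig, Mediator, _DEFAULT_KINDS, ITEM_VARYING, compare_random_slope_b, mediate
from .moderation import check_equivalence, fit_moderation, matched_random_terms


@dataclass
class WorkflowConfig:
    """Everything needed to (re)run the recommended workflow."""

    input: str | None = None
    column_map: dict | None = None
    cue_levels: tuple | None = None
    delimiter: str | None = None
    exclusions: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    mediators: tuple[str, ...] = ("belief",)
    mediator_kinds: dict | None = None
    alpha: float = 0.05
    mc_draws: int = 10_000
    seed: int | None = None
    gate_policy: str = "warn"
    run_moderation: bool = True
    run_model_comparison: bool = False
    output_dir: str | None = None

    def __post_init__(self):
        if self.gate_policy not in ("enforce", "warn"):
            raise ValueError("gate_policy must be 'enforce' or 'warn'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mediators"] = list(self.mediators)
        d["cue_levels"] = list(self.cue_levels) if self.cue_levels else None
        return d


def _jsonable(obj):
    import numpy as _np

    if isinstance(obj, (_np.floating, _np.integer)):
        return obj.item()
    if isinstance(obj, _np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


@dataclass
class WorkflowReport:
    """Bundled results with full provenance.

    When the gate fails under ``enforce``, only the gate section is
    populated and ``stopped_reason`` explains why.
    """

    gate: dict | None
    gate_decision: str
    stopped_reason: str | None
    centering: dict | None
    mediation: dict | None
    moderation: dict | None
    equivalence: dict | None
    model_comparison: dict | None
    warnings: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        # canonicalize to pure JSON types (tuples -> lists, numpy scalars
        # -> python) so parse -> serialize -> parse is lossless
        return json.loads(json.dumps(asdict(self), default=_jsonable))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "WorkflowReport":
        return cls(**json.loads(text))


def _load_table(config: WorkflowConfig, table: TrialTable | None) -> TrialTable:
    if table is not None:
        return table
    if config.input is None:
        raise BeliefmedError("no input table or path provided")
    return read_trials(config.input, column_map=config.column_map,
                       cue_levels=config.cue_levels, delimiter=config.delimiter)


def run_recommended_workflow(config: WorkflowConfig,
                             table: TrialTable | None = None) -> WorkflowReport:
    """Execute gate -> centering -> mediation (-> moderation/equivalence
    -> model comparison) and bundle everything with provenance."""
    captured: list[str] = []
    table = _load_table(config, table)
    clean, excl_log = apply_exclusions(table, config.exclusions)

    provenance = {
        "package": "beliefmed",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_trials_read": int(len(table.df)),
        "n_trials_excluded": int(excl_log.n_excluded),
        "exclusion_counts": {str(k): int(v) for k, v in excl_log.counts.items()},
    }

    # (a) the gate
    gate_dict = None
    gate_decision = "not_evaluated"
    try:
        gate = paired_t_test(summarize_participants(clean), alpha=config.alpha)
        gate_dict = gate.to_dict()
        gate_decision = "pass" if gate.significant else "fail"
    except (BeliefStructureError, UndefinedStatisticError) as err:
        captured.append(f"gate not evaluable: {err}")

    if gate_decision == "fail" and config.gate_policy == "enforce":
        reason = (
            "paired t-test gate failed (p = "
            f"{gate_dict['p']:.4f} >= alpha = {config.alpha}): the cue does not "
            "significantly affect belief predictions at the participant level, so "
            "item-level mediation through beliefs was not run (Type I protection)"
        )
        return WorkflowReport(
            gate=gate_dict, gate_decision=gate_decision, stopped_reason=reason,
            centering=None, mediation=None, moderation=None, equivalence=None,
            model_comparison=None, warnings=captured, provenance=provenance,
        )
    if gate_decision == "fail":
        captured.append("gate failed but gate_policy='warn': mediation results are "
                        "reported; path-a inference is anti-conservative")

    # (b) centering summary (the mediation call re-centers internally)
    to_center = ["cue", *config.mediators]
    centered = group_mean_center(clean, to_center)
    cent = {}
    inc = centered.included_df
    for var in to_center:
        worst = inc.groupby("participant")[f"{var}_c"].mean().abs().max()
        cent[var] = {"max_abs_participant_mean": float(worst)}

    # (c) mediation
    kinds = dict(_DEFAULT_KINDS)
    if config.mediator_kinds:
        kinds.update(config.mediator_kinds)
    meds = tuple(Mediator(m, kinds.get(m, ITEM_VARYING)) for m in config.mediators)
    med_cfg = MediationConfig(mediators=meds, mc_draws=config.mc_draws,
                              seed=config.seed, alpha=config.alpha,
                              exclusions=config.exclusions)
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        med = mediate(table, med_cfg)
    captured += [str(w.message) for w in wlist]

    moderation_dict = equivalence_dict = None
    if config.run_moderation:
        try:
            # match the random structure the mediation outcome model
            # retained, so the two models stay comparable
            mod = fit_moderation(table, exclusions=config.exclusions,
                                 alpha=config.alpha,
                                 random_terms=matched_random_terms(med))
            moderation_dict = mod.to_dict()
            if "belief" in med.retained_random_b_slopes:
                captured.append(
                    "equivalence not checked: the mediation outcome model retained "
                    "a random belief slope, which the moderation model cannot express"
                )
            elif "belief" in [m.name for m in meds]:
                equivalence_dict = check_equivalence(
                    med, mod, tol=1e-2, relative=False).to_dict()
        except (DegenerateDesignError, BeliefStructureError) as err:
            captured.append(f"moderation skipped: {err}")

    comparison_dict = None
    if config.run_model_comparison and "belief" in [m.name for m in meds]:
        comparison_dict = compare_random_slope_b(table, med_cfg).to_dict()

    report = WorkflowReport(
        gate=gate_dict, gate_decision=gate_decision, stopped_reason=None,
        centering=cent, mediation=med.to_dict(), moderation=moderation_dict,
        equivalence=equivalence_dict, model_comparison=comparison_dict,
        warnings=captured, provenance=provenance,
    )
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "workflow_report.json")
        med.to_table().to_csv(outdir / "mediation_table.csv", index=False)
        excl_log.to_csv(outdir / "exclusion_log.csv")
    return report
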