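"""Within-participant multilevel (1-1-1) mediation of cue effects on JOLs.

The cue (two levels, coded +1/-1) affects the trial-level judgment of
learning both directly (path c') and through one or two mediators: the
participant's global belief-based prediction and/or per-trial
processing fluency (log study time).  Path *a* regresses the
group-mean-centered mediator on the centered cue; the outcome model
regresses the JOL on the centered cue and mediator(s).  Random-effect
policy follows the nature of each mediator:

* a *global* mediator is constant within participant x cue level, so
  its path-a regression carries no random intercept (the centered mean
  is identically zero) and no random cue slope (it would be perfectly
  confounded with the residual);
* an *item-varying* mediator (fluency) keeps the random cue slope on
  path a;
* the outcome model starts maximal (random intercept + slopes for the
  cue and every mediator, diagonal covariance) and unsupported random
  terms are pruned.

The indirect effect is ``IND = a*b + cov(a_j, b_j)``; with a fixed
path-a slope the covariance term is structurally zero but is always
reported.  Inference for IND uses Monte-Carlo intervals on the product
of two independent normals (and a first-order Sobel z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    CenteredTrialTable,
    ExclusionLog,
    ExclusionPolicy,
    PairedTestResult,
    TrialTable,
    apply_exclusions,
    group_mean_center,
    paired_t_test,
    summarize_participants,
)
from .exceptions import BeliefmedError, BeliefStructureError, UndefinedStatisticError
from .lmm import INTERCEPT, LmmFit, LmmSpec, ModelComparison, fit_lmm, information_criteria, prune_random_effects

GLOBAL = "global"
ITEM_VARYING = "item_varying"
#: default mediator kinds by conventional column name
_DEFAULT_KINDS = {"belief": GLOBAL, "fluency": ITEM_VARYING}


@dataclass(frozen=True)
class Mediator:
    name: str
    kind: str = GLOBAL

    def __post_init__(self):
        if self.kind not in (GLOBAL, ITEM_VARYING):
            raise ValueError(f"mediator kind must be {GLOBAL!r} or {ITEM_VARYING!r}")


@dataclass
class MediationConfig:
    """Configuration for a mediation run.

    ``mediators`` holds 1-2 :class:`Mediator` entries; ``mc_draws``
    Monte-Carlo draws (>= 1000) are used for the indirect-effect CI at
    level ``1 - alpha``.
    """

    mediators: tuple[Mediator, ...] = (Mediator("belief", GLOBAL),)
    mc_draws: int = 10_000
    seed: int | None = None
    alpha: float = 0.05
    random_policy: str = "maximal"
    random_b_slopes: bool = True
    exclusions: ExclusionPolicy = field(default_factory=ExclusionPolicy)

    def __post_init__(self):
        if not 1 <= len(self.mediators) <= 2:
            raise ValueError("between one and two mediators are supported")
        if self.mc_draws < 1000:
            raise ValueError("mc_draws must be at least 1000")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# inference primitives


def monte_carlo_ci(a: float, se_a: float, b: float, se_b: float,
                   draws: int = 10_000, seed: int | None = None,
                   alpha: float = 0.05) -> tuple[float, float]:
    """Monte-Carlo interval for the product of two normal estimates.

    Draws independent ``N(a, se_a^2)`` and ``N(b, se_b^2)`` samples and
    returns the empirical (alpha/2, 1-alpha/2) quantiles of their
    product.  Seeded runs are identical.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    rng = np.random.default_rng(seed)
    prod = rng.normal(a, se_a, draws) * rng.normal(b, se_b, draws)
    lo, hi = np.quantile(prod, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def sobel_z(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """First-order Sobel statistic ``ab / sqrt(a^2 se_b^2 + b^2 se_a^2)``
    with a two-sided normal p value."""
    denom = np.sqrt(a * a * se_b * se_b + b * b * se_a * se_a)
    if denom == 0.0:
        raise UndefinedStatisticError("Sobel denominator is zero (a=b=0 or zero SEs)")
    z = a * b / denom
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def proportion_mediated(ind: float, total: float,
                        tol: float = 1e-12) -> tuple[float, bool]:
    """Indirect effect over total effect, with a suppression flag.

    The flag is set when the total effect is ~0 or the indirect effect
    has the opposite sign of the total (an inconsistent/suppression
    pattern), in which case the printed fraction is not interpretable
    as a proportion.  The value is never clamped.
    """
    if abs(total) < tol:
        return float("nan"), True
    prop = ind / total
    flagged = np.sign(ind) != np.sign(total) and ind != 0.0
    return float(prop), bool(flagged)


# ---------------------------------------------------------------------------
# component fits


def fit_path_a(data: CenteredTrialTable, mediator: Mediator,
               groups: str = "participant",
               random_slope: bool | None = None) -> tuple[LmmFit, list[dict]]:
    """Regress the centered mediator on the centered cue (path a).

    Global mediator: fixed slope only.  Item-varying mediator: random
    cue slope (random intercept stays suppressed — the centered mediator
    mean is identically zero per participant), pruned on failure.
    ``random_slope`` overrides the kind-based default; requesting it for
    a global mediator is refused.
    """
    outcome = f"{mediator.name}_c"
    if outcome not in data.df.columns:
        raise BeliefmedError(f"column {outcome!r} missing; center the mediator first")
    if random_slope and mediator.kind == GLOBAL:
        refuse_random_slope_for_global(mediator)
    use_slope = (mediator.kind == ITEM_VARYING) if random_slope is None else random_slope
    if not use_slope:
        spec = LmmSpec(outcome, ("cue_c",), random_terms=())
        return fit_lmm(spec, data, groups=groups), []
    spec = LmmSpec(outcome, ("cue_c",), random_terms=("cue_c",))
    final_spec, log, fit = prune_random_effects(spec, data, groups=groups)
    return fit, log


def fit_outcome_model(data: CenteredTrialTable, mediators: tuple[Mediator, ...],
                      groups: str = "participant",
                      random_b_slopes: bool = True) -> tuple[LmmFit, list[dict]]:
    """Regress the JOL on the centered cue and centered mediator(s).

    Starts from the maximal random structure (intercept + slopes for
    the cue and each mediator) and prunes random terms the data cannot
    support.  ``random_b_slopes=False`` drops the mediator slopes from
    the initial structure (used by the moderation-equivalence check).
    """
    med_cols = tuple(f"{m.name}_c" for m in mediators)
    fixed = ("cue_c", *med_cols)
    random = (INTERCEPT, "cue_c", *(med_cols if random_b_slopes else ()))
    spec = LmmSpec("jol", fixed, random_terms=random)
    final_spec, log, fit = prune_random_effects(spec, data, groups=groups)
    return fit, log


def refuse_random_slope_for_global(mediator: Mediator) -> None:
    if mediator.kind == GLOBAL:
        raise BeliefmedError(
            f"a random path-a slope for global mediator {mediator.name!r} is perfectly "
            "confounded with the residual error (the mediator is constant within "
            "participant x cue level); refusing to fit"
        )


# ---------------------------------------------------------------------------
# results


@dataclass
class MediationResults:
    """Estimates and inference from a multilevel mediation fit.

    ``paths`` has one row per mediator (a, b, indirect effect, Sobel
    and Monte-Carlo inference, proportion mediated); the direct effect
    c' and the total effect are scalars.  ``diff_ind`` (second minus
    first indirect effect) is present for two-mediator runs.
    """

    paths: pd.DataFrame
    c_prime: float
    se_cp: float
    df_cp: float
    t_cp: float
    p_cp: float
    ci_cp: tuple[float, float]
    total: float
    diff_ind: float | None
    diff_ind_ci: tuple[float, float] | None
    path_a_fits: dict[str, LmmFit]
    outcome_fit: LmmFit
    pruning_log: dict[str, list]
    exclusion_log: ExclusionLog | None
    gate: PairedTestResult | None
    config: MediationConfig
    alpha: float

    @property
    def mediator_names(self) -> list[str]:
        return list(self.paths.index)

    @property
    def retained_random_b_slopes(self) -> list[str]:
        """Mediators whose random outcome slope survived pruning."""
        return [m.name for m in self.config.mediators
                if f"{m.name}_c" in self.outcome_fit.spec.random_terms]

    def to_dict(self) -> dict:
        def clean(v):
            if v is None:
                return None
            v = float(v)
            return None if np.isnan(v) else v

        return {
            "mediators": {
                name: {k: (bool(v) if isinstance(v, (bool, np.bool_)) else clean(v))
                       for k, v in row.items()}
                for name, row in self.paths.iterrows()
            },
            "c_prime": {"estimate": clean(self.c_prime), "se": clean(self.se_cp),
                        "df": clean(self.df_cp), "t": clean(self.t_cp),
                        "p": clean(self.p_cp), "ci": [clean(x) for x in self.ci_cp]},
            "total": clean(self.total),
            "diff_ind": clean(self.diff_ind) if self.diff_ind is not None else None,
            "diff_ind_ci": ([clean(x) for x in self.diff_ind_ci]
                            if self.diff_ind_ci is not None else None),
            "gate": self.gate.to_dict() if self.gate else None,
            "pruning": self.pruning_log,
            "alpha": self.alpha,
            "seed": self.config.seed,
            "mc_draws": self.config.mc_draws,
        }

    def to_table(self) -> pd.DataFrame:
        """Delimited-friendly report: one row per effect, Table-1 style."""
        rows = []
        for name in self.paths.index:
            r = self.paths.loc[name]
            rows.append((f"a ({name})", r["a"], r["se_a"], r["df_a"], r["t_a"],
                         r["p_a"], r["ci_a_lower"], r["ci_a_upper"]))
            rows.append((f"b ({name})", r["b"], r["se_b"], r["df_b"], r["t_b"],
                         r["p_b"], r["ci_b_lower"], r["ci_b_upper"]))
        rows.append(("c'", self.c_prime, self.se_cp, self.df_cp, self.t_cp,
                     self.p_cp, *self.ci_cp))
        for name in self.paths.index:
            r = self.paths.loc[name]
            rows.append((f"IND ({name})", r["ind"], r["se_ind"], np.nan,
                         r["sobel_z"], r["sobel_p"], r["mc_lower"], r["mc_upper"]))
        return pd.DataFrame(rows, columns=["Effect", "Estimate", "SE", "df",
                                           "t or z", "p", "CI Lower", "CI Upper"])

    def summary(self) -> str:
        lines = [
            "Multilevel mediation of the cue effect on JOLs",
            f"mediators: {', '.join(f'{m.name} ({m.kind})' for m in self.config.mediators)}",
            f"n_obs = {self.outcome_fit.n_obs}, participants = {self.outcome_fit.n_clusters}",
            "",
            self.to_table().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            f"total effect = {self.total:.4f}",
        ]
        for name in self.paths.index:
            r = self.paths.loc[name]
            tag = " [suppression]" if r["suppression"] else ""
            lines.append(f"proportion mediated ({name}) = {r['prop_med']:.3f}{tag}")
        if self.diff_ind is not None:
            lo, hi = self.diff_ind_ci
            lines.append(f"Diff_IND (2nd - 1st) = {self.diff_ind:.4f}, "
                         f"{100 * (1 - self.alpha):.0f}% CI [{lo:.4f}, {hi:.4f}]")
        for stage, log in self.pruning_log.items():
            for entry in log:
                lines.append(f"pruned in {stage}: {entry['term']} ({entry['reason']})")
        if self.gate is not None:
            verdict = "significant" if self.gate.significant else "NOT significant"
            lines.append(f"gate: paired t({self.gate.df}) = {self.gate.t:.3f}, "
                         f"p = {self.gate.p:.4f} ({verdict})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the model object


class MultilevelMediation:
    """Multilevel mediation model for trial-level judgment data.

    Parameters
    ----------
    table
        A :class:`TrialTable` (exclusions are applied during ``fit``).
    mediators
        Mediator names, e.g. ``("belief",)`` or ``("belief", "fluency")``.
        Kinds default to global for ``belief`` and item-varying for
        ``fluency``; override with ``mediator_kinds``.
    config
        Full :class:`MediationConfig`; overrides the other arguments.
    """

    def __init__(self, table: TrialTable, mediators=("belief",),
                 mediator_kinds: dict[str, str] | None = None,
                 config: MediationConfig | None = None):
        self.table = table
        if config is None:
            kinds = dict(_DEFAULT_KINDS)
            if mediator_kinds:
                kinds.update(mediator_kinds)
            meds = tuple(Mediator(m, kinds.get(m, ITEM_VARYING)) for m in mediators)
            config = MediationConfig(mediators=meds)
        self.config = config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "MultilevelMediation":
        mediators = kw.pop("mediators", ("belief",))
        return cls(TrialTable(df), mediators=mediators, **kw)

    def fit(self, mc_draws: int | None = None, seed: int | None = None,
            alpha: float | None = None) -> MediationResults:
        cfg = self.config
        if mc_draws is not None or seed is not None or alpha is not None:
            cfg = replace(cfg,
                          mc_draws=mc_draws if mc_draws is not None else cfg.mc_draws,
                          seed=seed if seed is not None else cfg.seed,
                          alpha=alpha if alpha is not None else cfg.alpha)
        return mediate(self.table, cfg)


def mediate(table: TrialTable, config: MediationConfig | None = None) -> MediationResults:
    """End-to-end mediation: exclusions, centering, fits, Eq-style
    indirect effects, Monte-Carlo CIs.

    The paired t-test gate on the global belief mediator is evaluated
    and reported; a non-significant gate raises a warning here (the CLI
    workflow can enforce it as an error).
    """
    config = config or MediationConfig()
    clean, excl_log = apply_exclusions(table, config.exclusions)

    gate = None
    if any(m.kind == GLOBAL for m in config.mediators):
        try:
            gate = paired_t_test(summarize_participants(clean), alpha=config.alpha)
            if not gate.significant:
                warnings.warn(
                    "paired t-test gate: the cue effect on beliefs is not significant "
                    f"(p = {gate.p:.4f}); item-level path-a inference is anti-conservative",
                    stacklevel=2,
                )
        except (BeliefStructureError, UndefinedStatisticError) as err:
            warnings.warn(f"gate could not be evaluated: {err}", stacklevel=2)

    to_center = ["cue"] + [m.name for m in config.mediators]
    centered = group_mean_center(clean, to_center)

    ss = np.random.SeedSequence(config.seed)
    child = iter(ss.spawn(len(config.mediators) + 1))

    path_a_fits: dict[str, LmmFit] = {}
    pruning: dict[str, list] = {}
    rows = []
    for m in config.mediators:
        a_fit, a_log = fit_path_a(centered, m)
        path_a_fits[m.name] = a_fit
        if a_log:
            pruning[f"path_a ({m.name})"] = a_log

    out_fit, out_log = fit_outcome_model(centered, config.mediators,
                                         random_b_slopes=config.random_b_slopes)
    if out_log:
        pruning["outcome"] = out_log

    c_row = out_fit.params.loc["cue_c"]
    c_prime = float(c_row["Estimate"])

    inds = []
    for m in config.mediators:
        a_row = path_a_fits[m.name].params.loc["cue_c"]
        b_row = out_fit.params.loc[f"{m.name}_c"]
        a, se_a = float(a_row["Estimate"]), float(a_row["SE"])
        b, se_b = float(b_row["Estimate"]), float(b_row["SE"])
        cov_ab = 0.0  # fixed path-a slope / diagonal covariance: no a_j-b_j covariance
        ind = a * b + cov_ab
        inds.append((m, a, se_a, b, se_b, cov_ab, ind, a_row, b_row))

    total = sum(x[6] for x in inds) + c_prime

    for (m, a, se_a, b, se_b, cov_ab, ind, a_row, b_row) in inds:
        try:
            z, zp = sobel_z(a, se_a, b, se_b)
            se_ind = abs(a * b / z) if z != 0 else np.nan
        except UndefinedStatisticError:
            z, zp, se_ind = np.nan, np.nan, np.nan
        mc_lo, mc_hi = monte_carlo_ci(a, se_a, b, se_b, config.mc_draws,
                                      seed=next(child), alpha=config.alpha)
        prop, flagged = proportion_mediated(ind, total)
        rows.append({
            "a": a, "se_a": se_a, "df_a": float(a_row["df"]),
            "t_a": float(a_row["t"]), "p_a": float(a_row["p"]),
            "ci_a_lower": float(a_row["CI Lower"]), "ci_a_upper": float(a_row["CI Upper"]),
            "b": b, "se_b": se_b, "df_b": float(b_row["df"]),
            "t_b": float(b_row["t"]), "p_b": float(b_row["p"]),
            "ci_b_lower": float(b_row["CI Lower"]), "ci_b_upper": float(b_row["CI Upper"]),
            "cov_ab": cov_ab, "ind": ind, "se_ind": se_ind,
            "sobel_z": z, "sobel_p": zp, "mc_lower": mc_lo, "mc_upper": mc_hi,
            "prop_med": prop, "suppression": flagged,
        })
    paths = pd.DataFrame(rows, index=pd.Index([m.name for m in config.mediators],
                                              name="mediator"))

    diff_ind = diff_ci = None
    if len(config.mediators) == 2:
        diff_ind, diff_ci = _diff_ind(paths, config.mc_draws, next(child), config.alpha)

    return MediationResults(
        paths=paths, c_prime=c_prime, se_cp=float(c_row["SE"]),
        df_cp=float(c_row["df"]), t_cp=float(c_row["t"]), p_cp=float(c_row["p"]),
        ci_cp=(float(c_row["CI Lower"]), float(c_row["CI Upper"])),
        total=float(total), diff_ind=diff_ind, diff_ind_ci=diff_ci,
        path_a_fits=path_a_fits, outcome_fit=out_fit, pruning_log=pruning,
        exclusion_log=excl_log, gate=gate, config=config, alpha=config.alpha,
    )


def _diff_ind(paths: pd.DataFrame, draws: int, seed, alpha: float):
    r1, r2 = paths.iloc[0], paths.iloc[1]
    rng = np.random.default_rng(seed)
    p1 = rng.normal(r1["a"], r1["se_a"], draws) * rng.normal(r1["b"], r1["se_b"], draws)
    p2 = rng.normal(r2["a"], r2["se_a"], draws) * rng.normal(r2["b"], r2["se_b"], draws)
    diff = p2 - p1
    lo, hi = np.quantile(diff, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(r2["ind"] - r1["ind"]), (float(lo), float(hi))


def compare_mediators(result: MediationResults, draws: int | None = None,
                      seed: int | None = None) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo contrast of the two indirect effects (second - first)."""
    if len(result.paths) != 2:
        raise ValueError("mediator comparison requires exactly two fitted mediators")
    draws = draws or result.config.mc_draws
    return _diff_ind(result.paths, draws, seed, result.alpha)


def compare_random_slope_b(table: TrialTable, config: MediationConfig | None = None,
                           mediator: str = "belief") -> ModelComparison:
    """BIC comparison (ML) of the outcome model with vs without the
    random slope for the belief effect on JOLs.

    The with-slope entry is flagged unusable when that random effect
    cannot be estimated from the data.
    """
    config = config or MediationConfig()
    clean, _ = apply_exclusions(table, config.exclusions)
    to_center = ["cue"] + [m.name for m in config.mediators]
    centered = group_mean_center(clean, to_center)
    med_cols = tuple(f"{m.name}_c" for m in config.mediators)
    fixed = ("cue_c", *med_cols)
    with_spec = LmmSpec("jol", fixed, (INTERCEPT, "cue_c", f"{mediator}_c"))
    without_spec = LmmSpec("jol", fixed, (INTERCEPT, "cue_c"))
    entries = [
        information_criteria(with_spec, centered, label=f"random {mediator} slope"),
        information_criteria(without_spec, centered, label=f"no random {mediator} slope"),
    ]
    return ModelComparison(entries=entries)
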