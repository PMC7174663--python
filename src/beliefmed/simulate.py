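"""Synthetic data generation and the Type I / Type II error study.

Two generators live here.  :func:`simulate_belief_datasets` reproduces
the design of the error-rate study: per participant one global belief
prediction per cue level, drawn from normal distributions (null: both
levels N(50, 10^2); alternative: level 1 N(60, 10^2) vs level 2
N(50, 10^2)), each replicated ``trials_per_level`` times at the item
level.  :func:`run_error_rate_study` contrasts, per simulated dataset,
the participant-level paired t-test with the item-level regression of
group-mean-centered beliefs on the +-1 cue (fixed slope only, no random
effects) — the path-a fit of the mediation model.  Replicating a
participant-level prediction T times shrinks the naive item-level
standard error by about sqrt(T), so the item-level test rejects a true
null far more often than its nominal level; the study quantifies that
inflation and the power gained under a real effect.

:func:`generate_mediation_dataset` is the repository's fixture factory:
it instantiates the full mediation data-generating process (fixed
a/b/c', random intercept and slopes, residual noise, optional per-trial
fluency acting as a second mediator) and returns the generating truth
for parameter-recovery studies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .data import TrialTable, paired_t_test, group_mean_center, summarize_participants
from .exceptions import UndefinedStatisticError
from .lmm import LmmSpec, fit_lmm


@dataclass(frozen=True)
class SimDesign:
    """Design of one error-rate experiment (defaults: the null design)."""

    n_participants: int = 30
    trials_per_level: int = 20
    mean_level1: float = 50.0
    mean_level2: float = 50.0
    sd: float = 10.0
    n_reps: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    truncate: bool = False  # clip beliefs to [0, 100] (off: the draws are untruncated)

    def __post_init__(self):
        if self.n_participants < 1 or self.trials_per_level < 1:
            raise ValueError("counts must be positive")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    @classmethod
    def null(cls, **kw) -> "SimDesign":
        return cls(mean_level1=50.0, mean_level2=50.0, **kw)

    @classmethod
    def alternative(cls, **kw) -> "SimDesign":
        return cls(mean_level1=60.0, mean_level2=50.0, **kw)


def _belief_table(design: SimDesign, rng: np.random.Generator) -> TrialTable:
    J, T = design.n_participants, design.trials_per_level
    b1 = rng.normal(design.mean_level1, design.sd, J)
    b2 = rng.normal(design.mean_level2, design.sd, J)
    if design.truncate:
        b1, b2 = np.clip(b1, 0, 100), np.clip(b2, 0, 100)
    pid = np.repeat([f"p{j:03d}" for j in range(J)], 2 * T)
    cue = np.tile(np.repeat([1.0, -1.0], T), J)
    belief = np.repeat(np.column_stack([b1, b2]).ravel(), T)
    df = pd.DataFrame({
        "participant": pid, "cue": cue, "belief": belief,
        "jol": np.nan,  # the error study concerns beliefs only
    })
    return TrialTable(df)


def simulate_belief_datasets(design: SimDesign) -> Iterator[TrialTable]:
    """Yield ``design.n_reps`` independent belief datasets.

    Each replicate uses its own child stream of the master seed, so a
    given replicate is reproducible independently of how many of its
    predecessors were consumed.
    """
    children = np.random.SeedSequence(design.seed).spawn(design.n_reps)
    for child in children:
        yield _belief_table(design, np.random.default_rng(child))


@dataclass
class SimReport:
    """Rejection-rate summary of one error-rate experiment."""

    design: SimDesign
    reject_rate_ttest: float
    n_reject_ttest: int
    reject_rate_item_model: float
    n_reject_item_model: int
    conditional_item_reject_given_ttest_ns: float
    n_conditional_numerator: int
    n_conditional_denominator: int
    per_rep: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self, include_reps: bool = False) -> dict:
        out = {
            "design": asdict(self.design),
            "n_reps": self.design.n_reps,
            "reject_rate_ttest": self.reject_rate_ttest,
            "n_reject_ttest": self.n_reject_ttest,
            "reject_rate_item_model": self.reject_rate_item_model,
            "n_reject_item_model": self.n_reject_item_model,
            "conditional_item_reject_given_ttest_ns":
                self.conditional_item_reject_given_ttest_ns,
            "n_conditional_numerator": self.n_conditional_numerator,
            "n_conditional_denominator": self.n_conditional_denominator,
        }
        if include_reps:
            out["per_rep"] = self.per_rep.to_dict(orient="list")
        return out

    def to_json(self, path, **kw) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(**kw), fh, indent=2)

    def summary(self) -> str:
        d = self.design
        kind = "null" if d.mean_level1 == d.mean_level2 else "alternative"
        lines = [
            f"Error-rate study ({kind} design): {d.n_participants} participants x "
            f"{2 * d.trials_per_level} trials, {d.n_reps} replicates, alpha = {d.alpha}",
            f"paired t-test rejections:  {self.n_reject_ttest}/{d.n_reps} "
            f"({100 * self.reject_rate_ttest:.1f}%)",
            f"item-level model rejections: {self.n_reject_item_model}/{d.n_reps} "
            f"({100 * self.reject_rate_item_model:.1f}%)",
            f"item-level rejections among t-test non-significant: "
            f"{self.n_conditional_numerator}/{self.n_conditional_denominator} "
            f"({100 * self.conditional_item_reject_given_ttest_ns:.1f}%)",
        ]
        return "\n".join(lines)


def run_error_rate_study(design: SimDesign) -> SimReport:
    """Run the paired-t vs item-level-model comparison over all reps.

    The item-level test is the mediation path-a fit: group-mean-centered
    beliefs regressed on the +-1 cue with a fixed intercept and slope
    and no random effects (OLS with residual df).
    """
    records = []
    spec = LmmSpec("belief_c", ("cue_c",), random_terms=())
    for table in simulate_belief_datasets(design):
        tres = paired_t_test(summarize_participants(table), alpha=design.alpha)
        centered = group_mean_center(table, ["cue", "belief"])
        fit = fit_lmm(spec, centered)
        row = fit.params.loc["cue_c"]
        records.append((tres.mean_diff, tres.t, tres.p,
                        float(row["Estimate"]), float(row["t"]), float(row["p"])))
    per_rep = pd.DataFrame(records, columns=["mean_diff", "t_ttest", "p_ttest",
                                             "item_slope", "t_item", "p_item"])
    alpha = design.alpha
    rej_t = per_rep["p_ttest"] < alpha
    rej_i = per_rep["p_item"] < alpha
    ns_t = ~rej_t
    denom = int(ns_t.sum())
    numer = int((ns_t & rej_i).sum())
    return SimReport(
        design=design,
        reject_rate_ttest=float(rej_t.mean()),
        n_reject_ttest=int(rej_t.sum()),
        reject_rate_item_model=float(rej_i.mean()),
        n_reject_item_model=int(rej_i.sum()),
        conditional_item_reject_given_ttest_ns=(numer / denom if denom else float("nan")),
        n_conditional_numerator=numer,
        n_conditional_denominator=denom,
        per_rep=per_rep,
    )


def export_example_reps(null_design: SimDesign, alt_design: SimDesign,
                        out_prefix: str) -> list[str]:
    """Write one null and one alternative replicate with both tests'
    statistics as delimited text; returns the written paths."""
    paths = []
    for tag, design in (("null", null_design), ("alternative", alt_design)):
        table = next(simulate_belief_datasets(replace(design, n_reps=1)))
        report = run_error_rate_study(replace(design, n_reps=1))
        data_path = f"{out_prefix}_{tag}_data.csv"
        stats_path = f"{out_prefix}_{tag}_stats.csv"
        table.df[["participant", "cue", "belief"]].to_csv(data_path, index=False)
        report.per_rep.to_csv(stats_path, index=False)
        paths += [data_path, stats_path]
    return paths


# ---------------------------------------------------------------------------
# the mediation-dataset generator


@dataclass(frozen=True)
class SynthTruth:
    """Generating parameters for a synthetic mediation dataset.

    Units: beliefs and JOLs in percent; the cue is +-1, so the fixed
    path a means the expected belief difference between levels is 2a.
    Fluency is generated on the log-seconds scale (stored as raw
    seconds) with a per-level mean shift of 2 x ``fluency_cue_effect``.
    """

    a: float = 5.0
    b: float = 0.4
    c_prime: float = 2.0
    intercept: float = 50.0
    sd_intercept: float = 10.0
    sd_b_slope: float = 0.2
    sd_c_slope: float = 1.0
    sd_residual: float = 10.0
    belief_mean: float = 50.0
    sd_belief_between: float = 10.0
    sd_belief_within_level: float = 5.0
    include_fluency: bool = False
    fluency_log_mean: float = 0.1       # mean log study time (seconds)
    fluency_cue_effect: float = -0.1    # per +-1 unit of cue, on log seconds
    sd_fluency_cue_slope: float = 0.05
    fluency_sd: float = 0.3             # trial-level log-ST noise
    fluency_b: float = -5.0             # fluency -> JOL slope (per log second)
    sd_fluency_b_slope: float = 1.0
    clip_jol: bool = False

    def __post_init__(self):
        for name in ("sd_intercept", "sd_b_slope", "sd_c_slope", "sd_residual",
                     "sd_belief_between", "sd_belief_within_level",
                     "sd_fluency_cue_slope", "fluency_sd", "sd_fluency_b_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def generate_mediation_dataset(
    truth: SynthTruth | None = None,
    n_participants: int = 30,
    trials_per_level: int = 20,
    seed=None,
    missing_rate: float = 0.0,
) -> tuple[TrialTable, SynthTruth]:
    """Draw one dataset from the mediation data-generating process.

    Per participant: global beliefs per cue level around a participant
    base rate, a random intercept and random b / c' slopes around the
    fixed values, and trial-level residual noise.  JOLs are built from
    the *balanced* centered predictors; ``missing_rate`` then deletes
    completed trials at random (at least one trial per level always
    survives), emulating missing-at-random JOL loss.

    Returns the table and the truth record for recovery studies.
    """
    truth = truth or SynthTruth()
    rng = np.random.default_rng(seed)
    J, T = n_participants, trials_per_level
    frames = []
    n_clipped = 0
    for j in range(J):
        base = rng.normal(truth.belief_mean, truth.sd_belief_between)
        b1 = base + truth.a + rng.normal(0, truth.sd_belief_within_level)
        b2 = base - truth.a + rng.normal(0, truth.sd_belief_within_level)
        u0 = rng.normal(0, truth.sd_intercept)
        bj = truth.b + rng.normal(0, truth.sd_b_slope)
        cj = truth.c_prime + rng.normal(0, truth.sd_c_slope)
        cue = np.repeat([1.0, -1.0], T)
        belief = np.where(cue > 0, b1, b2)
        belief_c = belief - belief.mean()
        jol = (truth.intercept + u0 + bj * belief_c + cj * cue
               + rng.normal(0, truth.sd_residual, 2 * T))
        frame = {
            "participant": f"p{j:03d}", "cue": cue, "belief": belief, "jol": None,
        }
        if truth.include_fluency:
            aj_f = truth.fluency_cue_effect + rng.normal(0, truth.sd_fluency_cue_slope)
            log_st = (truth.fluency_log_mean + aj_f * cue
                      + rng.normal(0, truth.fluency_sd, 2 * T))
            bj_f = truth.fluency_b + rng.normal(0, truth.sd_fluency_b_slope)
            jol = jol + bj_f * (log_st - log_st.mean())
            frame["fluency"] = np.exp(log_st)  # stored as raw seconds
        if truth.clip_jol:
            n_clipped += int(((jol < 0) | (jol > 100)).sum())
            jol = np.clip(jol, 0.0, 100.0)
        frame["jol"] = jol
        frames.append(pd.DataFrame(frame))
    df = pd.concat(frames, ignore_index=True)
    if truth.clip_jol and n_clipped > 0.05 * len(df):
        import warnings
        warnings.warn(f"JOL clipping censored {n_clipped}/{len(df)} values (> 5%)",
                      stacklevel=2)
    if missing_rate:
        keep = rng.random(len(df)) > missing_rate
        for pid, sub in df.groupby("participant"):
            for lvl in (1.0, -1.0):
                idx = sub.index[sub["cue"] == lvl]
                if not keep[idx].any():
                    keep[idx[0]] = True
        df = df[keep].reset_index(drop=True)
    return TrialTable(df), truth


def example_like_table(seed=0) -> TrialTable:
    """A 17-row table mimicking the shape of the worked example: three
    participants, six trials each, one trial of the third participant
    missing.  Values are synthetic; only the layout is meaningful."""
    truth = SynthTruth(sd_belief_within_level=0.0, include_fluency=True)
    table, _ = generate_mediation_dataset(truth, n_participants=3,
                                          trials_per_level=3, seed=seed)
    df = table.df.drop(index=len(table.df) - 1).reset_index(drop=True)
    return TrialTable(df)
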