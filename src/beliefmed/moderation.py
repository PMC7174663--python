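"""Multilevel moderation of the cue effect on JOLs by belief differences.

An alternative to the mediation model used in earlier work: the JOL is
regressed on the centered cue, the per-participant belief difference
between cue levels (``DiffBelief``, a participant-level moderator) and
their interaction, with a random intercept and a random cue slope
(diagonal covariance).  Because the centered global belief equals
``DiffBelief/2 * cue`` for every trial — including participants with
unequal trial counts per level — the moderation model estimates the
same belief effect as the mediation model: the mediation direct effect
c' equals the moderation cue main effect, and the mediation path b
equals twice the interaction coefficient, whenever the mediation
outcome model carries no random belief slope.  :func:`check_equivalence`
verifies this relationship on a fitted pair of models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    ExclusionPolicy,
    TrialTable,
    apply_exclusions,
    group_mean_center,
    summarize_participants,
)
from .exceptions import DegenerateDesignError, EstimationFailureError
from .lmm import INTERCEPT, LmmFit, LmmSpec, fit_lmm, prune_random_effects
from .mediation import MediationResults

#: display names for the fixed effects, in design order
_EFFECT_NAMES = {
    "Intercept": "Intercept (r00)",
    "diff_belief": "DiffBelief (r01)",
    "cue_c": "Cue (r10)",
    "cue_x_diff_belief": "Cue x DiffBelief (r11)",
}


@dataclass
class ModerationResults:
    """Fixed and random estimates of the Cue x DiffBelief model."""

    params: pd.DataFrame
    variance_components: dict[str, float]
    residual_variance: float
    fit: LmmFit

    @property
    def r00(self) -> float:
        return float(self.params.loc["Intercept", "Estimate"])

    @property
    def r01(self) -> float:
        return float(self.params.loc["diff_belief", "Estimate"])

    @property
    def r10(self) -> float:
        """Cue main effect: the cue effect on JOLs with beliefs controlled."""
        return float(self.params.loc["cue_c", "Estimate"])

    @property
    def r11(self) -> float:
        """Cue x DiffBelief interaction: the belief moderation effect."""
        return float(self.params.loc["cue_x_diff_belief", "Estimate"])

    def to_dict(self) -> dict:
        return {
            "params": {t: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                       for t, row in self.params.iterrows()},
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "residual_variance": float(self.residual_variance),
        }

    def summary(self) -> str:
        tab = self.params.rename(index=_EFFECT_NAMES)
        lines = [
            "Multilevel moderation: JOL ~ Cue * DiffBelief",
            f"n_obs = {self.fit.n_obs}, participants = {self.fit.n_clusters}",
            "",
            tab.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "Random effects (variances):",
        ]
        for term, v in self.variance_components.items():
            lines.append(f"  {term:<12s} {v:.6f}")
        lines.append(f"  {'residual':<12s} {self.residual_variance:.6f}")
        return "\n".join(lines)


class MultilevelModeration:
    """Moderation model: JOL on centered cue, DiffBelief and their
    interaction, random intercept + random cue slope.

    ``random_cue_slope=False`` reproduces the random-intercept-only
    model of the earlier literature; it is off the default path because
    omitting the slope inflates the Type I error of the interaction.
    DiffBelief enters raw (not grand-mean-centered); this affects only
    the intercept and DiffBelief main effect, not the cue or
    interaction terms.
    """

    def __init__(self, table: TrialTable,
                 exclusions: ExclusionPolicy | None = None,
                 random_cue_slope: bool = True):
        self.table = table
        self.exclusions = exclusions if exclusions is not None else ExclusionPolicy()
        self.random_cue_slope = random_cue_slope

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "MultilevelModeration":
        return cls(TrialTable(df), **kw)

    def fit(self, alpha: float = 0.05) -> ModerationResults:
        return fit_moderation(self.table, exclusions=self.exclusions,
                              random_cue_slope=self.random_cue_slope, alpha=alpha)


def fit_moderation(table: TrialTable, exclusions: ExclusionPolicy | None = None,
                   random_cue_slope: bool = True, alpha: float = 0.05,
                   random_terms: tuple[str, ...] | None = None) -> ModerationResults:
    """Fit the Cue x DiffBelief moderation model.

    Requires the global-belief structure (DiffBelief is well defined
    per participant).  A moderator constant across participants leaves
    the main effect and interaction collinear with the intercept and
    cue columns and raises :class:`DegenerateDesignError`.

    By default the random structure starts at intercept + cue slope and
    unsupported terms are pruned (the same criteria as the mediation
    outcome model, so the two stay comparable).  Passing
    ``random_terms`` pins the structure exactly — used when matching a
    fitted mediation model for the equivalence check.
    """
    clean, _ = apply_exclusions(table, exclusions or ExclusionPolicy())
    summaries = summarize_participants(clean)  # validates global-belief structure
    diff = dict(zip(summaries["participant_id"], summaries["diff_belief"]))
    if summaries["diff_belief"].nunique() <= 1:
        raise DegenerateDesignError(
            "DiffBelief is constant across participants; the moderator main effect "
            "and interaction are not identifiable"
        )
    centered = group_mean_center(clean, ["cue"])
    df = centered.df
    df["diff_belief"] = df["participant"].map(diff)
    df["cue_x_diff_belief"] = df["cue_c"] * df["diff_belief"]

    pinned = random_terms is not None
    if not pinned:
        random_terms = (INTERCEPT, "cue_c") if random_cue_slope else (INTERCEPT,)
    spec = LmmSpec("jol", ("diff_belief", "cue_c", "cue_x_diff_belief"),
                   random_terms=tuple(random_terms))
    if pinned:
        fit = fit_lmm(spec, centered, alpha=alpha)
    else:
        final_spec, plog, fit = prune_random_effects(spec, centered)
        if alpha != 0.05:
            fit = fit_lmm(final_spec, centered, alpha=alpha)
            fit.pruned = plog
    if not fit.converged:
        raise EstimationFailureError("moderation model failed to converge")
    return ModerationResults(
        params=fit.params,
        variance_components=fit.variance_components,
        residual_variance=fit.residual_variance,
        fit=fit,
    )


def matched_random_terms(med: MediationResults) -> tuple[str, ...]:
    """Random terms of a fitted mediation outcome model that the
    moderation model can express (intercept and cue slope).  Fitting
    the moderation model with exactly these terms makes the two models
    comparable term by term."""
    return tuple(t for t in med.outcome_fit.spec.random_terms
                 if t in (INTERCEPT, "cue_c"))


@dataclass
class EquivalenceReport:
    """Side-by-side check that mediation and moderation report the same
    belief effect: c' vs the cue main effect, and b vs 2 x interaction."""

    c_prime_mediation: float
    r10_moderation: float
    abs_gap_c: float
    b_mediation: float
    two_r11: float
    abs_gap_b: float
    tol: float
    relative: bool
    passed: bool
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "c_prime_mediation": self.c_prime_mediation,
            "r10_moderation": self.r10_moderation,
            "abs_gap_c": self.abs_gap_c,
            "b_mediation": self.b_mediation,
            "two_r11": self.two_r11,
            "abs_gap_b": self.abs_gap_b,
            "tol": self.tol,
            "relative": self.relative,
            "passed": self.passed,
        }

    def summary(self) -> str:
        mode = "relative" if self.relative else "absolute"
        return (
            f"mediation c' = {self.c_prime_mediation:.6f} vs moderation cue effect "
            f"= {self.r10_moderation:.6f} (gap {self.abs_gap_c:.2e})\n"
            f"mediation b = {self.b_mediation:.6f} vs 2 x interaction "
            f"= {self.two_r11:.6f} (gap {self.abs_gap_b:.2e})\n"
            f"{'PASS' if self.passed else 'FAIL'} at {mode} tolerance {self.tol:g}"
        )


def check_equivalence(med: MediationResults, mod: ModerationResults,
                      tol: float = 1e-6, relative: bool = True,
                      mediator: str = "belief") -> EquivalenceReport:
    """Assert the mediation/moderation correspondence on fitted results.

    Precondition: the mediation outcome model must not have retained a
    random slope for the belief effect on JOLs — with that slope the
    two models are genuinely different (the moderation model has no
    analogue of it) and no equality is expected.
    """
    if mediator in med.retained_random_b_slopes:
        raise EstimationFailureError(
            "the mediation outcome model retained a random slope for the belief "
            "effect on JOLs; the moderation model has no such term and the two "
            "models are then inequivalent — refit mediation with "
            "random_b_slopes=False to compare"
        )
    c_med = med.c_prime
    b_med = float(med.paths.loc[mediator, "b"])
    gap_c = abs(c_med - mod.r10)
    gap_b = abs(b_med - 2.0 * mod.r11)
    if relative:
        ok_c = gap_c <= tol * max(abs(c_med), abs(mod.r10), 1e-12)
        ok_b = gap_b <= tol * max(abs(b_med), abs(2.0 * mod.r11), 1e-12)
    else:
        ok_c, ok_b = gap_c <= tol, gap_b <= tol
    return EquivalenceReport(
        c_prime_mediation=c_med, r10_moderation=mod.r10, abs_gap_c=gap_c,
        b_mediation=b_med, two_r11=2.0 * mod.r11, abs_gap_b=gap_b,
        tol=tol, relative=relative, passed=bool(ok_c and ok_b),
    )
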