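"""Long-format trial tables for cue / belief / fluency / JOL designs.

The central container is :class:`TrialTable`: one row per participant x
item, with a two-level cue coded +1 / -1, a global belief-based
prediction (percent), an optional per-trial fluency measure (self-paced
study time in seconds), and the judgment of learning (JOL, percent).
Operations cover reading delimited text, trial exclusions, natural-log
transformation and trimming of study times, participant-level summaries
(the per-participant belief difference ``DiffBelief``), the paired
t-test used as the Type-I-error gate, and group-mean centering, which
isolates within-participant effects by subtracting each participant's
own mean from every trial.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    BeliefStructureError,
    ParseError,
    SchemaError,
    UndefinedStatisticError,
    UnsupportedDesignError,
)

#: default column names, matching the layout of a typical long-format
#: export (SubID, Cue, Belief, ST, JOL)
DEFAULT_COLUMNS = {
    "participant": "SubID",
    "cue": "Cue",
    "belief": "Belief",
    "fluency": "ST",
    "jol": "JOL",
}

CUE_LEVEL1 = 1.0
CUE_LEVEL2 = -1.0


class TrialTable:
    """Long-format trial records with exclusion provenance.

    Wraps a :class:`pandas.DataFrame` with canonical columns
    ``participant, cue, belief, fluency, jol, included, reason``.
    ``cue`` is always coded +1 (level 1) / -1 (level 2).
    """

    _CORE = ["participant", "cue", "belief", "fluency", "jol", "included", "reason"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("participant", "cue", "belief", "jol") if c not in df.columns]
        if missing:
            raise SchemaError(f"trial table missing canonical columns: {missing}")
        df = df.copy()
        if "fluency" not in df.columns:
            df["fluency"] = np.nan
        if "included" not in df.columns:
            df["included"] = True
        if "reason" not in df.columns:
            df["reason"] = None
        self.df = df.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def included_df(self) -> pd.DataFrame:
        return self.df[self.df["included"]]

    @property
    def participants(self) -> list:
        return list(pd.unique(self.included_df["participant"]))

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def has_fluency(self) -> bool:
        return bool(self.included_df["fluency"].notna().any())

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "TrialTable":
        return type(self)(self.df.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<{type(self).__name__}: {len(self.df)} trials, "
            f"{self.n_participants} participants, "
            f"{int((~self.df['included']).sum())} excluded>"
        )


class CenteredTrialTable(TrialTable):
    """A :class:`TrialTable` carrying participant-mean-centered columns.

    Centered columns are named ``<variable>_c`` (e.g. ``cue_c``,
    ``belief_c``); per participant the mean of each centered variable
    over included trials is zero.
    """

    def __init__(self, df: pd.DataFrame, centered: tuple[str, ...] = ()):
        super().__init__(df)
        self.centered = tuple(centered)


# ---------------------------------------------------------------------------
# reading


def read_trials(
    source,
    column_map: dict[str, str] | None = None,
    cue_levels: tuple | None = None,
    delimiter: str | None = None,
) -> TrialTable:
    """Read a delimited long-format trial file into a :class:`TrialTable`.

    Parameters
    ----------
    source
        Path, file object, or string containing delimited text with a
        header row.  Comma is the default delimiter; tab is detected
        automatically when ``delimiter`` is None.
    column_map
        Mapping from canonical names (``participant, cue, belief,
        fluency, jol``) to the column names in the file.  Defaults to
        ``SubID, Cue, Belief, ST, JOL``.
    cue_levels
        Explicit ``(level1, level2)`` raw cue values; level 1 is coded
        +1 and level 2 is coded -1.  When omitted and the raw values are
        not already +-1, the sorted order is used with a warning.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)

    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    if delimiter is None:
        raw = pd.read_csv(source, sep=None, engine="python")
    else:
        raw = pd.read_csv(source, sep=delimiter)

    for canonical in ("participant", "cue", "belief", "jol"):
        if colmap[canonical] not in raw.columns:
            raise SchemaError(
                f"required column {colmap[canonical]!r} (for {canonical!r}) "
                f"not found; file has {list(raw.columns)}"
            )

    df = pd.DataFrame({"participant": raw[colmap["participant"]]})
    df["cue"] = _code_cue(raw[colmap["cue"]], cue_levels)
    for canonical in ("belief", "jol"):
        df[canonical] = _to_numeric(raw[colmap[canonical]], colmap[canonical])
    if colmap["fluency"] in raw.columns:
        df["fluency"] = _to_numeric(raw[colmap["fluency"]], colmap["fluency"])
    return TrialTable(df)


def _to_numeric(col: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    bad = col.notna() & out.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {col.iloc[row]!r} in column {name!r} at row {row}",
            row=row,
            column=name,
        )
    return out


def _code_cue(raw: pd.Series, cue_levels: tuple | None) -> pd.Series:
    values = pd.unique(raw.dropna())
    if len(values) < 2:
        raise UnsupportedDesignError(
            f"cue column has {len(values)} distinct level(s); a two-level contrast is required"
        )
    if len(values) > 2:
        raise UnsupportedDesignError(
            f"cue column has {len(values)} levels ({list(values)}); only two-level designs are supported"
        )
    if cue_levels is not None:
        lv1, lv2 = cue_levels
        if set(values) != {lv1, lv2}:
            raise UnsupportedDesignError(
                f"declared cue levels {cue_levels} do not match data levels {list(values)}"
            )
    else:
        numeric = pd.to_numeric(pd.Series(values), errors="coerce")
        if not numeric.isna().any() and set(numeric) == {1.0, -1.0}:
            return pd.to_numeric(raw).astype(float)  # already coded; identity
        lv1, lv2 = sorted(values)
        warnings.warn(
            f"cue levels not declared; using sorted order: {lv1!r}=+1, {lv2!r}=-1",
            stacklevel=3,
        )
    return raw.map({lv1: CUE_LEVEL1, lv2: CUE_LEVEL2}).astype(float)


# ---------------------------------------------------------------------------
# exclusions


@dataclass
class ExclusionPolicy:
    """Trial exclusion rules.

    JOL rules drop missing JOLs and JOLs outside ``jol_range``.  The
    fluency rule (active only when a fluency column is present) drops
    study times below ``fluency_min_seconds`` (default 200 ms) or above
    the participant's own mean plus ``fluency_sd_multiplier`` standard
    deviations, then natural-log transforms the surviving study times
    (the raw values are preserved in a ``fluency_raw`` column).
    """

    exclude_jol: bool = True
    jol_range: tuple[float, float] = (0.0, 100.0)
    exclude_fluency: bool = True
    fluency_min_seconds: float = 0.2
    fluency_sd_multiplier: float = 3.0
    log_transform_fluency: bool = True


@dataclass
class ExclusionLog:
    entries: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)
    dropped_participants: list = field(default_factory=list)
    fluency_logged: bool = False

    def to_csv(self, path_or_buf, **kw) -> None:
        self.entries.to_csv(path_or_buf, index=False, **kw)

    @property
    def n_excluded(self) -> int:
        return len(self.entries)


def apply_exclusions(
    table: TrialTable, rules: ExclusionPolicy | None = None
) -> tuple[TrialTable, ExclusionLog]:
    """Mark trials failing the active rules as excluded, with reasons.

    Returns a new table; the input is not modified.  A participant left
    with zero included trials in one cue level has all remaining trials
    excluded (reason ``missing_cue_level``) and is recorded in the log,
    since every model in this package needs the within-participant cue
    contrast.
    """
    if len(table.df) == 0:
        raise ValueError("cannot apply exclusions to an empty table")
    rules = rules or ExclusionPolicy()
    df = table.df.copy()
    records: list[tuple] = []

    def _exclude(mask: pd.Series, reason: str) -> None:
        mask = mask & df["included"]
        for idx in df.index[mask]:
            records.append((df.at[idx, "participant"], int(idx), reason))
        df.loc[mask, "included"] = False
        df.loc[mask, "reason"] = reason

    if rules.exclude_jol:
        _exclude(df["jol"].isna(), "jol_missing")
        lo, hi = rules.jol_range
        _exclude(df["jol"].notna() & ((df["jol"] < lo) | (df["jol"] > hi)), "jol_out_of_range")

    fluency_active = rules.exclude_fluency and df["fluency"].notna().any()
    if fluency_active:
        _exclude(df["fluency"].notna() & (df["fluency"] < rules.fluency_min_seconds),
                 "fluency_too_fast")
        # individual trimming threshold: mean + k*SD of the participant's
        # own (still included) study times
        grp = df[df["included"]].groupby("participant")["fluency"]
        thresh = grp.transform("mean") + rules.fluency_sd_multiplier * grp.transform("std")
        thresh = thresh.reindex(df.index)
        _exclude(df["included"] & df["fluency"].notna() & (df["fluency"] > thresh),
                 "fluency_too_slow")
        if rules.log_transform_fluency:
            df["fluency_raw"] = df["fluency"]
            ok = df["included"] & df["fluency"].notna()
            if (df.loc[ok, "fluency"] <= 0).any():
                raise ValueError("cannot log-transform non-positive study times")
            df.loc[ok, "fluency"] = np.log(df.loc[ok, "fluency"])

    # participants who lost an entire cue level cannot contribute a contrast
    dropped = []
    inc = df[df["included"]]
    for pid, sub in inc.groupby("participant"):
        if (sub["cue"] > 0).sum() == 0 or (sub["cue"] < 0).sum() == 0:
            dropped.append(pid)
    for pid in dropped:
        mask = df["included"] & (df["participant"] == pid)
        for idx in df.index[mask]:
            records.append((pid, int(idx), "missing_cue_level"))
        df.loc[mask, "included"] = False
        df.loc[mask, "reason"] = "missing_cue_level"

    entries = pd.DataFrame(records, columns=["participant_id", "row", "reason"])
    counts = entries["reason"].value_counts().to_dict() if len(entries) else {}
    log = ExclusionLog(
        entries=entries,
        counts=counts,
        dropped_participants=dropped,
        fluency_logged=bool(fluency_active and rules.log_transform_fluency),
    )
    out = TrialTable(df)
    if isinstance(table, CenteredTrialTable):  # pragma: no cover - defensive
        out = CenteredTrialTable(df, table.centered)
    return out, log


# ---------------------------------------------------------------------------
# centering


def group_mean_center(table: TrialTable, variables: list[str]) -> CenteredTrialTable:
    """Participant-mean-center ``variables`` over included trials.

    Adds ``<var>_c`` columns; excluded trials get NaN centered values.
    Centering a variable that is constant for every participant and
    constant overall returns zeros and emits a warning (degenerate but
    harmless).  Exclusions must be applied first: means are computed on
    included trials only.
    """
    df = table.df.copy()
    inc = df["included"]
    for var in variables:
        if var not in df.columns:
            raise SchemaError(f"cannot center unknown variable {var!r}")
        if not pd.api.types.is_numeric_dtype(df[var]):
            raise ParseError(f"variable {var!r} is not numeric", column=var)
        means = df.loc[inc].groupby("participant")[var].transform("mean")
        centered = pd.Series(np.nan, index=df.index, dtype=float)
        centered.loc[inc] = df.loc[inc, var] - means
        if inc.any() and df.loc[inc, var].nunique() == 1:
            warnings.warn(f"variable {var!r} is constant; centered values are all zero",
                          stacklevel=2)
        df[f"{var}_c"] = centered
    prev = table.centered if isinstance(table, CenteredTrialTable) else ()
    return CenteredTrialTable(df, tuple(dict.fromkeys([*prev, *variables])))


# ---------------------------------------------------------------------------
# participant summaries and the paired t-test gate


def summarize_participants(table: TrialTable) -> pd.DataFrame:
    """Per-participant belief levels, DiffBelief and trial counts.

    Requires the global-belief structure: the belief value is identical
    across a participant's included trials within one cue level.
    ``diff_belief`` is belief at cue level 1 minus belief at cue level 2.
    """
    rows = []
    for pid, sub in table.included_df.groupby("participant", sort=False):
        rec = {"participant_id": pid}
        for level, tag in ((CUE_LEVEL1, "level1"), (CUE_LEVEL2, "level2")):
            cell = sub.loc[sub["cue"] == level, "belief"]
            uniq = cell.dropna().unique()
            if len(uniq) > 1:
                raise BeliefStructureError(
                    f"belief varies within participant {pid!r} at cue {tag} "
                    f"({sorted(uniq)}); treat the mediator as item-varying instead"
                )
            rec[f"belief_{tag}"] = float(uniq[0]) if len(uniq) else np.nan
            rec[f"trials_{tag}"] = int(len(cell))
        rec["diff_belief"] = rec["belief_level1"] - rec["belief_level2"]
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["participant_id", "belief_level1", "belief_level2",
                 "diff_belief", "trials_level1", "trials_level2"],
    )


@dataclass
class PairedTestResult:
    """Two-sided paired t-test on the per-participant belief difference."""

    mean_diff: float
    se: float
    t: float
    df: int
    p: float
    ci: tuple[float, float]
    n: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff, "se": self.se, "t": self.t,
            "df": self.df, "p": self.p, "ci": list(self.ci),
            "n": self.n, "alpha": self.alpha,
        }


def paired_t_test(summaries: pd.DataFrame, alpha: float = 0.05) -> PairedTestResult:
    """Paired t-test of level-1 vs level-2 beliefs across participants.

    Operates on the output of :func:`summarize_participants`; the test
    statistic is the one-sample t on ``diff_belief`` with n-1 df.
    """
    diffs = np.asarray(summaries["diff_belief"], dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    n = len(diffs)
    if n < 2:
        raise UndefinedStatisticError("paired t-test needs at least 2 participants")
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        raise UndefinedStatisticError(
            "all belief differences are identical; the paired t statistic is undefined"
        )
    se = sd / np.sqrt(n)
    mean = diffs.mean()
    t = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return PairedTestResult(
        mean_diff=float(mean), se=float(se), t=float(t), df=int(df),
        p=float(p), ci=(float(mean - tcrit * se), float(mean + tcrit * se)),
        n=n, alpha=alpha,
    )
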