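"""Tabulation and statistics of per-fiber lysis outcomes.

One record per observed fibrin fiber: the experimental condition (bead and
plasmin concentrations, trial), whether the fiber was cleaved, at which
time-lapse frame and where (at the stamped ridge vs along its length),
whether a ridge-cleaved fiber showed further digestion (recoil/collapse),
and — for uncleaved fibers — whether it bundled with a neighbour and/or
elongated (lost its inherent tension).

Percentages are always reported together with their denominator convention:
elongation and bundling rates are fractions of *uncleaved* fibers, the
bundled→elongated rate is a fraction of *bundled* fibers, and cleavage-site
rates are fractions of *cleaved* fibers.  Pooled (all fibers of a condition)
and per-trial (mean ± SE across trials) aggregations are distinct and both
exposed, because they genuinely differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RECORD_COLUMNS",
    "CLEAVAGE_SITES",
    "FURTHER_DIGESTION",
    "FiberFateRecord",
    "RecordValidationError",
    "records_to_frame",
    "validate_records",
    "cleavage_time",
    "cleavage_times",
    "OutcomeTable",
    "tabulate",
    "BoxWhiskerSummary",
    "box_whisker",
    "AnovaResult",
    "two_group_test",
    "RegressionResult",
    "regress_vs_concentration",
]

#: fixed CSV schema for fiber fate records, one row per fiber
RECORD_COLUMNS = [
    "trial_id",
    "bead_concentration",
    "plasmin_concentration",
    "cleaved",
    "cleavage_frame",
    "cleavage_site",
    "further_digestion",
    "bundled",
    "elongated",
]

CLEAVAGE_SITES = ("ridge", "length")
FURTHER_DIGESTION = ("recoil_collapse", "none")

#: seconds between consecutive time-lapse frames
FRAME_INTERVAL_S = 30.0


@dataclass(frozen=True)
class FiberFateRecord:
    """Observed fate of one fiber under one condition.

    ``cleavage_frame`` is the 1-based index of the first frame showing the
    cleavage (frame 1 is captured at plasmin addition, so a cleaved fiber
    has frame ≥ 2).  ``bundled``/``elongated`` apply to uncleaved fibers;
    ``further_digestion`` applies to ridge-cleaved fibers only.
    """

    trial_id: str
    bead_concentration: float
    plasmin_concentration: float
    cleaved: bool
    cleavage_frame: int | None = None
    cleavage_site: str | None = None
    further_digestion: str | None = None
    bundled: bool = False
    elongated: bool = False


class RecordValidationError(ValueError):
    """Raised when fiber fate records violate the schema; lists bad rows."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = [f"row {i}: {msg}" for i, msg in problems]
        super().__init__("invalid fiber fate records:\n" + "\n".join(lines))


def records_to_frame(records) -> pd.DataFrame:
    """Coerce a list of FiberFateRecord (or a DataFrame) to the fixed schema."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError([(-1, f"missing columns: {missing}")])
    return df[RECORD_COLUMNS]


def validate_records(records) -> pd.DataFrame:
    """Validate records against the schema invariants.

    Returns the validated frame; raises :class:`RecordValidationError`
    listing every offending row otherwise.
    """
    df = records_to_frame(records)
    problems: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        if row["bead_concentration"] < 0 or row["plasmin_concentration"] < 0:
            problems.append((idx, "negative concentration"))
        if row["cleaved"]:
            frame = row["cleavage_frame"]
            if pd.isna(frame) or frame < 2 or frame != int(frame):
                problems.append(
                    (idx, f"cleaved fiber needs integer cleavage_frame >= 2, got {frame}")
                )
            if row["cleavage_site"] not in CLEAVAGE_SITES:
                problems.append((idx, f"bad cleavage_site {row['cleavage_site']!r}"))
            if row["cleavage_site"] == "ridge":
                if row["further_digestion"] not in FURTHER_DIGESTION:
                    problems.append(
                        (idx, f"ridge cleavage needs further_digestion in {FURTHER_DIGESTION}")
                    )
            elif not pd.isna(row["further_digestion"]):
                problems.append((idx, "further_digestion defined for non-ridge cleavage"))
            if row["bundled"] or row["elongated"]:
                problems.append((idx, "cleaved fiber cannot carry bundled/elongated flags"))
        else:
            for c in ("cleavage_frame", "cleavage_site", "further_digestion"):
                if not pd.isna(row[c]):
                    problems.append((idx, f"{c} defined for uncleaved fiber"))
    if problems:
        raise RecordValidationError(problems)
    return df


def cleavage_time(frame: int, interval: float = FRAME_INTERVAL_S) -> float:
    """Cleavage time (s) from a 1-based frame index.

    Frame 1 is captured at plasmin addition, so the time is
    ``frame·interval − interval``.
    """
    if frame < 1:
        raise ValueError(f"frame index must be >= 1, got {frame}")
    return frame * interval - interval


def cleavage_times(
    records, interval: float = FRAME_INTERVAL_S
) -> dict[tuple[float, float], np.ndarray]:
    """Cleavage times (s) of cleaved fibers, keyed by (bead, plasmin) condition."""
    df = validate_records(records)
    out: dict[tuple[float, float], np.ndarray] = {}
    cleaved = df[df["cleaved"]]
    for cond, grp in cleaved.groupby(["bead_concentration", "plasmin_concentration"]):
        out[cond] = (grp["cleavage_frame"].to_numpy(float) * interval) - interval
    return out


# ---------------------------------------------------------------------------
# tabulation

_COUNT_COLS = [
    "n_total",
    "n_cleaved",
    "n_uncleaved",
    "n_bundled",
    "n_bundled_and_elongated",
    "n_bundled_only",
    "n_elongated_without_bundling",
    "n_tense",
    "n_ridge_cleaved",
    "n_length_cleaved",
    "n_recoil_collapse",
    "n_no_further_digestion",
]

#: percentage column -> (numerator count, denominator count)
_PCT_DEFS = {
    "pct_uncleaved_of_total": ("n_uncleaved", "n_total"),
    "pct_bundled_of_uncleaved": ("n_bundled", "n_uncleaved"),
    "pct_elongated_of_bundled": ("n_bundled_and_elongated", "n_bundled"),
    "pct_elongated_without_bundling_of_uncleaved": (
        "n_elongated_without_bundling",
        "n_uncleaved",
    ),
    "pct_ridge_of_cleaved": ("n_ridge_cleaved", "n_cleaved"),
    "pct_length_of_cleaved": ("n_length_cleaved", "n_cleaved"),
    "pct_no_further_of_ridge": ("n_no_further_digestion", "n_ridge_cleaved"),
}


def _count_block(df: pd.DataFrame) -> pd.Series:
    cleaved = df["cleaved"].astype(bool)
    unc = df[~cleaved]
    clv = df[cleaved]
    bundled = unc["bundled"].astype(bool)
    elong = unc["elongated"].astype(bool)
    ridge = clv["cleavage_site"] == "ridge"
    return pd.Series(
        {
            "n_total": len(df),
            "n_cleaved": int(cleaved.sum()),
            "n_uncleaved": len(unc),
            "n_bundled": int(bundled.sum()),
            "n_bundled_and_elongated": int((bundled & elong).sum()),
            "n_bundled_only": int((bundled & ~elong).sum()),
            "n_elongated_without_bundling": int((~bundled & elong).sum()),
            "n_tense": int((~bundled & ~elong).sum()),
            "n_ridge_cleaved": int(ridge.sum()),
            "n_length_cleaved": int((~ridge).sum()),
            "n_recoil_collapse": int(
                (clv["further_digestion"] == "recoil_collapse").sum()
            ),
            "n_no_further_digestion": int((clv["further_digestion"] == "none").sum()),
        },
        dtype="int64",
    )


def _percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentages from a count frame; NaN (absent) where a denominator is 0."""
    out = {}
    for col, (num, den) in _PCT_DEFS.items():
        d = counts[den].astype(float)
        out[col] = np.where(d > 0, 100.0 * counts[num] / np.where(d > 0, d, 1), np.nan)
    return pd.DataFrame(out, index=counts.index)


@dataclass
class OutcomeTable:
    """Per-condition outcome counts and percentages, pooled and per-trial.

    ``counts``/``percentages`` are pooled over all trials of a condition
    (index: bead_concentration, plasmin_concentration).  ``per_trial``
    carries the same columns per (condition, trial); ``trial_stats`` holds
    the across-trial mean and standard error of each percentage.
    ``overall_counts``/``overall_percentages`` pool every record.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    per_trial: pd.DataFrame
    trial_stats: pd.DataFrame
    overall_counts: pd.Series
    overall_percentages: pd.Series

    @property
    def conditions(self) -> list[tuple[float, float]]:
        return list(self.counts.index)

    def to_frame(self) -> pd.DataFrame:
        """Pooled counts and percentages in one flat frame (CSV-friendly)."""
        return pd.concat([self.counts, self.percentages], axis=1).reset_index()


def tabulate(records) -> OutcomeTable:
    """Build the outcome table from validated fiber fate records.

    Counts are exact integers; every percentage recomputes exactly from its
    numerator/denominator pair.  Empty denominators yield absent (NaN)
    percentages, never 0.
    """
    df = validate_records(records)
    cond_keys = ["bead_concentration", "plasmin_concentration"]
    counts = df.groupby(cond_keys, sort=True).apply(_count_block, include_groups=False)
    per_trial_counts = df.groupby(cond_keys + ["trial_id"], sort=True).apply(
        _count_block, include_groups=False
    )
    per_trial = pd.concat(
        [per_trial_counts, _percentages(per_trial_counts)], axis=1
    )
    pct_cols = list(_PCT_DEFS)
    grouped = per_trial.groupby(cond_keys, sort=True)[pct_cols]
    trial_stats = pd.concat(
        {
            "mean": grouped.mean(),
            "se": grouped.sem(ddof=1),
            "n_trials": grouped.count(),
        },
        axis=1,
    )
    overall = _count_block(df)
    overall_pct = _percentages(overall.to_frame().T).iloc[0]
    return OutcomeTable(
        counts=counts,
        percentages=_percentages(counts),
        per_trial=per_trial,
        trial_stats=trial_stats,
        overall_counts=overall,
        overall_percentages=overall_pct,
    )


# ---------------------------------------------------------------------------
# summary statistics

@dataclass(frozen=True)
class BoxWhiskerSummary:
    """Box-and-whisker numbers: quartiles, 1.5×IQR whiskers, outliers, mean ± SE.

    Quartiles use linear interpolation.  Whisker ends are the most extreme
    *data values* inside the fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; points
    outside are outliers.
    """

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    mean: float
    se: float


def box_whisker(values) -> BoxWhiskerSummary:
    """Box-whisker summary of a sample (n ≥ 1)."""
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("box_whisker requires at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
    se = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else math.nan
    return BoxWhiskerSummary(
        n=int(x.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in outliers),
        mean=float(x.mean()),
        se=se,
    )


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA between two groups (≡ two-sided pooled t-test)."""

    F: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False


def two_group_test(a, b) -> AnovaResult:
    """Two-tailed one-way ANOVA comparing two samples (each n ≥ 2).

    Degenerate input with zero total variance returns F = 0, p = 1 with
    the ``degenerate`` flag set.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df_b, df_w = 1, a.size + b.size - 2
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return AnovaResult(0.0, df_b, df_w, 1.0, degenerate=True)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(a, b)
    if not math.isfinite(F):  # within-group variance 0, groups differ
        return AnovaResult(math.inf, df_b, df_w, 0.0, degenerate=True)
    return AnovaResult(float(F), df_b, df_w, float(p), degenerate=False)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of a percentage against (optionally log10) concentration."""

    slope: float
    intercept: float
    p_value: float
    r_value: float
    stderr: float
    xscale: str
    n: int


def regress_vs_concentration(
    concentrations, percentages, xscale: str = "log10"
) -> RegressionResult:
    """Ordinary least squares of per-trial percentages on concentration.

    ``xscale='log10'`` (default — the tested dilutions span two decades)
    regresses on log10(concentration); ``'linear'`` uses the raw scale.
    The p-value is the two-sided t-test on the slope.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(percentages, float)
    if x.size != y.size:
        raise ValueError("concentrations and percentages must have equal length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.unique(x).size < 2:
        raise ValueError("regression needs at least 2 distinct concentrations")
    if xscale == "log10":
        if np.any(x <= 0):
            raise ValueError("log10 x-scale requires positive concentrations")
        x = np.log10(x)
    elif xscale != "linear":
        raise ValueError("xscale must be 'log10' or 'linear'")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_value=float(res.rvalue),
        stderr=float(res.stderr),
        xscale=xscale,
        n=int(x.size),
    )
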