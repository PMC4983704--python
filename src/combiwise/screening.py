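"""Candidate-outcome screening: relative yearly change, outlier fences,
one-sample tests, sensitivity z-scores, step-down Sidak validation,
signal-to-noise ratios and the Spearman correlation matrix.

The screening design is discovery-then-validation: every candidate
biomarker is tested for non-zero mean relative yearly change in the
discovery cohort at unadjusted p < 0.05; the surviving family is re-tested
in each validation cohort with a step-down Sidak multiplicity adjustment
over the carried family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def relative_change(
    baseline: Sequence[float], followup: Sequence[float]
) -> tuple[np.ndarray, int]:
    """Per-subject relative percentage change, 100 * (v1 - v0) / v0.

    Subjects with a zero baseline are excluded; returns (deltas, number
    excluded).
    """
    v0 = np.asarray(baseline, dtype=float)
    v1 = np.asarray(followup, dtype=float)
    if v0.shape != v1.shape:
        raise ValueError("baseline and followup must align")
    ok = v0 != 0
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} subjects with zero baseline", stacklevel=2)
    return 100.0 * (v1[ok] - v0[ok]) / v0[ok], n_excluded


def exclude_outliers(
    deltas: Sequence[float], k: float = 3.0, quantile_method: str = "linear"
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Tukey-fence outlier removal.

    Removes values below ``Q1 - k*IQR`` or above ``Q3 + k*IQR`` with
    quartiles by linear interpolation of order statistics by default
    (``quantile_method`` accepts any numpy quantile method, e.g.
    ``"hazen"`` for Tukey-hinge-like behaviour).  No re-iteration.
    """
    x = np.asarray(deltas, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 values for quartile fences")
    q1, q3 = np.quantile(x, [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    keep = (x >= q1 - k * iqr) & (x <= q3 + k * iqr)
    return x[keep], x[~keep]


def one_sample_test(deltas: Sequence[float]) -> tuple[float, float]:
    """Two-sided one-sample t-test of mean relative change against 0."""
    x = np.asarray(deltas, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    if np.std(x, ddof=1) == 0:
        if np.mean(x) == 0:
            return 0.0, 1.0
        raise ValueError("zero standard deviation")
    res = stats.ttest_1samp(x, popmean=0.0)
    return float(res.statistic), float(res.pvalue)


def z_score(deltas: Sequence[float]) -> float:
    """Sensitivity index: mean group change divided by the group SD.

    This is a cohort-level signal-to-noise quantity (directly related to
    the power of a test of change), not a standardized individual score.
    """
    x = np.asarray(deltas, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return round(float(np.mean(x) / sd), 4)


def stepdown_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Sidak multiplicity adjustment.

    Sort ascending, set ``adj_(i) = 1 - (1 - p_(i))^(m - i + 1)``
    (i = 1..m), enforce monotone non-decreasing adjusted values with a
    running maximum, and return in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    with np.errstate(divide="ignore"):
        adj_sorted = -np.expm1((m - np.arange(m)) * np.log1p(-p[order]))
    adj_sorted = np.where(p[order] >= 1.0, 1.0, adj_sorted)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def snr(patient_deltas: Sequence[float], reference_deltas: Sequence[float]) -> float:
    """Mean absolute patient yearly change over mean absolute reference
    change (healthy-volunteer scan-rescan or yearly change)."""
    p = np.abs(np.asarray(patient_deltas, dtype=float))
    r = np.abs(np.asarray(reference_deltas, dtype=float))
    denom = r.mean()
    if denom == 0:
        raise ValueError("reference mean absolute change is zero")
    return float(p.mean() / denom)


def spearman_matrix(
    table: pd.DataFrame, alpha: float = 0.05, m_tests: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations with a Bonferroni significance mask.

    Correlations are pairwise-complete; a pair needs at least three paired
    observations.  The mask marks p < alpha / m_tests, with ``m_tests``
    defaulting to the number of variable pairs.  Constant columns yield an
    undefined rho and are masked out.

    Returns (rho, p, significant) DataFrames.
    """
    cols = list(table.columns)
    k = len(cols)
    if m_tests is None:
        m_tests = k * (k - 1) // 2
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    sig = pd.DataFrame(np.zeros((k, k), dtype=bool), index=cols, columns=cols)
    thresh = alpha / max(m_tests, 1)
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            if len(pair) < 3 or pair[cols[i]].nunique() < 2 or pair[cols[j]].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(pair[cols[i]], pair[cols[j]])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
            sig.iloc[i, j] = sig.iloc[j, i] = bool(np.isfinite(p) and p < thresh)
    return rho, pval, sig


# ---------------------------------------------------------------------------
# Cohort-level screening

@dataclass(frozen=True)
class OutcomeStats:
    """Screening summary for one biomarker in one cohort."""

    biomarker: str
    cohort: str
    n_used: int
    n_outliers_removed: int
    delta_mean: float
    delta_sd: float
    z: float
    t_stat: float
    p_raw: float
    p_adjusted: Optional[float] = None
    validated: Optional[bool] = None
    skewness: float = float("nan")
    excess_kurtosis: float = float("nan")
    normal_flag: bool = True
    outliers_kept_whole: bool = False


def _cohort_stats(
    deltas: np.ndarray,
    biomarker: str,
    cohort: str,
    fence_k: float = 3.0,
    max_outlier_fraction: float = 0.3,
    quantile_method: str = "linear",
) -> OutcomeStats:
    """Outlier-fence then one-sample test for one biomarker/cohort.

    If fencing would delete more than ``max_outlier_fraction`` of the
    subjects, or leaves a zero-variance sample (heavily discretized
    scales collapse the IQR so the fences remove every mover), the full
    dataset is tested instead and flagged.
    """
    kept, removed = exclude_outliers(deltas, k=fence_k, quantile_method=quantile_method)
    whole = False
    degenerate = removed.size and np.std(kept, ddof=1) == 0 and np.std(deltas, ddof=1) > 0
    if deltas.size and (removed.size / deltas.size > max_outlier_fraction or degenerate):
        kept, removed = deltas, np.empty(0)
        whole = True
    t, p = one_sample_test(kept)
    skew = float(stats.skew(kept, bias=False)) if kept.size > 2 else float("nan")
    kurt = float(stats.kurtosis(kept, bias=False)) if kept.size > 3 else float("nan")
    shapiro_p = float(stats.shapiro(kept).pvalue) if 3 <= kept.size <= 5000 else float("nan")
    normal = bool(
        abs(skew) <= 1 and abs(kurt) <= 1 and (np.isnan(shapiro_p) or shapiro_p > 0.05)
    )
    return OutcomeStats(
        biomarker=biomarker,
        cohort=cohort,
        n_used=int(kept.size),
        n_outliers_removed=int(removed.size),
        delta_mean=float(np.mean(kept)),
        delta_sd=float(np.std(kept, ddof=1)),
        z=z_score(kept),
        t_stat=t,
        p_raw=p,
        skewness=skew,
        excess_kurtosis=kurt,
        normal_flag=normal,
        outliers_kept_whole=whole,
    )


def screen_cohort(
    panel: pd.DataFrame,
    discovery: str,
    validation: Sequence[str] = (),
    alpha: float = 0.05,
    months: tuple[int, int] = (-12, 0),
    fence_k: float = 3.0,
    max_outlier_fraction: float = 0.3,
) -> pd.DataFrame:
    """Discovery-then-validation screening of a biomarker panel.

    ``panel`` is long-format with columns ``subject_id, cohort, biomarker,
    month, value``.  Per biomarker and cohort, subjects with both endpoint
    months are converted to relative yearly changes, fenced for outliers
    and tested against zero mean.  Biomarkers with raw p < ``alpha`` in
    the discovery cohort form the carried family; within each validation
    cohort that family's p-values receive a step-down Sidak adjustment and
    a biomarker is flagged validated when its adjusted p < ``alpha``.
    """
    required = {"subject_id", "cohort", "biomarker", "month", "value"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    m0, m1 = months
    stats_rows: dict[tuple[str, str], OutcomeStats] = {}
    for (cohort, biomarker), grp in panel.groupby(["cohort", "biomarker"], sort=True):
        wide = grp.pivot_table(index="subject_id", columns="month", values="value")
        if m0 not in wide.columns or m1 not in wide.columns:
            continue
        pairs = wide[[m0, m1]].dropna()
        if len(pairs) < 4:
            continue
        deltas, _ = relative_change(pairs[m0].to_numpy(), pairs[m1].to_numpy())
        stats_rows[(str(cohort), str(biomarker))] = _cohort_stats(
            deltas, str(biomarker), str(cohort),
            fence_k=fence_k, max_outlier_fraction=max_outlier_fraction,
        )

    family = sorted(
        b for (c, b), s in stats_rows.items() if c == discovery and s.p_raw < alpha
    )
    records = [vars(s).copy() for s in stats_rows.values()]
    df = pd.DataFrame(records)
    if df.empty:
        return df
    df["carried"] = (df["cohort"] == discovery) & df["biomarker"].isin(family)
    for vc in validation:
        mask = (df["cohort"] == vc) & df["biomarker"].isin(family)
        if not mask.any() or not family:
            continue
        adj = stepdown_sidak(df.loc[mask, "p_raw"].to_numpy())
        df.loc[mask, "p_adjusted"] = adj
        df.loc[mask, "validated"] = adj < alpha
    return df.sort_values(["biomarker", "cohort"]).reset_index(drop=True)
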