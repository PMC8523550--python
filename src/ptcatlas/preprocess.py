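"""Cell-level QC, log-normalization, HVG selection and the DEG screen.

All operations take genes x observations matrices (pandas DataFrames). The QC
thresholds and the three-part differential-expression rule follow the standard
droplet-based single-cell workflow: cells are dropped when mitochondrial
content exceeds 10% or total UMIs fall outside [500, 5000]; signature genes
must be expressed in >20% of either group, show |log2FC| > 0.5, and survive a
Bonferroni-adjusted Wilcoxon rank-sum test at 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCThresholds",
    "qc_filter",
    "log_normalize",
    "select_hvgs",
    "differential_expression_screen",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention thresholds: mito fraction cap and UMI window."""

    max_mito_fraction: float = 0.10
    min_umi: int = 500
    max_umi: int = 5000

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_umi >= self.max_umi:
            raise ValueError("min_umi must be < max_umi")


def qc_filter(
    counts: pd.DataFrame,
    mito_genes: set[str] | list[str] | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-quality cells; return (filtered counts, per-cell QC report).

    A cell is retained iff min_umi <= UMI total <= max_umi and its
    mitochondrial count fraction <= max_mito_fraction. The report records each
    cell's UMI total, mito fraction, pass flag and failure reason.
    """
    if mito_genes is None:
        mito_genes = [g for g in counts.index if str(g).startswith("MT-")]
    mito_present = [g for g in mito_genes if g in counts.index]
    if mito_genes and not mito_present:
        warnings.warn("no mito genes found in matrix; mito fraction set to 0")

    umi = counts.sum(axis=0)
    if mito_present:
        with np.errstate(invalid="ignore"):
            mito_frac = counts.loc[mito_present].sum(axis=0) / umi.replace(0, np.nan)
        mito_frac = mito_frac.fillna(0.0)
    else:
        mito_frac = pd.Series(0.0, index=counts.columns)

    low = umi < thresholds.min_umi
    high = umi > thresholds.max_umi
    mito_fail = mito_frac > thresholds.max_mito_fraction
    passed = ~(low | high | mito_fail)

    reason = pd.Series("", index=counts.columns, dtype=object)
    reason[low] = "low_umi"
    reason[high] = "high_umi"
    # mito failure recorded even when combined with a UMI failure
    reason[mito_fail & (reason == "")] = "high_mito"
    reason[mito_fail & (reason != "") & (reason != "high_mito")] += "+high_mito"

    report = pd.DataFrame(
        {"umi": umi, "mito_fraction": mito_frac, "passed": passed, "reason": reason}
    )
    filtered = counts.loc[:, passed]
    if filtered.shape[1] == 0:
        warnings.warn("all cells removed by QC filter")
    return filtered, report


def log_normalize(counts: pd.DataFrame, scale_factor: float = 10_000.0) -> pd.DataFrame:
    """Library-size normalize and log-transform: ln(1 + count/total * sf).

    Raises on zero-total cells (naming them) since their normalization is
    undefined.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total cells cannot be normalized: {list(zero.index[:5])}")
    return np.log1p(counts / totals * scale_factor)


def _hvg_vst(counts: pd.DataFrame) -> pd.Series:
    """Variance-stabilized HVG statistic.

    Fits a lowess trend of log10 variance on log10 mean over raw counts,
    standardizes each gene's counts by the trend-predicted standard deviation
    (clipped at sqrt(n_cells)), and scores genes by the variance of the
    standardized values.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = counts.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    score = np.zeros(len(mean))
    ok = (mean > 0) & (var > 0)
    if 0 < ok.sum() < 3:
        # too few informative genes to fit a trend: rank by raw variance
        score[ok] = var[ok]
    elif ok.sum() >= 3:
        lm, lv = np.log10(mean[ok]), np.log10(var[ok])
        order = np.argsort(lm)
        fit = lowess(lv[order], lm[order], frac=0.3, return_sorted=False)
        exp_sd = np.sqrt(10.0 ** fit)
        clip = np.sqrt(x.shape[1])
        sub = x[ok][order]
        z = (sub - mean[ok][order][:, None]) / exp_sd[:, None]
        np.clip(z, -clip, clip, out=z)
        v = (z ** 2).sum(axis=1) - z.sum(axis=1) ** 2 / x.shape[1]
        v /= x.shape[1] - 1
        tmp = np.zeros(ok.sum())
        tmp[order] = v
        score[ok] = tmp
    return pd.Series(score, index=counts.index)


def _hvg_dispersion(counts: pd.DataFrame, n_bins: int = 20) -> pd.Series:
    """Binned normalized-dispersion statistic (mean/dispersion z-scores)."""
    x = counts.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, x.var(axis=1, ddof=1) / mean, 0.0)
    df = pd.DataFrame({"mean": mean, "disp": disp}, index=counts.index)
    df["bin"] = pd.cut(df["mean"].rank(method="first"), bins=n_bins, labels=False)
    z = df.groupby("bin")["disp"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=1) if s.std(ddof=1) > 0 else s * 0.0
    )
    return z.fillna(0.0)


def select_hvgs(
    matrix: pd.DataFrame, n: int = 2000, method: str = "vst"
) -> list[str]:
    """Top-n highly variable genes by standardized dispersion.

    ``method`` is ``"vst"`` (lowess-detrended standardized variance, default)
    or ``"dispersion"`` (mean-binned normalized dispersion). Returns gene
    names ordered by decreasing statistic; ties broken by gene name for
    determinism.
    """
    if n > matrix.shape[0]:
        raise ValueError(f"requested {n} HVGs but matrix has {matrix.shape[0]} genes")
    if method == "vst":
        score = _hvg_vst(matrix)
    elif method == "dispersion":
        score = _hvg_dispersion(matrix)
    else:
        raise ValueError(f"unknown HVG method: {method!r}")
    if (score.max() - score.min()) == 0:
        warnings.warn("all genes have zero dispersion; HVG selection is arbitrary")
    order = score.sort_index().sort_values(ascending=False, kind="stable")
    return list(order.index[:n])


def _wilcoxon_p(a: np.ndarray, b: np.ndarray, exact_max: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small groups, else normal
    approximation with tie correction."""
    method = "exact" if (len(a) <= exact_max and len(b) <= exact_max) else "asymptotic"
    if method == "exact" and (len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)):
        # exact method does not handle ties; fall back to tie-corrected normal
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def differential_expression_screen(
    lognorm: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    min_frac: float = 0.20,
    min_abs_log2fc: float = 0.5,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Three-rule DEG screen between two groups of cells.

    ``groups`` is a binary labeling of the columns; the first label in sorted
    order is group A. For each gene the table reports log2FC (on de-logged
    means with pseudocount 1), expressed fractions per group, the Wilcoxon
    rank-sum p, the Bonferroni-adjusted p over all tested genes, and
    ``passes`` — true iff frac > min_frac in at least one group AND
    |log2FC| > min_abs_log2fc AND adjusted p < alpha.
    """
    groups = pd.Series(np.asarray(groups), index=lognorm.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    a_cols = groups[groups == levels[0]].index
    b_cols = groups[groups == levels[1]].index
    if len(a_cols) < 3 or len(b_cols) < 3:
        warnings.warn("a group has <3 cells; p-values are unreliable")

    a = lognorm.loc[:, a_cols].to_numpy(dtype=float)
    b = lognorm.loc[:, b_cols].to_numpy(dtype=float)

    frac_a = (a > 0).mean(axis=1)
    frac_b = (b > 0).mean(axis=1)
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    p = np.array([_wilcoxon_p(a[i], b[i]) for i in range(lognorm.shape[0])])
    p_adj = np.minimum(p * lognorm.shape[0], 1.0)

    passes = (
        ((frac_a > min_frac) | (frac_b > min_frac))
        & (np.abs(log2fc) > min_abs_log2fc)
        & (p_adj < alpha)
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "frac_a": frac_a,
            "frac_b": frac_b,
            "p": p,
            "p_adj": p_adj,
            "passes": passes,
        },
        index=lognorm.index,
    )
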