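"""Gene-covariate association screens.

Two screens over a log-normalized genes x cells matrix: genes correlated
with a per-cell TDS score (directional, thresholded on r and p), and
pseudotime-associated genes (PAGs: BH-controlled, ranked by |r|, top-N).
Pseudotime is an input vector here; trajectory inference is upstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["pearson_screen", "tds_correlated_genes", "pseudotime_associated_genes"]


def pearson_screen(
    lognorm: pd.DataFrame, covariate: pd.Series | np.ndarray, method: str = "pearson"
) -> pd.DataFrame:
    """Per-gene correlation with a covariate: columns r, p, p_adj (BH).

    Zero-variance genes get r = 0, p = 1. ``method`` is "pearson" or
    "spearman" (rank-transform both sides, then Pearson).
    """
    y = np.asarray(covariate, dtype=float)
    if len(y) != lognorm.shape[1]:
        raise ValueError("covariate length must equal the number of cells")
    keep = np.isfinite(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} cells with non-finite covariate dropped")
        y = y[keep]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 cells with finite covariate")
    if np.ptp(y) == 0:
        raise ValueError("constant covariate: correlation undefined")

    x = lognorm.to_numpy(dtype=float)[:, keep]
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method!r}")

    flat = np.ptp(x, axis=1) == 0
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    flat |= sx == 0
    r[flat] = 0.0
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[flat] = 1.0
    p = np.clip(p, 0.0, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"r": r, "p": p, "p_adj": p_adj}, index=lognorm.index)


def tds_correlated_genes(
    lognorm: pd.DataFrame,
    tds: pd.Series | np.ndarray,
    r_min: float = 0.5,
    p_max: float = 0.05,
    direction: str = "positive",
    method: str = "pearson",
) -> pd.DataFrame:
    """Genes whose expression tracks the per-cell TDS score.

    selected iff (r > r_min for direction="positive", r < -r_min for
    "negative", |r| > r_min for "both") and p < p_max. Returns the full
    association table sorted by |r| descending.
    """
    tab = pearson_screen(lognorm, tds, method=method)
    if direction == "positive":
        dir_ok = tab["r"] > r_min
    elif direction == "negative":
        dir_ok = tab["r"] < -r_min
    elif direction == "both":
        dir_ok = tab["r"].abs() > r_min
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    tab["selected"] = dir_ok & (tab["p"] < p_max)
    return tab.reindex(tab["r"].abs().sort_values(ascending=False, kind="stable").index)


def pseudotime_associated_genes(
    lognorm: pd.DataFrame,
    pseudotime: pd.Series | np.ndarray,
    n_top: int = 480,
    p_max: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pseudotime-associated genes: BH-significant, ranked by |r|, top n_top.

    Both signs are admitted (genes may rise or fall along pseudotime). The
    full table is returned with ``selected`` marking the PAG set; a warning
    is issued if fewer than n_top genes pass the BH cut.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    tab = pearson_screen(lognorm, pseudotime, method=method)
    tab = tab.reindex(tab["r"].abs().sort_values(ascending=False, kind="stable").index)
    passing = tab.index[tab["p_adj"] < p_max]
    if len(passing) < n_top:
        warnings.warn(f"only {len(passing)} genes pass BH at {p_max}; fewer than n_top={n_top}")
    selected = set(passing[:n_top])
    tab["selected"] = [g in selected for g in tab.index]
    return tab
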