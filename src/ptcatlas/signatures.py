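"""Signature scoring: per-cell module scores, bulk TDS, and the BRS centroid
score with BRAF-/RAS-like calling.

Module scores follow the binned-control convention: each cell's score is the
mean expression of the signature genes minus the mean of random control genes
drawn, per signature gene, from the expression bin that gene falls in. The
thyroid differentiation score (TDS) over the 13-gene panel is computed two
ways — as a module score per cell, and on bulk TPM as the sum of per-gene
median-centered log2 expression. The BRAF-RAS score (BRS) of a sample is

    BRS(t) = |v(t) - c(B)|^2 - |v(t) - c(R)|^2

on per-gene z-scored expression, where c(B)/c(R) are the centroids of the
signature in BRAF-mutant / RAS-mutant samples; negative BRS calls the sample
BRAF-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .simulate import TDS_PANEL

__all__ = [
    "ModuleScoreParams",
    "module_score",
    "tds_bulk",
    "tds_single_cell",
    "brs",
    "braf_ras_cell_scores",
]


@dataclass(frozen=True)
class ModuleScoreParams:
    """Binning and control-sampling parameters for module scores."""

    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_ctrl < 1:
            raise ValueError("n_ctrl must be >= 1")


def _expression_bins(avg: pd.Series, n_bins: int) -> pd.Series:
    """Equal-frequency bins of genes by average expression (rank-based cut)."""
    ranks = avg.rank(method="first")
    return pd.Series(
        pd.cut(ranks, bins=n_bins, labels=False, include_lowest=True), index=avg.index
    )


def module_score(
    lognorm: pd.DataFrame,
    signature: list[str],
    params: ModuleScoreParams = ModuleScoreParams(),
) -> pd.Series:
    """Per-cell signature score against expression-matched random controls.

    Genes are binned by their average expression across cells (``n_bins``
    equal-frequency bins); for each signature gene, ``n_ctrl`` control genes
    are sampled without replacement from its bin (with replacement plus a
    warning when the bin is too small). The score is
    mean(signature genes) - mean(union of sampled control genes), per cell.
    Deterministic given ``params.seed``.
    """
    present = [g for g in signature if g in lognorm.index]
    missing = [g for g in signature if g not in lognorm.index]
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from matrix: {missing[:5]}")
    if not present:
        raise ValueError("no signature genes present in the matrix")

    avg = lognorm.mean(axis=1)
    bins = _expression_bins(avg, params.n_bins)
    rng = child_rng(params.seed, "module_score")

    ctrl: set[str] = set()
    for g in present:
        # controls come from the gene's own bin; other signature genes stay
        # in the pool, so a signature spanning the whole universe scores ~0
        pool = bins.index[(bins == bins[g]) & (bins.index != g)]
        if len(pool) == 0:
            continue
        replace = len(pool) < params.n_ctrl
        if replace:
            warnings.warn(
                f"bin of gene {g} has only {len(pool)} control candidates; "
                "sampling with replacement"
            )
        picked = rng.choice(np.asarray(pool), size=params.n_ctrl, replace=replace)
        ctrl.update(picked.tolist())

    sig_mean = lognorm.loc[present].mean(axis=0)
    if ctrl:
        ctrl_mean = lognorm.loc[sorted(ctrl)].mean(axis=0)
    else:
        ctrl_mean = pd.Series(0.0, index=lognorm.columns)
    return sig_mean - ctrl_mean


def tds_bulk(
    tpm: pd.DataFrame,
    panel: tuple[str, ...] | list[str] = TDS_PANEL,
    reduce: str = "sum",
) -> pd.Series:
    """Thyroid differentiation score per bulk sample.

    Per gene g and sample s: d(g, s) = log2(TPM+1)(g, s) minus the per-gene
    median across samples; TDS(s) is the sum of d over the panel genes
    (``reduce="mean"`` averages instead). Missing panel genes are dropped
    with a warning.
    """
    present = [g for g in panel if g in tpm.index]
    missing = [g for g in panel if g not in tpm.index]
    if missing:
        warnings.warn(f"{len(missing)} panel genes absent: {missing}")
    if not present:
        raise ValueError("no panel genes present in the matrix")
    log2 = np.log2(tpm.loc[present] + 1.0)
    centered = log2.sub(log2.median(axis=1), axis=0)
    if reduce == "sum":
        return centered.sum(axis=0)
    if reduce == "mean":
        return centered.mean(axis=0)
    raise ValueError(f"unknown reduce: {reduce!r}")


def tds_single_cell(
    lognorm: pd.DataFrame,
    panel: tuple[str, ...] | list[str] = TDS_PANEL,
    params: ModuleScoreParams = ModuleScoreParams(),
) -> pd.Series:
    """Per-cell TDS as a module score over the 13-gene panel."""
    return module_score(lognorm, list(panel), params)


def brs(
    expr: pd.DataFrame,
    braf_samples: list[str],
    ras_samples: list[str],
    signature: list[str] | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """BRAF-RAS score and BRAF-/RAS-like call per sample.

    ``expr`` is genes x samples; ``signature`` restricts to the signature
    genes (all rows if None). Expression is z-scored per gene across the
    cohort (zero-variance genes excluded with a warning; ``normalize=False``
    skips the z-scoring and scores raw values), centroids c(B) and c(R) are
    per-gene means over the two mutant sets, and
    BRS = |v - c(B)|^2 - |v - c(R)|^2. Negative BRS -> BRAF-like; BRS >= 0 ->
    RAS-like.
    """
    if not braf_samples or not ras_samples:
        raise ValueError("both mutant sample sets must be non-empty")
    missing = [s for s in list(braf_samples) + list(ras_samples) if s not in expr.columns]
    if missing:
        raise ValueError(f"mutant samples absent from matrix: {missing[:5]}")
    if signature is not None:
        present = [g for g in signature if g in expr.index]
        if len(present) < len(signature):
            warnings.warn(
                f"{len(signature) - len(present)} signature genes absent from matrix"
            )
        if not present:
            raise ValueError("no signature genes present")
        expr = expr.loc[present]

    if normalize:
        sd = expr.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            warnings.warn(f"{int(flat.sum())} zero-variance genes excluded from BRS")
            expr = expr.loc[~flat]
            sd = sd[~flat]
        if expr.shape[0] == 0:
            raise ValueError("no informative genes for BRS")
        z = expr.sub(expr.mean(axis=1), axis=0).div(sd, axis=0)
    else:
        z = expr

    c_b = z[list(braf_samples)].mean(axis=1).to_numpy()
    c_r = z[list(ras_samples)].mean(axis=1).to_numpy()
    v = z.to_numpy()
    score = ((v - c_b[:, None]) ** 2).sum(axis=0) - ((v - c_r[:, None]) ** 2).sum(axis=0)
    call = np.where(score < 0, "BRAF-like", "RAS-like")
    return pd.DataFrame({"brs": score, "call": call}, index=expr.columns)


def braf_ras_cell_scores(
    lognorm: pd.DataFrame,
    braf_signature: list[str],
    ras_signature: list[str],
    params: ModuleScoreParams = ModuleScoreParams(),
) -> pd.DataFrame:
    """Per-cell BRAF and RAS module scores with independent control draws."""
    p_braf = ModuleScoreParams(params.n_bins, params.n_ctrl, seed=params.seed * 2 + 1)
    p_ras = ModuleScoreParams(params.n_bins, params.n_ctrl, seed=params.seed * 2 + 2)
    return pd.DataFrame(
        {
            "braf_score": module_score(lognorm, braf_signature, p_braf),
            "ras_score": module_score(lognorm, ras_signature, p_ras),
        }
    )
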