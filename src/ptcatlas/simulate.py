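"""Synthetic PTC-style cohorts: labeled bulk expression and single-cell counts.

The generator emulates the statistical structure the downstream pipeline
assumes about papillary thyroid carcinoma data, without any real patient data:

* a bulk cohort of tumor and paratumor samples in TPM, where tumors carry a
  latent *malignancy coordinate* that down-regulates the 13-gene thyroid
  differentiation (TDS) panel and up-regulates a BRAF-activation signature,
  with BRAF-mutant vs RAS-mutant tumors separated on a 71-gene stand-in
  signature and three planted molecular subtypes (RAS-like, BRAF-like-A,
  BRAF-like-B);
* a single-cell UMI count matrix whose cells occupy five states (normal,
  premalignant, and three malignant phenotypes: follicular-like, pEMT-like,
  dediff-like) along a branching pseudotime, with negative-binomial count
  noise, log-normal library sizes spanning the QC thresholds, and a dedicated
  ``MT-`` mitochondrial gene block.

Bulk and single-cell data share one gene-effect model driven by the same
latent coordinate (pseudotime for cells, malignancy for bulk samples); that
shared structure is what makes rank-based cell-vs-bulk comparison work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from ._seeds import child_rng

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigurationError",
    "STATES",
    "TISSUES",
    "TDS_PANEL",
    "generate_reference_cohort",
    "generate_single_cell_dataset",
    "generate_toy_fixture",
]

#: Cell states, ordered from root to branch tips of the latent trajectory.
STATES = ("normal", "premalignant", "follicular_like", "pemt_like", "dediff_like")

#: Tissue compartments a cell can be sampled from.
TISSUES = ("paratumor", "tumor", "lymph_node", "subcutaneous")

#: The 13 thyroid-function mRNA genes of the thyroid differentiation score.
TDS_PANEL = (
    "TG", "TPO", "SLC26A4", "DIO2", "TSHR", "PAX8", "DUOX1",
    "DUOX2", "NKX2-1", "GLIS3", "FOXE1", "TFF3", "FHL1",
)

#: Pseudotime interval (uniform) each state is drawn from. States beyond the
#: branch point (0.4) sit on one of two branches; normal < premalignant <
#: malignant in expectation.
_STATE_TIME = {
    "normal": (0.00, 0.20),
    "premalignant": (0.15, 0.32),
    "follicular_like": (0.48, 0.75),
    "pemt_like": (0.65, 1.00),
    "dediff_like": (0.65, 1.00),
}

_BRANCH_POINT = 0.4

#: Latent malignancy coordinate for bulk samples, by planted subtype.
_SUBTYPE_MALIGNANCY = {
    "RAS-like": (0.45, 0.60),
    "BRAF-like-A": (0.60, 0.80),
    "BRAF-like-B": (0.80, 1.00),
}
_PARATUMOR_MALIGNANCY = (0.00, 0.25)

_MALIGNANT_STATES = frozenset({"follicular_like", "pemt_like", "dediff_like"})


class ConfigurationError(ValueError):
    """Raised when a SimConfig cannot support the requested cohort."""


def _default_cells_per_state() -> dict[str, int]:
    return {
        "normal": 120,
        "premalignant": 80,
        "follicular_like": 100,
        "pemt_like": 100,
        "dediff_like": 100,
    }


def _default_tissue_mix() -> pd.DataFrame:
    mix = pd.DataFrame(
        [
            [0.90, 0.10, 0.00, 0.00],
            [0.70, 0.30, 0.00, 0.00],
            [0.10, 0.60, 0.30, 0.00],
            [0.00, 0.50, 0.50, 0.00],
            [0.00, 0.30, 0.30, 0.40],
        ],
        index=list(STATES),
        columns=list(TISSUES),
    )
    return mix


@dataclass
class SimConfig:
    """Parameters of the synthetic cohorts.

    effect_size is the log2-scale mean shift applied to signature genes across
    the full latent-coordinate range; dispersion is the negative-binomial
    inverse size (variance = mu + dispersion * mu^2; 0 recovers Poisson).
    """

    n_genes: int = 1000
    n_bulk_tumor: int = 50
    n_bulk_paratumor: int = 50
    n_braf: int = 30
    n_ras: int = 20
    n_cells_per_state: dict[str, int] = field(default_factory=_default_cells_per_state)
    tissue_mix: pd.DataFrame = field(default_factory=_default_tissue_mix)
    effect_size: float = 2.0
    dispersion: float = 0.12
    seed: int = 0
    # gene-universe layout
    n_braf_sig: int = 36
    n_ras_sig: int = 35
    n_pag: int = 60
    n_mito: int = 20
    # nuisance parameters
    bulk_noise_sd: float = 0.5     # log2-scale biological noise in bulk
    library_size_log_mean: float = float(np.log(2200.0))
    library_size_log_sd: float = 0.6
    # baseline abundance band (log2) of signature/PAG genes; the real panels
    # are high expressors in thyrocytes
    planted_base_log2_mean: float = 2.5
    planted_base_log2_sd: float = 0.6

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_bulk_tumor": self.n_bulk_tumor,
            "n_bulk_paratumor": self.n_bulk_paratumor,
            "n_braf": self.n_braf,
            "n_ras": self.n_ras,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0 (use a small value for the Poisson limit)")
        if self.n_braf + self.n_ras != self.n_bulk_tumor:
            raise ConfigurationError(
                f"n_braf + n_ras ({self.n_braf + self.n_ras}) must partition "
                f"n_bulk_tumor ({self.n_bulk_tumor})"
            )
        unknown = set(self.n_cells_per_state) - set(STATES)
        if unknown:
            raise ConfigurationError(f"unknown cell states: {sorted(unknown)}")
        if any(v < 0 for v in self.n_cells_per_state.values()):
            raise ConfigurationError("cell counts must be >= 0")
        mix = self.tissue_mix
        if not np.allclose(mix.sum(axis=1), 1.0):
            raise ConfigurationError("tissue_mix rows must sum to 1")
        if (mix.values < 0).any():
            raise ConfigurationError("tissue_mix entries must be >= 0")
        n_special = (
            len(TDS_PANEL) + self.n_braf_sig + self.n_ras_sig + self.n_pag + self.n_mito
        )
        if self.n_genes < n_special:
            raise ConfigurationError(
                f"n_genes ({self.n_genes}) smaller than the required signature "
                f"panels ({n_special} genes)"
            )


@dataclass
class GroundTruth:
    """Planted truth for a generated cohort.

    genes: per-gene membership table (tds_panel / braf_sig / ras_sig / pag /
    mito / null booleans plus pag_direction in {-1, 0, +1}).
    cells: per-cell state, tissue, pseudotime, branch, malignant flag.
    bulk_samples: per-sample malignancy label, mutation, planted subtype and
    latent malignancy coordinate.
    """

    genes: pd.DataFrame
    cells: pd.DataFrame | None = None
    bulk_samples: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# gene universe and effect model
# ---------------------------------------------------------------------------

def _gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out the gene universe and per-gene baseline abundances.

    Baselines sit on a log-normal grid; signature and PAG genes are boosted to
    moderate-high abundance so their signal survives count noise at realistic
    library sizes.
    """
    names: list[str] = list(TDS_PANEL)
    names += [f"BRAFSIG{i:03d}" for i in range(1, config.n_braf_sig + 1)]
    names += [f"RASSIG{i:03d}" for i in range(1, config.n_ras_sig + 1)]
    names += [f"PAG{i:03d}" for i in range(1, config.n_pag + 1)]
    names += [f"MT-SIM{i:02d}" for i in range(1, config.n_mito + 1)]
    n_null = config.n_genes - len(names)
    names += [f"GENE{i:04d}" for i in range(1, n_null + 1)]

    tab = pd.DataFrame(index=pd.Index(names, name="gene"))
    tab["tds_panel"] = tab.index.isin(TDS_PANEL)
    tab["braf_sig"] = tab.index.str.startswith("BRAFSIG")
    tab["ras_sig"] = tab.index.str.startswith("RASSIG")
    tab["pag"] = tab.index.str.startswith("PAG")
    tab["mito"] = tab.index.str.startswith("MT-")
    tab["null"] = ~(tab.tds_panel | tab.braf_sig | tab.ras_sig | tab.pag | tab.mito)

    direction = np.zeros(len(tab), dtype=int)
    pag_idx = np.flatnonzero(tab["pag"].to_numpy())
    # alternate up/down so both signs of monotone change are planted
    direction[pag_idx[::2]] = 1
    direction[pag_idx[1::2]] = -1
    tab["pag_direction"] = direction

    base = rng.normal(loc=0.0, scale=1.5, size=len(tab))
    # signature and planted-PAG genes are abundant in this lineage (the real
    # panels are high expressors in thyrocytes), so their baselines sit in a
    # tighter high band and their signal survives count noise
    planted = (tab.tds_panel | tab.braf_sig | tab.ras_sig | tab.pag).to_numpy()
    base[planted] = rng.normal(
        loc=config.planted_base_log2_mean,
        scale=config.planted_base_log2_sd,
        size=int(planted.sum()),
    )
    tab["base_log2"] = base
    return tab


def _effect_log2(genes: pd.DataFrame, t: np.ndarray, effect_size: float) -> np.ndarray:
    """Per-gene log2 mean shift at latent coordinate t (genes x observations).

    TDS panel and RAS signature fall with t; BRAF signature rises; planted
    PAGs follow their planted direction. Null and mito genes are flat.
    """
    t = np.asarray(t, dtype=float)[None, :]
    slope = np.zeros((len(genes), 1))
    slope[genes["tds_panel"].to_numpy(), 0] = -effect_size
    slope[genes["ras_sig"].to_numpy(), 0] = -effect_size
    slope[genes["braf_sig"].to_numpy(), 0] = effect_size
    pag = genes["pag"].to_numpy()
    slope[pag, 0] = effect_size * genes.loc[pag, "pag_direction"].to_numpy()
    return slope * t


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

def generate_reference_cohort(
    config: SimConfig,
    stream: str = "bulk",
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a labeled bulk cohort in TPM.

    ``stream`` names the sample-level randomness stream: two calls with the
    same config but different streams yield independent cohorts over the
    *same* gene universe (baselines and panels), the way an independent
    validation cohort shares the transcriptome with the reference cohort.

    Returns ``(tpm, labels, truth)`` where ``tpm`` is genes x samples with
    every column summing to 1e6, and ``labels`` carries per-sample
    ``malignancy`` (tumor/paratumor), ``mutation`` (BRAF/RAS, NA for
    paratumors) and planted ``subtype``.

    Tumor samples draw a latent malignancy coordinate whose range depends on
    their planted subtype (BRAF-like-B highest); the coordinate down-shifts
    the TDS panel and up-shifts the BRAF signature by ``effect_size`` log2
    units across its full range. Subtypes are additionally separated by
    subtype-specific offsets on the planted PAG block, which is the structure
    the PAG-based subtyping stage recovers.
    """
    config.validate()
    if config.n_bulk_tumor == 0 or config.n_bulk_paratumor == 0:
        raise ConfigurationError("both tumor and paratumor samples are required")
    if config.n_braf == 0 or config.n_ras == 0:
        raise ConfigurationError("both BRAF-mut and RAS-mut tumors are required")

    rng = child_rng(config.seed, stream)
    genes = _gene_table(config, child_rng(config.seed, "genes"))

    n_t, n_p = config.n_bulk_tumor, config.n_bulk_paratumor
    sample_ids = [f"T{i:03d}" for i in range(1, n_t + 1)] + [
        f"P{i:03d}" for i in range(1, n_p + 1)
    ]

    mutation = np.array(["BRAF"] * config.n_braf + ["RAS"] * config.n_ras + [""] * n_p)
    subtype = np.array([""] * (n_t + n_p), dtype=object)
    n_a = (config.n_braf + 1) // 2
    subtype[:n_a] = "BRAF-like-A"
    subtype[n_a:config.n_braf] = "BRAF-like-B"
    subtype[config.n_braf:n_t] = "RAS-like"

    malignancy_coord = np.empty(n_t + n_p)
    for i in range(n_t):
        lo, hi = _SUBTYPE_MALIGNANCY[subtype[i]]
        malignancy_coord[i] = rng.uniform(lo, hi)
    malignancy_coord[n_t:] = rng.uniform(*_PARATUMOR_MALIGNANCY, size=n_p)

    log2expr = (
        genes["base_log2"].to_numpy()[:, None]
        + _effect_log2(genes, malignancy_coord, config.effect_size)
        + rng.normal(scale=config.bulk_noise_sd, size=(len(genes), n_t + n_p))
    )

    # subtype fingerprints on the planted PAG block: BRAF-like-A perturbs the
    # first half of the block, BRAF-like-B the second half; RAS-like stays at
    # baseline. Each fingerprint is mass-balanced (up and down in equal parts)
    # and damped to half the single-cell effect, since bulk expression
    # averages over a tumor's cell mixture
    pag_idx = np.flatnonzero(genes["pag"].to_numpy())
    q = len(pag_idx) // 4
    shift = 0.5 * config.effect_size
    for j in range(n_t):
        if subtype[j] == "BRAF-like-A":
            log2expr[pag_idx[:q], j] += shift
            log2expr[pag_idx[q:2 * q], j] -= shift
        elif subtype[j] == "BRAF-like-B":
            log2expr[pag_idx[2 * q:3 * q], j] += shift
            log2expr[pag_idx[3 * q:4 * q], j] -= shift

    expr = np.exp2(log2expr)
    tpm = expr / expr.sum(axis=0, keepdims=True) * 1e6
    tpm = pd.DataFrame(tpm, index=genes.index, columns=sample_ids)

    labels = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "malignancy": ["tumor"] * n_t + ["paratumor"] * n_p,
            "mutation": [m or pd.NA for m in mutation],
            "subtype": [s or pd.NA for s in subtype],
            "malignancy_coord": malignancy_coord,
        }
    ).set_index("sample_id")

    truth = GroundTruth(genes=genes, bulk_samples=labels.copy())
    return tpm, labels, truth


# ---------------------------------------------------------------------------
# single-cell dataset
# ---------------------------------------------------------------------------

def generate_single_cell_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a single-cell UMI count matrix with annotation and truth.

    Returns ``(counts, annotation, truth)``: ``counts`` is genes x cells
    (integer UMIs), ``annotation`` has per-cell sample, tissue, state,
    pseudotime, branch and malignant flag.

    Counts are negative-binomial around state-specific means: each cell draws
    a pseudotime from its state's interval, the shared gene-effect model maps
    pseudotime to per-gene log2 shifts, relative abundances are renormalized
    per cell, and a log-normal library size scales them to expected counts.
    Mitochondrial genes receive a per-cell Beta-distributed mass fraction so
    that UMI totals and mito fractions straddle the QC thresholds.
    """
    config.validate()
    rng = child_rng(config.seed, "cells")
    genes = _gene_table(config, child_rng(config.seed, "genes"))

    states: list[str] = []
    for s in STATES:
        states += [s] * int(config.n_cells_per_state.get(s, 0))
    n_cells = len(states)
    if n_cells == 0:
        raise ConfigurationError("no cells requested")
    state_arr = np.array(states)

    t = np.empty(n_cells)
    for s in STATES:
        m = state_arr == s
        lo, hi = _STATE_TIME[s]
        t[m] = rng.uniform(lo, hi, size=m.sum())

    branch = np.where(t <= _BRANCH_POINT, "root", "")
    beyond = t > _BRANCH_POINT
    # dediff-like cells sit on branch B, pEMT-like on branch A; follicular-like
    # cells past the branch point split at random
    b_choice = rng.random(n_cells) < 0.5
    branch = np.where(beyond & (state_arr == "pemt_like"), "A", branch)
    branch = np.where(beyond & (state_arr == "dediff_like"), "B", branch)
    fol_beyond = beyond & (state_arr == "follicular_like")
    branch = np.where(fol_beyond & b_choice, "A", branch)
    branch = np.where(fol_beyond & ~b_choice, "B", branch)

    tissue = np.empty(n_cells, dtype=object)
    mix = config.tissue_mix
    for s in STATES:
        m = state_arr == s
        if m.sum() == 0:
            continue
        p = mix.loc[s].to_numpy()
        tissue[m] = rng.choice(list(mix.columns), size=m.sum(), p=p / p.sum())

    # relative abundance per cell
    log2rel = genes["base_log2"].to_numpy()[:, None] + _effect_log2(
        genes, t, config.effect_size
    )
    rel = np.exp2(log2rel)
    mito = genes["mito"].to_numpy()
    rel[mito, :] = 0.0
    rel /= rel.sum(axis=0, keepdims=True)

    # per-cell mito mass fraction, Beta with mean ~0.067 so a tail crosses 0.10
    mito_frac = rng.beta(2.0, 28.0, size=n_cells)
    mito_w = rng.lognormal(sigma=0.4, size=(int(mito.sum()), n_cells))
    mito_w /= mito_w.sum(axis=0, keepdims=True)
    rel *= (1.0 - mito_frac)[None, :]
    rel[mito, :] = mito_w * mito_frac[None, :]

    lib = rng.lognormal(
        mean=config.library_size_log_mean, sigma=config.library_size_log_sd, size=n_cells
    )
    mu = rel * lib[None, :]

    if config.dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / config.dispersion
        counts = rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-300)))

    cell_ids = [f"cell{i:05d}" for i in range(1, n_cells + 1)]
    counts = pd.DataFrame(counts, index=genes.index, columns=cell_ids)

    annotation = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample": [f"{tis}_s1" for tis in tissue],
            "tissue": tissue,
            "state": state_arr,
            "malignant": [s in _MALIGNANT_STATES for s in state_arr],
            "pseudotime": t,
            "branch": branch,
        }
    ).set_index("cell_id")

    truth = GroundTruth(genes=genes, cells=annotation.copy())
    return counts, annotation, truth


# ---------------------------------------------------------------------------
# hand-auditable fixtures
# ---------------------------------------------------------------------------

def generate_toy_fixture() -> dict[str, pd.DataFrame]:
    """Tiny deterministic fixtures with hand-auditable values.

    Returns a dict with:

    * ``bulk_tpm`` — 15 genes x 5 samples; the 13 TDS panel genes are laid out
      so sample ``S0`` sits exactly at every gene's per-sample median (TDS 0).
    * ``bulk_labels`` — tumor/paratumor labels for those samples.
    * ``contingency_cells`` — 40 cells forming the cluster x tissue table
      [[20, 0], [0, 20]].
    * ``knn_bulk`` / ``knn_labels`` / ``knn_cells`` — a 10-gene, 6-sample
      reference plus 3 query cells; ``cellA`` is value-identical to tumor
      sample ``T1`` and ``cellB`` is a monotone transform of paratumor ``P1``.

    All values are literal constants; the fixture is byte-stable.
    """
    tds = list(TDS_PANEL)
    rows = {}
    for i, g in enumerate(tds):
        base = 10.0 + i
        # S0 at the median of each gene; S1..S4 spread around it
        rows[g] = [base, base - 2.0, base - 1.0, base + 1.0, base + 2.0]
    rows["GENEX1"] = [5.0, 4.0, 6.0, 5.5, 4.5]
    rows["GENEX2"] = [1.0, 2.0, 1.5, 0.5, 2.5]
    bulk_tpm = pd.DataFrame(rows, index=["S0", "S1", "S2", "S3", "S4"]).T
    bulk_labels = pd.DataFrame(
        {"malignancy": ["paratumor", "tumor", "tumor", "paratumor", "tumor"]},
        index=pd.Index(["S0", "S1", "S2", "S3", "S4"], name="sample_id"),
    )

    contingency_cells = pd.DataFrame(
        {
            "cluster": ["c1"] * 20 + ["c2"] * 20,
            "tissue": ["tumor"] * 20 + ["paratumor"] * 20,
        },
        index=pd.Index([f"cell{i:02d}" for i in range(40)], name="cell_id"),
    )

    g10 = [f"g{i}" for i in range(1, 11)]
    knn_bulk = pd.DataFrame(
        {
            "T1": [9.0, 8.0, 7.5, 7.0, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5],
            "T2": [8.5, 9.0, 7.0, 6.5, 3.5, 2.0, 2.5, 1.0, 1.5, 0.8],
            "T3": [9.5, 7.5, 8.0, 7.2, 2.8, 3.0, 1.8, 1.2, 0.9, 0.6],
            "P1": [1.0, 1.5, 2.0, 2.5, 7.0, 7.5, 8.0, 8.5, 9.0, 9.5],
            "P2": [0.8, 1.2, 2.5, 2.2, 7.2, 8.0, 7.8, 9.0, 8.6, 9.2],
            "P3": [1.2, 0.9, 1.8, 2.8, 6.8, 7.2, 8.4, 8.2, 9.4, 9.0],
        },
        index=g10,
    )
    knn_labels = pd.DataFrame(
        {"malignancy": ["tumor", "tumor", "tumor", "paratumor", "paratumor", "paratumor"]},
        index=pd.Index(["T1", "T2", "T3", "P1", "P2", "P3"], name="sample_id"),
    )
    knn_cells = pd.DataFrame(
        {
            "cellA": knn_bulk["T1"].to_numpy(),               # identical to T1
            "cellB": np.sqrt(knn_bulk["P1"].to_numpy()),      # monotone map of P1
            "cellC": [5.0, 4.0, 6.0, 5.5, 4.0, 6.5, 5.2, 4.8, 5.8, 4.2],
        },
        index=g10,
    )

    return {
        "bulk_tpm": bulk_tpm,
        "bulk_labels": bulk_labels,
        "contingency_cells": contingency_cells,
        "knn_bulk": knn_bulk,
        "knn_labels": knn_labels,
        "knn_cells": knn_cells,
    }
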