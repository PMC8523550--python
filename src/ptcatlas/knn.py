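"""Bulk-referenced KNN malignancy classification of single cells.

Each cell is labeled malignant or non-malignant by majority vote among its k
nearest labeled bulk samples, with Spearman's rank correlation as the
similarity. Ranks make bulk TPM and cell log-normalized expression
commensurate, which is what lets a cross-platform reference work: any
per-observation monotone transform of expression leaves the prediction
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["KNNReference", "CellCall", "build_reference", "classify_cells", "validate_classifier"]

MALIGNANT = "malignant"
NON_MALIGNANT = "non-malignant"


@dataclass
class KNNReference:
    """Rank-transformed labeled bulk matrix over an HVG gene list."""

    genes: list[str]
    ranks: pd.DataFrame           # genes x samples, average ranks per sample
    labels: pd.Series             # per-sample: malignant / non-malignant
    k: int = 9
    n_dropped_hvgs: int = 0


@dataclass
class CellCall:
    """Prediction for one cell: label, vote count, and the neighbor set."""

    cell_id: str
    label: str                    # malignant / non-malignant / unclassifiable
    votes_malignant: int
    neighbors: list[str] = field(default_factory=list)
    correlations: list[float] = field(default_factory=list)


def build_reference(
    bulk: pd.DataFrame,
    labels: pd.Series | pd.DataFrame,
    hvgs: list[str],
    k: int = 9,
) -> KNNReference:
    """Rank-transform a labeled bulk cohort over the HVG/bulk intersection.

    ``labels`` maps sample id to malignant/non-malignant (a 'malignancy'
    column with tumor/paratumor values is also accepted and mapped). k must
    be odd so a binary majority never ties.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd for a binary majority vote")
    if isinstance(labels, pd.DataFrame):
        labels = labels["malignancy"]
    labels = labels.map(
        {"tumor": MALIGNANT, "paratumor": NON_MALIGNANT, MALIGNANT: MALIGNANT, NON_MALIGNANT: NON_MALIGNANT}
    )
    if labels.isna().any():
        raise ValueError("labels must be tumor/paratumor or malignant/non-malignant")
    if k > bulk.shape[1]:
        raise ValueError(f"k={k} exceeds the {bulk.shape[1]} reference samples")
    if labels.nunique() < 2:
        raise ValueError("reference must contain both labels")

    shared = [g for g in hvgs if g in bulk.index]
    dropped = len(hvgs) - len(shared)
    if len(shared) < 2:
        raise ValueError("fewer than 2 HVGs shared with the bulk matrix")
    if len(shared) < 50:
        warnings.warn(f"only {len(shared)} genes in the reference; discriminative power may be low")

    sub = bulk.loc[shared]
    ranks = pd.DataFrame(
        rankdata(sub.to_numpy(), axis=0), index=sub.index, columns=sub.columns
    )
    return KNNReference(
        genes=shared, ranks=ranks, labels=labels.loc[bulk.columns], k=k,
        n_dropped_hvgs=dropped,
    )


def _spearman_to_reference(cell_values: np.ndarray, ref_ranks: np.ndarray) -> np.ndarray:
    """Spearman correlation of one observation against every reference column.

    cell_values: (g,) raw values over the reference gene list; ref_ranks:
    (g, s) precomputed average ranks.
    """
    cr = rankdata(cell_values)
    cr = cr - cr.mean()
    rr = ref_ranks - ref_ranks.mean(axis=0, keepdims=True)
    denom = np.sqrt((cr ** 2).sum()) * np.sqrt((rr ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (cr @ rr) / denom


def classify_cells(ref: KNNReference, cells: pd.DataFrame) -> list[CellCall]:
    """Label each cell by majority vote among its k nearest bulk samples.

    Cells' genes missing from the reference list are zero-filled (absence in
    a dense 10x gene space means unmeasured) with a warning. Neighbors are
    the top-k samples by Spearman correlation, descending; boundary ties
    break by sample id. A cell with zero variance over the gene list is
    returned as "unclassifiable" rather than silently assigned.
    """
    missing = [g for g in ref.genes if g not in cells.index]
    if missing:
        warnings.warn(f"{len(missing)} reference genes absent from cells; zero-filled")
        cells = cells.reindex(ref.genes, fill_value=0.0)
    mat = cells.loc[ref.genes].to_numpy(dtype=float)
    ref_ranks = ref.ranks.to_numpy(dtype=float)
    sample_ids = np.asarray(ref.ranks.columns)
    labels = ref.labels.loc[ref.ranks.columns].to_numpy()
    # lexicographic sample-id order as the deterministic tie-break
    id_order = np.argsort(sample_ids)

    calls: list[CellCall] = []
    for j, cell_id in enumerate(cells.columns):
        v = mat[:, j]
        if np.ptp(v) == 0:
            calls.append(CellCall(str(cell_id), "unclassifiable", 0))
            continue
        rho = _spearman_to_reference(v, ref_ranks)
        # stable sort on (-rho) over id-sorted candidates -> ties by sample id
        order = id_order[np.argsort(-rho[id_order], kind="stable")][: ref.k]
        votes = int((labels[order] == MALIGNANT).sum())
        label = MALIGNANT if votes > ref.k / 2 else NON_MALIGNANT
        calls.append(
            CellCall(
                str(cell_id), label, votes,
                neighbors=sample_ids[order].tolist(),
                correlations=rho[order].tolist(),
            )
        )
    return calls


def calls_to_frame(calls: list[CellCall]) -> pd.DataFrame:
    """Tabulate CellCalls (cell_id, label, votes_malignant)."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in calls],
            "label": [c.label for c in calls],
            "votes_malignant": [c.votes_malignant for c in calls],
        }
    ).set_index("cell_id")


def validate_classifier(
    ref: KNNReference,
    validation_bulk: pd.DataFrame,
    validation_labels: pd.Series | pd.DataFrame,
) -> dict:
    """Sensitivity/specificity of the reference on a held-out bulk cohort.

    Each validation sample is classified as if it were a cell. The validation
    cohort must be disjoint from the reference by sample id. A class absent
    from the validation set leaves its metric None (undefined), not 0.
    """
    if isinstance(validation_labels, pd.DataFrame):
        validation_labels = validation_labels["malignancy"]
    validation_labels = validation_labels.map(
        {"tumor": MALIGNANT, "paratumor": NON_MALIGNANT, MALIGNANT: MALIGNANT, NON_MALIGNANT: NON_MALIGNANT}
    )
    overlap = set(validation_bulk.columns) & set(ref.ranks.columns)
    if overlap:
        raise ValueError(f"validation cohort overlaps the reference: {sorted(overlap)[:5]}")

    calls = classify_cells(ref, validation_bulk)
    pred = pd.Series({c.cell_id: c.label for c in calls})
    truth = validation_labels.loc[pred.index]

    tp = int(((pred == MALIGNANT) & (truth == MALIGNANT)).sum())
    fn = int(((pred != MALIGNANT) & (truth == MALIGNANT)).sum())
    tn = int(((pred == NON_MALIGNANT) & (truth == NON_MALIGNANT)).sum())
    fp = int(((pred != NON_MALIGNANT) & (truth == NON_MALIGNANT)).sum())

    sensitivity = tp / (tp + fn) if (tp + fn) else None
    specificity = tn / (tn + fp) if (tn + fp) else None
    confusion = pd.crosstab(truth.rename("truth"), pred.rename("predicted"))
    return {"sensitivity": sensitivity, "specificity": specificity, "confusion": confusion}
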