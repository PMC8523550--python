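"""Refined molecular subtyping of bulk cohorts on pseudotime-associated genes.

Samples are clustered on per-gene z-scored log2(TPM+1) over the PAG list
(Ward agglomerative clustering, cut at three clusters) and the clusters are
labeled by their mean TDS: highest -> RAS-like; of the remaining two, the
higher-TDS cluster is BRAF-like-A and the lower BRAF-like-B (the subtype
characterized by loss of differentiation). The refined three-way call is
compared against the binary BRS call by collapsing BRAF-like-{A,B} back to
BRAF-like and counting reassignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.cluster import AgglomerativeClustering

__all__ = ["SubtypeAssignment", "refine_subtypes", "compare_assignments", "dendrogram_newick"]

REFINED_LABELS = ("RAS-like", "BRAF-like-A", "BRAF-like-B")


@dataclass
class SubtypeAssignment:
    """Per-sample subtyping result."""

    sample_id: str
    brs_value: float
    binary_call: str              # BRAF-like / RAS-like from the BRS sign
    refined_call: str             # RAS-like / BRAF-like-A / BRAF-like-B
    cluster: int


def _zscored_pag_matrix(tpm: pd.DataFrame, pags: list[str]) -> pd.DataFrame:
    present = [g for g in pags if g in tpm.index]
    if len(present) < 2:
        raise ValueError("fewer than 2 PAG genes present in the matrix")
    if len(present) < len(pags):
        warnings.warn(f"{len(pags) - len(present)} PAG genes absent from the matrix")
    log2 = np.log2(tpm.loc[present] + 1.0)
    sd = log2.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} constant PAG genes excluded")
    if keep.sum() < 2:
        # fully degenerate cohort (e.g. identical samples): center only so
        # clustering stays defined; callers see the constant-gene warning
        warnings.warn("no informative PAG genes; cohort is degenerate")
        return log2.sub(log2.mean(axis=1), axis=0)
    log2 = log2.loc[keep]
    return log2.sub(log2.mean(axis=1), axis=0).div(log2.std(axis=1, ddof=0), axis=0)


def refine_subtypes(
    tpm: pd.DataFrame,
    pags: list[str],
    tds: pd.Series,
    brs_values: pd.DataFrame | pd.Series,
    linkage_method: str = "ward",
    mode: str = "joint",
) -> list[SubtypeAssignment]:
    """Three-way PAG-based subtype assignment for a bulk cohort.

    ``brs_values`` is either the frame returned by :func:`ptcatlas.signatures.brs`
    (columns brs, call) or a bare per-sample BRS series. ``mode="joint"``
    clusters all samples into 3 groups and labels them by mean TDS;
    ``mode="split"`` first splits by the binary BRS call and subclusters the
    BRAF-like samples into two.
    """
    if tpm.shape[1] < 3:
        raise ValueError("need at least 3 samples to form 3 subtypes")
    if isinstance(brs_values, pd.Series):
        brs_values = pd.DataFrame(
            {"brs": brs_values, "call": np.where(brs_values < 0, "BRAF-like", "RAS-like")}
        )
    missing = set(tpm.columns) - set(tds.index) | set(tpm.columns) - set(brs_values.index)
    if missing:
        raise ValueError(f"tds/brs do not cover all samples: {sorted(missing)[:5]}")

    z = _zscored_pag_matrix(tpm, pags)
    x = z.to_numpy().T                       # samples x genes

    if mode == "joint":
        metric_kw = {} if linkage_method == "ward" else {"metric": "euclidean"}
        model = AgglomerativeClustering(n_clusters=3, linkage=linkage_method, **metric_kw)
        clusters = model.fit_predict(x)
    elif mode == "split":
        clusters = np.full(tpm.shape[1], -1)
        call = brs_values.loc[tpm.columns, "call"].to_numpy()
        ras_mask = call == "RAS-like"
        clusters[ras_mask] = 0
        braf_idx = np.flatnonzero(~ras_mask)
        if len(braf_idx) < 2:
            raise ValueError("split mode needs at least 2 BRAF-like samples")
        sub = AgglomerativeClustering(n_clusters=2, linkage=linkage_method).fit_predict(
            x[braf_idx]
        )
        clusters[braf_idx] = sub + 1
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    sizes = pd.Series(clusters).value_counts()
    if (sizes == 1).any():
        warnings.warn("singleton cluster in subtype assignment")
    if len(sizes) < 3:
        warnings.warn("degenerate clustering: fewer than 3 distinct clusters")

    # map clusters to labels by mean TDS (descending); mean BRS breaks ties
    tds_vals = tds.loc[tpm.columns].to_numpy(dtype=float)
    brs_num = brs_values.loc[tpm.columns, "brs"].to_numpy(dtype=float)
    stats_tab = []
    for c in sorted(set(clusters)):
        m = clusters == c
        stats_tab.append((c, tds_vals[m].mean(), brs_num[m].mean()))
    # higher TDS first; higher (more RAS-like) BRS first on ties
    stats_tab.sort(key=lambda row: (-row[1], -row[2], row[0]))
    label_of = {c: REFINED_LABELS[i] for i, (c, _, _) in enumerate(stats_tab)}

    out = []
    for j, s in enumerate(tpm.columns):
        out.append(
            SubtypeAssignment(
                sample_id=str(s),
                brs_value=float(brs_num[j]),
                binary_call=str(brs_values.loc[s, "call"]),
                refined_call=label_of[clusters[j]],
                cluster=int(clusters[j]),
            )
        )
    return out


def assignments_to_frame(assignments: list[SubtypeAssignment]) -> pd.DataFrame:
    """Tabulate SubtypeAssignments indexed by sample id."""
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "brs": [a.brs_value for a in assignments],
            "binary_call": [a.binary_call for a in assignments],
            "refined_call": [a.refined_call for a in assignments],
            "cluster": [a.cluster for a in assignments],
        }
    ).set_index("sample_id")


def compare_assignments(
    binary_calls: pd.Series, refined_calls: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Reassignment fraction between binary BRS calls and refined subtypes.

    A sample counts as changed iff its refined macro-class (BRAF-like-A/B
    collapsed to BRAF-like) differs from its binary call. Returns the
    fraction and the full binary x refined cross-table.
    """
    if set(binary_calls.index) != set(refined_calls.index):
        diff = set(binary_calls.index) ^ set(refined_calls.index)
        raise ValueError(f"sample sets differ: {sorted(diff)[:5]}")
    refined = refined_calls.loc[binary_calls.index]
    macro = refined.map(
        {"RAS-like": "RAS-like", "BRAF-like-A": "BRAF-like", "BRAF-like-B": "BRAF-like"}
    )
    if macro.isna().any():
        raise ValueError("refined calls must be RAS-like / BRAF-like-A / BRAF-like-B")
    changed = (macro != binary_calls).sum()
    fraction = float(changed) / len(binary_calls)
    table = pd.crosstab(binary_calls.rename("binary"), refined.rename("refined"))
    return fraction, table


def dendrogram_newick(tpm: pd.DataFrame, pags: list[str], linkage_method: str = "ward") -> str:
    """Newick string of the sample dendrogram used for subtyping."""
    z = _zscored_pag_matrix(tpm, pags)
    lk = linkage(z.to_numpy().T, method=linkage_method)
    tree = to_tree(lk)
    names = list(map(str, tpm.columns))

    def rec(node) -> str:
        if node.is_leaf():
            return names[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"
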