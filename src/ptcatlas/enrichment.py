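"""Ro/e tissue-preference statistic for cluster x tissue tables.

Ro/e is the ratio of observed to expected cell counts per (cluster, tissue)
cell of a contingency table, with expectations from the independence margins
(the chi-square expected counts). Values above 1 indicate the cluster is
over-represented in that tissue; the statistic is reported descriptively,
with a whole-table chi-square test as an auxiliary column.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["ro_e"]


def ro_e(
    annotation: pd.DataFrame,
    cluster_key: str = "cluster",
    tissue_key: str = "tissue",
) -> pd.DataFrame:
    """Long-format Ro/e table from a per-cell annotation frame.

    Cells with a missing cluster or tissue are excluded (count reported via a
    warning); tissues with zero cells are dropped. Returns columns cluster,
    tissue, observed, expected, ro_e, chi2_p (the whole-table chi-square
    p-value, repeated on every row).
    """
    sub = annotation[[cluster_key, tissue_key]]
    n_missing = int(sub.isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(f"{n_missing} cells with missing {cluster_key}/{tissue_key} excluded")
        sub = sub.dropna()
    if len(sub) == 0:
        raise ValueError("no usable cells")

    obs = pd.crosstab(sub[cluster_key], sub[tissue_key])
    empty_cols = obs.columns[obs.sum(axis=0) == 0]
    if len(empty_cols):
        warnings.warn(f"tissues with zero cells dropped: {list(empty_cols)}")
        obs = obs.drop(columns=empty_cols)
    if obs.shape[1] < 2:
        raise ValueError("need at least 2 tissues with cells")

    row = obs.sum(axis=1).to_numpy(dtype=float)
    col = obs.sum(axis=0).to_numpy(dtype=float)
    expected = np.outer(row, col) / obs.to_numpy().sum()
    ratio = obs.to_numpy() / expected

    if (obs.shape[0] >= 2) and (obs.shape[1] >= 2) and obs.to_numpy().sum() > 0:
        chi2_p = float(chi2_contingency(obs.to_numpy())[1]) if obs.shape[0] > 1 else np.nan
    else:
        chi2_p = np.nan

    out = []
    for i, c in enumerate(obs.index):
        for j, t in enumerate(obs.columns):
            out.append(
                {
                    "cluster": c,
                    "tissue": t,
                    "observed": int(obs.iat[i, j]),
                    "expected": expected[i, j],
                    "ro_e": ratio[i, j],
                    "chi2_p": chi2_p,
                }
            )
    return pd.DataFrame(out)
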