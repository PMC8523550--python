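"""Readers and writers for the standard on-disk formats.

Single-cell counts travel as 10x-style MatrixMarket triplets (matrix.mtx with
1-based coordinates, features.tsv, barcodes.tsv); bulk matrices, annotations
and score tables as TSV with genes in rows and a header of observation ids;
gene signatures as one-symbol-per-line text files with ``#`` comments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_mtx_dir",
    "read_mtx_dir",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_signature",
    "write_signature",
]


def write_mtx_dir(counts: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write a genes x cells count matrix as matrix.mtx + features/barcodes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    return out


def read_mtx_dir(in_dir: str | Path) -> pd.DataFrame:
    """Read a matrix.mtx + features.tsv + barcodes.tsv directory."""
    d = Path(in_dir)
    mat = spio.mmread(d / "matrix.mtx").toarray()
    features = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    return pd.DataFrame(np.asarray(mat), index=features, columns=barcodes)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Genes-in-rows TSV with a header of observation ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_signature(path: str | Path) -> list[str]:
    """One gene symbol per line; ``#`` starts a comment; blanks ignored."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        name = line.split("#", 1)[0].strip()
        if name:
            genes.append(name)
    return genes


def write_signature(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")
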