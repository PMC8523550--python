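"""Score the thyroid differentiation and BRAF/RAS signatures on both cohorts.

Bulk: TDS per sample (sum of median-centered log2 expression over the
13-gene panel) and the BRS centroid score with BRAF-/RAS-like calls.
Single-cell: TDS, BRAF and RAS module scores per thyrocyte against
expression-matched random controls.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import ptcatlas as p

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = p.SimConfig(seed=SEED)
    tpm, labels, truth = p.generate_reference_cohort(cfg)

    tds = p.tds_bulk(tpm)
    sig71 = truth.genes.index[truth.genes.braf_sig | truth.genes.ras_sig].tolist()
    brs_tab = p.brs(
        np.log2(tpm + 1.0),
        labels.index[labels.mutation == "BRAF"].tolist(),
        labels.index[labels.mutation == "RAS"].tolist(),
        signature=sig71,
    )
    bulk_scores = pd.DataFrame({"tds": tds}).join(brs_tab).join(labels)
    bulk_scores.to_csv(RESULTS / "signature_scores_bulk.tsv", sep="\t")

    print("bulk TDS by group:")
    print(bulk_scores.groupby("malignancy")["tds"].mean().round(2).to_string())
    agree = (
        bulk_scores.dropna(subset=["mutation"])
        .assign(expected=lambda d: d.mutation.map({"BRAF": "BRAF-like", "RAS": "RAS-like"}))
        .pipe(lambda d: (d.call == d.expected).mean())
    )
    print(f"BRS call agrees with mutation for {agree:.0%} of tumors")

    counts, annotation, truth_sc = p.generate_single_cell_dataset(cfg)
    ln = p.log_normalize(counts)
    params = p.ModuleScoreParams(n_ctrl=30, seed=SEED)
    cell_scores = p.braf_ras_cell_scores(
        ln,
        truth_sc.genes.index[truth_sc.genes.braf_sig].tolist(),
        truth_sc.genes.index[truth_sc.genes.ras_sig].tolist(),
        params,
    )
    cell_scores["tds"] = p.tds_single_cell(ln, params=params)
    cell_scores = cell_scores.join(annotation[["state", "pseudotime"]])
    cell_scores.to_csv(RESULTS / "signature_scores_cells.tsv", sep="\t")

    print("\nper-state mean module scores:")
    print(
        cell_scores.groupby("state", observed=True)[["tds", "braf_score", "ras_score"]]
        .mean()
        .round(3)
        .to_string()
    )


if __name__ == "__main__":
    main()
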