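"""Generate the synthetic study cohorts and summarize their composition.

Produces the two datasets every later step consumes: a labeled bulk TPM
cohort (50 tumors split 30 BRAF-mut / 20 RAS-mut, 50 paratumors) and a
500-cell single-cell count matrix over five thyrocyte states with a
branching pseudotime. Full matrices land in scratch/ (regenerated on demand
from the seed); small summary tables go to results/.
"""

from pathlib import Path

import ptcatlas as p
from ptcatlas.io import write_matrix_tsv, write_mtx_dir

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg = p.SimConfig(seed=SEED)

    tpm, labels, _ = p.generate_reference_cohort(cfg)
    counts, annotation, truth = p.generate_single_cell_dataset(cfg)

    write_matrix_tsv(tpm, SCRATCH / "bulk_tpm.tsv")
    labels.to_csv(SCRATCH / "bulk_labels.tsv", sep="\t")
    write_mtx_dir(counts, SCRATCH / "sc_counts")
    annotation.to_csv(SCRATCH / "cell_annotation.tsv", sep="\t")

    bulk_summary = labels.groupby(["malignancy", "mutation"], dropna=False).size()
    cell_summary = annotation.groupby(["state", "tissue"], observed=True).size()
    bulk_summary.rename("n").to_csv(RESULTS / "cohort_bulk_composition.tsv", sep="\t")
    cell_summary.rename("n").to_csv(RESULTS / "cohort_cell_composition.tsv", sep="\t")

    print(f"bulk cohort: {tpm.shape[1]} samples x {tpm.shape[0]} genes")
    print(bulk_summary.to_string())
    print(f"\nsingle-cell: {counts.shape[1]} cells, median UMI {counts.sum().median():.0f}")
    print(cell_summary.unstack(fill_value=0).to_string())


if __name__ == "__main__":
    main()
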