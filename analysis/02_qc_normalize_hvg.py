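"""Quality control, normalization and highly variable gene selection.

Applies the standard droplet QC gates (mito fraction <= 10%, 500 <= UMI <=
5000), log-normalizes survivors to 10,000 counts, and picks the 500 most
variable genes of the 1000-gene universe as the feature space for the
cell-vs-bulk classifier.
"""

from pathlib import Path

import ptcatlas as p

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    counts, annotation, _ = p.generate_single_cell_dataset(p.SimConfig(seed=SEED))

    filtered, report = p.qc_filter(counts)
    summary = report.groupby(report.reason.replace("", "passed")).agg(
        n=("umi", "size"), median_umi=("umi", "median"), median_mito=("mito_fraction", "median")
    )
    summary.to_csv(RESULTS / "qc_summary.tsv", sep="\t")
    print(f"QC: {filtered.shape[1]} / {counts.shape[1]} cells retained")
    print(summary.round(3).to_string())

    hvgs = p.select_hvgs(counts, n=500)
    (RESULTS / "hvgs.txt").write_text("\n".join(hvgs) + "\n")
    print(f"\nwrote {len(hvgs)} HVGs to results/hvgs.txt")


if __name__ == "__main__":
    main()
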