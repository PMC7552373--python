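"""Screen differentially expressed genes for each comparison.

Per-gene unpaired Student's t-tests (p < 0.05, unadjusted) for the pooled
disorder-vs-healthy contrast and for each disease separately, plus
complete-linkage two-way clustering of the DEG submatrix for heatmap
ordering. Writes DEG tables and newick trees under results/.
"""

from pathlib import Path

from lungsig.ingest import read_expression
from lungsig.differential import student_t_test, select_degs, two_way_clustering

RESULTS = Path(__file__).resolve().parent.parent / "results"

COMPARISONS = {
    "disorder_vs_healthy": ["IPF", "NSCLC"],
    "IPF_vs_healthy": ["IPF"],
    "NSCLC_vs_healthy": ["NSCLC"],
}


def main() -> None:
    merged = read_expression(RESULTS / "merged_expression.tsv",
                             RESULTS / "data" / "sample_sheet.tsv")
    for name, group in COMPARISONS.items():
        sub = merged.subset_samples(merged.phenotype_mask(group + ["healthy"]))
        degs = select_degs(student_t_test(sub, group), alpha=0.05)
        degs.to_csv(RESULTS / f"degs_{name}.tsv", sep="\t")
        n_up = int((degs["direction"] > 0).sum())
        print(f"{name}: {len(degs)} DEGs at p<0.05 "
              f"({n_up} up, {len(degs) - n_up} down)")
        twc = two_way_clustering(sub.subset_genes(degs.index))
        (RESULTS / f"tree_genes_{name}.nwk").write_text(twc.gene_newick())
        (RESULTS / f"tree_samples_{name}.nwk").write_text(twc.sample_newick())


if __name__ == "__main__":
    main()
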