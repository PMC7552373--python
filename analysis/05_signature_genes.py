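"""Select signature genes by PCA loadings on probit-significant components.

For each comparison: PCA of the weight-filtered expression, components up
to 85% cumulative variance tested one at a time by Bayesian probit
regression against the phenotype, and genes with |loading| > 0.6 on a
significant (p < 0.05) component selected as the signature. The IPF and
NSCLC signatures are intersected (direction-consistent) into the common
signature. Writes PCA summaries, probit tables and signature TSVs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lungsig.ingest import read_expression
from lungsig.classify import filter_by_weight
from lungsig.signature import (
    fit_pca, select_components, probit_significance, select_signature_genes,
    intersect_signatures,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

COMPARISONS = {
    "disorder_vs_healthy": ["IPF", "NSCLC"],
    "IPF_vs_healthy": ["IPF"],
    "NSCLC_vs_healthy": ["NSCLC"],
}


def main() -> None:
    merged = read_expression(RESULTS / "merged_expression.tsv",
                             RESULTS / "data" / "sample_sheet.tsv")
    signatures = {}
    for name, group in COMPARISONS.items():
        sub = merged.subset_samples(merged.phenotype_mask(group + ["healthy"]))
        degs = pd.read_csv(RESULTS / f"degs_{name}.tsv", sep="\t", index_col=0)
        weights = pd.read_csv(RESULTS / f"weights_{name}.tsv", sep="\t", index_col=0)
        kept = filter_by_weight(weights, 1.0)
        pca = fit_pca(sub.subset_genes(kept))
        pca.summary().to_csv(RESULTS / f"pca_summary_{name}.tsv", sep="\t")
        candidates = select_components(pca, 0.85)
        labels = np.where(sub.phenotype_mask(group), "disease", "healthy")
        tests = probit_significance(pca.scores[candidates], labels,
                                    positive="disease")
        tests.to_csv(RESULTS / f"probit_{name}.tsv", sep="\t")
        significant = tests.index[tests["p"] < 0.05].tolist()
        sig = select_signature_genes(pca, significant, degs["direction"],
                                     loading_threshold=0.6, comparison=name)
        sig.to_csv(RESULTS / f"signature_{name}.tsv", sep="\t")
        signatures[name] = sig
        print(f"{name}: significant PCs {significant} "
              f"-> {len(sig)} signature genes")

    common, conflicts = intersect_signatures(
        signatures["IPF_vs_healthy"], signatures["NSCLC_vs_healthy"])
    common.to_csv(RESULTS / "common_signature.tsv", sep="\t")
    print(f"common signature: {len(common)} genes shared by IPF and NSCLC "
          f"with consistent direction ({len(conflicts)} direction conflicts)")


if __name__ == "__main__":
    main()
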