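"""Supervised classification of the DEG-filtered expression data.

Trains the RBF-kernel SVM per comparison, extracts per-gene weight
coefficients, keeps genes with weight > 1.0, and evaluates each model by
leave-one-out cross-validation (predictive power, ROC/AUC). Writes
weights, LOOCV predictions and ROC points under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from lungsig.ingest import read_expression
from lungsig.classify import (
    train_svm, gene_weights, filter_by_weight, loocv, predictive_power, roc_auc,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
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
        degs = pd.read_csv(RESULTS / f"degs_{name}.tsv", sep="\t", index_col=0)
        deg_m = sub.subset_genes(degs.index)
        model = train_svm(deg_m, group, seed=SEED)
        weights = gene_weights(model)
        weights.to_csv(RESULTS / f"weights_{name}.tsv", sep="\t")
        kept = filter_by_weight(weights, 1.0)
        preds = loocv(deg_m, group, seed=SEED)
        preds.to_csv(RESULTS / f"loocv_{name}.tsv", sep="\t")
        power, correct, total = predictive_power(preds)
        pos = group[0] if len(group) == 1 else "disorder"
        roc_points, auc = roc_auc(preds, positive=pos)
        roc_points.to_csv(RESULTS / f"roc_{name}.tsv", sep="\t", index=False)
        print(f"{name}: {len(kept)}/{len(degs)} genes with weight>1.0, "
              f"LOOCV predictive power {power}% ({correct}/{total}), "
              f"AUC {auc:.3f}")


if __name__ == "__main__":
    main()
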