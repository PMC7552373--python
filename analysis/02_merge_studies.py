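"""Merge the per-study cohorts into one cross-study "super array".

Reads the expression TSVs written by 01_simulate_cohorts.py, runs the
iterative-clustering normalization, and reports how much closer the two
studies' healthy-control centroids end up. Writes the merged matrix and
the fitted merge model under results/.
"""

import sys
from pathlib import Path

import numpy as np

from lungsig.ingest import read_expression
from lungsig.merge import merge_studies

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = RESULTS / "data"
    studies = [
        read_expression(path, data / "sample_sheet.tsv")
        for path in sorted(data.glob("expression_*.tsv"))
    ]
    a, b = studies

    def healthy_centroid(m):
        return m.values.loc[:, m.phenotype_mask("healthy")].mean(axis=1)

    pre = np.linalg.norm(healthy_centroid(a) - healthy_centroid(b))
    merged, model = merge_studies(studies, seed=SEED)
    sm = merged.samples
    cents = [
        merged.values.loc[:, ((sm.study_id == sid)
                              & (sm.phenotype == "healthy")).to_numpy()].mean(axis=1)
        for sid in sm.study_id.unique()
    ]
    post = np.linalg.norm(cents[0] - cents[1].to_numpy())
    print(f"merged {merged.n_genes} genes x {merged.n_samples} samples "
          f"in {model.n_iter} iterations (J {model.j_trace[0]:.0f} -> "
          f"{model.j_trace[-1]:.0f})")
    print(f"cross-study healthy centroid distance {pre:.1f} -> {post:.1f} "
          f"({100 * (1 - post / pre):.0f}% reduction)")
    merged.to_tsv(RESULTS / "merged_expression.tsv")
    model.to_json(RESULTS / "merge_model.json")


if __name__ == "__main__":
    main()
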