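"""DEG screening by per-gene Student's t-tests and two-way clustering.

The screen follows the classic microarray recipe: an unpaired
pooled-variance t-test per gene between a disease group and healthy
controls, an unadjusted p < alpha cut (Benjamini–Hochberg available but
off by default), and complete-linkage hierarchical clustering on
Euclidean distances over both genes and samples for heatmap ordering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from skbio import TreeNode

from .containers import ExpressionMatrix

__all__ = ["student_t_test", "select_degs", "two_way_clustering", "ClusterResult"]


def student_t_test(
    m: ExpressionMatrix,
    disease: str | list[str],
    control: str = "healthy",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test, disease vs control.

    ``disease`` may name one phenotype or a list pooled into a single
    disorder group.

    Returns a DEG table indexed by gene with columns ``t``, ``p``,
    ``direction`` (sign of mean_disease − mean_control), ``mean_disease``,
    ``mean_control`` and ``zero_variance`` (genes with no pooled variance,
    reported as p = 1). Pooled-variance (classic Student's) by default;
    ``welch=True`` switches to unequal variances.
    """
    dm = m.values.loc[:, m.phenotype_mask(disease)].to_numpy(dtype=float)
    cm = m.values.loc[:, m.phenotype_mask(control)].to_numpy(dtype=float)
    if dm.shape[1] < 2 or cm.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    t, p = stats.ttest_ind(dm, cm, axis=1, equal_var=not welch)
    mean_d, mean_c = dm.mean(axis=1), cm.mean(axis=1)
    flat = ~np.isfinite(t)
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    diff = mean_d - mean_c
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "direction": np.sign(diff).astype(int),
            "mean_disease": mean_d,
            "mean_control": mean_c,
            "zero_variance": flat,
        },
        index=m.genes,
    )


def select_degs(
    table: pd.DataFrame, alpha: float = 0.05, adjust: str | None = None
) -> pd.DataFrame:
    """Select genes with p < alpha, ordered by ascending p (ties by symbol).

    ``adjust="bh"`` applies Benjamini–Hochberg before thresholding
    (off by default, matching the unadjusted screen).
    """
    if table.empty:
        raise ValueError("empty DEG table")
    p = table["p"].to_numpy(dtype=float)
    if adjust == "bh":
        p = stats.false_discovery_control(p, method="bh")
    elif adjust is not None:
        raise ValueError(f"unknown adjustment: {adjust}")
    hits = table.loc[p < alpha].copy()
    hits["p_selected"] = p[p < alpha]
    # ascending p, ties broken by gene symbol
    return hits.sort_index(kind="stable").sort_values("p_selected", kind="stable")


@dataclass
class ClusterResult:
    """Two-way hierarchical clustering: linkage trees and leaf orders."""

    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    gene_order: list[str]
    sample_order: list[str]

    def gene_newick(self) -> str:
        return _to_newick(self.gene_linkage, self.gene_order_input)

    def sample_newick(self) -> str:
        return _to_newick(self.sample_linkage, self.sample_order_input)

    # input label orders (leaf ids in linkage refer to these)
    gene_order_input: list[str] = None
    sample_order_input: list[str] = None


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    buf = io.StringIO()
    TreeNode.from_linkage_matrix(Z, labels).write(buf)
    return buf.getvalue().strip()


def two_way_clustering(m: ExpressionMatrix) -> ClusterResult:
    """Complete-linkage Euclidean clustering over genes and over samples.

    Constant matrices are legal: all distances tie and the (deterministic)
    linkage order of the underlying implementation is used.
    """
    if m.n_genes < 2 or m.n_samples < 2:
        raise ValueError("need at least two genes and two samples")
    arr = m.values.to_numpy(dtype=float)
    gene_z = linkage(arr, method="complete", metric="euclidean")
    sample_z = linkage(arr.T, method="complete", metric="euclidean")
    genes = list(m.genes)
    samples = list(m.sample_ids)
    res = ClusterResult(
        gene_linkage=gene_z,
        sample_linkage=sample_z,
        gene_order=[genes[i] for i in leaves_list(gene_z)],
        sample_order=[samples[i] for i in leaves_list(sample_z)],
    )
    res.gene_order_input = genes
    res.sample_order_input = samples
    return res
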