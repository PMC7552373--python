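"""Cross-study merging into a single "super array".

Multiple studies measured on a shared gene universe are combined by an
XPN-style iterative-clustering normalization: genes and samples are
alternately k-means clustered, block means over (gene cluster × sample
cluster) cells summarize the shared biology, and each gene's per-study
affine response (sensitivity ``b`` and offset ``c``) relative to those
block means is harmonized toward the pooled, sample-size-weighted value.
The objective J — the squared distance between study-wise block centroids
and pooled block centroids — is tracked per iteration; the procedure
stops at relative convergence, and an iteration that fails to improve J
is rolled back, so the recorded trace is non-increasing.

Clustering operates on within-study standardized values so that samples
group by biology (phenotype) rather than by study-level batch offsets;
the affine correction itself is applied on the raw log2 scale.

Phenotypes present in only one study (here: each disease) are preserved:
their cluster structure enters the block means of that study alone, and
only the gene-level affine distortion — not the cluster-level signal — is
adjusted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix

__all__ = ["MergeModel", "merge_studies", "quantile_normalize_within"]

_EPS = 1e-12


@dataclass
class MergeModel:
    """Fitted merge: cluster assignments, objective trace and parameters."""

    gene_clusters: pd.Series
    sample_clusters: pd.Series
    j_trace: list[float]
    n_iter: int
    converged: bool
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "j_trace": self.j_trace,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "params": self.params,
            "gene_cluster_sizes": self.gene_clusters.value_counts().sort_index().tolist(),
            "sample_cluster_sizes": self.sample_clusters.value_counts().sort_index().tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def quantile_normalize_within(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize each column to the mean sorted profile."""
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = rows
    target = np.sort(arr, axis=0).mean(axis=1)
    return pd.DataFrame(target[ranks], index=values.index, columns=values.columns)


def merge_studies(
    studies: list[ExpressionMatrix],
    k_genes: int = 25,
    k_samples: int = 5,
    tol: float = 1e-4,
    max_iter: int = 50,
    seed: int = 0,
    quantile_normalize: bool = False,
) -> tuple[ExpressionMatrix, MergeModel]:
    """Merge ≥2 studies over their common genes.

    Returns the merged :class:`ExpressionMatrix` (gene intersection,
    all samples) and the fitted :class:`MergeModel` with its J trace.
    """
    if len(studies) < 2:
        raise ValueError("merge requires at least two studies")
    for em in studies:
        if em.n_samples < 2:
            raise ValueError("every study needs at least two samples")
    common = studies[0].genes
    for em in studies[1:]:
        common = common.intersection(em.genes)
    if len(common) == 0:
        raise ValueError("empty gene intersection across studies")
    common = common.sort_values()

    mats = []
    for em in studies:
        vals = em.values.loc[common]
        if quantile_normalize:
            vals = quantile_normalize_within(vals)
        mats.append(vals)
    X = pd.concat(mats, axis=1)
    sheet = pd.concat([em.samples for em in studies])
    study_of = sheet.loc[X.columns, "study_id"].to_numpy()
    phenotype_of = sheet.loc[X.columns, "phenotype"].to_numpy()
    study_ids = [em.samples["study_id"].iloc[0] for em in studies]
    n_genes, n_samples = X.shape
    if k_genes > n_genes:
        raise ValueError(f"k_genes={k_genes} exceeds {n_genes} common genes")
    if k_samples > n_samples:
        raise ValueError(f"k_samples={k_samples} exceeds {n_samples} samples")

    arr = X.to_numpy(dtype=float)
    best = arr.copy()
    j_trace: list[float] = []
    converged = False
    gc = np.zeros(n_genes, dtype=int)
    sc = np.zeros(n_samples, dtype=int)

    for _ in range(max_iter):
        Z = _standardize_within_study(arr, study_of, study_ids)
        gc = KMeans(k_genes, n_init=4, random_state=seed).fit_predict(Z)
        sc = KMeans(k_samples, n_init=4, random_state=seed).fit_predict(Z.T)
        A = _block_means(arr, gc, sc, k_genes, k_samples)
        j = _objective(arr, gc, sc, A, study_of, study_ids, k_genes, k_samples)
        if j_trace and j > j_trace[-1] + _EPS:
            break  # no improvement: roll back to the previous state
        best = arr.copy()
        if j_trace and abs(j_trace[-1] - j) <= tol * max(j_trace[-1], _EPS):
            j_trace.append(j)
            converged = True
            break
        j_trace.append(j)
        if j <= _EPS:
            converged = True
            break
        arr = _harmonize(arr, gc, sc, A, study_of, study_ids, phenotype_of)

    merged = ExpressionMatrix(
        pd.DataFrame(best, index=common, columns=X.columns), sheet.loc[X.columns]
    )
    model = MergeModel(
        gene_clusters=pd.Series(gc, index=common, name="gene_cluster"),
        sample_clusters=pd.Series(sc, index=X.columns, name="sample_cluster"),
        j_trace=j_trace,
        n_iter=len(j_trace),
        converged=converged,
        params={"k_genes": k_genes, "k_samples": k_samples, "tol": tol,
                "max_iter": max_iter, "seed": seed,
                "quantile_normalize": quantile_normalize},
    )
    return merged, model


def _standardize_within_study(arr, study_of, study_ids):
    """Per-gene z-scores within each study (zero-variance rows left at 0)."""
    Z = np.zeros_like(arr)
    for sid in study_ids:
        cols = study_of == sid
        block = arr[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        sd[sd < _EPS] = 1.0
        Z[:, cols] = (block - mu) / sd
    return Z


def _block_means(arr, gc, sc, k_genes, k_samples):
    A = np.zeros((k_genes, k_samples))
    for i in range(k_genes):
        gi = gc == i
        if not gi.any():
            continue
        sub = arr[gi]
        for j in range(k_samples):
            sj = sc == j
            if sj.any():
                A[i, j] = sub[:, sj].mean()
    return A


def _objective(arr, gc, sc, A, study_of, study_ids, k_genes, k_samples):
    """Size-weighted squared distance of study block centroids from pooled."""
    j_val = 0.0
    for i in range(k_genes):
        gi = gc == i
        if not gi.any():
            continue
        sub = arr[gi]
        for j in range(k_samples):
            sj = sc == j
            if not sj.any():
                continue
            for sid in study_ids:
                cell = sub[:, sj & (study_of == sid)]
                if cell.size:
                    j_val += cell.size * (cell.mean() - A[i, j]) ** 2
    return float(j_val)


def _harmonize(arr, gc, sc, A, study_of, study_ids, phenotype_of):
    """Harmonize each gene's per-study affine response toward the pooled one.

    For gene g in study p the model is x_gs ≈ b · A[α(g), β(s)] + c; the
    per-study (b, c) are replaced by their sample-size-weighted averages.
    Genes whose cluster profile carries no variation in some study (or a
    near-zero sensitivity) fall back to location-only matching of study
    means, which leaves within-study contrasts untouched.
    """
    out = arr.copy()
    n_genes = arr.shape[0]
    weights = np.array([float((study_of == sid).sum()) for sid in study_ids])
    weights = weights / weights.sum()

    n_studies = len(study_ids)
    b = np.ones((n_studies, n_genes))
    c = np.zeros((n_studies, n_genes))
    ok = np.zeros((n_studies, n_genes), dtype=bool)
    a_rows = A[gc]  # per-gene cluster profile over sample clusters

    # Offsets are only identifiable from biology present in every study:
    # anchor the intercepts on phenotypes shared by all studies (here the
    # healthy controls). Anchoring on study-exclusive groups (a disease
    # measured in one study only) would impute that study's composition
    # into the other studies' corrections.
    shared = [
        ph for ph in np.unique(phenotype_of)
        if all(((phenotype_of == ph) & (study_of == sid)).sum() >= 2
               for sid in study_ids)
    ]
    anchor = (np.isin(phenotype_of, shared) if shared
              else np.ones_like(study_of, dtype=bool))

    for p, sid in enumerate(study_ids):
        cols = study_of == sid
        a = a_rows[:, sc[cols]]  # genes × study samples
        x = arr[:, cols]
        a_mean = a.mean(axis=1)
        x_mean = x.mean(axis=1)
        a_var = ((a - a_mean[:, None]) ** 2).mean(axis=1)
        cov = ((a - a_mean[:, None]) * (x - x_mean[:, None])).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = cov / a_var
        # a trustworthy sensitivity needs profile variation in THIS study
        # and a slope of plausible magnitude; otherwise rescaling by the
        # cross-study average would shrink study-exclusive contrasts
        ok[p] = ((a_var > 0.05) & np.isfinite(slope)
                 & (np.abs(slope) > 0.4) & (np.abs(slope) < 2.5))
        b[p] = np.where(ok[p], slope, 1.0)
        anc = anchor[cols]
        c[p] = (x[:, anc].mean(axis=1)
                - b[p] * a_rows[:, sc[cols][anc]].mean(axis=1))

    usable = ok.all(axis=0)
    b_bar = np.einsum("p,pg->g", weights, b)
    c_bar = np.einsum("p,pg->g", weights, c)

    # location-only path: unit sensitivity, same anchored intercepts
    c_loc = np.zeros((n_studies, n_genes))
    for p, sid in enumerate(study_ids):
        cols = study_of == sid
        anc = anchor[cols]
        c_loc[p] = (arr[:, cols][:, anc].mean(axis=1)
                    - a_rows[:, sc[cols][anc]].mean(axis=1))
    c_loc_bar = np.einsum("p,pg->g", weights, c_loc)

    for p, sid in enumerate(study_ids):
        cols = study_of == sid
        x = out[:, cols]
        adj = b_bar[:, None] * (x - c[p][:, None]) / b[p][:, None] + c_bar[:, None]
        loc = x - c_loc[p][:, None] + c_loc_bar[:, None]
        out[:, cols] = np.where(usable[:, None], adj, loc)
    return out
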