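"""Signature-gene selection: PCA, probit component tests, loading threshold.

Principal components are extracted from the weight-filtered expression
matrix (samples × genes, gene-centered, unscaled). "Loading coefficients"
are defined on the correlation scale: the Pearson correlation between a
gene's expression and a component's score, bounded by ±1, so the
loading threshold (default |loading| > 0.6) is comparable across
matrices of any size.

Component relevance is assessed one PC at a time by Bayesian probit
regression of the phenotype on the standardized score with a
weakly-informative Student-t prior (df 1, i.e. Cauchy, scale 2.5) on the
slope — the penalty keeps the slope finite even under complete
separation. Significance is the two-sided Wald p of the slope at the
posterior mode. Components are considered up to the shortest prefix
reaching a cumulative variance proportion (default 85%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import ExpressionMatrix

__all__ = [
    "PCAModel", "fit_pca", "select_components", "probit_significance",
    "bayes_probit", "select_signature_genes", "intersect_signatures",
]


@dataclass
class PCAModel:
    """PC scores, correlation-scale loadings and variance proportions."""

    scores: pd.DataFrame      # samples × PCs
    loadings: pd.DataFrame    # genes × PCs (gene–score correlations)
    sdev: pd.Series           # per-PC standard deviation
    proportion: pd.Series     # eigenvalue / total variance
    cumulative: pd.Series
    constant_genes: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sdev": self.sdev, "proportion": self.proportion,
            "cumulative": self.cumulative,
        })


def fit_pca(m: ExpressionMatrix) -> PCAModel:
    """PCA of samples over genes (centered, not scaled).

    Constant genes get a loading of 0 on every component and are listed in
    ``constant_genes``.
    """
    if m.n_genes < 2 or m.n_samples < 2:
        raise ValueError("PCA needs at least two genes and two samples")
    X = m.values.to_numpy(dtype=float).T  # samples × genes
    Xc = X - X.mean(axis=0)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]
    scores = U * s
    var = s**2 / (X.shape[0] - 1)
    proportion = var / var.sum()
    pcs = [f"PC{i+1}" for i in range(n_comp)]

    gene_sd = Xc.std(axis=0)
    constant = gene_sd < 1e-12
    safe_gene_sd = np.where(constant, 1.0, gene_sd)
    score_c = scores - scores.mean(axis=0)
    score_sd = scores.std(axis=0)
    score_sd[score_sd < 1e-12] = 1.0
    # gene–score Pearson correlations: cov(gene, score) / (sd_gene * sd_score)
    cov = Xc.T @ score_c / X.shape[0]
    load = cov / (safe_gene_sd[:, None] * score_sd[None, :])
    load[constant] = 0.0
    load = np.clip(load, -1.0, 1.0)

    return PCAModel(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=pcs),
        loadings=pd.DataFrame(load, index=m.genes, columns=pcs),
        sdev=pd.Series(np.sqrt(var), index=pcs),
        proportion=pd.Series(proportion, index=pcs),
        cumulative=pd.Series(np.cumsum(proportion), index=pcs),
        constant_genes=list(m.genes[constant]),
    )


def select_components(model: PCAModel, cum_threshold: float = 0.85) -> list[str]:
    """Shortest prefix PC1..PCm whose cumulative proportion ≥ threshold."""
    cum = model.cumulative.to_numpy()
    idx = np.searchsorted(cum, cum_threshold - 1e-12)
    if idx >= len(cum):
        warnings.warn("cumulative proportion never reaches threshold; "
                      "returning all components")
        idx = len(cum) - 1
    return list(model.scores.columns[: idx + 1])


# ---------------------------------------------------------------------------
# Bayesian probit regression (penalized IRLS to the posterior mode)

def _neg_log_posterior(theta, z, y, prior_scales):
    eta = theta[0] + theta[1] * z
    ll = np.sum(np.where(y, stats.norm.logcdf(eta), stats.norm.logcdf(-eta)))
    # independent Cauchy priors on intercept and slope
    lp = -np.sum(np.log1p((theta / prior_scales) ** 2))
    return -(ll + lp)


def _grad(theta, z, y, prior_scales):
    eta = theta[0] + theta[1] * z
    sign = np.where(y, 1.0, -1.0)
    # d/d eta log Phi(sign*eta) = sign * phi(eta)/Phi(sign*eta)
    ratio = sign * np.exp(stats.norm.logpdf(eta) - stats.norm.logcdf(sign * eta))
    g0 = ratio.sum()
    g1 = (ratio * z).sum()
    gp = -2.0 * theta / (prior_scales**2 + theta**2)
    return -(np.array([g0, g1]) + gp)


def bayes_probit(
    y: np.ndarray, z: np.ndarray, prior_scale: float = 2.5,
    intercept_prior_scale: float = 10.0,
) -> tuple[float, float, float]:
    """Probit GLM of a binary outcome on one standardized covariate.

    Cauchy (Student-t, df 1) priors: scale ``prior_scale`` on the slope,
    ``intercept_prior_scale`` on the intercept. Returns
    ``(slope, standard_error, two_sided_p)`` from the Wald z at the
    posterior mode; the curvature is the observed information (finite
    differences of the analytic gradient).
    """
    y = np.asarray(y, dtype=bool)
    z = np.asarray(z, dtype=float)
    if y.all() or not y.any():
        raise ValueError("outcome is constant")
    if z.std() < 1e-12:
        raise ValueError("zero-variance score")
    scales = np.array([intercept_prior_scale, prior_scale])
    res = optimize.minimize(
        _neg_log_posterior, x0=np.zeros(2), args=(z, y, scales),
        jac=_grad, method="BFGS",
    )
    theta = res.x
    # observed information at the mode
    eps = 1e-5
    H = np.zeros((2, 2))
    for k in range(2):
        step = np.zeros(2)
        step[k] = eps
        H[:, k] = (_grad(theta + step, z, y, scales)
                   - _grad(theta - step, z, y, scales)) / (2 * eps)
    cov = np.linalg.inv((H + H.T) / 2)
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    slope = float(theta[1])
    if se == 0:
        return slope, se, 1.0
    zstat = slope / se
    return slope, se, float(2 * stats.norm.sf(abs(zstat)))


def probit_significance(
    scores: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    positive: str | int | bool | None = None,
    prior_scale: float = 2.5,
) -> pd.DataFrame:
    """Univariate Bayesian probit test of each PC score against phenotype.

    ``labels`` is a binary phenotype vector aligned to the score rows;
    ``positive`` names the disease level (default: the lexically larger).
    Returns one row per PC: slope, standard error and two-sided p.
    """
    lab = np.asarray(labels)
    levels = sorted(pd.unique(lab).tolist())
    if len(levels) != 2:
        raise ValueError(f"phenotype must be binary, got {levels}")
    if positive is None:
        positive = levels[1]
    y = lab == positive
    rows = []
    for pc in scores.columns:
        z = scores[pc].to_numpy(dtype=float)
        z = (z - z.mean()) / z.std()
        slope, se, p = bayes_probit(y, z, prior_scale=prior_scale)
        rows.append({"pc": pc, "coef": slope, "se": se, "p": p})
    return pd.DataFrame(rows).set_index("pc")


# ---------------------------------------------------------------------------

def select_signature_genes(
    model: PCAModel,
    significant_pcs: list[str],
    deg_directions: pd.Series,
    loading_threshold: float = 0.6,
    comparison: str = "",
) -> pd.DataFrame:
    """Genes with |loading| > threshold on ≥1 significant PC.

    Direction (+1 up / −1 down in disease) is taken from the DEG table.
    Returns a signature table indexed by gene: ``direction``,
    ``max_abs_loading``, ``comparison``.
    """
    if not significant_pcs:
        warnings.warn("no significant principal components; empty signature")
        return pd.DataFrame(
            columns=["direction", "max_abs_loading", "comparison"],
            index=pd.Index([], name="gene"),
        )
    sub = model.loadings[significant_pcs].abs()
    max_load = sub.max(axis=1)
    keep = max_load > loading_threshold
    genes = model.loadings.index[keep]
    return pd.DataFrame(
        {
            "direction": deg_directions.reindex(genes).fillna(0).astype(int),
            "max_abs_loading": max_load[keep],
            "comparison": comparison,
        },
        index=pd.Index(genes, name="gene"),
    )


def intersect_signatures(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Common signature genes with consistent direction.

    Returns the intersection table (direction, per-signature max loadings)
    and the list of genes excluded for conflicting directions.
    """
    shared = a.index.intersection(b.index)
    same = shared[(a.loc[shared, "direction"] == b.loc[shared, "direction"]).to_numpy()]
    conflicts = sorted(set(shared) - set(same))
    out = pd.DataFrame(
        {
            "direction": a.loc[same, "direction"],
            "max_abs_loading_a": a.loc[same, "max_abs_loading"],
            "max_abs_loading_b": b.loc[same, "max_abs_loading"],
        },
        index=pd.Index(same, name="gene"),
    ).sort_index()
    return out, conflicts
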