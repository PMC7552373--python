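"""Mutually exclusive alteration modules from binarized expression.

Disease samples are binarized against the healthy-control distribution:
a sample is *altered* for a gene when its expression deviates from the
control mean by more than ``k_sd`` control standard deviations in the
gene's differential direction (above for up-regulated genes, below for
down-regulated ones).

Exclusivity of a gene set is scored by a fixed-margin exact test: with
each gene's altered-sample count held at its observed margin and
placements uniform, phi is the probability of seeing at most the
observed number of co-altered samples (for a pair this is the lower
hypergeometric tail of the overlap). Small phi means the genes avoid
each other more than chance allows.

Module discovery samples collections of t disjoint k-gene modules by a
Metropolis MCMC whose stationary weight rewards exclusive modules
(weight exp(sum -log phi)); the fraction of retained states in which a
gene pair shares a module is its marginal probability, and maximal
cliques of the thresholded marginal graph (edge weight >= delta) are the
consensus modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "AlterationMatrix", "binarize_alterations", "exact_mutex_test",
    "MarginalGraph", "mutex_mcmc", "MutexModule", "consensus_modules",
    "coverage",
]


@dataclass
class AlterationMatrix:
    """Binary genes × disease-samples matrix (1 = altered)."""

    values: pd.DataFrame  # int 0/1
    k_sd: float
    directions: pd.Series
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def margins(self) -> pd.Series:
        return self.values.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def binarize_alterations(
    disease_m: ExpressionMatrix,
    control_m: ExpressionMatrix,
    deg_directions: pd.Series,
    k_sd: float = 2.0,
) -> AlterationMatrix:
    """Binarize disease expression against control mean ± k_sd·SD.

    Genes are restricted to the index of ``deg_directions`` (the signature
    set under study). Genes with (near-)zero control SD are excluded and
    listed on the result.
    """
    genes = pd.Index(deg_directions.index)
    genes = genes.intersection(disease_m.genes).intersection(control_m.genes)
    if control_m.n_samples < 2:
        raise ValueError("need at least two control samples")
    d = disease_m.values.loc[genes].to_numpy(dtype=float)
    c = control_m.values.loc[genes].to_numpy(dtype=float)
    mu = c.mean(axis=1)
    sd = c.std(axis=1, ddof=1)
    ok = sd > 1e-9
    direction = deg_directions.loc[genes].to_numpy()
    dev = d - mu[:, None]
    up = dev > (k_sd * sd)[:, None]
    down = dev < (-k_sd * sd)[:, None]
    altered = np.where(direction[:, None] >= 0, up, down).astype(int)
    keep = ok & (direction != 0)
    return AlterationMatrix(
        values=pd.DataFrame(
            altered[keep], index=genes[keep], columns=disease_m.sample_ids
        ),
        k_sd=k_sd,
        directions=deg_directions.loc[genes[keep]],
        excluded_genes=list(genes[~keep]),
    )


# ---------------------------------------------------------------------------
# exact fixed-margin exclusivity test

def _pair_phi(n: int, a: int, b: int, overlap: int) -> float:
    # lower tail of the hypergeometric overlap distribution
    return float(stats.hypergeom.cdf(overlap, n, a, b))


def _triple_phi(n: int, margins: tuple[int, int, int], obs_co: int) -> float:
    """Exact enumeration over 2^3 contingency cells for k = 3."""
    a1, a2, a3 = margins
    log_denom = (_logcomb(n, a1) + _logcomb(n, a2) + _logcomb(n, a3))
    total = 0.0
    for c111 in range(0, min(a1, a2, a3) + 1):
        for c110 in range(0, min(a1, a2) - c111 + 1):
            for c101 in range(0, min(a1, a3) - c111 + 1):
                c100 = a1 - c111 - c110 - c101
                if c100 < 0:
                    continue
                for c011 in range(0, min(a2, a3) - c111 + 1):
                    c010 = a2 - c111 - c110 - c011
                    c001 = a3 - c111 - c101 - c011
                    c000 = n - (c111 + c110 + c101 + c011 + c100 + c010 + c001)
                    if c010 < 0 or c001 < 0 or c000 < 0:
                        continue
                    co = c111 + c110 + c101 + c011
                    if co > obs_co:
                        continue
                    cells = (c111, c110, c101, c011, c100, c010, c001, c000)
                    log_count = math.lgamma(n + 1) - sum(
                        math.lgamma(c + 1) for c in cells
                    )
                    total += math.exp(log_count - log_denom)
    return min(total, 1.0)


def _logcomb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def exact_mutex_test(alt: AlterationMatrix, gene_set: list[str]) -> float:
    """Fixed-margin lower-tail probability phi of the observed co-alteration.

    Supported for module sizes 2 and 3 (exact enumeration). Degenerate
    margins (0 or all samples) raise.
    """
    k = len(gene_set)
    if k < 2:
        raise ValueError("gene set must have at least two genes")
    rows = alt.values.loc[list(gene_set)].to_numpy()
    n = alt.n_samples
    margins = rows.sum(axis=1)
    if (margins == 0).any() or (margins == n).any():
        raise ValueError("degenerate margin (0 or n) in gene set")
    if k == 2:
        overlap = int((rows[0] & rows[1]).sum())
        return _pair_phi(n, int(margins[0]), int(margins[1]), overlap)
    if k == 3:
        co = int((rows.sum(axis=0) >= 2).sum())
        return _triple_phi(n, tuple(int(x) for x in margins), co)
    raise NotImplementedError("exact test implemented for k <= 3")


# ---------------------------------------------------------------------------
# MCMC over module collections

@dataclass
class MarginalGraph:
    """Symmetric pairwise marginal probabilities from the module MCMC."""

    probabilities: pd.DataFrame  # genes × genes, diagonal 0
    t: int
    k: int
    iterations: int
    burn_in: int
    thinning: int
    seed: int

    def edge_list(self) -> pd.DataFrame:
        genes = self.probabilities.index
        rows = []
        arr = self.probabilities.to_numpy()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                rows.append((genes[i], genes[j], arr[i, j]))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "probability"])


def mutex_mcmc(
    alt: AlterationMatrix,
    t: int = 2,
    k: int = 2,
    iterations: int = 100_000,
    burn_in: int = 10_000,
    thinning: int = 10,
    seed: int = 0,
) -> MarginalGraph:
    """Metropolis sampling of collections of t disjoint k-gene modules.

    Stationary weight ``exp(sum_modules -log phi(module))``; the proposal
    swaps a uniformly chosen in-module gene with a uniformly chosen
    outside gene (states stay disjoint by construction). Genes with
    degenerate margins are excluded up front. Deterministic given seed.
    """
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    margins = alt.margins
    usable = margins.index[(margins > 0) & (margins < alt.n_samples)].tolist()
    genes = list(usable)
    if len(genes) < t * k:
        raise ValueError(f"need at least t*k={t*k} non-degenerate genes")
    rows = {g: alt.values.loc[g].to_numpy().astype(bool) for g in genes}
    n = alt.n_samples

    phi_cache: dict[tuple, float] = {}

    def phi(module: tuple[str, ...]) -> float:
        key = tuple(sorted(module))
        if key not in phi_cache:
            sub = np.array([rows[g] for g in key])
            m = sub.sum(axis=1)
            if len(key) == 2:
                val = _pair_phi(n, int(m[0]), int(m[1]),
                                int((sub[0] & sub[1]).sum()))
            else:
                val = _triple_phi(n, tuple(int(x) for x in m),
                                  int((sub.sum(axis=0) >= 2).sum()))
            phi_cache[key] = val
        return phi_cache[key]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    state = [
        [genes[perm[m * k + j]] for j in range(k)] for m in range(t)
    ]
    inside = {g for mod in state for g in mod}
    outside = [g for g in genes if g not in inside]
    log_w = sum(-math.log(max(phi(tuple(mod)), 1e-300)) for mod in state)

    idx = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((len(genes), len(genes)))
    n_kept = 0

    for it in range(iterations):
        m_pos = rng.integers(t * k)
        mod_i, slot = divmod(m_pos, k)
        out_i = rng.integers(len(outside))
        g_in, g_out = state[mod_i][slot], outside[out_i]
        new_mod = list(state[mod_i])
        new_mod[slot] = g_out
        new_phi = max(phi(tuple(new_mod)), 1e-300)
        old_phi = max(phi(tuple(state[mod_i])), 1e-300)
        delta = -math.log(new_phi) + math.log(old_phi)
        if delta >= 0 or rng.random() < math.exp(delta):
            state[mod_i][slot] = g_out
            outside[out_i] = g_in
            log_w += delta
        if it >= burn_in and (it - burn_in) % thinning == 0:
            n_kept += 1
            for mod in state:
                for x in range(k):
                    for y in range(x + 1, k):
                        i, j = idx[mod[x]], idx[mod[y]]
                        counts[i, j] += 1
                        counts[j, i] += 1

    probs = counts / max(n_kept, 1)
    return MarginalGraph(
        probabilities=pd.DataFrame(probs, index=genes, columns=genes),
        t=t, k=k, iterations=iterations, burn_in=burn_in,
        thinning=thinning, seed=seed,
    )


@dataclass
class MutexModule:
    """A consensus module: gene set, exact-test phi and coverage."""

    genes: list[str]
    phi: float
    coverage: float
    per_gene_coverage: dict[str, float]
    exclusive_counts: dict[str, int]


def consensus_modules(
    graph: MarginalGraph, alt: AlterationMatrix, delta: float = 0.2
) -> list[MutexModule]:
    """Maximal cliques of the delta-thresholded marginal graph.

    Each module is annotated with its exact-test phi (for clique sizes
    ≤ 3; larger cliques get the worst pairwise phi), union coverage, and
    per-gene exclusive-alteration counts (samples altered in that gene
    only).
    """
    G = nx.Graph()
    genes = list(graph.probabilities.index)
    G.add_nodes_from(genes)
    arr = graph.probabilities.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if arr[i, j] >= delta:
                G.add_edge(genes[i], genes[j])
    modules = []
    for clique in nx.find_cliques(G):
        if len(clique) < 2:
            continue
        clique = sorted(clique)
        if len(clique) <= 3:
            phi = exact_mutex_test(alt, clique)
        else:
            phi = max(
                exact_mutex_test(alt, [a, b])
                for x, a in enumerate(clique) for b in clique[x + 1:]
            )
        cov, per_gene = coverage(alt, clique)
        sub = alt.values.loc[clique].to_numpy()
        hits = sub.sum(axis=0)
        exclusive = {
            g: int((sub[i].astype(bool) & (hits == 1)).sum())
            for i, g in enumerate(clique)
        }
        modules.append(MutexModule(
            genes=clique, phi=phi, coverage=cov,
            per_gene_coverage=per_gene, exclusive_counts=exclusive,
        ))
    modules.sort(key=lambda mod: (mod.phi, -mod.coverage, mod.genes))
    return modules


def coverage(
    alt: AlterationMatrix, gene_set: list[str]
) -> tuple[float, dict[str, float]]:
    """Fraction of samples altered in ≥1 gene of the set (+ per-gene fractions)."""
    sub = alt.values.loc[list(gene_set)].to_numpy()
    n = alt.n_samples
    union = float((sub.sum(axis=0) > 0).mean())
    per_gene = {g: float(sub[i].mean()) for i, g in enumerate(gene_set)}
    return union, per_gene
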