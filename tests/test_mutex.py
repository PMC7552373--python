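"""Alteration binarization, exact exclusivity test and module MCMC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lungsig.mutex import (
    AlterationMatrix, binarize_alterations, exact_mutex_test, mutex_mcmc,
    consensus_modules, coverage, MarginalGraph,
)

from conftest import make_matrix


def alt_from_rows(rows, genes=None):
    rows = np.asarray(rows, dtype=int)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    vals = pd.DataFrame(rows, index=genes,
                        columns=[f"s{j}" for j in range(rows.shape[1])])
    return AlterationMatrix(vals, 2.0, pd.Series(1, index=vals.index))


# ---------------------------------------------------------------------------
# binarization

def test_binarization_direction_aware():
    """Control mean 8, SD 0.5: up-gene altered above 9, down below 7."""
    control = make_matrix(
        [[7.5, 8.5, 8.0, 8.0], [7.5, 8.5, 8.0, 8.0]],
        phenotypes=["healthy"] * 4)
    # observed control SD of (7.5, 8.5, 8, 8) is sqrt(1/6)=0.408; rescale
    # to SD exactly 0.5 by spacing 7.3875/8.6125
    c = 8 + (control.values.to_numpy() - 8) * (0.5 / np.sqrt(1 / 6))
    control = make_matrix(c, phenotypes=["healthy"] * 4)
    disease = make_matrix([[9.2, 8.7], [6.9, 7.5]],
                          phenotypes=["IPF", "IPF"], samples=["d1", "d2"])
    directions = pd.Series({"g0": 1, "g1": -1})
    alt = binarize_alterations(disease, control, directions, k_sd=2.0)
    assert alt.values.loc["g0"].tolist() == [1, 0]   # 9.2 > 9.0, 8.7 <= 9.0
    assert alt.values.loc["g1"].tolist() == [1, 0]   # 6.9 < 7.0, 7.5 >= 7.0


def test_binarization_excludes_zero_sd_genes():
    control = make_matrix([[8.0, 8.0, 8.0]], phenotypes=["healthy"] * 3)
    disease = make_matrix([[9.0]], phenotypes=["IPF"], samples=["d1"])
    alt = binarize_alterations(disease, control, pd.Series({"g0": 1}))
    assert alt.excluded_genes == ["g0"]
    assert alt.values.empty


# ---------------------------------------------------------------------------
# exact test

def test_exact_test_disjoint_pair_enumeration():
    """n=4, margins 2/2, overlap 0: 1 of C(4,2)=6 placements -> 1/6."""
    alt = alt_from_rows([[1, 1, 0, 0], [0, 0, 1, 1]])
    assert exact_mutex_test(alt, ["g0", "g1"]) == pytest.approx(1 / 6)


def test_exact_test_complete_overlap_is_one():
    alt = alt_from_rows([[1, 1, 0, 0], [1, 1, 0, 0]])
    assert exact_mutex_test(alt, ["g0", "g1"]) == pytest.approx(1.0)


def test_exact_test_matches_brute_force_oracle():
    """n=20, margins 8 and 6, overlap 1: exhaustive placement enumeration."""
    n, a, b, obs = 20, 8, 6, 1
    rows = np.zeros((2, n), int)
    rows[0, :a] = 1
    rows[1, :obs] = 1
    rows[1, a:a + b - obs] = 1
    alt = alt_from_rows(rows)
    fixed = set(range(a))
    count = total = 0
    for placement in itertools.combinations(range(n), b):
        total += 1
        count += len(fixed & set(placement)) <= obs
    assert exact_mutex_test(alt, ["g0", "g1"]) == pytest.approx(
        count / total, abs=1e-12)


def test_exact_test_monotone_in_overlap():
    n, a, b = 15, 6, 5
    phis = []
    for obs in range(b + 1):
        rows = np.zeros((2, n), int)
        rows[0, :a] = 1
        rows[1, :obs] = 1
        rows[1, a:a + b - obs] = 1
        phis.append(exact_mutex_test(alt_from_rows(rows), ["g0", "g1"]))
    assert all(p1 <= p2 + 1e-12 for p1, p2 in zip(phis, phis[1:]))
    assert phis[-1] == pytest.approx(1.0)


def test_exact_test_triple_matches_monte_carlo():
    rng = np.random.default_rng(0)
    n = 12
    rows = np.zeros((3, n), int)
    rows[0, :4] = 1
    rows[1, 4:7] = 1
    rows[2, [0, 7, 8, 9, 10]] = 1
    alt = alt_from_rows(rows)
    phi = exact_mutex_test(alt, ["g0", "g1", "g2"])
    obs_co = int((rows.sum(axis=0) >= 2).sum())
    hits = 0
    reps = 20000
    for _ in range(reps):
        sim = np.zeros((3, n), int)
        for i, m in enumerate(rows.sum(axis=1)):
            sim[i, rng.choice(n, int(m), replace=False)] = 1
        hits += (sim.sum(axis=0) >= 2).sum() <= obs_co
    assert phi == pytest.approx(hits / reps, abs=0.01)


def test_exact_test_degenerate_margins_raise():
    alt = alt_from_rows([[1, 1, 1, 1], [0, 0, 1, 1]])
    with pytest.raises(ValueError, match="degenerate"):
        exact_mutex_test(alt, ["g0", "g1"])
    alt0 = alt_from_rows([[0, 0, 0, 0], [0, 0, 1, 1]])
    with pytest.raises(ValueError, match="degenerate"):
        exact_mutex_test(alt0, ["g0", "g1"])


# ---------------------------------------------------------------------------
# MCMC and consensus

def _planted_fixture(seed, n_noise=20, n_samples=30, margin=8):
    rng = np.random.default_rng(seed)
    rows = [np.zeros(n_samples, int), np.zeros(n_samples, int)]
    rows[0][: n_samples // 2] = 1
    rows[1][n_samples // 2:] = 1
    for _ in range(n_noise):
        r = np.zeros(n_samples, int)
        r[rng.choice(n_samples, margin, replace=False)] = 1
        rows.append(r)
    return alt_from_rows(np.array(rows))


def test_mcmc_same_seed_identical_graphs():
    alt = _planted_fixture(0)
    g1 = mutex_mcmc(alt, iterations=20000, burn_in=2000, seed=3)
    g2 = mutex_mcmc(alt, iterations=20000, burn_in=2000, seed=3)
    assert (g1.probabilities.values == g2.probabilities.values).all()


def test_mcmc_recovers_planted_pair():
    alt = _planted_fixture(1)
    g = mutex_mcmc(alt, iterations=50000, burn_in=5000, seed=0)
    arr = g.probabilities
    planted = arr.loc["g0", "g1"]
    others = arr.to_numpy()[np.triu_indices(len(arr), 1)]
    assert planted > 0.2
    assert planted == pytest.approx(others.max())


def test_mcmc_uniform_null_stays_near_baseline():
    """All genes altered identically: every pair has phi=1, the chain is
    uniform over states, and no pair's marginal exceeds 3x the uniform
    baseline t*k*(k-1)/(G*(G-1))."""
    rows = np.zeros((12, 10), int)
    rows[:, :4] = 1
    alt = alt_from_rows(rows)
    g = mutex_mcmc(alt, t=2, k=2, iterations=60000, burn_in=5000, seed=1)
    baseline = 2 * 2 * 1 / (12 * 11)
    vals = g.probabilities.to_numpy()[np.triu_indices(12, 1)]
    assert vals.max() <= 3 * baseline


def test_mcmc_convergence_under_doubling():
    alt = _planted_fixture(2)
    g1 = mutex_mcmc(alt, iterations=50000, burn_in=5000, seed=0)
    g2 = mutex_mcmc(alt, iterations=100000, burn_in=5000, seed=0)
    d = abs(g1.probabilities.loc["g0", "g1"] - g2.probabilities.loc["g0", "g1"])
    assert d < 0.05


def test_mcmc_input_validation():
    alt = _planted_fixture(3, n_noise=1)
    with pytest.raises(ValueError):
        mutex_mcmc(alt, t=5, k=2, iterations=100, burn_in=10)
    with pytest.raises(ValueError):
        mutex_mcmc(alt, iterations=10, burn_in=100)


def _graph_from_edges(genes, edges):
    probs = pd.DataFrame(0.0, index=genes, columns=genes)
    for a, b, p in edges:
        probs.loc[a, b] = probs.loc[b, a] = p
    return MarginalGraph(probs, 2, 2, 1000, 100, 10, 0)


def test_consensus_single_strong_edge():
    alt = _planted_fixture(4, n_noise=2)
    genes = list(alt.values.index)
    graph = _graph_from_edges(genes, [("g0", "g1", 0.9), ("g2", "g3", 0.05)])
    modules = consensus_modules(graph, alt, delta=0.2)
    assert len(modules) == 1
    assert modules[0].genes == ["g0", "g1"]
    assert modules[0].phi == exact_mutex_test(alt, ["g0", "g1"])


def test_consensus_threshold_above_range_empty():
    alt = _planted_fixture(5, n_noise=2)
    graph = _graph_from_edges(list(alt.values.index), [("g0", "g1", 0.9)])
    assert consensus_modules(graph, alt, delta=1.1) == []


def test_consensus_lowering_delta_only_adds_edges():
    alt = _planted_fixture(6, n_noise=3)
    genes = list(alt.values.index)
    graph = _graph_from_edges(
        genes, [("g0", "g1", 0.9), ("g2", "g3", 0.3), ("g3", "g4", 0.25)])
    def edge_sets(delta):
        return {frozenset(e) for m in consensus_modules(graph, alt, delta)
                for e in itertools.combinations(m.genes, 2)}
    assert edge_sets(0.5) <= edge_sets(0.2)


def test_coverage_examples():
    rows = np.zeros((2, 45), int)
    rows[0, :4] = 1
    alt = alt_from_rows(rows[:1])
    cov, per_gene = coverage(alt, ["g0"])
    assert cov == pytest.approx(4 / 45)
    # disjoint pair: union coverage adds
    rows = np.zeros((2, 20), int)
    rows[0, :6] = 1
    rows[1, 6:12] = 1
    alt2 = alt_from_rows(rows)
    cov2, per2 = coverage(alt2, ["g0", "g1"])
    assert cov2 == pytest.approx(0.6)
    assert per2 == {"g0": pytest.approx(0.3), "g1": pytest.approx(0.3)}
    # gene altered everywhere
    alt3 = alt_from_rows(np.ones((1, 10), int))
    assert coverage(alt3, ["g0"])[0] == 1.0
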