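"""SVM training, gene weights, LOOCV, predictive power and ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungsig.classify import (
    train_svm, gene_weights, filter_by_weight, loocv, predictive_power, roc_auc,
)

from conftest import make_matrix, two_group_matrix


def _separated_matrix(rng, n_per_class=20, n_genes=5, gap=6.0, disease="IPF"):
    """Two clusters `gap` noise-SDs apart on every gene."""
    vals = np.hstack([
        rng.normal(gap / 2, 1.0, (n_genes, n_per_class)),
        rng.normal(-gap / 2, 1.0, (n_genes, n_per_class)),
    ])
    phen = [disease] * n_per_class + ["healthy"] * n_per_class
    return make_matrix(vals, phenotypes=phen)


def test_separable_data_trains_to_perfect_accuracy():
    rng = np.random.default_rng(0)
    m = _separated_matrix(rng)
    model = train_svm(m, "IPF", seed=0)
    preds = model.predict(m)
    truth = np.where(m.phenotype_mask("IPF"), "IPF", "healthy")
    assert (preds["predicted"].to_numpy() == truth).all()
    assert model.cv_accuracy == 1.0


def test_dual_coefficients_sum_to_zero():
    rng = np.random.default_rng(1)
    m = _separated_matrix(rng, gap=2.0)
    model = train_svm(m, "IPF", seed=0)
    assert abs(model.dual_coef.sum()) < 1e-8


def test_duplicating_samples_keeps_decision_values():
    rng = np.random.default_rng(2)
    m = _separated_matrix(rng)
    dup_vals = np.hstack([m.values.to_numpy()] * 2)
    dup = make_matrix(dup_vals,
                      samples=[f"d{j}" for j in range(dup_vals.shape[1])],
                      phenotypes=list(m.samples["phenotype"]) * 2)
    # interior dual coefficients (separable, cost 10): solution is unique
    m1 = train_svm(m, "IPF", cost=10.0, seed=0)
    m2 = train_svm(dup, "IPF", cost=10.0, seed=0)
    d1 = m1.decision_values(m)
    d2 = m2.decision_values(
        make_matrix(m.values.to_numpy(), samples=[f"d{j}" for j in range(m.n_samples)],
                    phenotypes=list(m.samples["phenotype"])))
    assert np.allclose(d1, d2, atol=1e-6)


def test_single_class_or_tiny_class_rejected():
    m = make_matrix(np.zeros((3, 4)), phenotypes=["healthy"] * 4)
    with pytest.raises(ValueError):
        train_svm(m, "IPF")
    m2 = make_matrix(np.random.default_rng(0).normal(size=(3, 4)),
                     phenotypes=["IPF", "healthy", "healthy", "healthy"])
    with pytest.raises(ValueError):
        train_svm(m2, "IPF")


def test_planted_gene_outweighs_noise_genes():
    """Only gene 0 differs between classes; its weight beats all 50 noise genes."""
    rng = np.random.default_rng(3)
    m = two_group_matrix(rng, 20, 20, 51, effect_genes=[0], effect=3.0)
    model = train_svm(m, "IPF", seed=0)
    w = gene_weights(model)["weight"]
    assert w.iloc[0] > w.iloc[1:].max()


def test_duplicated_gene_gets_equal_weight():
    rng = np.random.default_rng(4)
    m = two_group_matrix(rng, 10, 10, 20, effect_genes=[0], effect=2.0)
    vals = np.vstack([m.values.to_numpy(), m.values.to_numpy()[0:1]])
    dup = make_matrix(vals, genes=[f"g{i}" for i in range(20)] + ["g0_copy"],
                      phenotypes=list(m.samples["phenotype"]))
    w = gene_weights(train_svm(dup, "IPF", seed=0))["weight"]
    assert w["g0"] == pytest.approx(w["g0_copy"], rel=1e-9)


def test_permuted_labels_shrink_planted_weights():
    """Permuting labels destroys the planted genes' weight advantage.

    The comparison is made on the signal-carrying genes themselves: the
    global maximum over all genes is an order statistic of the noise tail
    and is not a reliable signal readout in the saturated soft-margin
    regime.
    """
    rng = np.random.default_rng(5)
    m = two_group_matrix(rng, 20, 20, 30, effect_genes=range(5), effect=2.0)
    planted = [f"g{i}" for i in range(5)]
    w_signal = gene_weights(train_svm(m, "IPF", seed=0))["weight"][planted].max()
    perm = rng.permutation(m.n_samples)
    m_perm = make_matrix(m.values.to_numpy(),
                         phenotypes=[m.samples["phenotype"].iloc[j] for j in perm])
    w_null = gene_weights(train_svm(m_perm, "IPF", seed=0))["weight"][planted].max()
    assert w_null < w_signal


def test_weights_invariant_to_sample_order():
    rng = np.random.default_rng(6)
    m = two_group_matrix(rng, 8, 8, 15, effect_genes=[1], effect=2.0)
    perm = rng.permutation(m.n_samples)
    m2 = m.subset_samples(list(m.sample_ids[perm]))
    w1 = gene_weights(train_svm(m, "IPF", seed=0))["weight"]
    w2 = gene_weights(train_svm(m2, "IPF", seed=0))["weight"]
    # equal up to the solver's numerical tolerance
    assert np.allclose(w1, w2, rtol=0.02, atol=0.02)
    assert w1.idxmax() == w2.idxmax()


def test_filter_by_weight_is_strict():
    w = pd.DataFrame({"weight": [1.5, 0.9, 1.0]}, index=["a", "b", "c"])
    assert filter_by_weight(w, 1.0) == ["a"]
    assert filter_by_weight(w, 0.0) == ["a", "b", "c"]
    assert filter_by_weight(w, 99.0) == []


def test_loocv_returns_one_prediction_per_sample():
    rng = np.random.default_rng(7)
    m = _separated_matrix(rng, n_per_class=5)
    preds = loocv(m, "IPF", seed=0)
    assert len(preds) == m.n_samples
    assert (preds.index == m.sample_ids).all()


def test_loocv_perfect_on_separable_data():
    rng = np.random.default_rng(8)
    m = _separated_matrix(rng)
    preds = loocv(m, "IPF", seed=0)
    power, correct, total = predictive_power(preds)
    assert power == 100.0 and correct == total == 40


def test_loocv_near_chance_on_permuted_labels():
    rng = np.random.default_rng(9)
    vals = rng.normal(0, 1, (10, 60))
    phen = list(rng.permutation(["IPF"] * 30 + ["healthy"] * 30))
    m = make_matrix(vals, phenotypes=phen)
    preds = loocv(m, "IPF", seed=0)
    acc = (preds["truth"] == preds["predicted"]).mean()
    half = 1.96 * np.sqrt(0.25 / 60)
    assert 0.5 - half <= acc <= 0.5 + half


@pytest.mark.parametrize("correct,total,expected", [
    (104, 114, 91.23),
    (63, 68, 92.65),
    (94, 97, 96.91),
    (43, 46, 93.48),
    (11, 12, 91.67),
])
def test_predictive_power_reporting(correct, total, expected):
    preds = pd.DataFrame({
        "truth": ["IPF"] * total,
        "predicted": ["IPF"] * correct + ["healthy"] * (total - correct),
        "probability": [0.9] * total,
    })
    power, c, t = predictive_power(preds)
    assert (power, c, t) == (expected, correct, total)


def _pred_frame(y, scores):
    return pd.DataFrame({
        "truth": np.where(y, "IPF", "healthy"),
        "predicted": np.where(np.asarray(scores) > 0.5, "IPF", "healthy"),
        "probability": scores,
    })


def test_auc_extremes():
    y = np.array([True] * 3 + [False] * 3)
    perfect = _pred_frame(y, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    _, auc = roc_auc(perfect, "IPF")
    assert auc == 1.0
    inverted = _pred_frame(~y, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    _, auc_inv = roc_auc(inverted, "IPF")
    assert auc_inv == 0.0


def test_auc_equals_mann_whitney_with_ties():
    rng = np.random.default_rng(10)
    for _ in range(20):
        n1, n0 = rng.integers(5, 30, 2)
        y = np.array([True] * n1 + [False] * n0)
        scores = rng.choice(np.linspace(0, 1, 7), size=n1 + n0)  # heavy ties
        _, auc = roc_auc(_pred_frame(y, scores), "IPF")
        u = stats.mannwhitneyu(scores[:n1], scores[n1:]).statistic
        assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_auc_random_scores_near_half():
    rng = np.random.default_rng(11)
    y = np.array([True] * 100 + [False] * 100)
    scores = rng.random(200)
    _, auc = roc_auc(_pred_frame(y, scores), "IPF")
    # 95% interval of AUC under H0 at n=100+100 is ~0.5 +/- 0.08
    assert 0.42 <= auc <= 0.58
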