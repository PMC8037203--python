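import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirsig import (
    fit_rvm_hyperparams,
    fold_change,
    hierarchical_cluster,
    pooled_variances,
    rvm_t_test,
    select_markers,
)
from mirsig.de import signed_fold_change

from .oracles import complete_linkage_heights


def _expr(rng, n_assays=20, n1=6, n0=6, shift=0.0):
    x = rng.normal(0.0, 1.0, size=(n_assays, n1 + n0))
    x[:, :n1] += shift
    labels = np.array([True] * n1 + [False] * n0)
    return pd.DataFrame(x, index=[f"a{i}" for i in range(n_assays)]), labels


class TestRvmFit:
    def test_likelihood_at_fit_beats_random_hyperparameters(self):
        rng = np.random.default_rng(0)
        prec = rng.gamma(3.0, 0.4, size=400)
        s2 = rng.chisquare(10, size=400) / 10 / prec
        hyper = fit_rvm_hyperparams(s2, 10)

        def loglik(a, b):
            return float(np.sum(np.log(a * b) + stats.f.logpdf(a * b * s2, 10, 2 * a)))

        assert hyper.log_likelihood == pytest.approx(loglik(hyper.a, hyper.b), rel=1e-9)
        for _ in range(20):
            a, b = np.exp(rng.uniform(-2, 3, size=2))
            assert loglik(a, b) <= hyper.log_likelihood + 1e-9

    def test_equal_variances_shrink_to_common_value(self):
        hyper = fit_rvm_hyperparams(np.full(60, 0.8), 10)
        moderated = (10 * 0.8 + 2.0 / hyper.b) / (10 + 2.0 * hyper.a)
        assert moderated == pytest.approx(0.8, rel=1e-3)

    def test_degenerate_and_undersized_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_rvm_hyperparams(np.zeros(50), 10)
        with pytest.raises(ValueError, match=">= 10"):
            fit_rvm_hyperparams(np.ones(5), 10)


class TestRvmT:
    def test_identical_group_means_give_t_zero_p_one(self):
        x = np.tile(np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]), (5, 1))
        expr = pd.DataFrame(x)
        labels = np.array([True, True, True, False, False, False])
        table = rvm_t_test(expr, labels, hyper=None)
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_without_prior_equals_classical_pooled_t(self):
        rng = np.random.default_rng(1)
        expr, labels = _expr(rng, n_assays=50)
        table = rvm_t_test(expr, labels, hyper=None)
        t_ref, p_ref = stats.ttest_ind(
            expr.loc[:, labels], expr.loc[:, ~labels], axis=1, equal_var=True
        )
        assert np.abs(table["t"].to_numpy() - t_ref).max() < 1e-10
        assert np.abs(table["p"].to_numpy() - p_ref).max() < 1e-10

    def test_label_swap_flips_t_sign_and_shift_invariance(self):
        rng = np.random.default_rng(2)
        expr, labels = _expr(rng)
        hyper = fit_rvm_hyperparams(*pooled_variances(expr, labels))
        table = rvm_t_test(expr, labels, hyper)
        flipped = rvm_t_test(expr, ~labels, hyper)
        assert np.allclose(table["t"], -flipped["t"])
        shifted = expr.copy()
        shifted.iloc[3] += 100.0  # constant offset on one assay
        table_shift = rvm_t_test(shifted, labels, hyper)
        assert table_shift.at["a3", "t"] == pytest.approx(table.at["a3", "t"])

    def test_moderation_widens_effective_degrees_of_freedom(self):
        rng = np.random.default_rng(3)
        expr, labels = _expr(rng, n_assays=100)
        hyper = fit_rvm_hyperparams(*pooled_variances(expr, labels))
        table = rvm_t_test(expr, labels, hyper)
        assert (table["df"] > 10).all()  # beyond the classical n1+n0-2 = 10

    def test_power_increases_with_effect_size(self):
        rates = []
        for shift in (0.0, 0.5, 1.0, 1.5):
            hits = 0
            for seed in range(15):
                rng = np.random.default_rng(1000 + seed)
                expr, labels = _expr(rng, n_assays=40, shift=shift)
                table = rvm_t_test(expr, labels, hyper=None)
                hits += int((table["p"] < 0.05).sum())
            rates.append(hits)
        assert rates == sorted(rates)
        assert rates[-1] > rates[0]

    def test_small_group_rejected(self):
        expr = pd.DataFrame(np.ones((12, 3)))
        with pytest.raises(ValueError, match=">= 2"):
            rvm_t_test(expr, np.array([True, False, False]), hyper=None)


class TestFoldChange:
    @pytest.mark.parametrize("delta, fc", [(1.0, 2.0), (-1.0, -2.0),
                                           (np.log2(1.5), 1.5), (0.0, 1.0)])
    def test_signed_convention(self, delta, fc):
        assert signed_fold_change(np.array([delta]))[0] == pytest.approx(fc)

    def test_fold_change_from_group_means(self):
        expr = pd.DataFrame([[3.0, 3.0, 2.0, 2.0], [1.0, 1.0, 2.0, 2.0]],
                            index=["up", "down"])
        labels = np.array([True, True, False, False])
        fc = fold_change(expr, labels)
        assert fc["up"] == pytest.approx(2.0)
        assert fc["down"] == pytest.approx(-2.0)


class TestSelectMarkers:
    def _table(self):
        return pd.DataFrame(
            {
                "p": [0.01, 0.02, 0.001, 0.03, 0.04, 0.9, 0.5, 0.7, 0.6, 0.8],
                "fc": [2.0, 1.7, 1.5, -2.0, -1.6, 1.1, -1.05, 1.2, -1.3, 1.0],
            },
            index=[f"m{i}" for i in range(10)],
        )

    def test_direction_up_returns_only_up_significant(self):
        assert select_markers(self._table(), direction="up") == ["m0", "m1", "m2"]

    def test_direction_none_returns_both_directions(self):
        assert select_markers(self._table(), direction=None) == \
            ["m0", "m1", "m2", "m3", "m4"]

    def test_zero_alpha_empty(self):
        assert select_markers(self._table(), p_max=0.0) == []

    def test_vacuous_fc_filter(self):
        got = select_markers(self._table(), fc_min=1.0, direction=None)
        assert got == ["m0", "m1", "m2", "m3", "m4"]


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 4))
        x[:, 1] = x[:, 0]
        expr = pd.DataFrame(x, columns=["s0", "s1", "s2", "s3"])
        _, samples = hierarchical_cluster(expr)
        first = samples.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_at_distance_two(self):
        expr = pd.DataFrame({"s0": [1.0, 2.0, 3.0, 4.0], "s1": [8.0, 6.0, 4.0, 2.0]},
                            index=["a", "b", "c", "d"])
        _, samples = hierarchical_cluster(expr)
        assert samples.linkage[0, 2] == pytest.approx(2.0)

    def test_merge_heights_match_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(5, 8)))
        assays, _ = hierarchical_cluster(expr)
        dist = 1.0 - np.corrcoef(expr.to_numpy())
        np.fill_diagonal(dist, 0.0)
        expected = complete_linkage_heights(dist)
        assert np.allclose(np.sort(assays.linkage[:, 2]), np.sort(expected), atol=1e-10)

    def test_zero_variance_item_named_in_error(self):
        expr = pd.DataFrame(np.random.default_rng(6).normal(size=(4, 5)),
                            index=["a", "b", "flat", "d"])
        expr.loc["flat"] = 7.0
        with pytest.raises(ValueError, match="flat"):
            hierarchical_cluster(expr)
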