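"""Signature derivation: t-filter, SNR, DLDA, stepwise selection, reduction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gescreen import (
    NoDiscriminantGenesError,
    de_filter,
    derive_signature,
    divergence_reduce,
    dlda_fit,
    dlda_predict,
    forward_select,
    loocv_accuracy,
    snr,
)
from conftest import two_group_matrix


class TestDEFilter:
    def test_identical_groups_not_selected(self):
        m = two_group_matrix([[1, 2, 3]], [[1, 2, 3]])
        res = de_filter(m)
        assert res.iloc[0]["t"] == 0
        assert res.iloc[0]["p"] == 1
        assert not res.iloc[0]["selected"]

    def test_zero_variance_unequal_means_perfectly_separated(self):
        m = two_group_matrix([[0, 0, 0]], [[1, 1, 1]])
        res = de_filter(m)
        assert res.iloc[0]["p"] == 0
        assert res.iloc[0]["selected"]

    def test_matches_reference_t_distribution(self):
        a, b = [1, 2, 3, 4], [3, 4, 5, 6]
        res = de_filter(two_group_matrix([a], [b]))
        ref = stats.ttest_ind(a, b)  # pooled-variance two-sample t
        assert res.iloc[0]["t"] == pytest.approx(ref.statistic)
        assert res.iloc[0]["p"] == pytest.approx(ref.pvalue)
        assert res.iloc[0]["t"] == pytest.approx(-2.19, abs=0.01)
        assert res.iloc[0]["p"] == pytest.approx(0.071, abs=0.001)
        assert not res.iloc[0]["selected"]

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        m = two_group_matrix(rng.normal(10, 1, (1500, 10)),
                             rng.normal(10, 1, (1500, 10)))
        res = de_filter(m)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            de_filter(two_group_matrix([[1]], [[1, 2]]))


class TestSNR:
    def test_analytic_values(self):
        m = two_group_matrix([[1, 2, 3]], [[4, 5, 6]])
        assert snr(m).iloc[0]["snr"] == pytest.approx(-1.5)
        m = two_group_matrix([[1.5, 2.5]], [[1.0, 2.0]])
        # means 2 vs 1.5, sds ~0.7071 each
        assert snr(m).iloc[0]["snr"] == pytest.approx(0.5 / (2 * np.sqrt(0.5)))

    def test_equal_means_zero(self):
        m = two_group_matrix([[1, 2, 3]], [[3, 2, 1]])
        assert snr(m).iloc[0]["snr"] == 0

    def test_rank_ties_broken_by_gene_id(self):
        m = two_group_matrix([[1, 2, 3], [1, 2, 3], [0, 1, 2]],
                             [[4, 5, 6], [4, 5, 6], [0, 1, 2]],
                             genes=["b", "a", "c"])
        table = snr(m)
        assert table.loc["a", "rank"] == 1  # tie with b -> id order
        assert table.loc["b", "rank"] == 2
        assert table.loc["c", "rank"] == 3


class TestDLDA:
    def test_hand_arithmetic_fit(self):
        m = two_group_matrix([[1, 3]], [[5, 7]])
        model = dlda_fit(m, ["g0"])
        assert model.class_means.loc["g0", "treated"] == 2
        assert model.class_means.loc["g0", "vehicle"] == 6
        assert model.pooled_var["g0"] == pytest.approx(2.0)

    def test_constant_gene_floored(self):
        m = two_group_matrix([[2, 2, 2]], [[2, 2, 2]])
        model = dlda_fit(m, ["g0"])
        assert model.pooled_var["g0"] > 0

    def test_fit_matches_direct_formulas(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5, 1, (5, 6))
        b = rng.normal(7, 2, (5, 4))
        m = two_group_matrix(a, b)
        model = dlda_fit(m, list(m.gene_ids))
        np.testing.assert_allclose(model.class_means["treated"], a.mean(1))
        np.testing.assert_allclose(model.class_means["vehicle"], b.mean(1))
        wss = ((a - a.mean(1, keepdims=True)) ** 2).sum(1) \
            + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
        np.testing.assert_allclose(model.pooled_var, wss / 8)

    def test_predict_examples_and_tie_rule(self):
        m = two_group_matrix([[0, 0], [0, 0]], [[10, 10], [10, 10]])
        model = dlda_fit(m, ["g0", "g1"])
        assert dlda_predict(model, {"g0": 1, "g1": 1}) == "treated"
        assert dlda_predict(model, {"g0": 9, "g1": 9}) == "vehicle"
        assert dlda_predict(model, {"g0": 5, "g1": 5}) == "vehicle"  # tie

    def test_predict_missing_gene_raises(self):
        m = two_group_matrix([[0, 0]], [[10, 10]])
        model = dlda_fit(m, ["g0"])
        with pytest.raises(KeyError, match="g0"):
            dlda_predict(model, {"other": 1})

    def test_predict_matches_gaussian_classifier_oracle(self):
        # independent oracle: equal-prior shared-diagonal-covariance Gaussian
        # log-likelihoods via scipy.stats.norm
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = rng.integers(1, 5)
            a = rng.normal(0, 1, (g, rng.integers(3, 6)))
            b = rng.normal(rng.normal(), 1, (g, rng.integers(3, 6)))
            m = two_group_matrix(a, b)
            genes = list(m.gene_ids)
            model = dlda_fit(m, genes)
            x = rng.normal(0, 2, g)
            sd = np.sqrt(model.pooled_var.to_numpy())
            ll_t = stats.norm.logpdf(
                x, model.class_means["treated"], sd).sum()
            ll_v = stats.norm.logpdf(
                x, model.class_means["vehicle"], sd).sum()
            expected = "treated" if ll_t > ll_v else "vehicle"
            assert dlda_predict(model, dict(zip(genes, x))) == expected


class TestLOOCV:
    def test_perfect_separation(self):
        rng = np.random.default_rng(1)
        m = two_group_matrix([1 + 0.01 * rng.normal(size=10)],
                             [100 + 0.01 * rng.normal(size=10)])
        assert loocv_accuracy(m, ["g0"]) == 1.0

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(2)
        m = two_group_matrix(rng.normal(0, 1, (1, 40)),
                             rng.normal(0, 1, (1, 40)))
        acc = loocv_accuracy(m, ["g0"])
        assert 0.2 <= acc <= 0.8  # binomial tolerance around 0.5 at n=80

    def test_manual_four_fold_enumeration(self):
        # hand-enumerated folds: A1 -> treated (correct), A2 -> vehicle
        # (wrong), B1 -> treated (wrong), B2 -> tie -> vehicle (correct)
        m = two_group_matrix([[1, 3]], [[2, 6]])
        assert loocv_accuracy(m, ["g0"]) == 0.5


class TestForwardSelect:
    def test_single_perfect_separator(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1, (5, 20))
        sep = np.concatenate([np.zeros(10), np.ones(10) * 50])
        rows = np.vstack([sep, noise])
        m = two_group_matrix(rows[:, :10], rows[:, 10:],
                             genes=["hit", "n1", "n2", "n3", "n4", "n5"])
        model = forward_select(m, de_filter(m), snr(m))
        assert model.genes == ["hit"]
        assert model.selection_trace == [1.0]

    def test_no_de_genes_raises(self):
        m = two_group_matrix([[1, 2, 3]], [[1, 2, 3]])
        with pytest.raises(NoDiscriminantGenesError, match="p < 0.01"):
            forward_select(m, de_filter(m), snr(m))

    def test_trace_nondecreasing_and_capped(self, default_two_group):
        matrix, _ = default_two_group
        de = de_filter(matrix)
        model = forward_select(matrix, de, snr(matrix), cap=7)
        assert 1 <= len(model.genes) <= 7
        assert all(b >= a for a, b in
                   zip(model.selection_trace, model.selection_trace[1:]))
        assert set(model.genes) <= set(de.index[de["selected"]])
        assert model.loocv_accuracy == model.selection_trace[-1]


class TestDivergenceReduce:
    def _planted(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 10
        up = np.vstack([np.full(n, 10.0), np.full(n, 1.0)]).reshape(1, -1)
        rows = []
        genes = []
        for i, shift in enumerate([8, 8, 8]):  # three strong down genes
            rows.append(np.concatenate([rng.normal(2, 0.1, n),
                                        rng.normal(2 + shift, 0.1, n)]))
            genes.append(f"down{i}")
        rows.append(np.concatenate([rng.normal(9, 0.1, n),
                                    rng.normal(1, 0.1, n)]))
        genes.append("up0")
        arr = np.vstack(rows)
        return two_group_matrix(arr[:, :n], arr[:, n:], genes=genes)

    def test_reduces_to_smallest_divergent_subset(self):
        m = self._planted()
        full = dlda_fit(m, ["down0", "down1", "down2", "up0"])
        full.loocv_accuracy = loocv_accuracy(m, full.genes)
        reduced = divergence_reduce(m, full)
        assert len(reduced.genes) == 2
        signs = set(np.sign(reduced.class_means["treated"]
                            - reduced.class_means["vehicle"]))
        assert signs == {1.0, -1.0}
        assert reduced.loocv_accuracy >= full.loocv_accuracy

    def test_matches_exhaustive_subset_oracle(self):
        m = self._planted(seed=4)
        genes = ["down0", "down1", "down2", "up0"]
        full = dlda_fit(m, genes)
        full.loocv_accuracy = loocv_accuracy(m, genes)
        reduced = divergence_reduce(m, full)

        # oracle: enumerate every divergent subset, keep accurate ones,
        # order by (size, -summed |SNR|, genes)
        snr_vals = snr(m)["snr"].abs()
        diff = m.group_values("treated").mean(1) - m.group_values("vehicle").mean(1)
        sign = dict(zip(m.gene_ids, np.sign(diff)))
        best = None
        for size in range(1, len(genes) + 1):
            options = []
            for combo in itertools.combinations(sorted(genes), size):
                if {1.0, -1.0} <= {sign[g] for g in combo}:
                    acc = loocv_accuracy(m, list(combo))
                    if acc >= full.loocv_accuracy:
                        options.append((-sum(snr_vals[g] for g in combo), combo))
            if options:
                best = sorted(options)[0][1]
                break
        assert tuple(reduced.genes) == best

    def test_same_direction_signature_returns_warning(self):
        m = self._planted()
        model = dlda_fit(m, ["down0", "down1"])
        model.loocv_accuracy = loocv_accuracy(m, model.genes)
        out = divergence_reduce(m, model)
        assert out.divergence_warning
        assert out.genes == ["down0", "down1"]

    def test_minimal_divergent_signature_fixed_point(self):
        m = self._planted()
        model = dlda_fit(m, ["down0", "up0"])
        model.loocv_accuracy = loocv_accuracy(m, model.genes)
        out = divergence_reduce(m, model)
        assert out.genes == ["down0", "up0"]
        assert not out.divergence_warning


class TestDeriveSignature:
    def test_end_to_end_properties(self, default_two_group):
        matrix, truth = default_two_group
        model = derive_signature(matrix)
        assert 1 <= len(model.genes) <= 7
        assert model.loocv_accuracy >= 0.99
        # every selected gene is a strong discriminator: planted genes
        # dominate the SNR ranking on this data
        table = snr(matrix)
        for g in model.genes:
            assert table.loc[g, "rank"] <= 25 or g in truth.signature_genes
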