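import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crickspace as cs
from crickspace.boundary import (
    depletion_pvalue,
    fit_boundary,
    fraction_in_depleted,
    shuffle_dataset,
)


def frame_from_ratios(ratios, beta_m=None, alpha_m=5.1, alpha_p=1.34):
    ratios = np.asarray(ratios, dtype=float)
    beta_m = np.full(ratios.size, 10.0) if beta_m is None else np.asarray(beta_m)
    beta_p = ratios * beta_m
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(ratios.size)],
            "beta_m": beta_m,
            "beta_p": beta_p,
            "m": beta_m / alpha_m,
            "p": beta_m * beta_p / (alpha_m * alpha_p),
        }
    )


class TestFitBoundary:
    def test_degenerate_shared_ratio(self):
        frame = frame_from_ratios(np.full(50, 3.0))
        fit = fit_boundary(frame, seed=1)
        assert fit.k == pytest.approx(3.0)
        assert fit.k_se == 0.0

    def test_order_statistic_rule(self):
        """k is the largest ratio with at most 1% of genes strictly below
        (brute-force sort oracle)."""
        ratios = np.arange(1.0, 101.0)
        frame = frame_from_ratios(ratios)
        fit = fit_boundary(frame, exclusion_fraction=0.01, seed=1)
        srt = np.sort(ratios)
        candidates = [v for v in srt if np.sum(srt < v) <= 0.01 * srt.size]
        assert fit.k == pytest.approx(max(candidates))
        assert fit.k == pytest.approx(2.0)

    def test_scale_equivariance(self, rates_frame):
        base = fit_boundary(rates_frame, exclusion_fraction=0.2, seed=3)
        scaled_p = rates_frame.assign(beta_p=rates_frame["beta_p"] * 7.0)
        assert fit_boundary(scaled_p, 0.2, seed=3).k == pytest.approx(7.0 * base.k)
        scaled_m = rates_frame.assign(beta_m=rates_frame["beta_m"] * 4.0)
        assert fit_boundary(scaled_m, 0.2, seed=3).k == pytest.approx(base.k / 4.0)

    def test_small_fraction_warns_and_uses_minimum(self):
        frame = frame_from_ratios(np.arange(1.0, 21.0))
        with pytest.warns(UserWarning):
            fit = fit_boundary(frame, exclusion_fraction=0.01, seed=1)
        assert fit.k == pytest.approx(1.0)

    def test_too_few_genes(self):
        with pytest.raises(cs.InvalidParameterError):
            fit_boundary(frame_from_ratios([1.0, 2.0]), seed=0)


class TestShuffle:
    def test_single_gene_identity(self, yeast):
        frame = frame_from_ratios([5.0])
        shuffled = shuffle_dataset(frame, yeast, seed=0)
        assert shuffled["p"].iloc[0] == pytest.approx(frame["p"].iloc[0])
        assert shuffled["beta_p"].iloc[0] == pytest.approx(frame["beta_p"].iloc[0])

    def test_marginals_conserved(self, yeast, small_gene_table):
        truth, _ = small_gene_table
        big = pd.concat([truth] * 13, ignore_index=True)  # ~5000 rows
        shuffled = shuffle_dataset(big, yeast, seed=4)
        ks_p = stats.ks_2samp(shuffled["p"], big["p"]).pvalue
        ks_bp = stats.ks_2samp(shuffled["beta_p"], big["beta_p"]).pvalue
        assert ks_p > 0.01 and ks_bp > 0.01
        assert shuffled["beta_p"].max() <= big["beta_p"].max()

    def test_permutation_mode_exact_marginals(self, yeast, small_gene_table):
        truth, _ = small_gene_table
        shuffled = shuffle_dataset(truth, yeast, seed=4, replace=False)
        np.testing.assert_allclose(np.sort(shuffled["p"]), np.sort(truth["p"]))
        np.testing.assert_allclose(np.sort(shuffled["beta_p"]), np.sort(truth["beta_p"]))

    def test_expected_below_count_matches_marginal_product(self, yeast):
        """Shuffling destroys a planted exclusion zone: the mean below-boundary
        count matches the brute-force integral of the product of the two
        empirical marginals."""
        spec = cs.GeneTableSpec(n_genes=400, k_true=0.1, depletion_mode="hard-boundary", seed=9)
        truth, _ = cs.generate_gene_table(spec, yeast)
        k = 0.1
        scale = yeast.alpha_m * yeast.alpha_p
        p = truth["p"].to_numpy()
        bp = truth["beta_p"].to_numpy()
        # brute force: P(ratio < k) under independent marginals
        below = (bp[None, :] ** 2 < k * scale * p[:, None]).mean()
        expected = below * len(truth)
        counts = []
        rng = np.random.default_rng(11)
        for _ in range(300):
            shuffled = shuffle_dataset(truth, yeast, seed=rng)
            counts.append(np.sum(shuffled["beta_p"] / shuffled["beta_m"] < k))
        counts = np.array(counts)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3 * se + 1e-9
        assert expected > 5  # the zone really is refilled by shuffling


class TestDepletionPvalue:
    def test_extreme_pseudocount(self, yeast):
        spec = cs.GeneTableSpec(n_genes=1000, k_true=2.0, depletion_mode="hard-boundary", seed=2)
        truth, _ = cs.generate_gene_table(spec, yeast)
        test = depletion_pvalue(truth, 2.0, yeast, n_shuffles=1000, seed=0)
        assert test.observed_below == 0
        assert test.p_value == pytest.approx(1.0 / 1001.0)

    def test_planted_depletion_detected(self, yeast):
        spec = cs.GeneTableSpec(n_genes=2000, k_true=1.0, depletion_mode="hard-boundary", seed=3)
        truth, _ = cs.generate_gene_table(spec, yeast)
        k = fit_boundary(truth, seed=1).k
        test = depletion_pvalue(truth, k, yeast, n_shuffles=1000, seed=1)
        assert test.p_value <= 0.01

    def test_null_calibration(self, yeast):
        """On data generated from independent marginals the test is not
        anti-conservative: few replicates reach p < 0.05."""
        pvals = []
        for s in range(25):
            truth, _ = cs.generate_gene_table(cs.GeneTableSpec(n_genes=500, seed=200 + s), yeast)
            k = fit_boundary(truth, seed=s, n_boot=10).k
            pvals.append(depletion_pvalue(truth, k, yeast, n_shuffles=200, seed=s).p_value)
        assert np.mean(np.array(pvals) < 0.05) <= 0.15

    def test_determinism_and_order_invariance(self, yeast, small_gene_table):
        truth, _ = small_gene_table
        k = fit_boundary(truth, seed=0).k
        a = depletion_pvalue(truth, k, yeast, n_shuffles=200, seed=7)
        b = depletion_pvalue(truth, k, yeast, n_shuffles=200, seed=7)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_counts, b.null_counts)
        reordered = truth.sample(frac=1.0, random_state=0).reset_index(drop=True)
        c = depletion_pvalue(reordered, k, yeast, n_shuffles=200, seed=7)
        assert c.observed_below == a.observed_below

    def test_invalid_inputs(self, yeast, small_gene_table):
        truth, _ = small_gene_table
        with pytest.raises(cs.InvalidParameterError):
            depletion_pvalue(truth, -1.0, yeast, n_shuffles=200, seed=0)
        with pytest.raises(cs.InvalidParameterError):
            depletion_pvalue(truth, 1.0, yeast, n_shuffles=10, seed=0)


class TestFractionInDepleted:
    def test_all_above(self):
        frame = frame_from_ratios([2.0, 3.0, 4.0])
        assert fraction_in_depleted(frame, 1.0) == 0.0

    def test_planted_fraction(self):
        ratios = np.concatenate([np.full(25, 0.5), np.full(75, 2.0)])
        frame = frame_from_ratios(ratios)
        assert fraction_in_depleted(frame, 1.0) == pytest.approx(0.25)

    def test_self_consistency_with_fit(self, yeast):
        truth, _ = cs.generate_gene_table(cs.GeneTableSpec(n_genes=1000, seed=8), yeast)
        fit = fit_boundary(truth, exclusion_fraction=0.01, seed=1)
        frac = fraction_in_depleted(truth, fit.k)
        assert frac <= 0.01 + 1e-12
        assert frac >= 0.005
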