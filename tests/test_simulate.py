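"""Generator invariants: family structure, moments, missingness, determinism."""

import numpy as np
import pytest

import twinaxe as tx
from twinaxe.simulate import (
    generate_item_responses,
    generate_latents,
    inject_missingness,
)


def _corr_pairs(x):
    return np.corrcoef(x[0::2], x[1::2])[0, 1]


class TestLatentStructure:
    def test_theta_is_exact_sum_of_components(self, hyper_truth):
        lat = generate_latents(hyper_truth, tx.CohortDesign(n_mz=200, n_dz=300), 1)
        np.testing.assert_array_equal(lat.theta, lat.A + lat.C + lat.D + lat.E)

    def test_mz_share_genetic_values_dz_correlate_half(self, hyper_truth):
        design = tx.CohortDesign(n_mz=20000, n_dz=20000)
        lat = generate_latents(hyper_truth, design, 2)
        is_mz = np.repeat(lat.zygosity == "MZ", 2)
        a_mz = lat.A[is_mz]
        np.testing.assert_array_equal(a_mz[0::2], a_mz[1::2])
        a_dz = lat.A[~is_mz]
        # 3 MC standard errors for a correlation at n = 20000 pairs
        assert abs(_corr_pairs(a_dz) - 0.5) < 3.0 / np.sqrt(20000)

    def test_dominance_correlations(self):
        params = tx.GeneticParams(
            model="ADE", sigma2_a=0.2, sigma2_d=0.4, beta0=np.log(0.3)
        )
        lat = generate_latents(params, tx.CohortDesign(n_mz=20000, n_dz=20000), 3)
        is_mz = np.repeat(lat.zygosity == "MZ", 2)
        np.testing.assert_array_equal(lat.D[is_mz][0::2], lat.D[is_mz][1::2])
        assert abs(_corr_pairs(lat.D[~is_mz]) - 0.25) < 3.0 / np.sqrt(20000)
        assert abs(lat.D.var() - 0.4) < 0.02

    def test_twin_trait_correlations_homoscedastic_case(self):
        # MZ: (a + c) / total; DZ: (a/2 + c) / total, within 3 MC SEs
        params = tx.GeneticParams(
            model="ACE", sigma2_a=0.4, sigma2_c=0.2, beta0=np.log(0.4)
        )
        n = 30000
        lat = generate_latents(params, tx.CohortDesign(n_mz=n, n_dz=n), 4)
        total = 0.4 + 0.2 + 0.4
        is_mz = np.repeat(lat.zygosity == "MZ", 2)
        se = 1.0 / np.sqrt(n)
        assert abs(_corr_pairs(lat.theta[is_mz]) - 0.6 / total) < 3 * se
        assert abs(_corr_pairs(lat.theta[~is_mz]) - 0.4 / total) < 3 * se

    def test_heteroscedastic_e_variance_matches_lognormal_moment(self, hyper_truth):
        # E[exp(b0 + b1 A)] = exp(b0) * exp(b1^2 sigma2_A / 2) = 0.349
        lat = generate_latents(hyper_truth, tx.CohortDesign(n_mz=100000, n_dz=0), 5)
        expected = 0.19 * np.exp(2.20**2 * 0.25 / 2.0)
        assert abs(lat.E.var() - expected) < 0.01
        # and E-variance is exp(beta0) = 0.19 when the slope is off
        flat = tx.GeneticParams(
            model="AE", sigma2_a=0.25, beta0=float(np.log(0.19))
        )
        lat0 = generate_latents(flat, tx.CohortDesign(n_mz=100000, n_dz=0), 5)
        assert abs(lat0.E.var() - 0.19) < 0.005

    def test_degenerate_decomposition_var_theta_is_exp_beta0(self):
        params = tx.GeneticParams(model="AE", sigma2_a=0.0, beta0=np.log(0.5))
        lat = generate_latents(params, tx.CohortDesign(n_mz=0, n_dz=50000), 6)
        assert np.all(lat.A == 0.0)
        assert abs(lat.theta.var() - 0.5) < 0.01

    def test_seed_reproducibility(self, hyper_truth):
        d = tx.CohortDesign(n_mz=50, n_dz=50)
        a = generate_latents(hyper_truth, d, 7)
        b = generate_latents(hyper_truth, d, 7)
        c = generate_latents(hyper_truth, d, 8)
        np.testing.assert_array_equal(a.theta, b.theta)
        assert not np.array_equal(a.theta, c.theta)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            tx.GeneticParams(model="ADE", sigma2_c=0.1, sigma2_d=0.1)
        with pytest.raises(ValueError):
            tx.GeneticParams(model="AE", interaction=False, beta1=1.0)


class TestItemResponses:
    def test_zero_discrimination_gives_uniform_categories(self, hyper_truth):
        bank = tx.ItemBank(
            alphas=np.zeros(2),
            thresholds=[np.array([0.0, -1.0, 1.0])] * 2,
        )
        lat = generate_latents(hyper_truth, tx.CohortDesign(
            n_mz=20000, n_dz=0, n_categories=(3, 3)), 9)
        table = generate_item_responses(lat, bank, 10)
        freqs = np.bincount(table.responses[:, 0], minlength=3) / 40000
        np.testing.assert_allclose(freqs, 1 / 3, atol=3 * np.sqrt(2 / 9 / 40000))

    def test_frequencies_match_gpcm_probs_at_fixed_theta(self):
        # all variance off => theta == 0 for everyone
        params = tx.GeneticParams(model="AE", sigma2_a=0.0, beta0=-30.0)
        lat = generate_latents(params, tx.CohortDesign(
            n_mz=50000, n_dz=0, n_categories=(4,)), 11)
        bank = tx.ItemBank(
            alphas=np.array([1.3]),
            thresholds=[np.array([0.0, -0.5, 0.3, 1.1])],
        )
        table = generate_item_responses(lat, bank, 12)
        freqs = np.bincount(table.responses[:, 0], minlength=4) / 100000
        probs = tx.gpcm_category_probs(0.0, 1.3, bank.thresholds[0])
        np.testing.assert_allclose(freqs, probs, atol=0.006)

    def test_no_missing_without_spec_and_categories_in_range(
        self, small_bank, hyper_truth
    ):
        lat = generate_latents(hyper_truth, tx.CohortDesign(
            n_mz=100, n_dz=100, n_categories=small_bank.n_categories), 13)
        table = generate_item_responses(lat, small_bank, 14)
        assert table.missing_mask.sum() == 0
        assert table.responses.min() >= 0
        assert (table.responses < np.array(small_bank.n_categories)).all()

    def test_item_with_too_few_categories_rejected(self):
        with pytest.raises(ValueError):
            tx.ItemBank(alphas=np.array([1.0]), thresholds=[np.array([0.0])])


class TestMissingness:
    def test_counts_round_to_nearest_family(self, small_bank, hyper_truth):
        design = tx.CohortDesign(
            n_mz=50, n_dz=50, n_categories=small_bank.n_categories,
            missingness_spec=((0.95, 0), (0.05, 1)),
        )
        lat = generate_latents(hyper_truth, design, 15)
        table = generate_item_responses(lat, small_bank, 16)
        out = inject_missingness(table, design, 17)
        per_family = out.missing_mask.reshape(100, -1).sum(axis=1)
        assert (per_family == 0).sum() == 95
        assert (per_family == 1).sum() == 5

    def test_cohort_missingness_pattern(self, bank9, hyper_truth):
        design = tx.CohortDesign(
            n_mz=500, n_dz=500,
            missingness_spec=((0.95, 0), (0.02, 1), (0.01, 5), (0.02, 9)),
        )
        lat = generate_latents(hyper_truth, design, 18)
        table = generate_item_responses(lat, bank9, 19)
        out = inject_missingness(table, design, 20)
        per_family = out.missing_mask.reshape(1000, -1).sum(axis=1)
        counts = {m: int((per_family == m).sum()) for m in (0, 1, 5, 9)}
        assert counts == {0: 950, 1: 20, 5: 10, 9: 20}

    def test_all_complete_spec_leaves_table_unchanged(self, small_cohort):
        table, _, _ = small_cohort
        design = tx.CohortDesign(
            n_mz=60, n_dz=80, n_categories=table.n_categories,
            missingness_spec=((1.0, 0),),
        )
        out = inject_missingness(table, design, 21)
        np.testing.assert_array_equal(out.responses, table.responses)

    def test_impossible_per_family_count_rejected(self):
        with pytest.raises(ValueError):
            tx.CohortDesign(
                n_mz=10, n_dz=0, n_categories=(3, 3),
                missingness_spec=((0.5, 5),),
            )
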