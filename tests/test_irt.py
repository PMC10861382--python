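"""Marginal-ML IRT stage: oracles, nesting, recovery, classical statistics."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import twinaxe as tx
from twinaxe.gpcm import item_probs
from twinaxe.irt import (
    classical_stats,
    fit_irt,
    item_information,
    marginal_log_lik,
    select_one_twin,
)
from twinaxe.simulate import generate_item_responses, generate_latents


def _unit_variance_cohort(bank, n_families, seed):
    """Cohort whose latent trait is ~standard normal (the MML convention)."""
    params = tx.GeneticParams(model="AE", sigma2_a=0.5, beta0=float(np.log(0.5)))
    design = tx.CohortDesign(
        n_mz=0, n_dz=n_families, n_categories=bank.n_categories
    )
    lat = generate_latents(params, design, seed)
    return generate_item_responses(lat, bank, seed + 1)


@pytest.fixture(scope="module")
def gpcm_fit_data(bank9):
    table = _unit_variance_cohort(bank9, 2000, 31)
    responses = select_one_twin(table, 32)
    return table, responses


class TestFitIrt:
    def test_aic_identity_and_parameter_count(self, gpcm_fit_data):
        _, responses = gpcm_fit_data
        fit = fit_irt(responses, (7,) * 9, kind="GPCM", max_iter=40)
        # 9 discriminations + 9 * 6 free thresholds
        assert fit.n_parameters == 63
        assert fit.aic == -2.0 * fit.log_lik + 2.0 * fit.n_parameters

    def test_pcm_nested_in_gpcm(self, gpcm_fit_data):
        _, responses = gpcm_fit_data
        pcm = fit_irt(responses, (7,) * 9, kind="PCM")
        gpcm = fit_irt(responses, (7,) * 9, kind="GPCM")
        assert pcm.log_lik <= gpcm.log_lik + 1e-6
        assert pcm.n_parameters == 54

    def test_gpcm_recovers_discriminations(self, bank9, gpcm_fit_data):
        _, responses = gpcm_fit_data
        fit = fit_irt(responses, (7,) * 9, kind="GPCM")
        err = np.abs(fit.item_bank.alphas - bank9.alphas)
        assert err.mean() < 0.15

    def test_marginal_likelihood_matches_independent_quadrature(
        self, gpcm_fit_data
    ):
        from scipy.special import roots_hermitenorm

        _, responses = gpcm_fit_data
        fit = fit_irt(responses, (7,) * 9, kind="GPCM", max_iter=10)
        bank = fit.item_bank
        sub = responses[:20]
        # brute force: same fixed 61-node rule, naive per-person loop
        nodes, wts = roots_hermitenorm(61)
        wts = wts / np.sqrt(2.0 * np.pi)
        brute = 0.0
        for row in sub:
            per_node = np.ones(61)
            for q, th in enumerate(nodes):
                for i, y in enumerate(row):
                    per_node[q] *= item_probs(
                        "GPCM", th, bank.alphas[i], bank.thresholds[i]
                    )[y]
            brute += np.log((wts * per_node).sum())
        assert abs(marginal_log_lik(sub, bank) - brute) < 1e-8
        # and the fixed rule agrees with adaptive quadrature to its truncation
        adaptive = 0.0
        for row in sub:
            def integrand(th, row=row):
                p = 1.0
                for i, y in enumerate(row):
                    p *= item_probs("GPCM", th, bank.alphas[i], bank.thresholds[i])[y]
                return p * norm.pdf(th)
            val, _ = quad(integrand, -9, 9, limit=200)
            adaptive += np.log(val)
        assert abs(marginal_log_lik(sub, bank) - adaptive) < 0.1

    def test_model_recovery_prefers_generating_pcm(self):
        # PCM data (all alphas 1): AIC should favour PCM over GPCM mostly
        thr = [np.concatenate([[0.0], np.linspace(-1.2, 1.2, 3)])] * 5
        pcm_bank = tx.ItemBank(alphas=np.ones(5), thresholds=thr, model_kind="PCM")
        wins = 0
        for rep in range(5):
            table = _unit_variance_cohort(pcm_bank, 500, 100 + rep)
            responses = select_one_twin(table, 200 + rep)
            pcm = fit_irt(responses, (4,) * 5, kind="PCM")
            gpcm = fit_irt(responses, (4,) * 5, kind="GPCM")
            wins += pcm.aic < gpcm.aic
        assert wins >= 3

    def test_em_loglik_monotone(self, gpcm_fit_data):
        _, responses = gpcm_fit_data
        lls = [
            fit_irt(responses[:400], (7,) * 9, kind="GPCM", max_iter=m,
                    tol=0.0).log_lik
            for m in (2, 5, 12)
        ]
        assert lls[0] <= lls[1] + 1e-8 <= lls[2] + 2e-8

    def test_unobserved_category_collapsed(self):
        rng = np.random.default_rng(7)
        responses = rng.integers(0, 2, size=(200, 2)) * 2  # categories {0, 2}
        fit = fit_irt(responses, (3, 3), kind="GPCM")
        assert fit.collapsed == {0: [1], 1: [1]}
        assert fit.item_bank.n_categories == (2, 2)
        with pytest.raises(ValueError):
            fit_irt(responses, (3, 3), kind="GPCM", collapse_unobserved=False)


class TestItemInformation:
    def test_information_nonnegative_and_additive(self, bank9):
        grid = np.linspace(-3, 3, 41)
        info = item_information(bank9, grid)
        assert (info["items"] >= 0).all()
        np.testing.assert_allclose(info["total"], info["items"].sum(axis=0))

    def test_matches_enumeration_oracle(self, bank9):
        # info = alpha^2 * Var(K | theta), variance enumerated by hand
        grid = np.array([-1.0, 0.0, 1.3])
        info = item_information(bank9, grid)
        for i in (0, 4):
            for j, th in enumerate(grid):
                p = tx.gpcm_category_probs(th, bank9.alphas[i], bank9.thresholds[i])
                k = np.arange(p.size)
                var = (p * k**2).sum() - (p * k).sum() ** 2
                np.testing.assert_allclose(
                    info["items"][i, j], bank9.alphas[i] ** 2 * var, rtol=1e-10
                )

    def test_zero_discrimination_zero_information(self):
        bank = tx.ItemBank(
            alphas=np.array([0.0]), thresholds=[np.array([0.0, 0.5, 1.0])]
        )
        info = item_information(bank, np.linspace(-2, 2, 11))
        np.testing.assert_allclose(info["items"], 0.0, atol=1e-12)

    def test_empty_grid_rejected(self, bank9):
        with pytest.raises(ValueError):
            item_information(bank9, np.array([]))


class TestClassicalStats:
    def test_duplicated_items_give_alpha_one(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 5, size=200)
        responses = np.column_stack([col, col])
        table = tx.ItemResponseTable(
            family_id=np.arange(100),
            zygosity=np.array(["MZ"] * 50 + ["DZ"] * 50, dtype=object),
            responses=responses,
            n_categories=(5, 5),
        )
        stats = classical_stats(table)
        np.testing.assert_allclose(stats["cronbach_alpha"], 1.0, atol=1e-12)

    def test_alpha_and_item_rest_match_direct_recomputation(self, small_cohort):
        table, _, _ = small_cohort
        stats = classical_stats(table)
        resp = table.responses[~table.missing_mask.any(axis=1)].astype(float)
        n_i = resp.shape[1]
        direct_alpha = (n_i / (n_i - 1)) * (
            1 - resp.var(axis=0, ddof=1).sum() / resp.sum(axis=1).var(ddof=1)
        )
        np.testing.assert_allclose(stats["cronbach_alpha"], direct_alpha)
        for i in range(n_i):
            rest = resp.sum(axis=1) - resp[:, i]
            np.testing.assert_allclose(
                stats["item_rest"][i], np.corrcoef(resp[:, i], rest)[0, 1]
            )

    def test_constant_item_flagged_undefined(self):
        rng = np.random.default_rng(6)
        responses = np.column_stack(
            [rng.integers(0, 3, 100), np.ones(100, dtype=int)]
        )
        table = tx.ItemResponseTable(
            family_id=np.arange(50),
            zygosity=np.array(["MZ"] * 50, dtype=object),
            responses=responses,
            n_categories=(3, 3),
        )
        with pytest.warns(UserWarning, match="zero variance"):
            stats = classical_stats(table)
        assert np.isnan(stats["item_rest"][1])

    def test_sum_score_twin_correlations_positive_for_familial_trait(
        self, small_cohort
    ):
        table, _, _ = small_cohort
        stats = classical_stats(table)
        assert stats["mz_sum_corr"] > stats["dz_sum_corr"] > 0
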