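"""Biometric model: derived quantities and the joint density vs grid oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import halfnorm, lognorm, norm

import twinaxe as tx
from twinaxe.genetic import ModelState, joint_log_density, log_prior


class TestDerivedQuantities:
    def test_env_variance_values(self):
        assert tx.env_variance(np.log(0.19), 2.20, 0.0) == pytest.approx(0.19)
        assert tx.env_variance(0.0, 0.0, 12.3) == pytest.approx(1.0)
        assert tx.env_variance(np.log(0.19), 2.20, 0.5) == pytest.approx(
            0.19 * np.exp(1.10), rel=1e-12
        )

    @settings(derandomize=True, max_examples=60)
    @given(
        beta0=st.floats(-3, 1),
        beta1=st.floats(-3, 3),
        g=st.floats(-2, 2),
        dg=st.floats(0.01, 1.0),
    )
    def test_env_variance_positive_and_monotone_in_g(self, beta0, beta1, g, dg):
        lo, hi = tx.env_variance(beta0, beta1, [g, g + dg])
        assert lo > 0 and hi > 0
        if beta1 * dg > 1e-6:
            assert hi > lo
        elif beta1 * dg < -1e-6:
            assert hi < lo

    def test_heritability_ae(self):
        p = tx.GeneticParams(model="AE", sigma2_a=0.25, beta0=float(np.log(0.19)))
        assert tx.heritability(p) == pytest.approx(0.25 / 0.44)
        assert round(100 * tx.heritability(p)) == 57

    def test_heritability_ace_and_edge_cases(self):
        p = tx.GeneticParams(
            model="ACE", sigma2_a=0.27, sigma2_c=0.31, beta0=float(np.log(0.51))
        )
        assert tx.heritability(p) == pytest.approx(0.27 / 1.09, rel=1e-3)
        zero = tx.GeneticParams(model="AE", sigma2_a=0.0, beta0=np.log(0.3))
        assert tx.heritability(zero) == 0.0
        with pytest.raises(ValueError):
            tx.heritability(tx.GeneticParams(model="AE", beta0=-np.inf))

    def test_heritability_scale_invariant(self):
        p = tx.GeneticParams(model="AE", sigma2_a=0.25, beta0=float(np.log(0.19)))
        for c in (0.5, 2.0, 7.3):
            scaled = tx.GeneticParams(
                model="AE", sigma2_a=c * 0.25, beta0=float(np.log(c * 0.19))
            )
            assert tx.heritability(scaled) == pytest.approx(tx.heritability(p))

    def test_interaction_effect_size(self):
        assert round(tx.interaction_effect_size(2.20, 0.25), 2) == 3.00
        assert round(tx.interaction_effect_size(2.16, 0.27), 2) == 3.07
        assert tx.interaction_effect_size(0.0, 0.5) == 1.0

    def test_total_phenotypic_variance(self):
        hyper = tx.GeneticParams(
            model="AE", sigma2_a=0.25, beta0=float(np.log(0.19))
        )
        assert tx.total_phenotypic_variance(hyper) == pytest.approx(0.44)
        inat = tx.GeneticParams(
            model="ACE", sigma2_a=0.27, sigma2_c=0.31, beta0=float(np.log(0.51))
        )
        assert tx.total_phenotypic_variance(inat) == pytest.approx(1.09)
        bare = tx.GeneticParams(model="AE", beta0=np.log(0.7))
        assert tx.total_phenotypic_variance(bare) == pytest.approx(0.7)


def _one_pair_setup(beta1=0.8):
    """One MZ pair answering one 2-category item."""
    params = tx.GeneticParams(
        model="AE", interaction=beta1 != 0.0, sigma2_a=0.3,
        beta0=float(np.log(0.2)), beta1=beta1,
    )
    items = tx.ItemBank(
        alphas=np.array([1.2]), thresholds=[np.array([0.0, 0.4])]
    )
    data = tx.ItemResponseTable(
        family_id=np.array([0]),
        zygosity=np.array(["MZ"], dtype=object),
        responses=np.array([[1], [0]]),
        n_categories=(2,),
    )
    spec = tx.ModelSpec(flavour="AE", interaction=beta1 != 0.0)
    return params, items, data, spec


def _independent_log_density(params, items, a, th1, th2, y1, y2):
    """Same joint density assembled from elementary pieces (the oracle)."""
    alpha, b = items.alphas[0], items.thresholds[0][1]
    out = 0.0
    for th, y in ((th1, y1), (th2, y2)):
        p2 = expit(alpha * (th - b))
        out += np.log(p2 if y == 1 else 1.0 - p2)
    out += norm.logpdf(a, scale=np.sqrt(params.sigma2_a))
    for th in (th1, th2):
        sd = np.sqrt(np.exp(params.beta0 + params.beta1 * a))
        out += norm.logpdf(th - a, scale=sd)
    return out


class TestJointLogDensity:
    def test_pointwise_against_independent_assembly(self):
        params, items, data, spec = _one_pair_setup()
        prior = log_prior(params, items, spec)
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, th1, th2 = rng.normal(scale=1.2, size=3)
            state = ModelState(
                params=params, items=items,
                A=np.array([a, a]), C=np.zeros(2), D=np.zeros(2),
                theta=np.array([th1, th2]),
            )
            got = joint_log_density(state, data, spec)
            want = _independent_log_density(
                params, items, a, th1, th2, 1, 0
            ) + prior
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_marginal_likelihood_by_grid_integration(self):
        # integrate exp(joint - prior) over (A, theta1, theta2) and compare
        # with the independent oracle integrated on the same grid
        params, items, data, spec = _one_pair_setup()
        prior = log_prior(params, items, spec)
        a_g = np.linspace(-2.2, 2.2, 23)
        t_g = np.linspace(-3.0, 3.0, 31)
        da, dt = a_g[1] - a_g[0], t_g[1] - t_g[0]
        total_mod, total_ora = 0.0, 0.0
        for a in a_g:
            for th1 in t_g:
                for th2 in t_g:
                    state = ModelState(
                        params=params, items=items,
                        A=np.array([a, a]), C=np.zeros(2), D=np.zeros(2),
                        theta=np.array([th1, th2]),
                    )
                    total_mod += np.exp(
                        joint_log_density(state, data, spec) - prior
                    )
                    total_ora += np.exp(
                        _independent_log_density(params, items, a, th1, th2, 1, 0)
                    )
        total_mod *= da * dt * dt
        total_ora *= da * dt * dt
        assert abs(total_mod - total_ora) < 1e-4
        assert 0.0 < total_mod < 1.0

    def test_beta1_zero_reduces_to_homoscedastic_density(self):
        params, items, data, _ = _one_pair_setup(beta1=0.0)
        hom = tx.GeneticParams(
            model="AE", interaction=False, sigma2_a=0.3, beta0=float(np.log(0.2))
        )
        state = ModelState(
            params=params, items=items,
            A=np.array([0.4, 0.4]), C=np.zeros(2), D=np.zeros(2),
            theta=np.array([0.1, -0.6]),
        )
        spec_on = tx.ModelSpec(flavour="AE", interaction=True)
        spec_off = tx.ModelSpec(flavour="AE", interaction=False)
        with_inter = joint_log_density(state, data, spec_on)
        state.params = hom
        without = joint_log_density(state, data, spec_off)
        # only the beta1 prior term differs when beta1 = 0
        diff = norm.logpdf(0.0, scale=spec_on.priors.beta1_scale)
        np.testing.assert_allclose(with_inter - without, diff, rtol=1e-10)

    def test_marginalised_missing_entry_drops_exactly_its_term(self):
        params, items, _, spec = _one_pair_setup()
        full = tx.ItemResponseTable(
            family_id=np.array([0]), zygosity=np.array(["MZ"], dtype=object),
            responses=np.array([[1], [0]]), n_categories=(2,),
        )
        holed = tx.ItemResponseTable(
            family_id=np.array([0]), zygosity=np.array(["MZ"], dtype=object),
            responses=np.array([[1], [-1]]), n_categories=(2,),
        )
        state = ModelState(
            params=params, items=items,
            A=np.array([0.2, 0.2]), C=np.zeros(2), D=np.zeros(2),
            theta=np.array([0.5, -0.3]),
        )
        term = np.log(
            1.0 - expit(items.alphas[0] * (-0.3 - items.thresholds[0][1]))
        )
        np.testing.assert_allclose(
            joint_log_density(state, full, spec)
            - joint_log_density(state, holed, spec),
            term,
            rtol=1e-10,
        )
        # imputing the same value restores the full-data density
        state.imputed = np.array([[1], [0]])
        np.testing.assert_allclose(
            joint_log_density(state, holed, spec),
            joint_log_density(state, full, spec),
            rtol=1e-12,
        )

    def test_invalid_category_and_dimension_mismatch(self):
        params, items, data, spec = _one_pair_setup()
        state = ModelState(
            params=params, items=items,
            A=np.zeros(4), C=np.zeros(4), D=np.zeros(4), theta=np.zeros(4),
        )
        with pytest.raises(ValueError):
            joint_log_density(state, data, spec)


def test_log_prior_matches_scipy_assembly():
    params, items, _, spec = _one_pair_setup()
    pr = spec.priors
    want = (
        halfnorm.logpdf(np.sqrt(params.sigma2_a), scale=pr.sigma_a_scale)
        + norm.logpdf(params.beta0, scale=pr.beta0_scale)
        + norm.logpdf(params.beta1, scale=pr.beta1_scale)
        + norm.logpdf(items.thresholds[0][1], scale=pr.threshold_scale)
    )
    # alpha_1 is the anchor: no prior term for it
    np.testing.assert_allclose(log_prior(params, items, spec), want, rtol=1e-12)
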