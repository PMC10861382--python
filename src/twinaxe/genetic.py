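"""The joint probability model: biometric decomposition x GPCM measurement.

Variance decomposition of the latent trait theta = A + C + D + E, with the
unique-environmental variance log-linear in the genetic value (AxE/GxE):

    Var(E_j | g_j) = exp(beta0 + beta1 * g_j),   g_j = A_j (+ D_j under ADE)

Derived quantities follow the plug-in conventions used for reporting:
narrow-sense heritability h2 = sigma2_A / total phenotypic variance with the
E component evaluated at g = 0 (i.e. exp(beta0)), and the interaction effect
size exp(beta1 * sqrt(sigma2_A)) — the factor by which the environmental
variance grows for an individual one genetic SD above the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import halfnorm, lognorm, multivariate_normal, norm

from .gpcm import item_log_probs
from .types import (
    MISSING,
    GeneticParams,
    ItemBank,
    ItemResponseTable,
    ModelSpec,
    PriorSpec,
)

__all__ = [
    "env_variance",
    "heritability",
    "interaction_effect_size",
    "total_phenotypic_variance",
    "ModelState",
    "measurement_log_lik",
    "latent_log_density",
    "log_prior",
    "joint_log_density",
]


def env_variance(beta0: float, beta1: float, g):
    """Unique-environmental variance exp(beta0 + beta1 * g); always positive."""
    return np.exp(beta0 + beta1 * np.asarray(g, dtype=float))


def total_phenotypic_variance(params: GeneticParams) -> float:
    """Sum of the model's variance components, E evaluated at g = 0."""
    return (
        params.sigma2_a
        + params.sigma2_c
        + params.sigma2_d
        + float(np.exp(params.beta0))
    )


def heritability(params: GeneticParams) -> float:
    """Narrow-sense h2 = sigma2_A / total phenotypic variance, in [0, 1]."""
    total = total_phenotypic_variance(params)
    if total <= 0:
        raise ValueError("total phenotypic variance is zero")
    return params.sigma2_a / total


def interaction_effect_size(beta1: float, sigma2_a: float) -> float:
    """exp(beta1 * sqrt(sigma2_A)): E-variance fold-change at A = sigma_A."""
    if sigma2_a < 0:
        raise ValueError("sigma2_a must be non-negative")
    return float(np.exp(beta1 * np.sqrt(sigma2_a)))


# --------------------------------------------------------------------------
# Joint density


@dataclass
class ModelState:
    """One configuration of every sampled quantity.

    ``imputed`` optionally holds category values for the missing entries of
    the data table (same shape as the responses, ignored where observed);
    when absent, missing entries are marginalised (contribute nothing).
    """

    params: GeneticParams
    items: ItemBank
    A: np.ndarray
    C: np.ndarray
    D: np.ndarray
    theta: np.ndarray
    imputed: Optional[np.ndarray] = None


def measurement_log_lik(
    responses: np.ndarray, items: ItemBank, theta: np.ndarray
) -> float:
    """Sum of GPCM log-probabilities of the non-missing responses."""
    total = 0.0
    for i in range(items.n_items):
        y = responses[:, i]
        obs = y != MISSING
        if not obs.any():
            continue
        lp = item_log_probs(
            items.model_kind, theta[obs], items.alphas[i], items.thresholds[i]
        )
        total += float(lp[np.arange(obs.sum()), y[obs]].sum())
    return total


def latent_log_density(state: ModelState, zygosity: np.ndarray) -> float:
    """Log density of the latent components under the family structure.

    MZ pairs share one A (and D) draw, so their genetic values enter as a
    single normal density; DZ pairs enter as bivariate normals with
    correlation 0.5 (A) and 0.25 (D). E = theta - A - C - D is independent
    normal with the heteroscedastic AxE variance.
    """
    p = state.params
    is_mz = np.repeat(zygosity == "MZ", 2)
    t1 = np.arange(0, state.A.size, 2)  # first twin of each family
    total = 0.0

    def family_gauss(values: np.ndarray, var: float, corr: float) -> float:
        if var == 0.0:
            if np.any(values != 0.0):
                return -np.inf
            return 0.0
        v1, v2 = values[t1], values[t1 + 1]
        mz = is_mz[t1]
        out = 0.0
        if mz.any():
            if not np.allclose(v1[mz], v2[mz]):
                raise ValueError("MZ co-twins must share genetic values")
            out += float(norm.logpdf(v1[mz], scale=np.sqrt(var)).sum())
        if (~mz).any():
            cov = var * np.array([[1.0, corr], [corr, 1.0]])
            pairs = np.column_stack([v1[~mz], v2[~mz]])
            out += float(multivariate_normal.logpdf(pairs, cov=cov).sum())
        return out

    total += family_gauss(state.A, p.sigma2_a, 0.5)
    if p.model == "ACE":
        if p.sigma2_c == 0.0:
            if np.any(state.C != 0.0):
                return -np.inf
        else:
            if not np.allclose(state.C[t1], state.C[t1 + 1]):
                raise ValueError("C must be shared within families")
            total += float(
                norm.logpdf(state.C[t1], scale=np.sqrt(p.sigma2_c)).sum()
            )
    if p.model == "ADE":
        total += family_gauss(state.D, p.sigma2_d, 0.25)

    g = state.A + state.D
    e = state.theta - state.A - state.C - state.D
    var_e = env_variance(p.beta0, p.beta1, g)
    total += float(norm.logpdf(e, scale=np.sqrt(var_e)).sum())
    return total


def log_prior(params: GeneticParams, items: ItemBank, spec: ModelSpec) -> float:
    """Log prior density in the natural parametrisation (SDs, alphas)."""
    pr: PriorSpec = spec.priors
    total = float(halfnorm.logpdf(np.sqrt(params.sigma2_a), scale=pr.sigma_a_scale))
    if spec.flavour == "ACE":
        total += float(
            halfnorm.logpdf(np.sqrt(params.sigma2_c), scale=pr.sigma_c_scale)
        )
    if spec.flavour == "ADE":
        total += float(
            halfnorm.logpdf(np.sqrt(params.sigma2_d), scale=pr.sigma_d_scale)
        )
    total += float(norm.logpdf(params.beta0, scale=pr.beta0_scale))
    if spec.interaction:
        total += float(norm.logpdf(params.beta1, scale=pr.beta1_scale))
    for i in range(items.n_items):
        if not (spec.anchor == "alpha1" and i == 0):
            total += float(
                lognorm.logpdf(items.alphas[i], s=pr.log_alpha_scale)
            )
        total += float(
            norm.logpdf(items.thresholds[i][1:], scale=pr.threshold_scale).sum()
        )
    return total


def joint_log_density(
    state: ModelState, data: ItemResponseTable, spec: ModelSpec
) -> float:
    """Log joint density of data, latents, item and hyperparameters.

    Measurement terms cover the observed responses, plus the imputed values'
    terms when ``state.imputed`` is set; marginalised missing entries
    contribute nothing.
    """
    if state.theta.size != data.n_individuals:
        raise ValueError("state dimensions do not match the data")
    if state.params.model != spec.flavour or (
        state.params.beta1 != 0.0 and not spec.interaction
    ):
        raise ValueError("state parameters inconsistent with the model spec")
    responses = data.responses
    if state.imputed is not None:
        responses = np.where(data.missing_mask, state.imputed, responses)
    return (
        measurement_log_lik(responses, state.items, state.theta)
        + latent_log_density(state, data.zygosity)
        + log_prior(state.params, state.items, spec)
    )
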