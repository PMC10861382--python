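"""Result surfaces: posterior summary tables, AxE credibility curves, and
DIC model-comparison tables.

Summary tables report, per hyperparameter, the posterior mean, SD and 95%
HPD interval, plus derived rows: exp(beta0) (the E-variance at g = 0),
plug-in narrow-sense heritability, total phenotypic variance, and the
interaction effect size exp(beta1 * sqrt(sigma2_A)). Derived point values
use plug-in posterior means; h2 is additionally reported as the posterior
mean of the per-draw ratio. A parameter is flagged significant when its HPD
excludes zero — except variance components, which are bounded at zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diagnostics import hpd_interval
from .genetic import (
    env_variance,
    heritability,
    interaction_effect_size,
    total_phenotypic_variance,
)
from .sampler import PosteriorFit
from .types import ModelSpec

__all__ = [
    "summarize",
    "credibility_curve",
    "model_selection_table",
    "compare_genetic_models",
]

_VARIANCE_PARAMS = {"sigma2_a", "sigma2_c", "sigma2_d", "exp_beta0"}


def _row(name, draws, prob=0.95):
    lo, hi = hpd_interval(draws, prob)
    significant = not (lo <= 0.0 <= hi)
    if name in _VARIANCE_PARAMS:
        significant = np.nan  # bounded at zero; the HPD test does not apply
    return {
        "parameter": name,
        "mean": float(np.mean(draws)),
        "sd": float(np.std(draws, ddof=1)),
        "hpd_lo": lo,
        "hpd_hi": hi,
        "significant": significant,
    }


def summarize(fit: PosteriorFit, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Posterior summary table with derived biometric quantities.

    Pure: the same fit always yields an identical table. The DIC is attached
    as ``table.attrs['dic']`` (omitted with a warning if the fit carries no
    deviance trace).
    """
    spec = spec or fit.spec
    rows = [_row(name, fit.draws_flat(name)) for name in fit.param_names]
    if "beta0" in fit.draws:
        rows.append(_row("exp_beta0", np.exp(fit.draws_flat("beta0"))))

    mean_params = fit.posterior_mean_params()
    h2_plug = heritability(mean_params)
    rows.append(
        {
            "parameter": "h2 (plug-in)",
            "mean": h2_plug,
            "sd": np.nan,
            "hpd_lo": np.nan,
            "hpd_hi": np.nan,
            "significant": np.nan,
        }
    )
    # posterior-mean-of-ratio h2, with its own HPD
    var_draws = np.exp(fit.draws_flat("beta0"))
    total = fit.draws_flat("sigma2_a") + var_draws
    if "sigma2_c" in fit.draws:
        total = total + fit.draws_flat("sigma2_c")
    if "sigma2_d" in fit.draws:
        total = total + fit.draws_flat("sigma2_d")
    h2_draws = fit.draws_flat("sigma2_a") / total
    rows.append(_row("h2 (posterior mean)", h2_draws))
    rows[-1]["significant"] = np.nan

    rows.append(
        {
            "parameter": "total phenotypic variance",
            "mean": total_phenotypic_variance(mean_params),
            "sd": np.nan,
            "hpd_lo": np.nan,
            "hpd_hi": np.nan,
            "significant": np.nan,
        }
    )
    if spec.interaction:
        rows.append(
            {
                "parameter": "AxE effect size",
                "mean": interaction_effect_size(
                    mean_params.beta1, mean_params.sigma2_a
                ),
                "sd": np.nan,
                "hpd_lo": np.nan,
                "hpd_hi": np.nan,
                "significant": np.nan,
            }
        )

    table = pd.DataFrame(rows)
    if fit.deviance is not None and fit.deviance.size:
        table.attrs["dic"] = dict(fit.dic)
    else:
        warnings.warn("fit has no deviance trace; DIC omitted", stacklevel=2)
    table.attrs["converged"] = fit.converged
    table.attrs["psrf"] = dict(fit.psrf)
    return table


def credibility_curve(
    fit: PosteriorFit,
    g_grid=None,
    prob: float = 0.95,
) -> pd.DataFrame:
    """Pointwise posterior band of the E-variance curve exp(beta0 + beta1 g).

    The default grid is the sorted posterior means of the individual genetic
    values (the estimated range of g in the cohort). Bands are equal-tailed
    quantiles (median and (1 +/- prob)/2).
    """
    if g_grid is None:
        g_grid = np.sort(fit.g_mean)
    grid = np.asarray(g_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty genetic-value grid")
    b0 = fit.draws_flat("beta0")
    b1 = fit.draws_flat("beta1") if "beta1" in fit.draws else np.zeros_like(b0)
    curves = env_variance(b0[:, None], b1[:, None], grid[None, :])
    lo_q, hi_q = (1.0 - prob) / 2.0, (1.0 + prob) / 2.0
    return pd.DataFrame(
        {
            "g": grid,
            "median": np.quantile(curves, 0.5, axis=0),
            "lo": np.quantile(curves, lo_q, axis=0),
            "hi": np.quantile(curves, hi_q, axis=0),
        }
    )


def model_selection_table(fits: list, focus: str = "marginal") -> pd.DataFrame:
    """Ranked DIC table; the lowest-DIC model is flagged preferred.

    All fits must be of the same dataset. By default the ranking uses each
    fit's hyperparameter-focused DIC (latents integrated out), which is the
    reliable criterion for nested genetic models; it falls back to (or with
    ``focus='conditional'`` always uses) the conditional-deviance DIC, which
    is also reported as its own column. Ties flag every tied model, in
    deterministic model-name order.
    """
    if not fits:
        raise ValueError("need at least one fit")
    if focus not in ("marginal", "conditional"):
        raise ValueError(f"unknown DIC focus {focus!r}")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different datasets")
    rows = []
    for f in fits:
        use_marg = focus == "marginal" and f.dic_marginal is not None
        ranked = f.dic_marginal if use_marg else f.dic
        rows.append(
            {
                "model": f.spec.label,
                "DIC": ranked["DIC"],
                "pD": ranked["pD"],
                "conditional_DIC": f.dic["DIC"],
                "focus": "marginal" if use_marg else "conditional",
                "converged": f.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("model", kind="stable")
    best = table["DIC"].min()
    table["preferred"] = table["DIC"] == best
    return table.sort_values(["DIC", "model"], kind="stable").reset_index(
        drop=True
    )


def compare_genetic_models(
    data, fits: list, n_deviance_draws: int = 40
) -> pd.DataFrame:
    """DIC comparison of genetic models sharing one measurement layer.

    Re-evaluates every fit's hyperparameter-focused deviance against a
    *common* item bank (the element-wise average of the fits' posterior-mean
    banks). The models under comparison differ only in the genetic layer;
    plugging each fit's own bank into its deviance adds independent
    measurement noise of several deviance units, which would swamp the
    single-parameter complexity penalty that separates nested models. The
    common bank removes that noise from the comparison while leaving the
    genetic-layer evidence intact.
    """
    from .marginal import marginal_dic
    from .types import ItemBank

    if not fits:
        raise ValueError("need at least one fit")
    if len({f.data_hash for f in fits}) > 1:
        raise ValueError("fits were computed on different datasets")
    if any(f.item_bank_mean is None for f in fits):
        raise ValueError("every fit needs a posterior-mean item bank")
    banks = [f.item_bank_mean for f in fits]
    common = ItemBank(
        alphas=np.mean([b.alphas for b in banks], axis=0),
        thresholds=[
            np.mean([b.thresholds[i] for b in banks], axis=0)
            for i in range(banks[0].n_items)
        ],
    )
    rows = []
    for f in fits:
        dic = marginal_dic(data, common, f.spec, f.draws, n_deviance_draws)
        rows.append(
            {
                "model": f.spec.label,
                "DIC": dic["DIC"],
                "pD": dic["pD"],
                "conditional_DIC": f.dic["DIC"],
                "converged": f.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("model", kind="stable")
    table["preferred"] = table["DIC"] == table["DIC"].min()
    return table.sort_values(["DIC", "model"], kind="stable").reset_index(
        drop=True
    )
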