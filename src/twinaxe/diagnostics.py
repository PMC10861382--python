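"""Convergence and model-fit diagnostics for MCMC output.

PSRF is the classic Gelman-Rubin potential scale reduction factor computed
from between- and within-chain variances of equal-length chains. DIC follows
Spiegelhalter et al.'s construction: ``pD = Dbar - D(point estimate)`` and
``DIC = Dbar + pD``, with the deviance focused on all sampled quantities
(latent trait values and item parameters included) and the point estimate
taken at posterior means. The HPD interval is the empirical shortest window
containing the requested posterior mass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "dic_components", "hpd_interval"]


def gelman_rubin(chains: np.ndarray) -> float:
    """PSRF from an ``(n_chains, n_draws)`` array; needs >= 2 chains.

    ``sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain variance
    and B/n the variance of the chain means. Identical degenerate chains
    yield 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two equal-length chains")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains too short for a variance estimate")
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def dic_components(deviance_trace: np.ndarray, deviance_at_point: float) -> dict:
    """{Dbar, pD, DIC} from a deviance trace and the point-estimate deviance."""
    trace = np.asarray(deviance_trace, dtype=float).ravel()
    if trace.size == 0:
        raise ValueError("empty deviance trace")
    dbar = float(trace.mean())
    pd_ = dbar - float(deviance_at_point)
    return {"Dbar": dbar, "pD": pd_, "DIC": dbar + pd_}


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest empirical interval containing ``prob`` posterior mass.

    Sorts the draws and exhaustively minimises ``x[i + m - 1] - x[i]`` over
    windows of ``m = ceil(prob * n)`` draws.
    """
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie strictly between 0 and 1")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least two draws")
    m = int(np.ceil(prob * n))
    m = min(max(m, 1), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])
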