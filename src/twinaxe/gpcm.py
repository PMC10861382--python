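"""Polytomous IRT response-probability kernels (partial-credit family + GRM).

The generalized partial credit model (GPCM) gives category probabilities as a
softmax over cumulative step sums: for item *i* with discrimination alpha_i
and thresholds beta_i1 = 0, beta_i2, ..., beta_iK, the (0-based) category
``k`` has unnormalised log-weight

    sum_{h <= k} alpha_i * (theta - beta_ih) = alpha_i * (k * theta - B_ik)

with ``B_ik`` the cumulative threshold sum. The structural beta_i1 = 0 term
appears in every cumulative sum, so it drops out of the softmax; probabilities
depend only on the K - 1 free thresholds. PCM is the special case alpha = 1.

The graded response model (GRM) is cumulative-logit:
``P(Y >= k) = expit(alpha * (theta - c_k))`` with strictly increasing
cutpoints c_k.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_softmax, softmax

__all__ = [
    "gpcm_category_probs",
    "gpcm_log_probs",
    "grm_log_probs",
    "item_log_probs",
    "item_probs",
]

_TINY = 1e-300


def _gpcm_logits(theta: np.ndarray, alpha: float, thresholds: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    thr = np.asarray(thresholds, dtype=float)
    k = np.arange(thr.size, dtype=float)
    bcum = np.cumsum(thr)
    return alpha * (np.multiply.outer(theta, k) - bcum)


def gpcm_log_probs(theta, alpha: float, thresholds) -> np.ndarray:
    """Log category probabilities, shape ``theta.shape + (K,)``."""
    return log_softmax(_gpcm_logits(theta, alpha, thresholds), axis=-1)


def grm_log_probs(theta, alpha: float, thresholds) -> np.ndarray:
    """GRM log category probabilities; ``thresholds[1:]`` are the cutpoints."""
    theta = np.asarray(theta, dtype=float)
    cut = np.asarray(thresholds, dtype=float)[1:]
    if cut.size and np.any(np.diff(cut) <= 0):
        raise ValueError("GRM cutpoints must be strictly increasing")
    # P(Y >= k) for k = 1..K-1, padded with 1 (k=0) and 0 (k=K)
    upper = expit(alpha * (theta[..., None] - cut))
    shape = theta.shape + (1,)
    cdf = np.concatenate([np.ones(shape), upper, np.zeros(shape)], axis=-1)
    probs = cdf[..., :-1] - cdf[..., 1:]
    return np.log(np.clip(probs, _TINY, None))


def item_log_probs(model_kind: str, theta, alpha: float, thresholds) -> np.ndarray:
    if model_kind in ("PCM", "GPCM"):
        return gpcm_log_probs(theta, alpha, thresholds)
    if model_kind == "GRM":
        return grm_log_probs(theta, alpha, thresholds)
    raise ValueError(f"unknown IRT model kind {model_kind!r}")


def item_probs(model_kind: str, theta, alpha: float, thresholds) -> np.ndarray:
    return np.exp(item_log_probs(model_kind, theta, alpha, thresholds))


def gpcm_category_probs(theta: float, alpha: float, thresholds) -> np.ndarray:
    """GPCM probability vector over the item's K categories at one trait value.

    ``thresholds`` carries the structural leading zero (length K). Raises on
    non-finite ``theta`` or fewer than two categories.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    thr = np.asarray(thresholds, dtype=float)
    if thr.size < 2:
        raise ValueError("item needs at least 2 categories")
    return softmax(_gpcm_logits(np.float64(theta), alpha, thr), axis=-1)
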