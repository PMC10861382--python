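"""Stand-alone IRT stage: marginal maximum likelihood for PCM/GPCM/GRM.

Fits polytomous IRT models to one randomly selected twin per family (to
respect the independence assumption of marginal ML), integrating the latent
trait over a standard-normal density with fixed Gauss-Hermite quadrature and
maximising by EM: the E-step computes posterior node weights per respondent,
the M-step re-optimises each item against its expected category counts.
Missing responses simply drop out of the likelihood (full-information ML).

Model comparison is by AIC = -2 loglik + 2 p. PCM is nested in GPCM (unit
discriminations), so the GPCM log-likelihood can never fall below the PCM's
at the respective optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, roots_hermitenorm

from .gpcm import item_log_probs
from .types import MISSING, ItemBank, ItemResponseTable

__all__ = [
    "FittedIRT",
    "select_one_twin",
    "fit_irt",
    "item_information",
    "classical_stats",
]


@dataclass
class FittedIRT:
    item_bank: ItemBank
    log_lik: float
    n_parameters: int
    converged: bool
    n_em_iter: int
    collapsed: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_lik + 2.0 * self.n_parameters


def select_one_twin(table: ItemResponseTable, seed) -> np.ndarray:
    """One random twin per family -> (n_families, n_items) response matrix."""
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, 2, table.n_families)
    rows = 2 * np.arange(table.n_families) + pick
    return table.responses[rows].copy()


def _collapse_unobserved(responses: np.ndarray, n_categories) -> tuple[np.ndarray, list, dict]:
    """Merge never-observed categories into their lower neighbour.

    Returns remapped responses, the reduced per-item category counts, and a
    record of what was collapsed.
    """
    out = responses.copy()
    new_ks: list[int] = []
    record: dict[int, list[int]] = {}
    for i, k in enumerate(n_categories):
        y = out[:, i]
        seen = np.zeros(k, dtype=bool)
        seen[y[y != MISSING]] = True
        if seen.all():
            new_ks.append(k)
            continue
        mapping = np.cumsum(seen) - 1
        mapping = np.maximum(mapping, 0)
        obs = y != MISSING
        out[obs, i] = mapping[y[obs]]
        new_ks.append(int(seen.sum()))
        record[i] = np.where(~seen)[0].tolist()
    if any(k < 2 for k in new_ks):
        raise ValueError("an item has fewer than 2 observed categories")
    return out, new_ks, record


def _pack(kind: str, alpha: float, thr: np.ndarray) -> np.ndarray:
    free = thr[1:]
    if kind == "PCM":
        return free.copy()
    if kind == "GPCM":
        return np.concatenate([[np.log(alpha)], free])
    # GRM: first cutpoint + log-increments keeps the ordering strict
    inc = np.diff(free)
    return np.concatenate([[np.log(alpha)], [free[0]], np.log(inc)])


def _unpack(kind: str, x: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    if kind == "PCM":
        return 1.0, np.concatenate([[0.0], x])
    if kind == "GPCM":
        return float(np.exp(x[0])), np.concatenate([[0.0], x[1:]])
    cuts = x[1] + np.concatenate([[0.0], np.cumsum(np.exp(x[2:]))])
    return float(np.exp(x[0])), np.concatenate([[0.0], cuts])


def _init_item(kind: str, k: int) -> tuple[float, np.ndarray]:
    if kind == "GRM":
        return 1.0, np.concatenate([[0.0], np.linspace(-1.5, 1.5, k - 1)])
    return 1.0, np.concatenate([[0.0], np.zeros(k - 1)])


def fit_irt(
    responses: np.ndarray,
    n_categories,
    kind: str = "GPCM",
    n_quadrature: int = 61,
    max_iter: int = 200,
    tol: float = 1e-6,
    collapse_unobserved: bool = True,
) -> FittedIRT:
    """Marginal-ML fit of a polytomous IRT model.

    ``responses`` is a persons x items integer matrix (0-based categories,
    -1 missing); rows must be independent respondents (one twin per family).
    Never-observed categories are collapsed into their neighbour by default;
    non-convergence after ``max_iter`` EM sweeps is flagged, not raised.
    """
    if kind not in ("PCM", "GPCM", "GRM"):
        raise ValueError(f"unknown IRT model kind {kind!r}")
    responses = np.asarray(responses, dtype=np.int64)
    record: dict = {}
    ks = list(n_categories)
    if collapse_unobserved:
        responses, ks, record = _collapse_unobserved(responses, ks)
    else:
        for i, k in enumerate(ks):
            y = responses[:, i]
            if np.unique(y[y != MISSING]).size < k:
                raise ValueError(f"item {i} has unobserved categories")
    n_items = len(ks)

    nodes, wts = roots_hermitenorm(n_quadrature)
    log_w = np.log(wts) - 0.5 * np.log(2.0 * np.pi)  # standard-normal weights

    alphas = np.empty(n_items)
    thresholds: list[np.ndarray] = []
    for i in range(n_items):
        a, t = _init_item(kind, ks[i])
        alphas[i] = a
        thresholds.append(t)

    def _tables() -> list[np.ndarray]:
        return [
            item_log_probs(kind if kind != "PCM" else "GPCM", nodes, alphas[i], thresholds[i])
            for i in range(n_items)
        ]

    def _person_loglik(tables) -> np.ndarray:
        ll = np.tile(log_w, (responses.shape[0], 1))
        for i in range(n_items):
            y = responses[:, i]
            obs = y != MISSING
            ll[obs] += tables[i][:, y[obs]].T
        return ll

    log_lik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tables = _tables()
        ll_pq = _person_loglik(tables)
        person_ml = logsumexp(ll_pq, axis=1)
        new_log_lik = float(person_ml.sum())
        post = np.exp(ll_pq - person_ml[:, None])  # E-step weights

        if new_log_lik - log_lik < tol and it > 1:
            log_lik = new_log_lik
            converged = True
            break
        log_lik = new_log_lik

        for i in range(n_items):
            y = responses[:, i]
            obs = y != MISSING
            counts = np.zeros((n_quadrature, ks[i]))
            for k in range(ks[i]):
                sel = obs & (y == k)
                if sel.any():
                    counts[:, k] = post[sel].sum(axis=0)

            def neg_expected(x, i=i, counts=counts):
                a, t = _unpack(kind, x, ks[i])
                lp = item_log_probs(
                    kind if kind != "PCM" else "GPCM", nodes, a, t
                )
                return -float((counts * lp).sum())

            x0 = _pack(kind, alphas[i], thresholds[i])
            res = minimize(neg_expected, x0, method="L-BFGS-B")
            if res.fun <= neg_expected(x0):
                alphas[i], thresholds[i] = _unpack(kind, res.x, ks[i])

    bank = ItemBank(
        alphas=alphas,
        thresholds=thresholds,
        model_kind=kind,
    )
    n_free_thr = sum(k - 1 for k in ks)
    n_params = n_free_thr if kind == "PCM" else n_free_thr + n_items
    return FittedIRT(
        item_bank=bank,
        log_lik=log_lik,
        n_parameters=n_params,
        converged=converged,
        n_em_iter=it,
        collapsed=record,
    )


def marginal_log_lik(
    responses: np.ndarray, bank: ItemBank, n_quadrature: int = 61
) -> float:
    """Brute-force marginal likelihood at fixed parameters (oracle hook)."""
    nodes, wts = roots_hermitenorm(n_quadrature)
    log_w = np.log(wts) - 0.5 * np.log(2.0 * np.pi)
    responses = np.asarray(responses, dtype=np.int64)
    ll = np.tile(log_w, (responses.shape[0], 1))
    kind = "GPCM" if bank.model_kind == "PCM" else bank.model_kind
    for i in range(bank.n_items):
        y = responses[:, i]
        obs = y != MISSING
        tab = item_log_probs(kind, nodes, bank.alphas[i], bank.thresholds[i])
        ll[obs] += tab[:, y[obs]].T
    return float(logsumexp(ll, axis=1).sum())


def item_information(bank: ItemBank, theta_grid) -> dict:
    """Fisher information per item on a trait grid, plus the test total.

    For the partial-credit family this is alpha^2 * Var(category | theta);
    generally it is sum_k P'_k(theta)^2 / P_k(theta). Returns
    ``{"theta", "items" (n_items x grid), "total"}``.
    """
    grid = np.asarray(theta_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty theta grid")
    kind = "GPCM" if bank.model_kind == "PCM" else bank.model_kind
    curves = np.empty((bank.n_items, grid.size))
    for i in range(bank.n_items):
        p = np.exp(item_log_probs(kind, grid, bank.alphas[i], bank.thresholds[i]))
        a = bank.alphas[i]
        if kind == "GPCM":
            k = np.arange(p.shape[-1])
            mean_k = (p * k).sum(axis=-1)
            var_k = (p * k**2).sum(axis=-1) - mean_k**2
            curves[i] = a**2 * var_k
        else:  # GRM
            from scipy.special import expit

            cut = bank.thresholds[i][1:]
            f = expit(a * (grid[:, None] - cut))
            fprime = a * f * (1.0 - f)
            dp = np.concatenate(
                [np.zeros((grid.size, 1)), fprime], axis=1
            ) - np.concatenate([fprime, np.zeros((grid.size, 1))], axis=1)
            curves[i] = (dp**2 / np.clip(p, 1e-12, None)).sum(axis=-1)
    return {"theta": grid, "items": curves, "total": curves.sum(axis=0)}


def classical_stats(table: ItemResponseTable) -> dict:
    """Sum scores, Cronbach's alpha, item-rest and MZ/DZ sum-score correlations.

    Alpha and item-rest correlations use individuals with complete responses;
    sum scores are reported on the 1-based category scale (minimum = number
    of items). Twin-pair sum-score correlations use pairs in which both
    twins are complete. A zero-variance item yields an undefined (NaN)
    item-rest correlation with a warning.
    """
    n_items = table.n_items
    if n_items < 2:
        raise ValueError("need at least two items")
    complete = ~table.missing_mask.any(axis=1)
    resp = table.responses[complete].astype(float)
    if resp.shape[0] < 3:
        raise ValueError("too few complete responders")

    item_var = resp.var(axis=0, ddof=1)
    total = resp.sum(axis=1)
    alpha = (n_items / (n_items - 1)) * (1.0 - item_var.sum() / total.var(ddof=1))

    item_rest = np.full(n_items, np.nan)
    for i in range(n_items):
        rest = total - resp[:, i]
        if item_var[i] == 0.0 or rest.var(ddof=1) == 0.0:
            warnings.warn(
                f"item {i + 1} has zero variance; item-rest undefined",
                stacklevel=2,
            )
            continue
        item_rest[i] = np.corrcoef(resp[:, i], rest)[0, 1]

    sum_scores = np.full(table.n_individuals, np.nan)
    sum_scores[complete] = table.responses[complete].sum(axis=1) + n_items

    pair_complete = complete[0::2] & complete[1::2]
    s1, s2 = sum_scores[0::2], sum_scores[1::2]
    out_corr = {}
    for zyg in ("MZ", "DZ"):
        sel = pair_complete & (table.zygosity == zyg)
        if sel.sum() >= 3:
            out_corr[zyg] = float(np.corrcoef(s1[sel], s2[sel])[0, 1])
        else:
            out_corr[zyg] = np.nan

    return {
        "cronbach_alpha": float(alpha),
        "item_rest": item_rest,
        "sum_scores": sum_scores,
        "mz_sum_corr": out_corr["MZ"],
        "dz_sum_corr": out_corr["DZ"],
        "n_complete": int(complete.sum()),
    }
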