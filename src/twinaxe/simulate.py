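"""Synthetic twin cohorts with the structure the one-step analysis assumes.

The latent trait of individual *j* is theta_j = A_j + C_j + D_j + E_j:

* additive genetic values A are identical within MZ pairs; within DZ pairs
  they are built as ``sqrt(sigma2_A / 2) * (z_family + z_individual)``, which
  induces exactly the biometric DZ correlation of 0.5;
* dominance values D (ADE only) share a quarter of their variance within DZ
  pairs (correlation 0.25) and are identical within MZ pairs;
* the shared environment C is one draw per family (ACE only);
* the unique environment E is independent across individuals with
  heteroscedastic variance ``exp(beta0 + beta1 * g_j)`` where ``g_j`` is the
  additive genetic value (or A + D under ADE) — the AxE/GxE interaction.

Item responses follow the GPCM at theta_j; missingness is injected completely
at random according to a per-family pattern (fraction of families x number of
missing item scores), emulating a cohort in which ~95% of families are
complete and small fractions miss one, several, or one twin's full set of
scores.

All draws go through one ``numpy.random.Generator`` seeded by the caller, so
a cohort is bit-reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from .gpcm import item_log_probs
from .types import (
    MISSING,
    CohortDesign,
    GeneticParams,
    ItemBank,
    ItemResponseTable,
    LatentTwinSample,
)

__all__ = [
    "generate_latents",
    "generate_item_responses",
    "inject_missingness",
    "simulate_cohort",
    "default_item_bank",
    "hyperactivity_truth",
    "inattention_truth",
    "hyperactivity_design",
    "inattention_design",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_latents(
    params: GeneticParams, design: CohortDesign, seed
) -> LatentTwinSample:
    """Draw per-individual latent components for a cohort.

    MZ families come first, then DZ. Returns a sample whose ``theta`` is the
    exact sum of its components.
    """
    rng = _rng(seed)
    n_mz, n_dz = design.n_mz, design.n_dz
    n = 2 * (n_mz + n_dz)
    zygosity = np.array(["MZ"] * n_mz + ["DZ"] * n_dz, dtype=object)

    sd_a = np.sqrt(params.sigma2_a)
    a_mz = np.repeat(rng.normal(0.0, 1.0, n_mz), 2) * sd_a
    half = np.sqrt(params.sigma2_a / 2.0)
    a_dz = half * (
        np.repeat(rng.normal(0.0, 1.0, n_dz), 2) + rng.normal(0.0, 1.0, 2 * n_dz)
    )
    A = np.concatenate([a_mz, a_dz])

    C = np.zeros(n)
    if params.model == "ACE":
        C = np.repeat(rng.normal(0.0, np.sqrt(params.sigma2_c), n_mz + n_dz), 2)

    D = np.zeros(n)
    if params.model == "ADE":
        d_mz = np.repeat(rng.normal(0.0, 1.0, n_mz), 2) * np.sqrt(params.sigma2_d)
        # DZ dominance correlation 0.25: a quarter of the variance is shared
        d_dz = np.sqrt(params.sigma2_d) * (
            0.5 * np.repeat(rng.normal(0.0, 1.0, n_dz), 2)
            + np.sqrt(0.75) * rng.normal(0.0, 1.0, 2 * n_dz)
        )
        D = np.concatenate([d_mz, d_dz])

    g = A + D
    e_sd = np.exp(0.5 * (params.beta0 + params.beta1 * g))
    E = rng.normal(0.0, 1.0, n) * e_sd

    return LatentTwinSample(A=A, C=C, D=D, E=E, zygosity=zygosity, params=params)


def generate_item_responses(
    latents: LatentTwinSample, items: ItemBank, seed
) -> ItemResponseTable:
    """Sample ordinal responses from the item bank at each individual's theta."""
    rng = _rng(seed)
    theta = latents.theta
    n = theta.size
    resp = np.empty((n, items.n_items), dtype=np.int64)
    for i in range(items.n_items):
        probs = np.exp(
            item_log_probs(items.model_kind, theta, items.alphas[i], items.thresholds[i])
        )
        cum = np.cumsum(probs, axis=-1)
        u = rng.random(n)
        resp[:, i] = np.minimum(
            (u[:, None] > cum).sum(axis=-1), items.thresholds[i].size - 1
        )
    n_fam = n // 2
    return ItemResponseTable(
        family_id=np.arange(n_fam),
        zygosity=latents.zygosity,
        responses=resp,
        n_categories=items.n_categories,
    )


def _missingness_counts(spec, n_families: int) -> list[tuple[int, int]]:
    """(families, missing scores) per group, rounded to the nearest family."""
    counts = []
    for frac, m in spec:
        if m == 0:
            continue
        counts.append((int(round(frac * n_families)), m))
    if sum(c for c, _ in counts) > n_families:
        raise ValueError("missingness fractions exceed the cohort")
    return counts


def inject_missingness(
    table: ItemResponseTable, design: CohortDesign, seed
) -> ItemResponseTable:
    """Blank item scores completely at random following the design's pattern."""
    rng = _rng(seed)
    out = table.copy()
    counts = _missingness_counts(design.missingness_spec, table.n_families)
    n_slots = 2 * table.n_items
    for _, m in counts:
        if m > n_slots:
            raise ValueError(
                f"cannot blank {m} scores in a family with {n_slots} responses"
            )
    total = sum(c for c, _ in counts)
    chosen = rng.choice(table.n_families, size=total, replace=False)
    pos = 0
    for n_fam, m in counts:
        for f in chosen[pos : pos + n_fam]:
            slots = rng.choice(n_slots, size=m, replace=False)
            rows = 2 * f + slots // table.n_items
            cols = slots % table.n_items
            out.responses[rows, cols] = MISSING
        pos += n_fam
    return out


def simulate_cohort(
    params: GeneticParams, design: CohortDesign, items: ItemBank, seed
) -> tuple[ItemResponseTable, LatentTwinSample]:
    """Latents -> responses -> missingness, all from one seeded stream."""
    rng = _rng(seed)
    latents = generate_latents(params, design, rng)
    table = generate_item_responses(latents, items, rng)
    table = inject_missingness(table, design, rng)
    return table, latents


# --------------------------------------------------------------------------
# Study conditions: cohort sizes, generating values and a calibrated item
# bank on the reporting scale (geometric-mean discrimination 1, first
# threshold 0).

# discriminations near 1, normalised to geometric mean exactly 1 so that
# generating biometric values sit on the reporting scale (see sampler docs)
_RAW_ALPHAS = np.array([1.0, 0.9, 1.1, 0.8, 1.2, 0.95, 1.05, 0.85, 1.15])
_DEFAULT_ALPHAS = _RAW_ALPHAS / np.exp(np.mean(np.log(_RAW_ALPHAS)))


def default_item_bank(n_items: int = 9, n_categories: int = 7) -> ItemBank:
    """Nine 7-category items with discriminations near 1 and spread thresholds.

    Thresholds span roughly +/- 2 trait SDs of the cohorts simulated here,
    with a small item-specific shift so items differ in difficulty.
    """
    alphas = np.resize(_DEFAULT_ALPHAS, n_items)
    thresholds = []
    for i in range(n_items):
        shift = 0.1 * (i - (n_items - 1) / 2)
        free = np.linspace(-1.5, 1.5, n_categories - 1) + shift
        thresholds.append(np.concatenate([[0.0], free]))
    return ItemBank(alphas=alphas, thresholds=thresholds, model_kind="GPCM")


def hyperactivity_truth() -> GeneticParams:
    """AE with AxE at the hyperactivity posterior means (sigma2_A = 0.25,
    exp(beta0) = 0.19, beta1 = 2.20)."""
    return GeneticParams(
        model="AE", interaction=True, sigma2_a=0.25, beta0=float(np.log(0.19)),
        beta1=2.20,
    )


def inattention_truth() -> GeneticParams:
    """ACE with AxE at the inattention posterior means (sigma2_A = 0.27,
    sigma2_C = 0.31, exp(beta0) = 0.51, beta1 = 2.16)."""
    return GeneticParams(
        model="ACE", interaction=True, sigma2_a=0.27, sigma2_c=0.31,
        beta0=float(np.log(0.51)), beta1=2.16,
    )


def hyperactivity_design(n_mz: int = 415, n_dz: int = 669) -> CohortDesign:
    """Cohort shape of the hyperactivity analysis sample: 415 MZ + 669 DZ
    pairs, 9 seven-category items, ~95% complete families, 2% missing one
    score, 1% missing several, 2% missing one twin's full set."""
    return CohortDesign(
        n_mz=n_mz,
        n_dz=n_dz,
        n_categories=(7,) * 9,
        missingness_spec=((0.95, 0), (0.02, 1), (0.01, 5), (0.02, 9)),
    )


def inattention_design(n_mz: int = 415, n_dz: int = 669) -> CohortDesign:
    return CohortDesign(
        n_mz=n_mz,
        n_dz=n_dz,
        n_categories=(7,) * 9,
        missingness_spec=((0.94, 0), (0.03, 1), (0.01, 4), (0.02, 9)),
    )
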