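"""Core containers for twin item-response data and biometric model parameters.

The observable unit is a twin *family*: a zygosity label (MZ/DZ) and two
individuals, each answering the same ordinal questionnaire items. Individuals
are stored in family-major order (family 0 twin 1, family 0 twin 2, family 1
twin 1, ...), so individual ``j`` belongs to family ``j // 2`` and is twin
``j % 2 + 1``. Missing item responses are coded ``-1``.

Categories are stored 0-based internally (``0 .. K_i - 1``); the CSV dialect
and user-facing tables are 1-based (SWAN codes 1-7).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "CohortDesign",
    "GeneticParams",
    "PriorSpec",
    "ModelSpec",
    "ItemBank",
    "ItemResponseTable",
    "LatentTwinSample",
    "MCMCSettings",
]


@dataclass(frozen=True)
class CohortDesign:
    """Shape of a simulated twin cohort.

    ``missingness_spec`` is a sequence of ``(fraction_of_families,
    n_missing_item_scores)`` pairs; fractions must sum to at most 1, the
    remainder of families stays complete.
    """

    n_mz: int
    n_dz: int
    n_categories: tuple[int, ...] = (7,) * 9
    missingness_spec: tuple[tuple[float, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        if any(k < 2 for k in self.n_categories):
            raise ValueError("every item needs at least 2 categories")
        total = sum(f for f, _ in self.missingness_spec)
        if total > 1.0 + 1e-12:
            raise ValueError("missingness fractions sum to more than 1")
        if any(f < 0 for f, _ in self.missingness_spec):
            raise ValueError("missingness fractions must be non-negative")
        if any(m < 0 or m > 2 * self.n_items for _, m in self.missingness_spec):
            raise ValueError(
                "per-family missing count must lie in [0, 2 * n_items]"
            )

    @property
    def n_items(self) -> int:
        return len(self.n_categories)

    @property
    def n_families(self) -> int:
        return self.n_mz + self.n_dz


@dataclass(frozen=True)
class GeneticParams:
    """Biometric hyperparameters of the variance decomposition.

    The unique-environmental variance is log-linear in the genetic value:
    ``Var(E_j | A_j) = exp(beta0 + beta1 * A_j)`` (with ``G_j = A_j + D_j``
    taking the place of ``A_j`` under ADE). ``interaction=False`` forces
    ``beta1 = 0`` (homoscedastic E).
    """

    model: str = "AE"
    interaction: bool = False
    sigma2_a: float = 0.0
    sigma2_c: float = 0.0
    sigma2_d: float = 0.0
    beta0: float = 0.0
    beta1: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("AE", "ACE", "ADE"):
            raise ValueError(f"unknown model flavour {self.model!r}")
        for name in ("sigma2_a", "sigma2_c", "sigma2_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.model in ("AE", "ADE") and self.sigma2_c > 0:
            raise ValueError(f"{self.model} model excludes a C component")
        if self.model != "ADE" and self.sigma2_d > 0:
            raise ValueError("dominance variance requires the ADE model")
        if not self.interaction and self.beta1 != 0.0:
            raise ValueError("beta1 must be 0 when interaction is off")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative default priors for the one-step model.

    Scales are standard deviations: half-normal on the latent component SDs
    sigma_A/C/D, normal on beta0/beta1 and on free thresholds, lognormal on
    item discriminations.
    """

    sigma_a_scale: float = 2.0
    sigma_c_scale: float = 2.0
    sigma_d_scale: float = 2.0
    beta0_scale: float = 10.0
    beta1_scale: float = 10.0
    log_alpha_scale: float = 1.0
    threshold_scale: float = 10.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"prior scale {name} must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Which biometric flavour to fit, and how the joint model is identified.

    Location is identified by mu = 0 and a structural first threshold of 0
    for every item; scale by anchoring the first item's discrimination at 1
    (``anchor='alpha1'``).
    """

    flavour: str = "AE"
    interaction: bool = False
    priors: PriorSpec = field(default_factory=PriorSpec)
    anchor: str = "alpha1"

    def __post_init__(self) -> None:
        if self.flavour not in ("AE", "ACE", "ADE"):
            raise ValueError(f"unknown model flavour {self.flavour!r}")
        if self.anchor not in ("alpha1",):
            raise ValueError(f"unknown anchor convention {self.anchor!r}")

    @property
    def label(self) -> str:
        return self.flavour + (" with AxE" if self.interaction else "")

    def hyperparameter_names(self) -> list[str]:
        names = ["sigma2_a"]
        if self.flavour == "ACE":
            names.append("sigma2_c")
        if self.flavour == "ADE":
            names.append("sigma2_d")
        names.append("beta0")
        if self.interaction:
            names.append("beta1")
        return names


@dataclass
class ItemBank:
    """GPCM/PCM/GRM item parameters.

    ``thresholds[i]`` has length ``K_i`` with a structural leading zero (the
    identification constraint beta_i1 = 0 for the partial-credit family; for
    GRM the remaining ``K_i - 1`` entries are the strictly increasing
    cumulative-logit cutpoints and the leading zero is a placeholder).
    """

    alphas: np.ndarray
    thresholds: list[np.ndarray]
    model_kind: str = "GPCM"

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        if len(self.thresholds) != self.alphas.size:
            raise ValueError("alphas and thresholds disagree on item count")
        if self.model_kind not in ("PCM", "GPCM", "GRM"):
            raise ValueError(f"unknown IRT model kind {self.model_kind!r}")
        for t in self.thresholds:
            if t.size < 2:
                raise ValueError("every item needs at least 2 categories")
            if t[0] != 0.0:
                raise ValueError("first threshold is structural and must be 0")
            if self.model_kind == "GRM" and np.any(np.diff(t[1:]) <= 0):
                raise ValueError("GRM cutpoints must be strictly increasing")

    @property
    def n_items(self) -> int:
        return int(self.alphas.size)

    @property
    def n_categories(self) -> tuple[int, ...]:
        return tuple(int(t.size) for t in self.thresholds)


@dataclass
class ItemResponseTable:
    """Family-structured ordinal responses with zygosity and missingness.

    ``responses`` is ``(2 * n_families, n_items)`` int, 0-based categories,
    ``MISSING`` (= -1) for unobserved entries.
    """

    family_id: np.ndarray
    zygosity: np.ndarray
    responses: np.ndarray
    n_categories: tuple[int, ...]

    def __post_init__(self) -> None:
        self.family_id = np.asarray(self.family_id)
        self.zygosity = np.asarray(self.zygosity, dtype=object)
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if self.responses.shape != (2 * self.family_id.size, len(self.n_categories)):
            raise ValueError("responses shape inconsistent with families/items")
        if not set(np.unique(self.zygosity)) <= {"MZ", "DZ"}:
            raise ValueError("zygosity must be 'MZ' or 'DZ'")
        ks = np.asarray(self.n_categories)
        bad = (self.responses >= ks[None, :]) | (
            (self.responses < 0) & (self.responses != MISSING)
        )
        if bad.any():
            raise ValueError("response category out of range")

    @property
    def n_families(self) -> int:
        return int(self.family_id.size)

    @property
    def n_individuals(self) -> int:
        return 2 * self.n_families

    @property
    def n_items(self) -> int:
        return len(self.n_categories)

    @property
    def is_mz_family(self) -> np.ndarray:
        return self.zygosity == "MZ"

    @property
    def missing_mask(self) -> np.ndarray:
        return self.responses == MISSING

    def copy(self) -> "ItemResponseTable":
        return ItemResponseTable(
            family_id=self.family_id.copy(),
            zygosity=self.zygosity.copy(),
            responses=self.responses.copy(),
            n_categories=self.n_categories,
        )

    def data_hash(self) -> str:
        """Content fingerprint, used to refuse cross-dataset DIC comparisons."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.responses).tobytes())
        h.update("".join(map(str, self.family_id)).encode())
        h.update("".join(self.zygosity).encode())
        h.update(str(self.n_categories).encode())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame, 1-based categories, NaN for missing."""
        n_f, n_i = self.n_families, self.n_items
        resp = self.responses.astype(float)
        resp[resp == MISSING] = np.nan
        df = pd.DataFrame(
            {
                "family_id": np.repeat(self.family_id, 2),
                "zygosity": np.repeat(self.zygosity, 2),
                "twin": np.tile([1, 2], n_f),
            }
        )
        for i in range(n_i):
            df[f"item_{i + 1}"] = resp[:, i] + 1.0
        return df


@dataclass
class LatentTwinSample:
    """Per-individual latent components; ``theta = A + C + D + E`` exactly."""

    A: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    zygosity: np.ndarray
    params: GeneticParams

    @property
    def theta(self) -> np.ndarray:
        return self.A + self.C + self.D + self.E

    @property
    def genetic_value(self) -> np.ndarray:
        """A + D: the value the E-variance conditions on under ADE."""
        return self.A + self.D

    @property
    def n_individuals(self) -> int:
        return int(self.A.size)


@dataclass(frozen=True)
class MCMCSettings:
    """Chain schedule. Defaults: 2 chains, 5,000 burn-in, 10,000 retained."""

    n_chains: int = 2
    burn_in: int = 5000
    n_iter: int = 10000
    thin: int = 1
    psrf_threshold: float = 1.1
    max_init_retries: int = 5

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.burn_in < 0 or self.n_iter <= 0 or self.thin < 1:
            raise ValueError("invalid chain schedule")
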