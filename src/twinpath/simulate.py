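"""Synthetic twin/sibling cohort generation.

Builds seeded cohorts with the family structure the downstream pipeline
assumes: monozygotic (MZ) and dizygotic (DZ) twin pairs, non-twin
full-sibling pairs, and singletons.  Two focal outcome columns carry a
user-specified bivariate A/C/Tw/E (additive genetic, shared environment,
twin-specific shared environment, non-shared environment) structure via a
lower-triangular Cholesky loading parameterization; extra outcome columns
are equicorrelated Gaussians for multiplicity testing.

Latent factors are unit-variance Gaussian, so loadings live on the raw trait
scale and the implied covariance algebra is exact.  Genetic factors
correlate 1.0 across MZ co-twins and 0.5 across DZ co-twins and full
siblings; shared-environment factors are identical within a family;
twin-specific factors are identical within MZ/DZ pairs and independent for
everyone else (they still contribute within-person variance, keeping total
variance equal across pair types); non-shared factors are always
independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PAIR_TYPES = ("MZ", "DZ", "NotTwin")

#: genetic correlation across siblings, by pair type
GENETIC_SHARING = {"MZ": 1.0, "DZ": 0.5, "NotTwin": 0.5}
#: twin-specific shared-environment correlation across siblings
TWIN_ENV_SHARING = {"MZ": 1.0, "DZ": 1.0, "NotTwin": 0.0}

_SOURCES = ("a", "c", "t", "e")


@dataclass(frozen=True)
class CholeskyParams:
    """Lower-triangular bivariate loadings for the A, C, Tw and E sources.

    ``x11`` loads trait 1 on the source's first factor, ``x21``/``x22`` load
    trait 2 on the first/second factor.  Diagonals must be non-negative
    (sign identification); the non-shared diagonals must be positive so the
    residual covariance is non-degenerate.
    """

    a11: float = 0.0
    a21: float = 0.0
    a22: float = 0.0
    c11: float = 0.0
    c21: float = 0.0
    c22: float = 0.0
    t11: float = 0.0
    t21: float = 0.0
    t22: float = 0.0
    e11: float = 1.0
    e21: float = 0.0
    e22: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a11", "a22", "c11", "c22", "t11", "t22", "e11", "e22"):
            if getattr(self, name) < 0:
                raise ValueError(f"diagonal loading {name} must be >= 0")
        if self.e11 <= 0 or self.e22 <= 0:
            raise ValueError("e11 and e22 must be > 0 (nondegenerate residual variance)")

    def lam(self, source: str) -> np.ndarray:
        """2x2 lower-triangular loading matrix for one source ('a','c','t','e')."""
        if source not in _SOURCES:
            raise ValueError(f"unknown source {source!r}")
        g = lambda suffix: getattr(self, f"{source}{suffix}")
        return np.array([[g("11"), 0.0], [g("21"), g("22")]])

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort draw."""

    n_mz_pairs: int = 134
    n_dz_pairs: int = 72
    n_sib_pairs: int = 290
    n_singletons: int = 0
    loadings: CholeskyParams = field(default_factory=CholeskyParams)
    covariate_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_extra_outcomes: int = 0
    extra_outcome_rho: float = 0.0
    age_range: tuple[float, float] = (22.0, 36.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_sib_pairs", "n_singletons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.extra_outcome_rho < 1.0:
            raise ValueError("extra_outcome_rho must be in [0, 1)")
        if self.n_extra_outcomes < 0:
            raise ValueError("n_extra_outcomes must be >= 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (lo, hi) with lo < hi")


def compute_bmi(weight_lbs, height_in):
    """Body mass index from imperial units: ``703 * weight / height**2``.

    The 703 factor is the standard CDC conversion from lb/in^2 to kg/m^2.
    Inputs may be scalars or arrays; all values must be positive.
    """
    weight_lbs = np.asarray(weight_lbs, dtype=float)
    height_in = np.asarray(height_in, dtype=float)
    if np.any(weight_lbs <= 0) or np.any(height_in <= 0):
        raise ValueError("weight and height must be positive")
    out = 703.0 * weight_lbs / height_in**2
    return float(out) if out.ndim == 0 else out


def simulate_pair(pair_type: str, params: CholeskyParams, rng: np.random.Generator) -> np.ndarray:
    """Draw one sibling pair's structural traits.

    Returns the 4-vector ``(trait1_sib1, trait2_sib1, trait1_sib2,
    trait2_sib2)`` implied by the Cholesky loadings and the sharing rules
    for ``pair_type``.
    """
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"unknown pair_type {pair_type!r}; expected one of {PAIR_TYPES}")
    lat = _pair_latents(pair_type, rng, n=1)
    traits = _traits_from_latents(params, lat)
    return traits[0]


def _pair_latents(pair_type: str, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Latent factor draws for n pairs: each entry (n, 2, 2) = (pair, sib, factor)."""
    r_a = GENETIC_SHARING[pair_type]
    r_t = TWIN_ENV_SHARING[pair_type]
    lat = {}
    # additive genetic: sib2 = r*sib1 + sqrt(1-r^2)*independent
    a1 = rng.standard_normal((n, 2))
    a2 = r_a * a1 + np.sqrt(1.0 - r_a**2) * rng.standard_normal((n, 2))
    lat["a"] = np.stack([a1, a2], axis=1)
    # shared environment: identical across siblings
    c = rng.standard_normal((n, 2))
    lat["c"] = np.stack([c, c], axis=1)
    # twin-specific shared environment
    t1 = rng.standard_normal((n, 2))
    t2 = t1 if r_t == 1.0 else rng.standard_normal((n, 2))
    lat["t"] = np.stack([t1, t2], axis=1)
    # non-shared environment: independent for everyone
    lat["e"] = rng.standard_normal((n, 2, 2))
    return lat


def _traits_from_latents(params: CholeskyParams, lat: dict[str, np.ndarray]) -> np.ndarray:
    """Map latent factors to observed traits; returns (n, 4) pair vectors."""
    n = lat["a"].shape[0]
    traits = np.zeros((n, 2, 2))
    for s in _SOURCES:
        traits += lat[s] @ params.lam(s).T
    return traits.reshape(n, 4)  # (t1_s1, t2_s1, t1_s2, t2_s2)


def simulate_pairs(pair_type: str, params: CholeskyParams, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`simulate_pair`: (n, 4) array of pair trait vectors."""
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"unknown pair_type {pair_type!r}; expected one of {PAIR_TYPES}")
    return _traits_from_latents(params, _pair_latents(pair_type, rng, n))


def _simulate_singletons(params: CholeskyParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) structural traits for individuals without a modelled sibling."""
    traits = np.zeros((n, 2))
    for s in _SOURCES:
        traits += rng.standard_normal((n, 2)) @ params.lam(s).T
    return traits


# ---------------------------------------------------------------------------
# cohort assembly

_RACE_LEVELS = ("white", "black", "asian", "other")
_RACE_PROBS = (0.72, 0.14, 0.06, 0.08)


def _draw_covariates(n: int, age: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics, anthropometrics and fitness scores for n individuals."""
    sex = rng.binomial(1, 0.46, n)  # 1 = male
    race = rng.choice(_RACE_LEVELS, size=n, p=_RACE_PROBS)
    education = rng.integers(1, 6, n)  # ordinal 1-5
    income = rng.integers(1, 9, n)  # ordinal 1-8
    gait_speed = np.clip(rng.normal(1.3, 0.15, n), 0.5, None)
    icv = rng.normal(1.45e6, 1.4e5, n) + sex * 1.2e5
    height = np.where(sex == 1, rng.normal(69.5, 2.8, n), rng.normal(64.2, 2.6, n))
    height = np.clip(height, 52.0, None)
    weight = np.clip(rng.normal(30.0 + 2.1 * height, 25.0, n), 80.0, None)
    endurance = rng.normal(100.0, 15.0, n)
    grip = rng.normal(100.0, 15.0, n) + sex * 8.0
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race": race,
            "education": education,
            "income": income,
            "gait_speed": gait_speed,
            "icv": icv,
            "height": height,
            "weight": weight,
            "bmi": compute_bmi(weight, height),
            "endurance": endurance,
            "grip": grip,
        }
    )


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a long-format per-individual cohort table.

    One row per individual with identifiers (``individual_id``,
    ``family_id``, ``zygosity``, ``twin_order``), covariates, and outcome
    columns.  ``outcome_1``/``outcome_2`` carry the configured bivariate
    A/C/Tw/E structure plus linear covariate effects; ``outcome_3..`` (if
    requested) are equicorrelated standard Gaussians independent of the
    covariates.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range

    rows: list[dict] = []
    traits: list[np.ndarray] = []
    fam = 0

    def add_pair(pair_type: str, zygosity: str) -> None:
        nonlocal fam
        fam += 1
        t4 = simulate_pair(pair_type, config.loadings, rng)
        base_age = rng.uniform(lo, hi - 5.0)
        if pair_type == "NotTwin":
            gap = rng.uniform(0.5, 4.5)
            ages = (base_age, min(base_age + gap, hi))
        else:
            ages = (base_age, base_age)
        for sib in (0, 1):
            rows.append(
                {
                    "family_id": f"F{fam:05d}",
                    "zygosity": zygosity,
                    "twin_order": (sib + 1) if zygosity in ("MZ", "DZ") else np.nan,
                    "age": ages[sib],
                }
            )
            traits.append(t4[2 * sib : 2 * sib + 2])

    for _ in range(config.n_mz_pairs):
        add_pair("MZ", "MZ")
    for _ in range(config.n_dz_pairs):
        add_pair("DZ", "DZ")
    for _ in range(config.n_sib_pairs):
        add_pair("NotTwin", "NotTwin")
    single = _simulate_singletons(config.loadings, config.n_singletons, rng)
    for i in range(config.n_singletons):
        fam += 1
        rows.append(
            {
                "family_id": f"F{fam:05d}",
                "zygosity": "NotTwin",
                "twin_order": np.nan,
                "age": rng.uniform(lo, hi),
            }
        )
        traits.append(single[i])

    n = len(rows)
    table = pd.DataFrame(rows)
    table.insert(0, "individual_id", [f"I{i:06d}" for i in range(1, n + 1)])
    cov = _draw_covariates(n, table.pop("age").to_numpy(), rng)
    table = pd.concat([table, cov], axis=1)

    structural = np.asarray(traits) if n else np.zeros((0, 2))
    out1 = structural[:, 0].copy() if n else np.zeros(0)
    out2 = structural[:, 1].copy() if n else np.zeros(0)
    for name, slopes in config.covariate_effects.items():
        if name not in table.columns:
            raise ValueError(f"covariate_effects names unknown column {name!r}")
        x = pd.to_numeric(table[name]).to_numpy(dtype=float)
        s1, s2 = (slopes if np.ndim(slopes) else (slopes, slopes))
        out1 += s1 * x
        out2 += s2 * x
    table["outcome_1"] = out1
    table["outcome_2"] = out2

    if config.n_extra_outcomes:
        k = config.n_extra_outcomes
        rho = config.extra_outcome_rho
        # equicorrelated: sqrt(rho)*shared + sqrt(1-rho)*independent
        shared = rng.standard_normal((n, 1))
        extra = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n, k))
        for j in range(k):
            table[f"outcome_{j + 3}"] = extra[:, j]

    return table


def write_cohort(table: pd.DataFrame, path: str | Path, *, seed: int | None = None,
                 config: SimConfig | None = None,
                 column_map: dict[str, str] | None = None) -> None:
    """Write a cohort CSV plus a JSON sidecar recording the seed/config.

    ``column_map`` renames columns on output (canonical name -> file name),
    e.g. to match an existing data dictionary; the sidecar records the map.
    """
    path = Path(path)
    out = table.rename(columns=column_map) if column_map else table
    out.to_csv(path, index=False)
    sidecar: dict = {"rows": int(len(table))}
    if column_map:
        sidecar["column_map"] = dict(column_map)
    if config is not None:
        d = dataclasses.asdict(config)
        d["loadings"] = config.loadings.as_dict()
        sidecar["config"] = d
        sidecar["seed"] = config.seed
    if seed is not None:
        sidecar["seed"] = seed
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=float))


def read_cohort(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a cohort CSV, undoing any ``column_map`` renaming from write time."""
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns={v: k for k, v in column_map.items()})
    return table
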