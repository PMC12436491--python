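"""Calibrated synthetic cohorts of male university fitness records.

The real study cohort (6,698 records) is not publicly deposited; this module
generates stand-in cohorts that reproduce its published statistical
structure: the pairwise Pearson correlations between continuous BMI and the
four fitness tests, and the four-category BMI class mix
(underweight/normal/overweight/obese = 355/4,991/1,270/82).

Mechanics: a Gaussian copula.  Latent draws come from a multivariate normal
whose correlation matrix is *calibrated* — for each variable pair the latent
correlation is solved (Brent root-finding on a Hermite-polynomial expansion
of the post-transform covariance) so that after pushing the latent normals
through the marginal quantile functions the *Pearson* correlation of the
simulated variables converges to the requested target as n grows.  The BMI
marginal is a mixture of per-category truncated normals whose mixture
weights equal the class proportions, so labels are exactly multinomial.
The copula correlation between BMI and the fitness scores is the planted,
learnable dependence every downstream model is trained and judged on.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from math import factorial

import numpy as np
import pandas as pd
from numpy.polynomial import hermite_e
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import norm, truncnorm

from .preprocess import CATEGORIES, FEATURE_COLUMNS, categorize_bmi

__all__ = [
    "VARIABLES",
    "REFERENCE_CORR",
    "REFERENCE_CLASS_COUNTS",
    "TruncNormal",
    "Normal",
    "BmiMixture",
    "Perturbation",
    "GeneratorConfig",
    "Cohort",
    "default_config",
    "single_feature_config",
    "latent_correlation",
    "simulate_cohort",
    "empirical_correlations",
    "COHORT_CSV_COLUMNS",
]

#: copula variable order: continuous BMI then the four tests
VARIABLES = ("bmi",) + FEATURE_COLUMNS

#: observed pairwise Pearson correlations of the reference male cohort
#: (rows/cols ordered as VARIABLES)
REFERENCE_CORR = np.array([
    [1.0,       0.200954, -0.278618, -0.045984,  0.005206],
    [0.200954,  1.0,      -0.405648, -0.131292,  0.007651],
    [-0.278618, -0.405648, 1.0,       0.207525, -0.010552],
    [-0.045984, -0.131292, 0.207525,  1.0,      -0.01116],
    [0.005206,  0.007651, -0.010552, -0.01116,   1.0],
])

#: reference class counts (A underweight, B normal, C overweight, D obese)
REFERENCE_CLASS_COUNTS = (355, 4991, 1270, 82)

#: canonical cohort CSV schema
COHORT_CSV_COLUMNS = ("id", "run_3000m_s", "pullups", "situps",
                      "shuttle_60m_s", "height_cm", "weight_kg", "bmi",
                      "bmi_category")

#: BMI category bounds used by the mixture marginal, with outer truncation
_BMI_EDGES = (14.0, 18.5, 25.0, 30.0, 45.0)


# ---------------------------------------------------------------------------
# marginal distribution specs (each exposes a vectorized quantile function)

@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal marginal; ``integer=True`` rounds to whole counts."""

    mean: float
    sd: float
    lo: float
    hi: float
    integer: bool = False

    def ppf(self, u):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        x = truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)
        if self.integer:
            x = np.clip(np.round(x), self.lo, self.hi)
        return x


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float

    def ppf(self, u):
        return norm.ppf(u, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class BmiMixture:
    """Mixture of per-category truncated normals on adjoining BMI intervals.

    The mixture weight of each component equals the target class proportion,
    so ``categorize_bmi`` applied to draws reproduces the class mix exactly
    in distribution.  The quantile function is piecewise: the u-axis is cut
    at the cumulative proportions and each piece maps to its component.
    """

    proportions: tuple[float, float, float, float]
    means: tuple[float, ...] = (17.5, 21.5, 26.5, 31.5)
    sds: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    edges: tuple[float, ...] = _BMI_EDGES

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        props = np.asarray(self.proportions, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(props)])
        cum[-1] = 1.0
        out = np.empty_like(u)
        for k in range(len(props)):
            lo_u, hi_u = cum[k], cum[k + 1]
            mask = (u >= lo_u) & (u < hi_u) if k < len(props) - 1 else u >= lo_u
            if not mask.any():
                continue
            local = (u[mask] - lo_u) / max(hi_u - lo_u, 1e-300)
            local = np.clip(local, 0.0, 1.0)
            a = (self.edges[k] - self.means[k]) / self.sds[k]
            b = (self.edges[k + 1] - self.means[k]) / self.sds[k]
            out[mask] = truncnorm.ppf(local, a, b, loc=self.means[k],
                                      scale=self.sds[k])
        return out


@dataclass(frozen=True)
class Perturbation:
    """Anonymization-style uniform jitter on the anthropometrics."""

    height_jitter_cm: float = 0.5
    weight_jitter_kg: float = 1.0


# ---------------------------------------------------------------------------
# generator configuration

@dataclass
class GeneratorConfig:
    n: int
    corr_target: np.ndarray
    marginals: dict
    class_proportions: np.ndarray
    height_marginal: Normal = field(default_factory=lambda: Normal(172.0, 6.0))
    perturb: Perturbation | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.corr_target = np.asarray(self.corr_target, dtype=float)
        self.class_proportions = np.asarray(self.class_proportions, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        c = self.corr_target
        if c.shape != (5, 5):
            raise ValueError("corr_target must be 5x5")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("corr_target must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("corr_target must have unit diagonal")
        p = self.class_proportions
        if p.shape != (4,) or np.any(p < 0):
            raise ValueError("class_proportions must be 4 non-negative values")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1 (within 1e-9)")
        missing = [v for v in VARIABLES if v not in self.marginals]
        if missing:
            raise ValueError(f"missing marginal specs: {missing}")

    # -- serialization (YAML/JSON mirror of the fields) --

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, (tuple, list)):
                return [plain(x) for x in v]
            if isinstance(v, np.bool_):
                return bool(v)
            if isinstance(v, (np.floating, np.integer)):
                return float(v)
            return v

        def marg(m):
            d = {"family": type(m).__name__}
            d.update({k: plain(v) for k, v in m.__dict__.items()})
            return d
        return {
            "n": int(self.n),
            "corr_target": self.corr_target.tolist(),
            "marginals": {k: marg(v) for k, v in self.marginals.items()},
            "class_proportions": self.class_proportions.tolist(),
            "height_marginal": marg(self.height_marginal),
            "perturb": (None if self.perturb is None
                        else dict(self.perturb.__dict__)),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        families = {"TruncNormal": TruncNormal, "Normal": Normal,
                    "BmiMixture": BmiMixture}

        def marg(md):
            md = dict(md)
            fam = families[md.pop("family")]
            md = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in md.items()}
            return fam(**md)

        perturb = d.get("perturb")
        return cls(
            n=d["n"],
            corr_target=np.asarray(d["corr_target"]),
            marginals={k: marg(v) for k, v in d["marginals"].items()},
            class_proportions=np.asarray(d["class_proportions"]),
            height_marginal=marg(d["height_marginal"]),
            perturb=None if perturb is None else Perturbation(**perturb),
            seed=d.get("seed", 0),
        )


def default_config(n: int = 6698, seed: int = 0,
                   perturb: Perturbation | None = None) -> GeneratorConfig:
    """Generator configuration matching the reference cohort's structure."""
    counts = np.asarray(REFERENCE_CLASS_COUNTS, dtype=float)
    props = counts / counts.sum()
    marginals = {
        "bmi": BmiMixture(proportions=tuple(map(float, props))),
        "run_3000m_s": TruncNormal(810.0, 60.0, 600.0, 1200.0),
        "pullups": TruncNormal(10.0, 4.0, 0.0, 30.0, integer=True),
        "situps": TruncNormal(40.0, 8.0, 0.0, 80.0, integer=True),
        "shuttle_60m_s": TruncNormal(10.0, 0.8, 7.0, 14.0),
    }
    return GeneratorConfig(n=n, corr_target=REFERENCE_CORR.copy(),
                           marginals=marginals, class_proportions=props,
                           perturb=perturb, seed=seed)


def single_feature_config(feature: str = "run_3000m_s", strength: float = 0.8,
                          n: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Config planting a dependence of BMI on exactly one fitness test.

    All other copula correlations are zero, so any importance a model assigns
    away from ``feature`` is spurious — the recovery oracle for the attention
    analysis.
    """
    if feature not in FEATURE_COLUMNS:
        raise ValueError(f"unknown feature {feature!r}")
    cfg = default_config(n=n, seed=seed)
    corr = np.eye(5)
    j = VARIABLES.index(feature)
    corr[0, j] = corr[j, 0] = strength
    return replace(cfg, corr_target=corr)


# ---------------------------------------------------------------------------
# copula calibration

_HERMITE_ORDER = 24
_QUAD_NODES = 160


def _hermite_profile(ppf) -> tuple[np.ndarray, float]:
    """Hermite coefficients and variance of g(Z) with g = ppf(Phi(z))."""
    nodes, wts = hermite_e.hermegauss(_QUAD_NODES)
    w = wts / np.sqrt(2.0 * np.pi)
    u = np.clip(ndtr(nodes), 1e-14, 1.0 - 1e-14)
    g = np.asarray(ppf(u), dtype=float)
    mean = w @ g
    var = w @ (g - mean) ** 2
    he = hermite_e.hermevander(nodes, _HERMITE_ORDER)  # (nodes, M+1)
    coeffs = np.array([w @ (g * he[:, m]) / factorial(m)
                       for m in range(1, _HERMITE_ORDER + 1)])
    return coeffs, float(var)


def _pair_pearson(coeffs_j, coeffs_k, var_j, var_k, rho: float) -> float:
    m = np.arange(1, _HERMITE_ORDER + 1)
    fact = np.array([factorial(i) for i in m], dtype=float)
    cov = np.sum(fact * coeffs_j * coeffs_k * rho ** m)
    return cov / np.sqrt(var_j * var_k)


def _repair_psd(matrix: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue clipping + diagonal renormalization to the nearest-ish
    valid correlation matrix."""
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() >= floor:
        return matrix
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


_latent_cache: dict[bytes, np.ndarray] = {}


def latent_correlation(config: GeneratorConfig) -> np.ndarray:
    """Latent Gaussian correlation matrix calibrated to the Pearson targets.

    For each off-diagonal pair the latent correlation solves
    ``pearson(g_j(Z1), g_k(Z2); rho) = target`` by Brent root-finding on the
    Hermite expansion of the transformed covariance; the assembled matrix is
    then PSD-repaired.  Deterministic, simulation-free, cached per target
    matrix + marginal set.
    """
    key = (config.corr_target.tobytes()
           + repr(sorted(config.marginals.items())).encode())
    if key in _latent_cache:
        return _latent_cache[key]
    profiles = {v: _hermite_profile(config.marginals[v].ppf)
                for v in VARIABLES}
    latent = np.eye(5)
    for j in range(5):
        for k in range(j + 1, 5):
            target = config.corr_target[j, k]
            if target == 0.0:
                continue
            cj, vj = profiles[VARIABLES[j]]
            ck, vk = profiles[VARIABLES[k]]

            def f(rho):
                return _pair_pearson(cj, ck, vj, vk, rho) - target

            lo, hi = -0.9995, 0.9995
            if f(lo) > 0 or f(hi) < 0:
                raise ValueError(
                    f"target correlation {target:+.4f} between "
                    f"{VARIABLES[j]} and {VARIABLES[k]} is unreachable under "
                    f"the configured marginals")
            latent[j, k] = latent[k, j] = brentq(f, lo, hi, xtol=1e-10)
    latent = _repair_psd(latent)
    if np.linalg.eigvalsh(latent).min() <= 0:
        raise ValueError("latent correlation matrix not positive definite "
                         "after repair")
    _latent_cache[key] = latent
    return latent


# ---------------------------------------------------------------------------
# cohort container and simulation

@dataclass
class Cohort:
    """A cohort table plus provenance metadata.

    ``df`` follows the canonical CSV schema (:data:`COHORT_CSV_COLUMNS`).
    """

    df: pd.DataFrame
    provenance: str = "synthetic"
    seed_used: int | None = None

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path_or_buf=None):
        return self.df.to_csv(path_or_buf, index=False,
                              float_format="%.6f")

    @classmethod
    def from_csv(cls, path_or_buf) -> "Cohort":
        df = pd.read_csv(path_or_buf)
        missing = [c for c in COHORT_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort CSV missing columns: {missing}")
        bad = set(df["bmi_category"].unique()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown BMI categories in CSV: {sorted(bad)}")
        return cls(df=df[list(COHORT_CSV_COLUMNS)], provenance="file",
                   seed_used=None)


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort from the calibrated Gaussian copula.

    Same config (including seed) gives a bit-identical table.  Category
    labels are assigned from the true (pre-perturbation) BMI; the optional
    jitter touches only the height/weight columns, mimicking anonymization.
    """
    config.validate()
    latent = latent_correlation(config)
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(latent)
    z = rng.standard_normal((config.n, 5)) @ chol.T
    u = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)

    cols = {v: np.asarray(config.marginals[v].ppf(u[:, i]), dtype=float)
            for i, v in enumerate(VARIABLES)}
    bmi = cols["bmi"]
    u_height = rng.uniform(1e-12, 1.0 - 1e-12, size=config.n)
    height = config.height_marginal.ppf(u_height)
    weight = bmi * (height / 100.0) ** 2
    category = categorize_bmi(bmi)

    if config.perturb is not None:
        height = height + rng.uniform(-config.perturb.height_jitter_cm,
                                      config.perturb.height_jitter_cm,
                                      size=config.n)
        weight = weight + rng.uniform(-config.perturb.weight_jitter_kg,
                                      config.perturb.weight_jitter_kg,
                                      size=config.n)

    df = pd.DataFrame({
        "id": np.arange(1, config.n + 1),
        "run_3000m_s": cols["run_3000m_s"],
        "pullups": cols["pullups"].astype(int),
        "situps": cols["situps"].astype(int),
        "shuttle_60m_s": cols["shuttle_60m_s"],
        "height_cm": height,
        "weight_kg": weight,
        "bmi": bmi,
        "bmi_category": category,
    })
    return Cohort(df=df, provenance="synthetic", seed_used=config.seed)


def empirical_correlations(cohort: Cohort | pd.DataFrame) -> np.ndarray:
    """Pearson correlation matrix over (BMI, 3000 m, pull-ups, sit-ups,
    shuttle), in :data:`VARIABLES` order."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if len(df) < 3:
        raise ValueError("need at least 3 records for a correlation matrix")
    x = df.loc[:, list(VARIABLES)].to_numpy(dtype=float)
    sd = x.std(axis=0)
    for j, s in enumerate(sd):
        if s <= 0:
            raise ValueError(f"column {VARIABLES[j]!r} has zero variance")
    return np.corrcoef(x, rowvar=False)
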