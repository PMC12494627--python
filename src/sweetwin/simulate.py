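"""Synthetic twin cohorts with known A/C/D/E structure.

The generator draws, per pair, component deviates with the cross-twin
correlations of the classical twin design (A: 1 / 0.5; C: 1; D: 1 / 0.25;
E: 0 for MZ/DZ) and sums them with a linear mean model.  Two traits may
share additive-genetic (A12) and unique-environment (E12) covariance, the
generative counterpart of the bivariate AE model.  Deviates are Gaussian —
the likelihood's own assumption — so passing recovery tests certifies the
estimators under the model, not robustness to real-data skew.

Named presets ``uk_like`` and ``fin_like`` encode the published study
conditions of the two cohorts this package emulates (pair counts,
complete-pair rates, phenotype means and variances, heritabilities, age and
sex composition, sweet-liking status proportions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import STATUS_ORDER, ThresholdSet, classify_status, thresholds_from_proportions
from .data import PairTable, TwinCohort, pairs_from_values

__all__ = [
    "TraitSpec",
    "SimulationSpec",
    "simulate_cohort",
    "simulate_bivariate_cohort",
    "simulate_pair_values",
    "discretize_status",
    "preset",
    "PRESETS",
]

#: cross-twin correlation of each component's deviates
_GAMMA = {
    "MZ": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 0.0},
    "DZ": {"A": 0.5, "C": 1.0, "D": 0.25, "E": 0.0},
}


@dataclass
class TraitSpec:
    """Generative variance components and mean model for one trait."""

    A: float = 0.0
    C: float = 0.0
    D: float = 0.0
    E: float = 1.0
    intercept: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0

    def total(self) -> float:
        return self.A + self.C + self.D + self.E


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic cohort.

    ``n_pairs`` maps zygosity tokens (MZ, DZ_SS, DZ_OS) to pair counts;
    ``incomplete_rate`` is the probability that a pair contributes only one
    phenotyped twin (per zygosity when a dict).  ``cross`` holds A12/E12 for
    exactly two traits.  Ages are drawn per pair (twins share age) and
    centered at ``age_mean`` in the mean model; ``beta_age`` is per year.
    """

    n_pairs: dict
    traits: dict  # name -> TraitSpec
    cross: dict | None = None  # {"A12": float, "E12": float}
    age_mean: float = 30.0
    age_sd: float = 5.0
    sex_female_prop: float = 0.5
    incomplete_rate: object = 0.0
    cohort: str = "SIM"
    thresholds: ThresholdSet | None = None

    def __post_init__(self):
        for z, n in self.n_pairs.items():
            if z not in _GAMMA["MZ"] and z not in ("MZ", "DZ_SS", "DZ_OS"):
                raise ValueError(f"unknown zygosity {z!r}")
            if n < 0:
                raise ValueError("n_pairs must be >= 0")
        for name, ts in self.traits.items():
            if min(ts.A, ts.C, ts.D, ts.E) < 0:
                raise ValueError(f"generative variances must be >= 0 ({name})")
            if ts.total() <= 0:
                raise ValueError(f"trait {name} has non-positive total variance")
        if self.cross is not None:
            if len(self.traits) != 2:
                raise ValueError("cross covariances need exactly two traits")
            (t1, t2) = [self.traits[k] for k in self.traits]
            a12 = self.cross.get("A12", 0.0)
            e12 = self.cross.get("E12", 0.0)
            if a12 * a12 > t1.A * t2.A + 1e-12:
                raise ValueError("A12 implies a non-PSD genetic covariance")
            if e12 * e12 > t1.E * t2.E + 1e-12:
                raise ValueError("E12 implies a non-PSD environmental covariance")
            if t1.C or t2.C or t1.D or t2.D:
                raise ValueError("bivariate simulation supports AE structure only")

    def _rate(self, z) -> float:
        if isinstance(self.incomplete_rate, dict):
            return float(self.incomplete_rate.get(z, 0.0))
        return float(self.incomplete_rate)


def _draw_component(rng, n, gamma, cov):
    """(n, 2, k) deviates with cross-twin correlation gamma, trait cov matrix."""
    k = cov.shape[0]
    common = rng.multivariate_normal(np.zeros(k), gamma * cov, size=n,
                                     method="eigh")
    indiv = rng.multivariate_normal(np.zeros(k), (1.0 - gamma) * cov,
                                    size=(n, 2), method="eigh")
    return common[:, None, :] + indiv


def simulate_cohort(spec: SimulationSpec, seed=None, rng=None) -> TwinCohort:
    """Draw a long-format twin cohort under the spec's generative model."""
    if rng is None:
        rng = np.random.default_rng(seed)
    names = list(spec.traits)
    k = len(names)
    covs = {}
    for comp in ("A", "C", "D", "E"):
        m = np.diag([getattr(spec.traits[t], comp) for t in names]).astype(float)
        if spec.cross is not None and comp in ("A", "E"):
            m[0, 1] = m[1, 0] = float(spec.cross.get(f"{comp}12", 0.0))
        covs[comp] = m
    rows = []
    for zyg in ("MZ", "DZ_SS", "DZ_OS"):
        n = int(spec.n_pairs.get(zyg, 0))
        if n == 0:
            continue
        gclass = "MZ" if zyg == "MZ" else "DZ"
        values = np.zeros((n, 2, k))
        for comp in ("A", "C", "D", "E"):
            if covs[comp].any():
                values += _draw_component(rng, n, _GAMMA[gclass][comp], covs[comp])
        ages = np.maximum(rng.normal(spec.age_mean, spec.age_sd, size=n), 1.0)
        if zyg == "DZ_OS":
            first_f = rng.random(n) < 0.5
            sexes = np.where(first_f[:, None], [["F", "M"]], [["M", "F"]])
        else:
            fem = rng.random(n) < spec.sex_female_prop
            sexes = np.where(np.repeat(fem[:, None], 2, axis=1), "F", "M")
        drop = rng.random(n) < spec._rate(zyg)
        drop_side = rng.integers(0, 2, size=n)
        for i in range(n):
            for j in (0, 1):
                fam = f"{spec.cohort}_{zyg}_{i:04d}"
                sex_ij = sexes[i, j]
                pheno = {}
                for t_i, t in enumerate(names):
                    ts = spec.traits[t]
                    mu = (
                        ts.intercept
                        + ts.beta_age * (ages[i] - spec.age_mean)
                        + ts.beta_sex * (1.0 if sex_ij == "M" else 0.0)
                    )
                    v = mu + values[i, j, t_i]
                    if drop[i] and j == drop_side[i]:
                        v = np.nan
                    pheno[t] = v
                rows.append(
                    {"family_id": fam, "twin_order": j + 1, "zygosity": zyg,
                     "sex": sex_ij, "age": ages[i], "cohort": spec.cohort,
                     **pheno}
                )
    df = pd.DataFrame(
        rows,
        columns=["family_id", "twin_order", "zygosity", "sex", "age", "cohort"]
        + names,
    )
    registry = {t: None for t in names}
    return TwinCohort(df, registry)


def simulate_bivariate_cohort(spec: SimulationSpec, seed=None, rng=None) -> TwinCohort:
    """Two-trait cohort with cross-trait A12/E12 structure (alias of
    :func:`simulate_cohort`; the spec must declare two traits and ``cross``)."""
    if spec.cross is None or len(spec.traits) != 2:
        raise ValueError("spec must declare two traits and cross covariances")
    return simulate_cohort(spec, seed=seed, rng=rng)


def simulate_pair_values(n: int, variance: float, correlation: float, rng,
                         mean: float = 0.0) -> np.ndarray:
    """(n, 2) pair values from a bivariate normal with given within-pair
    correlation — the moment-level generator used when only printed pair
    correlations (not components) define the study condition."""
    cov = variance * np.array([[1.0, correlation], [correlation, 1.0]])
    return rng.multivariate_normal([mean, mean], cov, size=n, method="cholesky")


def discretize_status(cohort: TwinCohort, trait: str, thresholds: ThresholdSet,
                      out: str = "sweet_status") -> TwinCohort:
    """Standardize a trait within the cohort and cut it at liability thresholds.

    Adds an ordered SD/MSL/ESL column; missing values stay missing.
    """
    if trait not in cohort.trait_registry:
        raise KeyError(f"unknown trait {trait!r}")
    vals = cohort.data[trait].to_numpy(float)
    mu, sd = np.nanmean(vals), np.nanstd(vals)
    if not sd > 0:
        raise ValueError("trait has zero variance")
    z = (vals - mu) / sd
    labels = classify_status(z, cutoffs=thresholds.as_tuple())
    new = cohort.copy()
    new.data[out] = np.asarray(labels).astype(object)
    new.trait_registry[out] = None
    return TwinCohort(new.data, new.trait_registry, new.age_centered)


# ----------------------------------------------------------------------
# named presets: the two published cohorts' study conditions
# ----------------------------------------------------------------------

def _uk_like() -> SimulationSpec:
    v, h2 = 384.6, 0.48
    v2, h2_2 = 1.0, 0.52
    rg, re = 0.31, 0.06
    a1, e1 = h2 * v, (1 - h2) * v
    a2, e2 = h2_2 * v2, (1 - h2_2) * v2
    return SimulationSpec(
        n_pairs={"MZ": 244, "DZ_SS": 250, "DZ_OS": 0},
        traits={
            "liking": TraitSpec(A=a1, E=e1, intercept=52.62),
            "fl_sweet": TraitSpec(A=a2, E=e2, intercept=5.0),
        },
        cross={"A12": rg * np.sqrt(a1 * a2), "E12": re * np.sqrt(e1 * e2)},
        age_mean=55.64,
        age_sd=12.51,
        sex_female_prop=0.90,
        incomplete_rate={"MZ": 0.07, "DZ_SS": 0.04},
        cohort="UK",
        thresholds=thresholds_from_proportions((0.42, 0.22, 0.36)),
    )


def _fin_like() -> SimulationSpec:
    v, h2 = 218.5, 0.30
    v2, h2_2 = 1.0, 0.53
    rg, re = 0.19, 0.22
    a1, e1 = h2 * v, (1 - h2) * v
    a2, e2 = h2_2 * v2, (1 - h2_2) * v2
    return SimulationSpec(
        n_pairs={"MZ": 111, "DZ_SS": 80, "DZ_OS": 68},
        traits={
            "liking": TraitSpec(A=a1, E=e1, intercept=60.29),
            "fl_sweetfat": TraitSpec(A=a2, E=e2, intercept=5.0),
        },
        cross={"A12": rg * np.sqrt(a1 * a2), "E12": re * np.sqrt(e1 * e2)},
        age_mean=22.67,
        age_sd=0.47,
        sex_female_prop=0.60,
        incomplete_rate={"MZ": 0.12, "DZ_SS": 0.15, "DZ_OS": 0.37},
        cohort="FIN",
        thresholds=thresholds_from_proportions((0.24, 0.32, 0.44)),
    )


PRESETS = {"uk_like": _uk_like, "fin_like": _fin_like}


def preset(name: str) -> SimulationSpec:
    """Return a fresh SimulationSpec for a named cohort preset."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
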