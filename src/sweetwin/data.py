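"""Twin cohort tables: reading, validation, and reshaping.

A cohort is a long-format table with one row per twin individual
(``family_id, twin_order, zygosity, sex, age, cohort`` plus any number of
phenotype columns).  The classical twin design needs a wide, one-row-per-pair
view of a phenotype, which :func:`pair_wide` provides.  Missing phenotype
cells (empty or ``NA`` in input files) are carried as NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ("family_id", "twin_order", "zygosity", "sex", "age", "cohort")
ZYGOSITY_TOKENS = ("MZ", "DZ_SS", "DZ_OS")
SEX_TOKENS = ("F", "M")
#: input tokens treated as missing, in addition to pandas' defaults
NA_TOKENS = ("", "NA")
#: numeric sex coding used by every mean model: F=0 (reference), M=1
SEX_CODE = {"F": 0.0, "M": 1.0}


class CohortValidationError(ValueError):
    """A record violates a cohort invariant (named family in the message)."""


class StructuralError(CohortValidationError):
    """The table's family structure is impossible (e.g. >2 rows per family)."""


@dataclass
class TwinCohort:
    """Validated long-format twin phenotype table.

    Parameters
    ----------
    data:
        DataFrame with the meta columns plus one column per trait.
    trait_registry:
        Mapping trait name -> inclusive ``(low, high)`` scale bounds, or
        ``None`` when the scale is unbounded/unknown.  Registered bounds are
        enforced on construction.
    """

    data: pd.DataFrame
    trait_registry: dict = field(default_factory=dict)
    #: set by :func:`center_covariates`; centered ages are deviations, not years
    age_centered: bool = False

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        missing_meta = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing_meta:
            raise CohortValidationError(f"missing required columns: {missing_meta}")
        for t in self.traits:
            self.trait_registry.setdefault(t, None)
        self._validate()

    # -- basic views ---------------------------------------------------
    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    @property
    def n_families(self) -> int:
        return self.data["family_id"].nunique()

    def copy(self) -> "TwinCohort":
        return TwinCohort(self.data.copy(), dict(self.trait_registry),
                          self.age_centered)

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        bad_order = ~df["twin_order"].isin([1, 2])
        if bad_order.any():
            raise CohortValidationError(
                f"twin_order must be 1 or 2 (rows {list(df.index[bad_order])})"
            )
        bad_zyg = ~df["zygosity"].isin(ZYGOSITY_TOKENS)
        if bad_zyg.any():
            raise CohortValidationError(
                f"unknown zygosity token(s): {sorted(df.loc[bad_zyg, 'zygosity'].unique())}"
            )
        bad_sex = ~df["sex"].isin(SEX_TOKENS)
        if bad_sex.any():
            raise CohortValidationError(
                f"unknown sex token(s): {sorted(df.loc[bad_sex, 'sex'].unique())}"
            )
        if not self.age_centered:
            age = pd.to_numeric(df["age"], errors="coerce")
            if ((age <= 0) & age.notna()).any():
                fam = df.loc[(age <= 0) & age.notna(), "family_id"].iloc[0]
                raise CohortValidationError(f"age must be > 0 (family {fam})")

        for fam, g in df.groupby("family_id", sort=False):
            if len(g) > 2:
                raise StructuralError(f"family {fam} has {len(g)} records (max 2)")
            if len(g) == 2 and g["twin_order"].iloc[0] == g["twin_order"].iloc[1]:
                raise StructuralError(f"family {fam} has duplicate twin_order")
            if g["zygosity"].nunique() > 1:
                raise CohortValidationError(f"family {fam} has inconsistent zygosity")
            if g["cohort"].nunique() > 1:
                raise CohortValidationError(f"family {fam} has inconsistent cohort")
            if len(g) == 2:
                zyg = g["zygosity"].iloc[0]
                same_sex = g["sex"].iloc[0] == g["sex"].iloc[1]
                if zyg == "MZ" and not same_sex:
                    raise CohortValidationError(f"MZ family {fam} has mixed sex")
                if zyg == "DZ_OS" and same_sex:
                    raise CohortValidationError(f"DZ_OS family {fam} has equal sex")

        for trait, bounds in self.trait_registry.items():
            if bounds is None or trait not in df.columns:
                continue
            lo, hi = bounds
            vals = pd.to_numeric(df[trait], errors="coerce")
            out = ((vals < lo) | (vals > hi)) & vals.notna()
            if out.any():
                fam = df.loc[out, "family_id"].iloc[0]
                raise CohortValidationError(
                    f"trait {trait!r} out of bounds [{lo}, {hi}] (family {fam})"
                )


def read_long_table(path, trait_registry: dict | None = None) -> TwinCohort:
    """Read a UTF-8 delimited long twin table and validate it.

    Empty cells and ``NA`` become missing markers.  Row order is preserved.
    """
    df = pd.read_csv(
        path,
        na_values=list(NA_TOKENS),
        dtype={"family_id": str, "zygosity": str, "sex": str, "cohort": str},
    )
    if "twin_order" in df.columns:
        df["twin_order"] = pd.to_numeric(df["twin_order"], errors="raise")
    return TwinCohort(df, dict(trait_registry or {}))


def write_long_table(cohort: TwinCohort, path) -> None:
    """Write a cohort back to CSV; missing markers become ``NA``."""
    cohort.data.to_csv(path, index=False, na_rep="NA")


@dataclass
class PairTable:
    """Wide one-row-per-family view of one or more traits.

    Columns: ``family_id, zygosity, cohort, complete`` plus, for every trait
    ``t`` and covariate ``c``, columns ``t_1, t_2`` and ``c_1, c_2``
    (twin_order 1 -> suffix ``_1``).  ``sex`` covariate columns are numeric
    (F=0, M=1).  ``complete`` is True when every trait slot is non-missing.
    """

    frame: pd.DataFrame
    traits: tuple
    covariates: tuple = ()

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_complete(self) -> int:
        return int(self.frame["complete"].sum())

    def values(self, trait: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        trait = trait or self.traits[0]
        f = self.frame
        return (
            f[f"{trait}_1"].to_numpy(float),
            f[f"{trait}_2"].to_numpy(float),
        )

    def zygosity_class(self) -> np.ndarray:
        """Collapse DZ_SS and DZ_OS into one DZ class (genetic correlation 0.5)."""
        z = self.frame["zygosity"].to_numpy()
        return np.where(z == "MZ", "MZ", "DZ")


def pair_wide(cohort: TwinCohort, trait, covariates=()) -> PairTable:
    """Reshape a cohort to one row per family for the given trait(s).

    Families where every trait value is missing are dropped; families with
    exactly one observed member are retained and flagged incomplete.
    """
    traits = [trait] if isinstance(trait, str) else list(trait)
    for t in traits:
        if t not in cohort.trait_registry:
            raise KeyError(f"unknown trait {t!r}")
    covariates = tuple(covariates)
    df = cohort.data.copy()
    df["sex"] = df["sex"].map(SEX_CODE)
    value_cols = list(dict.fromkeys(traits + [c for c in covariates]))
    if len(df) == 0:
        cols = ["family_id", "zygosity", "cohort", "complete"]
        for name in traits + list(covariates):
            cols += [f"{name}_1", f"{name}_2"]
        return PairTable(pd.DataFrame(columns=cols), tuple(traits), covariates)

    wide = df.pivot(index="family_id", columns="twin_order", values=value_cols)
    wide.columns = [f"{name}_{order}" for name, order in wide.columns]
    for name in value_cols:
        for order in (1, 2):
            col = f"{name}_{order}"
            if col not in wide.columns:
                wide[col] = np.nan
    meta = df.groupby("family_id", sort=False)[["zygosity", "cohort"]].first()
    out = meta.join(wide).reset_index()
    # preserve first-appearance family order
    order = {f: i for i, f in enumerate(df["family_id"].unique())}
    out = out.sort_values("family_id", key=lambda s: s.map(order)).reset_index(drop=True)

    trait_cols = [f"{t}_{j}" for t in traits for j in (1, 2)]
    vals = out[trait_cols]
    observed = vals.notna()
    out = out.loc[observed.any(axis=1)].reset_index(drop=True)
    out["complete"] = observed.loc[observed.any(axis=1)].all(axis=1).to_numpy()
    cols = ["family_id", "zygosity", "cohort", "complete"] + [
        f"{name}_{j}" for name in value_cols for j in (1, 2)
    ]
    return PairTable(out[cols], tuple(traits), covariates)


def pairs_from_values(
    trait: str,
    groups: dict,
    cohort_label: str = "SIM",
) -> PairTable:
    """Assemble a minimal :class:`PairTable` from raw per-zygosity value arrays.

    ``groups`` maps a zygosity token to an ``(n, 2)`` array of pair values
    (NaN marks a missing member).  Convenience constructor for simulation
    studies that bypass the long-format plumbing.
    """
    rows = []
    for zyg, arr in groups.items():
        if zyg not in ZYGOSITY_TOKENS:
            raise ValueError(f"unknown zygosity token {zyg!r}")
        arr = np.asarray(arr, float).reshape(-1, 2)
        for i, (v1, v2) in enumerate(arr):
            rows.append((f"{cohort_label}_{zyg}_{i}", zyg, cohort_label, v1, v2))
    frame = pd.DataFrame(
        rows, columns=["family_id", "zygosity", "cohort", f"{trait}_1", f"{trait}_2"]
    )
    obs = frame[[f"{trait}_1", f"{trait}_2"]].notna()
    frame = frame.loc[obs.any(axis=1)].reset_index(drop=True)
    frame["complete"] = obs.loc[obs.any(axis=1)].all(axis=1).to_numpy()
    return PairTable(frame, (trait,), ())


def center_covariates(cohort: TwinCohort) -> TwinCohort:
    """Return a cohort with age centered at the sample mean.

    Centering is idempotent; an all-missing age column is an error.
    """
    out = cohort.copy()
    age = pd.to_numeric(out.data["age"], errors="coerce")
    if age.notna().sum() == 0:
        raise CohortValidationError("cannot center age: all ages missing")
    centered = age - age.mean()
    out_df = out.data
    out_df["age"] = centered
    return TwinCohort(out_df, out.trait_registry, age_centered=True)


def group_score(cohort: TwinCohort, item_names, group_name: str) -> TwinCohort:
    """Add a trait equal to the per-individual mean over non-missing items.

    All items must be registered and share the same scale bounds; individuals
    missing every item get a missing group score.
    """
    items = list(item_names)
    if not items:
        raise ValueError("empty item list")
    bounds = set()
    for it in items:
        if it not in cohort.trait_registry:
            raise KeyError(f"unknown trait {it!r}")
        bounds.add(cohort.trait_registry[it])
    if len(bounds) > 1:
        raise ValueError(f"items do not share a common scale: {sorted(bounds, key=str)}")
    out = cohort.copy()
    out.data[group_name] = out.data[items].mean(axis=1, skipna=True)
    out.trait_registry[group_name] = bounds.pop()
    return TwinCohort(out.data, out.trait_registry)
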