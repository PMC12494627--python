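"""End-to-end analysis: classification -> correlations -> univariate models
-> heterogeneity -> bivariate decomposition, with report tables.

The stage order follows the pre-registered strategy of the twin study this
package emulates.  Outputs are a pure function of (input data, config,
seed): the run log records the seed and library versions, and reruns with
the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_cohort, status_proportions, thresholds_from_proportions
from .data import TwinCohort, pair_wide, read_long_table, center_covariates
from .descriptives import correlation_screen, intraclass_pearson, polychoric
from .heterogeneity import omnibus_test, per_parameter_tests
from .bivariate import fit_bivariate
from .simulate import PRESETS, preset, simulate_cohort
from .univariate import (
    MODEL_COMPONENTS,
    compare_models,
    fit_continuous,
    fit_ordinal,
    heritability,
    profile_ci,
)

log = logging.getLogger("sweetwin")

__all__ = ["AnalysisConfig", "PipelineError", "run_pipeline", "select_model"]

#: full models containing each submodel (used by the selection rule)
_FULLS_OF = {"AE": ("ACE", "ADE"), "CE": ("ACE",), "DE": ("ADE",),
             "E": ("ACE", "ADE")}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    source: str  # path to a long CSV, or a preset name
    outdir: str = "sweetwin_out"
    focal_trait: str = "liking"
    status_mode: str = "cutoffs"  # cutoffs | quantile
    rescale: bool = True
    cutoffs: tuple = (0.0, 15.0)
    covariates: tuple = ("age", "sex")
    alpha: float = 0.05
    models: tuple = ("ACE", "ADE", "AE", "CE", "DE", "E")
    stratify: str = "cohort"
    seed: int = 0
    secondary_traits: tuple | str = "auto"
    compute_cis: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cutoffs", "covariates", "models"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def select_model(pairs, kind: str = "continuous", covariates=(), alpha: float = 0.05,
                 trait=None):
    """Fit the ACE/ADE family and pick the best model by backward elimination.

    Both full models are fitted; the family is the one fitting better (under
    the direct symmetric parameterization they attain the same likelihood,
    in which case the sign of the unconstrained C estimate decides: a
    negative C is the classic DZ-correlation-below-half pattern that the
    ADE family captures).  Components are then removed along the nested
    chain full -> AE -> E: the shared-environment (or dominance) component
    is tested first and dropped when its LRT is non-significant at
    ``alpha``; the additive component is tested only from the reduced
    model (a significant p means the component is retained).  E is never
    removed.
    """
    fitter = fit_continuous if kind == "continuous" else fit_ordinal
    fits = {m: fitter(pairs, model=m, covariates=covariates, trait=trait)
            for m in MODEL_COMPONENTS}
    rows = []
    for sub, fulls in _FULLS_OF.items():
        for fullname in fulls:
            lrt = compare_models(fits[fullname], fits[sub])
            rows.append((sub, fullname, lrt.statistic, lrt.df, lrt.p))
    table = pd.DataFrame(rows, columns=["sub", "full", "statistic", "df", "p"])

    if fits["ADE"].loglik > fits["ACE"].loglik + 1e-6:
        family = "ADE"
    elif fits["ACE"].loglik > fits["ADE"].loglik + 1e-6:
        family = "ACE"
    else:
        family = "ACE" if fits["ACE"].params.get("C", 0.0) >= 0 else "ADE"

    #: submodel reached by dropping one component from a model
    drop_map = {
        ("ACE", "C"): "AE", ("ACE", "A"): "CE",
        ("ADE", "D"): "AE", ("ADE", "A"): "DE",
        ("AE", "A"): "E", ("CE", "C"): "E", ("DE", "D"): "E",
    }
    current = family
    while True:
        droppable = [(c, sub) for (m, c), sub in drop_map.items() if m == current]
        if not droppable:
            break
        # A is tested last: drop C/D along the full -> AE -> E chain first,
        # falling back to the A drop only when C/D must be retained
        non_a = [(c, s) for c, s in droppable if c != "A"]
        a_drop = [(c, s) for c, s in droppable if c == "A"]
        moved = False
        for tests in (t for t in (non_a, a_drop) if t):
            results = []
            for comp, sub in tests:
                lrt = compare_models(fits[current], fits[sub])
                results.append((lrt.p, comp, sub))
            p, comp, sub = max(results)  # least significant removable component
            if p >= alpha:
                current = sub
                moved = True
                break
        if not moved:
            break
    return current, table, fits


def _load_cohort(config: AnalysisConfig, rng) -> TwinCohort:
    if config.source in PRESETS:
        spec = preset(config.source)
        return simulate_cohort(spec, rng=rng), spec
    return read_long_table(config.source), None


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: f"{v:.4f}" if np.isfinite(v) else "NA")
    return out


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        return round(float(x), 6)
    if isinstance(x, (np.integer, int)):
        return int(x)
    return x


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis and write the report bundle to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bundle: dict = {}

    # ---- stage 1: load / simulate + classify -------------------------
    log.info("stage=load source=%s seed=%s", config.source, config.seed)
    cohort, spec = _load_cohort(config, rng)
    if cohort.n_individuals == 0:
        raise PipelineError("load", "empty cohort")
    trait = config.focal_trait
    if trait not in cohort.trait_registry:
        raise PipelineError("load", f"focal trait {trait!r} not in cohort")
    log.info("stage=classify mode=%s", config.status_mode)
    try:
        if config.status_mode == "quantile":
            thresholds = spec.thresholds if spec is not None else None
            if thresholds is None:
                raise PipelineError("classify", "quantile mode needs preset thresholds")
            cohort = classify_cohort(cohort, trait, mode="quantile",
                                     thresholds=thresholds)
        else:
            cohort = classify_cohort(cohort, trait, mode="cutoffs",
                                     rescale=config.rescale, cutoffs=config.cutoffs)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage-labelled rethrow
        raise PipelineError("classify", str(e))
    cohort = center_covariates(cohort)

    cohorts = {c: TwinCohort(g.reset_index(drop=True), dict(cohort.trait_registry),
                             cohort.age_centered)
               for c, g in cohort.data.groupby("cohort", sort=True)}

    # ---- table 1: demographics & status ------------------------------
    rows = []
    for cname, co in cohorts.items():
        df = co.data
        pairs = df.groupby("family_id").size()
        sp = status_proportions(df["sweet_status"])
        row = {
            "cohort": cname,
            "n_individuals": len(df),
            "n_families": df["family_id"].nunique(),
            "pct_female": float((df["sex"] == "F").mean()),
            "age_mean_centered": float(df["age"].mean()),
            f"{trait}_mean": float(df[trait].mean()),
            f"{trait}_sd": float(df[trait].std()),
        }
        for z in ("MZ", "DZ_SS", "DZ_OS"):
            sub = df[df["zygosity"] == z]
            fams = sub.groupby("family_id")[trait].apply(lambda s: s.notna().sum())
            row[f"pairs_{z}"] = int(len(fams))
            row[f"pct_complete_{z}"] = float((fams == 2).mean()) if len(fams) else np.nan
        for k in ("SD", "MSL", "ESL"):
            row[f"prop_{k}"] = sp.proportions[k]
        rows.append(row)
    table1 = pd.DataFrame(rows)
    _fmt(table1).to_csv(outdir / "table1.tsv", sep="\t", index=False)
    bundle["table1"] = table1

    # ---- table 2: twin correlations ----------------------------------
    log.info("stage=descriptives")
    rows = []
    for cname, co in cohorts.items():
        pt_c = pair_wide(co, trait)
        pt_s = pair_wide(co, "sweet_status")
        for z in ("MZ", "DZ"):
            mask = pt_c.zygosity_class() == z
            sub = type(pt_c)(pt_c.frame[mask].reset_index(drop=True),
                             pt_c.traits, pt_c.covariates)
            try:
                est = intraclass_pearson(sub)
                rows.append((cname, z, "continuous_pearson", est.r,
                             est.ci[0] if est.ci else np.nan,
                             est.ci[1] if est.ci else np.nan, est.n_pairs))
            except ValueError as e:
                log.warning("table2 %s %s continuous: %s", cname, z, e)
            mask_s = pt_s.zygosity_class() == z
            sub_s = type(pt_s)(pt_s.frame[mask_s].reset_index(drop=True),
                               pt_s.traits, pt_s.covariates)
            try:
                est = polychoric(sub_s)
                rows.append((cname, z, "ordinal_polychoric", est.r,
                             np.nan, np.nan, est.n_pairs))
            except ValueError as e:
                log.warning("table2 %s %s ordinal: %s", cname, z, e)
    table2 = pd.DataFrame(rows, columns=["cohort", "zygosity", "statistic",
                                         "r", "ci_lo", "ci_hi", "n_pairs"])
    _fmt(table2).to_csv(outdir / "table2.tsv", sep="\t", index=False)
    bundle["table2"] = table2

    # ---- table 3: univariate best fits -------------------------------
    log.info("stage=univariate")
    table3: dict = {}
    pair_tables = {}
    for cname, co in cohorts.items():
        pt = pair_wide(co, trait, covariates=config.covariates)
        pt_s = pair_wide(co, "sweet_status", covariates=config.covariates)
        pair_tables[cname] = (pt, pt_s)
        entry = {}
        best_c, cmp_c, fits_c = select_model(pt, "continuous", config.covariates,
                                             config.alpha)
        fit_c = fits_c[best_c]
        hc = heritability(fit_c)
        entry["continuous"] = {
            "best_model": best_c, "loglik": fit_c.loglik, "n_free": fit_c.n_free,
            "h2": hc["h2"], "total_variance": hc["total"],
        }
        if config.compute_cis:
            entry["continuous"]["h2_ci"] = profile_ci(fit_c, "h2").as_tuple()
            entry["continuous"]["total_ci"] = profile_ci(fit_c, "total").as_tuple()
        best_o, cmp_o, fits_o = select_model(pt_s, "ordinal", config.covariates,
                                             config.alpha)
        fit_o = fits_o[best_o]
        ho = heritability(fit_o)
        entry["ordinal"] = {
            "best_model": best_o, "loglik": fit_o.loglik, "n_free": fit_o.n_free,
            "h2": ho["h2"],
            "tau1": fit_o.params["tau1"], "tau2": fit_o.params["tau2"],
        }
        if config.compute_cis:
            entry["ordinal"]["h2_ci"] = profile_ci(fit_o, "h2").as_tuple()
        entry["model_comparison"] = {
            "continuous": cmp_c.to_dict("records"),
            "ordinal": cmp_o.to_dict("records"),
        }
        table3[cname] = entry
    with open(outdir / "table3.json", "w") as fh:
        json.dump(_jsonable(table3), fh, indent=2, sort_keys=True)
    bundle["table3"] = table3

    # ---- heterogeneity -----------------------------------------------
    log.info("stage=heterogeneity")
    het_rows = []
    if len(cohorts) >= 2:
        datasets = {c: pair_tables[c][0] for c in cohorts}
        best_models = {table3[c]["continuous"]["best_model"] for c in cohorts}
        model = best_models.pop() if len(best_models) == 1 else "AE"
        omni = omnibus_test(datasets, model=model, kind="continuous",
                            covariates=config.covariates)
        het_rows.append(("cohort", omni.label, omni.statistic, omni.df, omni.p))
        if omni.p < config.alpha:
            for t in per_parameter_tests(datasets, model=model, kind="continuous",
                                         covariates=config.covariates):
                het_rows.append(("cohort", t.label, t.statistic, t.df, t.p))
    # sex heterogeneity: same-sex pairs only, if both strata are populated
    sex_sets = {}
    for sex in ("F", "M"):
        sub = cohort.data[
            (cohort.data["sex"] == sex)
            & (cohort.data["zygosity"].isin(["MZ", "DZ_SS"]))
        ]
        if sub["family_id"].nunique() >= 30:
            co = TwinCohort(sub.reset_index(drop=True), dict(cohort.trait_registry),
                            cohort.age_centered)
            sex_sets[sex] = pair_wide(co, trait, covariates=("age",))
    if len(sex_sets) == 2:
        omni = omnibus_test(sex_sets, model="AE", kind="continuous",
                            covariates=("age",))
        het_rows.append(("sex", omni.label, omni.statistic, omni.df, omni.p))
        if omni.p < config.alpha:
            for t in per_parameter_tests(sex_sets, model="AE", kind="continuous",
                                         covariates=("age",)):
                het_rows.append(("sex", t.label, t.statistic, t.df, t.p))
    het = pd.DataFrame(het_rows, columns=["split", "test", "statistic", "df", "p"])
    _fmt(het).to_csv(outdir / "heterogeneity.tsv", sep="\t", index=False)
    bundle["heterogeneity"] = het

    # ---- correlation screen + bivariate ------------------------------
    log.info("stage=bivariate")
    if config.secondary_traits == "auto":
        others = [t for t in cohort.traits
                  if t not in (trait, "sweet_status")]
    else:
        others = list(config.secondary_traits)
    biv_rows = []
    screens = []
    for cname, co in cohorts.items():
        if not others:
            break
        scr = correlation_screen(co, trait, others, alpha=config.alpha)
        scr.insert(0, "cohort", cname)
        screens.append(scr)
        for t in scr.loc[scr["selected"], "trait"]:
            pt2 = pair_wide(co, [trait, t], covariates=config.covariates)
            res = fit_bivariate(pt2, covariates=config.covariates)
            c = res.components
            biv_rows.append((cname, t, c.h2[1], c.e2[1], c.rp, c.rg, c.re,
                             res.boundary))
    screen = (pd.concat(screens, ignore_index=True) if screens
              else pd.DataFrame(columns=["cohort", "trait", "n", "r", "p",
                                         "selected"]))
    _fmt(screen).to_csv(outdir / "screen.tsv", sep="\t", index=False)
    table4 = pd.DataFrame(
        biv_rows,
        columns=["cohort", "trait", "h2_trait", "e2_trait", "rP", "rg", "re",
                 "boundary"],
    )
    _fmt(table4).to_csv(outdir / "table4.tsv", sep="\t", index=False)
    bundle["screen"] = screen
    bundle["table4"] = table4

    # ---- run log ------------------------------------------------------
    run_log = {
        "config": _jsonable(dataclasses.asdict(config)),
        "seed": config.seed,
        "versions": {
            "sweetwin": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    bundle["run_log"] = run_log
    log.info("stage=done outdir=%s", outdir)
    return bundle
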