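"""Multi-group twin models: sex and cohort heterogeneity tests.

A grouped fit maximizes the joint likelihood over several datasets (e.g.
cohorts) with a chosen set of parameters tied to equality across groups.
The omnibus test ties *all* parameters at once (df = (G-1) x P); on
rejection, per-parameter follow-ups tie one parameter at a time
(df = G-1 each), mirroring the sequential testing logic of multi-group
structural models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .univariate import (
    ContinuousObjective,
    OrdinalObjective,
    FitResult,
    LRTResult,
    _minimize_scaled,
    _optimize,
    _BIG,
)

__all__ = ["GroupedFit", "fit_grouped", "omnibus_test", "per_parameter_tests"]


def build_objective(pairs, kind: str, model: str, covariates=(), trait=None):
    if kind == "continuous":
        return ContinuousObjective(pairs, model, covariates, trait)
    if kind == "ordinal":
        return OrdinalObjective(pairs, model, covariates, trait)
    raise ValueError(f"unknown kind {kind!r}")


@dataclass
class GroupedFit:
    loglik: float
    n_free: int
    groups: dict  # group label -> param dict
    tied: frozenset
    param_names: tuple
    converged: bool
    group_fits: dict = field(default_factory=dict, repr=False)


def _layout(param_names, group_labels, tied):
    """Free-vector layout: one slot per tied name, else one per (name, group)."""
    slots = []
    index = {}  # (group, name) -> slot
    for name in param_names:
        if name in tied:
            slot = len(slots)
            slots.append((name, None))
            for g in group_labels:
                index[(g, name)] = slot
        else:
            for g in group_labels:
                index[(g, name)] = len(slots)
                slots.append((name, g))
    return slots, index


def fit_grouped(datasets: dict, model: str = "AE", kind: str = "continuous",
                covariates=(), tied=frozenset(), trait=None) -> GroupedFit:
    """Joint ML over groups with the listed parameter names tied to equality.

    ``datasets`` maps a group label to its :class:`PairTable`.  Unlisted
    parameters stay free per group; with no ties the joint fit decomposes
    into independent per-group fits.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two groups")
    labels = list(datasets)
    objs = {g: build_objective(datasets[g], kind, model, covariates, trait)
            for g in labels}
    names = objs[labels[0]].param_names
    for g in labels[1:]:
        if objs[g].param_names != names:
            raise ValueError("groups have mismatched parameter sets")
    tied = frozenset(tied)
    unknown = tied - set(names)
    if unknown:
        raise ValueError(f"constraints on unknown parameters: {sorted(unknown)}")

    single = {g: _optimize(objs[g]) for g in labels}
    slots, index = _layout(names, labels, tied)
    theta0 = np.empty(len(slots))
    for s, (name, g) in enumerate(slots):
        if g is None:
            theta0[s] = np.mean([single[lbl].params[name] for lbl in labels])
        else:
            theta0[s] = single[g].params[name]

    def split(theta):
        return {
            g: np.array([theta[index[(g, n)]] for n in names]) for g in labels
        }

    def joint_nll(theta):
        per = split(theta)
        return sum(objs[g].negloglik(per[g]) for g in labels)

    scale = np.empty(len(slots))
    for s, (name, g) in enumerate(slots):
        gs = labels[0] if g is None else g
        scale[s] = objs[gs].scale()[names.index(name)]
    res = _minimize_scaled(joint_nll, theta0, scale, maxiter=2000)
    if not tied:
        # independent fits are the exact joint optimum; use them if better
        indep = sum(-single[g].loglik for g in labels)
        if indep < res.fun:
            theta_best = np.empty(len(slots))
            for s, (name, g) in enumerate(slots):
                theta_best[s] = single[g].params[name]
            res.x, res.fun = theta_best, indep
    per = split(res.x)
    groups = {g: dict(zip(names, per[g])) for g in labels}
    return GroupedFit(
        loglik=-float(res.fun),
        n_free=len(slots),
        groups=groups,
        tied=tied,
        param_names=tuple(names),
        converged=bool(res.fun < _BIG),
        group_fits=single,
    )


def omnibus_test(datasets: dict, model: str = "AE", kind: str = "continuous",
                 covariates=(), trait=None) -> LRTResult:
    """All parameters tied across groups vs all free; df = (G-1) x P."""
    free = fit_grouped(datasets, model, kind, covariates, tied=frozenset(), trait=trait)
    tied = fit_grouped(datasets, model, kind, covariates,
                       tied=frozenset(free.param_names), trait=trait)
    df = free.n_free - tied.n_free
    stat = max(0.0, 2.0 * (free.loglik - tied.loglik))
    return LRTResult(statistic=stat, df=df, p=float(chi2.sf(stat, df)),
                     label="omnibus")


def per_parameter_tests(datasets: dict, model: str = "AE",
                        kind: str = "continuous", covariates=(),
                        trait=None) -> list[LRTResult]:
    """One LRT per parameter: that parameter tied alone, others free."""
    free = fit_grouped(datasets, model, kind, covariates, tied=frozenset(), trait=trait)
    out = []
    for name in free.param_names:
        tied = fit_grouped(datasets, model, kind, covariates,
                           tied=frozenset([name]), trait=trait)
        df = free.n_free - tied.n_free
        stat = max(0.0, 2.0 * (free.loglik - tied.loglik))
        out.append(LRTResult(statistic=stat, df=df, p=float(chi2.sf(stat, df)),
                             label=name))
    return out
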