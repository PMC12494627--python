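"""Univariate twin models by full-information maximum likelihood.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C), nonadditive genetic (D) and unique
environmental (E) sources.  Cross-twin correlations of the genetic deviates
are 1 (MZ) for both A and D, and 0.5 (A) / 0.25 (D) within DZ pairs; C is
perfectly shared and E independent.  With twins reared together C and D are
not jointly identified, so the model families are ACE, ADE and their
submodels AE, CE, DE, E.

Components are estimated under the *direct symmetric* parameterization:
free, unbounded real parameters (no Cholesky, no non-negativity).  This
avoids boundary-induced upward bias in the estimates and keeps likelihood
ratio tests on their nominal chi-square calibration.

Likelihood: complete pairs contribute bivariate normal densities with the
expected pair covariance; singleton twins contribute univariate marginals
(no imputation).  Ordinal (liability-threshold) fits constrain the latent
liability to mean 0 / variance 1, estimate two free thresholds shared
across zygosity, and let covariates shift the liability mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from .classify import status_codes, thresholds_from_proportions
from .data import PairTable
from .descriptives import bvn_rect
from ._profile import ProfileCI, profile_interval

__all__ = [
    "MODEL_COMPONENTS",
    "VarianceComponents",
    "FitResult",
    "LRTResult",
    "expected_pair_covariance",
    "fit_continuous",
    "fit_ordinal",
    "fit_saturated",
    "test_assumptions",
    "compare_models",
    "heritability",
    "profile_ci",
]

MODEL_COMPONENTS = {
    "ACE": ("A", "C", "E"),
    "ADE": ("A", "D", "E"),
    "AE": ("A", "E"),
    "CE": ("C", "E"),
    "DE": ("D", "E"),
    "E": ("E",),
}
#: cross-twin weights of each component's covariance contribution
GAMMA = {
    "MZ": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 0.0},
    "DZ": {"A": 0.5, "C": 1.0, "D": 0.25, "E": 0.0},
}

_BIG = 1e10


@dataclass
class VarianceComponents:
    """A/C/D/E variance components (absent components are 0)."""

    A: float = 0.0
    C: float = 0.0
    D: float = 0.0
    E: float = 0.0
    parameterization: str = "AE"

    def total(self) -> float:
        return self.A + self.C + self.D + self.E

    def pair_covariance(self, zygosity: str) -> float:
        g = GAMMA["MZ" if zygosity == "MZ" else "DZ"]
        return g["A"] * self.A + g["C"] * self.C + g["D"] * self.D


def expected_pair_covariance(vc: VarianceComponents, zygosity: str) -> np.ndarray:
    """Model-implied 2x2 covariance of a twin pair.

    Diagonal is the total variance A+C+D+E; the off-diagonal is A+C+D for MZ
    pairs and 0.5*A + C + 0.25*D for DZ pairs (same-sex and opposite-sex DZ
    share components — no sex limitation).
    """
    if zygosity not in ("MZ", "DZ", "DZ_SS", "DZ_OS"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    t = vc.total()
    c = vc.pair_covariance(zygosity)
    return np.array([[t, c], [c, t]])


@dataclass
class LRTResult:
    """Likelihood-ratio test: statistic = 2*(loglik_full - loglik_sub)."""

    statistic: float
    df: int
    p: float
    label: str = ""


@dataclass
class FitResult:
    loglik: float
    model: str
    kind: str  # continuous | ordinal | saturated
    params: dict
    n_free: int
    converged: bool
    gradient_norm: float
    n_complete: int
    n_single: int
    profile_cis: dict = field(default_factory=dict)
    _objective: object = field(default=None, repr=False)
    _theta: np.ndarray = field(default=None, repr=False)

    def components(self) -> VarianceComponents:
        comps = {k: self.params.get(k, 0.0) for k in ("A", "C", "D", "E")}
        if self.kind == "ordinal":
            comps["E"] = self.params.get(
                "E", 1.0 - sum(self.params.get(k, 0.0) for k in ("A", "C", "D"))
            )
        return VarianceComponents(parameterization=self.model, **comps)


# ----------------------------------------------------------------------
# data extraction
# ----------------------------------------------------------------------

class _PairArrays:
    """Per-zygosity-class complete-pair and singleton arrays with designs."""

    def __init__(self, pairs: PairTable, trait, covariates, ordinal=False,
                 intercept=True):
        trait = trait or pairs.traits[0]
        self.trait = trait
        self.covariates = tuple(covariates)
        f = pairs.frame
        if ordinal:
            y1 = status_codes(f[f"{trait}_1"])
            y2 = status_codes(f[f"{trait}_2"])
        else:
            y1 = f[f"{trait}_1"].to_numpy(float)
            y2 = f[f"{trait}_2"].to_numpy(float)
        cov1, cov2 = [], []
        for c in self.covariates:
            if f"{c}_1" not in f.columns:
                raise KeyError(f"covariate {c!r} not attached to the pair table")
            cov1.append(f[f"{c}_1"].to_numpy(float))
            cov2.append(f[f"{c}_2"].to_numpy(float))
        ones = np.ones(len(f))
        base = [ones] if intercept else []
        X1 = np.column_stack(base + cov1) if (base or cov1) else np.zeros((len(f), 0))
        X2 = np.column_stack(base + cov2) if (base or cov2) else np.zeros((len(f), 0))
        self.p = X1.shape[1]

        ok1 = np.isfinite(y1) & np.isfinite(X1).all(axis=1)
        ok2 = np.isfinite(y2) & np.isfinite(X2).all(axis=1)
        zcls = np.where(f["zygosity"].to_numpy() == "MZ", "MZ", "DZ")

        self.groups = {}
        for z in ("MZ", "DZ"):
            m = (zcls == z) & ok1 & ok2
            self.groups[z] = (
                np.column_stack([y1[m], y2[m]]),
                np.stack([X1[m], X2[m]], axis=1),  # (n, 2, p)
            )
        s1 = ok1 & ~ok2
        s2 = ok2 & ~ok1
        self.single_y = np.concatenate([y1[s1], y2[s2]])
        self.single_X = np.vstack([X1[s1], X2[s2]]) if self.p else np.zeros((s1.sum() + s2.sum(), 0))
        self.single_z = np.concatenate([zcls[s1], zcls[s2]])
        self.single_side = np.concatenate([np.ones(s1.sum(), int), 2 * np.ones(s2.sum(), int)])
        self.n_complete = sum(len(self.groups[z][0]) for z in self.groups)
        self.n_single = len(self.single_y)

    def pooled_moments(self):
        """Double-entry correlations per class, pooled variance, OLS betas."""
        ys, Xs = [], []
        corr = {}
        for z in ("MZ", "DZ"):
            Y, X = self.groups[z]
            if len(Y) >= 3:
                de1 = np.concatenate([Y[:, 0], Y[:, 1]])
                de2 = np.concatenate([Y[:, 1], Y[:, 0]])
                with np.errstate(invalid="ignore"):
                    corr[z] = float(np.corrcoef(de1, de2)[0, 1])
                if not np.isfinite(corr[z]):
                    corr[z] = 0.0
            else:
                corr[z] = 0.0
            ys.extend([Y[:, 0], Y[:, 1]])
            Xs.extend([X[:, 0, :], X[:, 1, :]])
        ys.append(self.single_y)
        Xs.append(self.single_X)
        y = np.concatenate(ys)
        X = np.vstack(Xs)
        if self.p:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        else:
            beta = np.zeros(0)
            resid = y
        var = float(np.var(resid, ddof=self.p)) if len(resid) > self.p else 1.0
        return corr.get("MZ", 0.0), corr.get("DZ", 0.0), max(var, 1e-12), beta


# ----------------------------------------------------------------------
# continuous objective
# ----------------------------------------------------------------------

class ContinuousObjective:
    kind = "continuous"

    def __init__(self, pairs: PairTable, model: str, covariates=(), trait=None):
        if model not in MODEL_COMPONENTS:
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.comp_names = MODEL_COMPONENTS[model]
        self.data = _PairArrays(pairs, trait, covariates, ordinal=False)
        self.param_names = (
            ["mu"]
            + [f"beta_{c}" for c in self.data.covariates]
            + list(self.comp_names)
        )
        self.n_free = len(self.param_names)
        rmz, rdz, var, beta = self.data.pooled_moments()
        self._moments = (rmz, rdz, var, beta)
        self.vscale = var

    def _components(self, theta):
        p = self.data.p
        comps = dict.fromkeys(("A", "C", "D", "E"), 0.0)
        for name, val in zip(self.comp_names, theta[p:]):
            comps[name] = float(val)
        return theta[: self.data.p], comps

    def negloglik(self, theta):
        theta = np.asarray(theta, float)
        beta, comps = self._components(theta)
        total = comps["A"] + comps["C"] + comps["D"] + comps["E"]
        vs = self.vscale
        bad = max(0.0, 1e-8 - total / vs)
        covs = {}
        for z in ("MZ", "DZ"):
            g = GAMMA[z]
            c = g["A"] * comps["A"] + g["C"] * comps["C"] + g["D"] * comps["D"]
            covs[z] = c
            bad += max(0.0, (abs(c) - total) / vs + 1e-8)
        if bad > 0:
            return _BIG * (1.0 + bad)
        nll = 0.0
        log2pi = np.log(2.0 * np.pi)
        for z in ("MZ", "DZ"):
            Y, X = self.data.groups[z]
            n = len(Y)
            if n == 0:
                continue
            c = covs[z]
            det = total * total - c * c
            mu1 = X[:, 0, :] @ beta
            mu2 = X[:, 1, :] @ beta
            r1 = Y[:, 0] - mu1
            r2 = Y[:, 1] - mu2
            quad = (total * r1 * r1 - 2.0 * c * r1 * r2 + total * r2 * r2) / det
            nll += n * log2pi + 0.5 * n * np.log(det) + 0.5 * quad.sum()
        if self.data.n_single:
            r = self.data.single_y - self.data.single_X @ beta
            nll += 0.5 * (
                self.data.n_single * (log2pi + np.log(total)) + (r * r).sum() / total
            )
        return float(nll)

    def starts(self):
        rmz, rdz, var, beta = self._moments
        out = []

        def mk(**kw):
            comp_vals = [kw.get(n, 0.0) for n in self.comp_names]
            out.append(np.concatenate([beta, comp_vals]))

        a2 = 2.0 * (rmz - rdz)  # Falconer moment start
        if self.model == "AE":
            mk(A=rmz * var, E=(1 - rmz) * var)
            mk(A=a2 * var, E=(1 - a2) * var)
        elif self.model == "ACE":
            mk(A=a2 * var, C=(2 * rdz - rmz) * var, E=(1 - rmz) * var)
        elif self.model == "ADE":
            mk(A=(4 * rdz - rmz) * var, D=2 * (rmz - 2 * rdz) * var, E=(1 - rmz) * var)
        elif self.model == "CE":
            mk(C=0.5 * (rmz + rdz) * var, E=(1 - 0.5 * (rmz + rdz)) * var)
        elif self.model == "DE":
            mk(D=rmz * var, E=(1 - rmz) * var)
        mk(E=var)  # E-only start
        mk(**{n: var / len(self.comp_names) for n in self.comp_names})
        # keep only starts inside the positive-definite region
        return [t for t in out if self.negloglik(t) < _BIG] or [out[-1]]

    def scale(self):
        s = np.ones(self.n_free)
        s[: self.data.p] = max(1.0, np.sqrt(self.vscale))
        s[self.data.p:] = max(1.0, self.vscale)
        return s


# ----------------------------------------------------------------------
# ordinal (liability-threshold) objective
# ----------------------------------------------------------------------

class OrdinalObjective:
    """Liability-threshold likelihood with standardized components.

    Free parameters: two thresholds, covariate slopes on the liability mean,
    and the non-E standardized components (E = 1 - sum, direct symmetric so
    any real value is admissible as long as implied pair correlations stay
    inside (-1, 1)).
    """

    kind = "ordinal"

    def __init__(self, pairs: PairTable, model: str, covariates=(), trait=None):
        if model not in MODEL_COMPONENTS:
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.free_comps = [c for c in MODEL_COMPONENTS[model] if c != "E"]
        self.data = _PairArrays(pairs, trait, covariates, ordinal=True, intercept=False)
        self.param_names = (
            ["tau1", "tau2"]
            + [f"beta_{c}" for c in self.data.covariates]
            + list(self.free_comps)
        )
        self.n_free = len(self.param_names)
        self._aggregate = self.data.p == 0
        if self._aggregate:
            self.tables = {}
            for z in ("MZ", "DZ"):
                Y, _ = self.data.groups[z]
                tab = np.zeros((3, 3))
                for i, j in zip(Y[:, 0].astype(int), Y[:, 1].astype(int)):
                    tab[i, j] += 1
                self.tables[z] = tab
            self.single_counts = np.bincount(
                self.data.single_y.astype(int), minlength=3
            ).astype(float)
        counts = np.zeros(3)
        for z in ("MZ", "DZ"):
            Y, _ = self.data.groups[z]
            counts += np.bincount(Y.astype(int).ravel(), minlength=3)
        counts += np.bincount(self.data.single_y.astype(int), minlength=3)
        self._marginal_counts = counts
        empty = counts == 0
        if empty.any() and counts.sum() > 0:
            raise ValueError(
                f"empty status category {np.flatnonzero(empty).tolist()}: "
                "threshold at infinity"
            )

    def _split(self, theta):
        theta = np.asarray(theta, float)
        tau = theta[:2]
        beta = theta[2 : 2 + self.data.p]
        comps = dict.fromkeys(("A", "C", "D"), 0.0)
        for name, val in zip(self.free_comps, theta[2 + self.data.p :]):
            comps[name] = float(val)
        return tau, beta, comps

    def _pair_corr(self, comps, z):
        g = GAMMA[z]
        return g["A"] * comps["A"] + g["C"] * comps["C"] + g["D"] * comps["D"]

    def negloglik(self, theta):
        tau, beta, comps = self._split(theta)
        bad = max(0.0, 1e-6 - (tau[1] - tau[0]))
        rs = {z: self._pair_corr(comps, z) for z in ("MZ", "DZ")}
        for r in rs.values():
            bad += max(0.0, abs(r) - 0.999)
        if bad > 0:
            return _BIG * (1.0 + bad)
        edges = np.array([-np.inf, tau[0], tau[1], np.inf])
        nll = 0.0
        if self._aggregate:
            lo1, lo2 = np.meshgrid(edges[:-1], edges[:-1], indexing="ij")
            hi1, hi2 = np.meshgrid(edges[1:], edges[1:], indexing="ij")
            for z in ("MZ", "DZ"):
                tab = self.tables[z]
                if tab.sum() == 0:
                    continue
                cell = np.clip(bvn_rect((lo1, lo2), (hi1, hi2), rs[z]), 1e-300, 1.0)
                nll -= float((tab * np.log(cell)).sum())
            if self.single_counts.sum():
                pk = np.clip(np.diff(norm.cdf(edges)), 1e-300, 1.0)
                nll -= float((self.single_counts * np.log(pk)).sum())
            return nll
        lo_edges = edges[:-1]
        hi_edges = edges[1:]
        for z in ("MZ", "DZ"):
            Y, X = self.data.groups[z]
            if len(Y) == 0:
                continue
            m1 = X[:, 0, :] @ beta
            m2 = X[:, 1, :] @ beta
            c1 = Y[:, 0].astype(int)
            c2 = Y[:, 1].astype(int)
            pr = bvn_rect(
                (lo_edges[c1] - m1, lo_edges[c2] - m2),
                (hi_edges[c1] - m1, hi_edges[c2] - m2),
                rs[z],
            )
            nll -= float(np.log(np.clip(pr, 1e-300, 1.0)).sum())
        if self.data.n_single:
            m = self.data.single_X @ beta
            c = self.data.single_y.astype(int)
            pr = norm.cdf(hi_edges[c] - m) - norm.cdf(lo_edges[c] - m)
            nll -= float(np.log(np.clip(pr, 1e-300, 1.0)).sum())
        return nll

    def starts(self):
        counts = self._marginal_counts
        props = counts / counts.sum()
        try:
            ts = thresholds_from_proportions(props)
            tau = [ts.tau1, ts.tau2]
        except ValueError:
            tau = [-0.43, 0.43]
        beta = np.zeros(self.data.p)
        out = []
        for a in (0.4, 0.2):
            comp_vals = []
            for name in self.free_comps:
                comp_vals.append(a if name == "A" else 0.1)
            out.append(np.concatenate([tau, beta, comp_vals]))
        out.append(np.concatenate([tau, beta, np.zeros(len(self.free_comps))]))
        return out

    def scale(self):
        return np.ones(self.n_free)


# ----------------------------------------------------------------------
# saturated model
# ----------------------------------------------------------------------

class SaturatedObjective:
    """Free means/variances per twin order and zygosity, free covariances.

    Constraint flags successively equate means across twin order, variances
    across order, means across zygosity and variances across zygosity —
    the assumption chain of the classical twin design.  Covariate slopes
    (no intercept; the group means play that role) are shared throughout.
    """

    kind = "saturated"

    def __init__(self, pairs: PairTable, covariates=(), trait=None,
                 eq_mean_order=False, eq_var_order=False,
                 eq_mean_zyg=False, eq_var_zyg=False):
        self.flags = (eq_mean_order, eq_var_order, eq_mean_zyg, eq_var_zyg)
        self.data = _PairArrays(pairs, trait, covariates, ordinal=False, intercept=False)
        self.model = "saturated"
        mean_names, var_names = [], []
        if eq_mean_zyg:
            mean_names = ["mu"]
        elif eq_mean_order:
            mean_names = ["mu_MZ", "mu_DZ"]
        else:
            mean_names = ["mu_MZ_1", "mu_MZ_2", "mu_DZ_1", "mu_DZ_2"]
        if eq_var_zyg:
            var_names = ["v"]
        elif eq_var_order:
            var_names = ["v_MZ", "v_DZ"]
        else:
            var_names = ["v_MZ_1", "v_MZ_2", "v_DZ_1", "v_DZ_2"]
        self.mean_names, self.var_names = mean_names, var_names
        self.param_names = (
            mean_names + var_names + ["c_MZ", "c_DZ"]
            + [f"beta_{c}" for c in self.data.covariates]
        )
        self.n_free = len(self.param_names)
        self._idx = {n: i for i, n in enumerate(self.param_names)}
        _, _, var, beta = self.data.pooled_moments()
        self.vscale = var
        self._beta0 = beta

    def _lookup(self, theta, base, z, j):
        idx = self._idx
        for key in (f"{base}_{z}_{j}", f"{base}_{z}", base):
            if key in idx:
                return theta[idx[key]]
        raise KeyError(base)

    def negloglik(self, theta):
        theta = np.asarray(theta, float)
        p = self.data.p
        beta = theta[self.n_free - p:] if p else np.zeros(0)
        vs = self.vscale
        bad = 0.0
        params = {}
        for z in ("MZ", "DZ"):
            v1 = self._lookup(theta, "v", z, 1)
            v2 = self._lookup(theta, "v", z, 2)
            c = theta[self._idx[f"c_{z}"]]
            det = v1 * v2 - c * c
            bad += max(0.0, 1e-8 - v1 / vs) + max(0.0, 1e-8 - v2 / vs)
            bad += max(0.0, 1e-8 - det / (vs * vs))
            params[z] = (v1, v2, c, det)
        if bad > 0:
            return _BIG * (1.0 + bad)
        log2pi = np.log(2.0 * np.pi)
        nll = 0.0
        for z in ("MZ", "DZ"):
            Y, X = self.data.groups[z]
            n = len(Y)
            if n == 0:
                continue
            v1, v2, c, det = params[z]
            mu1 = self._lookup(theta, "mu", z, 1) + (X[:, 0, :] @ beta if p else 0.0)
            mu2 = self._lookup(theta, "mu", z, 2) + (X[:, 1, :] @ beta if p else 0.0)
            r1 = Y[:, 0] - mu1
            r2 = Y[:, 1] - mu2
            quad = (v2 * r1 * r1 - 2.0 * c * r1 * r2 + v1 * r2 * r2) / det
            nll += n * log2pi + 0.5 * n * np.log(det) + 0.5 * quad.sum()
        for yi, xi, z, side in zip(
            self.data.single_y, self.data.single_X, self.data.single_z,
            self.data.single_side,
        ):
            v = self._lookup(theta, "v", z, side)
            mu = self._lookup(theta, "mu", z, side) + (float(xi @ beta) if p else 0.0)
            nll += 0.5 * (log2pi + np.log(v) + (yi - mu) ** 2 / v)
        return float(nll)

    def starts(self):
        theta = np.zeros(self.n_free)
        for z in ("MZ", "DZ"):
            Y, _ = self.data.groups[z]
            m = Y.mean(axis=0) if len(Y) else np.zeros(2)
            v = Y.var(axis=0) if len(Y) > 1 else np.ones(2) * self.vscale
            cv = float(np.cov(Y.T)[0, 1]) if len(Y) > 1 else 0.0
            for j in (1, 2):
                for key in (f"mu_{z}_{j}", f"mu_{z}", "mu"):
                    if key in self._idx:
                        theta[self._idx[key]] = m[j - 1]
                        break
                for key in (f"v_{z}_{j}", f"v_{z}", "v"):
                    if key in self._idx:
                        theta[self._idx[key]] = max(v[j - 1], 1e-6)
                        break
            theta[self._idx[f"c_{z}"]] = cv
        if self.data.p:
            theta[-self.data.p:] = self._beta0
        return [theta]

    def scale(self):
        s = np.ones(self.n_free)
        for name, i in self._idx.items():
            if name.startswith("v") or name.startswith("c_"):
                s[i] = max(1.0, self.vscale)
            elif name.startswith("mu"):
                s[i] = max(1.0, np.sqrt(self.vscale))
        return s


# ----------------------------------------------------------------------
# optimization driver
# ----------------------------------------------------------------------

def _minimize_scaled(fun, x0, scale, maxiter=1000):
    """L-BFGS-B in scale-free coordinates (theta = scale * x)."""
    scale = np.asarray(scale, float)

    def f(x):
        return fun(x * scale)

    res = minimize(
        f,
        np.asarray(x0, float) / scale,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9, "eps": 1e-8},
    )
    res.x = res.x * scale
    return res


def _optimize(obj, starts=None) -> FitResult:
    starts = starts if starts is not None else obj.starts()
    scale = obj.scale() if hasattr(obj, "scale") else np.ones(obj.n_free)
    best = None
    for th0 in starts:
        res = _minimize_scaled(obj.negloglik, th0, scale)
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= _BIG:  # every start trapped in the penalty region
        res = minimize(obj.negloglik, starts[0], method="Nelder-Mead",
                       options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8})
        if res.fun < best.fun:
            best = res
    jac = getattr(best, "jac", None)
    if jac is None:
        gnorm = np.nan
    else:
        gnorm = float(np.max(np.abs(jac)) / max(1.0, abs(best.fun)))
    converged = bool(best.fun < _BIG and (np.isnan(gnorm) or gnorm < 1e-5 * 100))
    params = dict(zip(obj.param_names, np.asarray(best.x, float)))
    if obj.kind == "ordinal":
        params["E"] = 1.0 - sum(
            params.get(k, 0.0) for k in ("A", "C", "D") if k in params
        )
    return FitResult(
        loglik=-float(best.fun),
        model=obj.model,
        kind=obj.kind,
        params=params,
        n_free=obj.n_free,
        converged=converged,
        gradient_norm=gnorm,
        n_complete=obj.data.n_complete,
        n_single=obj.data.n_single,
        _objective=obj,
        _theta=np.asarray(best.x, float),
    )


def fit_continuous(pairs: PairTable, model: str = "AE", covariates=(),
                   trait=None) -> FitResult:
    """FIML fit of a continuous twin model (direct symmetric components)."""
    return _optimize(ContinuousObjective(pairs, model, covariates, trait))


def fit_ordinal(pairs: PairTable, model: str = "AE", covariates=(),
                trait=None) -> FitResult:
    """FIML fit of the liability-threshold twin model to 3-category status."""
    return _optimize(OrdinalObjective(pairs, model, covariates, trait))


def fit_saturated(pairs: PairTable, covariates=(), trait=None) -> FitResult:
    """Saturated model: free means/variances per twin order x zygosity."""
    return _optimize(SaturatedObjective(pairs, covariates, trait))


_ASSUMPTION_CHAIN = (
    ("equal means across twin order", dict(eq_mean_order=True)),
    ("equal variances across twin order", dict(eq_mean_order=True, eq_var_order=True)),
    ("equal means across zygosity",
     dict(eq_mean_order=True, eq_var_order=True, eq_mean_zyg=True)),
    ("equal variances across zygosity",
     dict(eq_mean_order=True, eq_var_order=True, eq_mean_zyg=True, eq_var_zyg=True)),
)


def test_assumptions(pairs: PairTable, covariates=(), trait=None) -> list[LRTResult]:
    """Sequential assumption tests against increasingly restricted saturated models.

    Each step equates one further set of parameters (means across twin
    order, variances across order, means across zygosity, variances across
    zygosity) and is tested against the previous model by LRT; a small p
    flags an assumption violation.
    """
    prev = fit_saturated(pairs, covariates, trait)
    out = []
    for label, flags in _ASSUMPTION_CHAIN:
        cur = _optimize(SaturatedObjective(pairs, covariates, trait, **flags))
        lrt = compare_models(prev, cur)
        lrt.label = label
        out.append(lrt)
        prev = cur
    return out


def compare_models(full: FitResult, sub: FitResult) -> LRTResult:
    """Likelihood-ratio test of a nested submodel against a fuller model."""
    df = full.n_free - sub.n_free
    if df <= 0:
        raise ValueError("sub must have fewer free parameters than full")
    stat = 2.0 * (full.loglik - sub.loglik)
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic {stat:.3g}: models not nested or not converged"
        )
    stat = max(stat, 0.0)
    return LRTResult(statistic=float(stat), df=df, p=float(chi2.sf(stat, df)))


def heritability(fit: FitResult) -> dict:
    """Standardized variance shares (h2, c2/d2, e2) and the total variance.

    Ordinal fits are already on the unit liability scale, so the shares are
    the components themselves.
    """
    vc = fit.components()
    total = vc.total()
    if total <= 0:
        raise ValueError(f"non-positive total variance {total}")
    out = {"h2": vc.A / total, "e2": vc.E / total, "total": total}
    if fit.model in ("ACE", "CE"):
        out["c2"] = vc.C / total
    if fit.model in ("ADE", "DE"):
        out["d2"] = vc.D / total
    return out


# ----------------------------------------------------------------------
# profile-likelihood confidence intervals
# ----------------------------------------------------------------------

def _quantity_fn(fit: FitResult, param: str):
    obj = fit._objective
    names = obj.param_names
    if param in names:
        i = names.index(param)
        return lambda th: th[i]
    comp_idx = {n: names.index(n) for n in ("A", "C", "D", "E") if n in names}

    if fit.kind == "ordinal":
        if param == "h2":
            i = comp_idx.get("A")
            if i is None:
                raise KeyError("model has no A component")
            return lambda th: th[i]
        if param == "e2":
            idxs = list(comp_idx.values())
            return lambda th: 1.0 - sum(th[i] for i in idxs)
        raise KeyError(f"unknown profile quantity {param!r}")

    idxs = list(comp_idx.values())
    if param in ("total", "total_variance"):
        return lambda th: sum(th[i] for i in idxs)
    if param == "h2":
        ia = comp_idx.get("A")
        if ia is None:
            raise KeyError("model has no A component")
        return lambda th: th[ia] / sum(th[i] for i in idxs)
    if param == "e2":
        ie = comp_idx["E"]
        return lambda th: th[ie] / sum(th[i] for i in idxs)
    raise KeyError(f"unknown profile quantity {param!r}")


def profile_ci(fit: FitResult, param: str, level: float = 0.95) -> ProfileCI:
    """Profile-likelihood CI for a raw parameter or standardized quantity.

    Bounds solve 2*(loglik_hat - loglik_profile(v)) = chi2_1(level), found by
    outward bracketing and bisection to 1e-4 of the parameter scale.
    Standardized quantities (``h2``, ``e2``, ``total``) are profiled on their
    own scale via constrained refits.
    """
    if fit._objective is None:
        raise ValueError("fit carries no objective; cannot profile")
    ci = profile_interval(
        fit._objective.negloglik, fit._theta, _quantity_fn(fit, param), level=level
    )
    fit.profile_cis[param] = ci
    return ci
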