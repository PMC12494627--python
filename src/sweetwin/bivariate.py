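"""Bivariate AE twin models: genetic and environmental correlation decomposition.

For two continuous traits the phenotypic correlation decomposes as

    rP = rg * sqrt(h2_1 * h2_2) + re * sqrt(e2_1 * e2_2)

where rg = A12 / sqrt(A1*A2) is the additive-genetic correlation and
re = E12 / sqrt(E1*E2) the unique-environment correlation.  The fit is FIML
over the 4-variate normal per pair (twin1 trait1, twin1 trait2, twin2
trait1, twin2 trait2): cross-twin cross-trait covariance is A12 (MZ) or
0.5*A12 (DZ); the within-person cross-trait covariance is A12 + E12.  All
six components are free (direct symmetric).  Pairs with any missing slot
contribute the marginal normal of their observed entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PairTable
from .univariate import ContinuousObjective, FitResult, _BIG, _minimize_scaled
from ._profile import ProfileCI, profile_interval

__all__ = ["BivariateComponents", "BivariateResult", "fit_bivariate",
           "decompose_correlation"]


def decompose_correlation(h2_1, e2_1, h2_2, e2_2, rg, re) -> float:
    """Phenotypic correlation implied by standardized bivariate components."""
    for name, v in [("h2_1", h2_1), ("e2_1", e2_1), ("h2_2", h2_2), ("e2_2", e2_2)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if abs(h2_1 + e2_1 - 1.0) > 1e-6 or abs(h2_2 + e2_2 - 1.0) > 1e-6:
        raise ValueError("standardized components must satisfy h2 + e2 = 1")
    if abs(rg) > 1.0 or abs(re) > 1.0:
        raise ValueError("correlations must lie in [-1, 1]")
    return float(rg * np.sqrt(h2_1 * h2_2) + re * np.sqrt(e2_1 * e2_2))


@dataclass
class BivariateComponents:
    A1: float
    E1: float
    A2: float
    E2: float
    A12: float
    E12: float

    @property
    def totals(self) -> tuple[float, float]:
        return (self.A1 + self.E1, self.A2 + self.E2)

    @property
    def h2(self) -> tuple[float, float]:
        t1, t2 = self.totals
        return (self.A1 / t1, self.A2 / t2)

    @property
    def e2(self) -> tuple[float, float]:
        t1, t2 = self.totals
        return (self.E1 / t1, self.E2 / t2)

    @property
    def rg(self) -> float:
        d = self.A1 * self.A2
        return float(self.A12 / np.sqrt(d)) if d > 0 else np.nan

    @property
    def re(self) -> float:
        d = self.E1 * self.E2
        return float(self.E12 / np.sqrt(d)) if d > 0 else np.nan

    @property
    def rp(self) -> float:
        t1, t2 = self.totals
        return float((self.A12 + self.E12) / np.sqrt(t1 * t2))


@dataclass
class BivariateResult:
    components: BivariateComponents
    fit: FitResult
    boundary: bool = False
    profile_cis: dict = field(default_factory=dict)


class BivariateObjective:
    kind = "bivariate"
    model = "AE"

    _COMP_NAMES = ("A1", "E1", "A2", "E2", "A12", "E12")

    def __init__(self, pairs: PairTable, covariates=(), traits=None):
        traits = tuple(traits or pairs.traits)
        if len(traits) != 2:
            raise ValueError("need exactly two traits")
        self.traits = traits
        self.covariates = tuple(covariates)
        f = pairs.frame
        # slot order: twin1/trait1, twin1/trait2, twin2/trait1, twin2/trait2
        Y = np.column_stack([
            f[f"{traits[0]}_1"].to_numpy(float),
            f[f"{traits[1]}_1"].to_numpy(float),
            f[f"{traits[0]}_2"].to_numpy(float),
            f[f"{traits[1]}_2"].to_numpy(float),
        ])
        ones = np.ones(len(f))
        X_by_twin = []
        for j in (1, 2):
            cols = [ones]
            for c in self.covariates:
                cols.append(f[f"{c}_{j}"].to_numpy(float))
            X_by_twin.append(np.column_stack(cols))
        self.p = 1 + len(self.covariates)
        # design per slot: trait of slot decides which beta block applies
        self.X = [X_by_twin[0], X_by_twin[0], X_by_twin[1], X_by_twin[1]]
        self.slot_trait = (0, 1, 0, 1)
        cov_ok = [np.isfinite(x).all(axis=1) for x in X_by_twin]
        obs = np.isfinite(Y)
        obs[:, 0] &= cov_ok[0]
        obs[:, 1] &= cov_ok[0]
        obs[:, 2] &= cov_ok[1]
        obs[:, 3] &= cov_ok[1]
        zcls = np.where(f["zygosity"].to_numpy() == "MZ", "MZ", "DZ")
        keep = obs.any(axis=1)
        Y, obs, zcls = Y[keep], obs[keep], zcls[keep]
        self.Xk = [x[keep] for x in self.X]
        self.patterns = []
        for z in ("MZ", "DZ"):
            zm = zcls == z
            if not zm.any():
                continue
            pats = {}
            for i in np.flatnonzero(zm):
                key = tuple(obs[i])
                pats.setdefault(key, []).append(i)
            for key, idx in pats.items():
                idx = np.array(idx)
                slots = np.flatnonzero(np.array(key))
                Ys = Y[np.ix_(idx, slots)]
                Xs = [self.Xk[s][idx] for s in slots]
                self.patterns.append((z, slots, Ys, Xs))
        self.n_complete = int((obs.sum(axis=1) == 4).sum())
        self.n_partial = int(((obs.sum(axis=1) < 4)).sum())
        self.param_names = (
            [f"{b}_{t}" for t in traits for b in
             (["mu"] + [f"beta_{c}" for c in self.covariates])]
        )
        # flatten: first trait block then second
        self.param_names = (
            [f"mu_{traits[0]}"] + [f"beta_{c}_{traits[0]}" for c in self.covariates]
            + [f"mu_{traits[1]}"] + [f"beta_{c}_{traits[1]}" for c in self.covariates]
            + list(self._COMP_NAMES)
        )
        self.n_free = len(self.param_names)
        # moment scales
        self.vscale = [max(np.nanvar(Y[:, [0, 2]]), 1e-12),
                       max(np.nanvar(Y[:, [1, 3]]), 1e-12)]
        self._pairs = pairs

    def _sigma(self, comps, z):
        A1, E1, A2, E2, A12, E12 = comps
        W = np.array([[A1 + E1, A12 + E12], [A12 + E12, A2 + E2]])
        g = 1.0 if z == "MZ" else 0.5
        G = g * np.array([[A1, A12], [A12, A2]])
        return np.block([[W, G], [G, W]])

    def negloglik(self, theta):
        theta = np.asarray(theta, float)
        b1 = theta[: self.p]
        b2 = theta[self.p: 2 * self.p]
        comps = theta[2 * self.p:]
        betas = (b1, b2)
        sig = {z: self._sigma(comps, z) for z in ("MZ", "DZ")}
        bad = 0.0
        for z in ("MZ", "DZ"):
            ev = np.linalg.eigvalsh(sig[z])
            vs = np.sqrt(self.vscale[0] * self.vscale[1])
            if ev[0] <= 1e-10 * vs:
                bad += (1e-10 * vs - ev[0]) / vs
        if bad > 0:
            return _BIG * (1.0 + bad)
        log2pi = np.log(2.0 * np.pi)
        nll = 0.0
        for z, slots, Ys, Xs in self.patterns:
            sub = sig[z][np.ix_(slots, slots)]
            sign, logdet = np.linalg.slogdet(sub)
            if sign <= 0:
                return _BIG
            mu = np.column_stack([
                Xs[j] @ betas[self.slot_trait[s]] for j, s in enumerate(slots)
            ])
            R = Ys - mu
            sol = np.linalg.solve(sub, R.T).T
            quad = np.einsum("ij,ij->i", R, sol)
            n, k = R.shape
            nll += 0.5 * (n * (k * log2pi + logdet) + quad.sum())
        return float(nll)

    def starts(self):
        # univariate AE moment fits per trait + cross moments
        uni = []
        for t in self.traits:
            obj = ContinuousObjective(self._pairs, "AE", self.covariates, trait=t)
            rmz, rdz, var, beta = obj._moments
            uni.append((max(min(rmz, 0.95), -0.5) * var, var, beta))
        (A1, V1, beta1), (A2, V2, beta2) = uni
        # within-person cross covariance from residual-ish raw values
        f = self._pairs.frame
        x = np.concatenate([f[f"{self.traits[0]}_1"], f[f"{self.traits[0]}_2"]])
        y = np.concatenate([f[f"{self.traits[1]}_1"], f[f"{self.traits[1]}_2"]])
        ok = np.isfinite(x) & np.isfinite(y)
        cw = float(np.cov(x[ok], y[ok])[0, 1]) if ok.sum() > 2 else 0.0
        cw *= 0.9  # shrink toward independence so starts stay positive definite
        starts = []
        for fgen in (0.5, 0.0):
            comps = [A1, V1 - A1, A2, V2 - A2, fgen * cw, (1 - fgen) * cw]
            starts.append(np.concatenate([beta1, beta2, comps]))
        return starts

    def sample_cross_correlation(self) -> float:
        """Raw within-person cross-trait correlation (degeneracy guard)."""
        f = self._pairs.frame
        x = np.concatenate([f[f"{self.traits[0]}_1"], f[f"{self.traits[0]}_2"]])
        y = np.concatenate([f[f"{self.traits[1]}_1"], f[f"{self.traits[1]}_2"]])
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            return 0.0
        return float(np.corrcoef(x[ok], y[ok])[0, 1])

    def scale(self):
        s = np.ones(self.n_free)
        s[: self.p] = max(1.0, np.sqrt(self.vscale[0]))
        s[self.p: 2 * self.p] = max(1.0, np.sqrt(self.vscale[1]))
        v12 = np.sqrt(self.vscale[0] * self.vscale[1])
        s[2 * self.p:] = np.array([
            max(1.0, self.vscale[0]), max(1.0, self.vscale[0]),
            max(1.0, self.vscale[1]), max(1.0, self.vscale[1]),
            max(1.0, v12), max(1.0, v12),
        ])
        return s


def fit_bivariate(pairs: PairTable, covariates=(), traits=None) -> BivariateResult:
    """FIML bivariate AE fit returning components and correlation decomposition."""
    obj = BivariateObjective(pairs, covariates, traits)
    best = None
    for th0 in obj.starts():
        res = _minimize_scaled(obj.negloglik, th0, obj.scale(), maxiter=2000)
        if best is None or res.fun < best.fun:
            best = res
    theta = np.asarray(best.x, float)
    params = dict(zip(obj.param_names, theta))
    comps = BivariateComponents(*[params[n] for n in obj._COMP_NAMES])
    # boundary: the MLE sits at (or the data imply) a singular covariance,
    # where the penalty keeps the optimizer away and estimates are unreliable
    t1, t2 = comps.totals
    boundary = bool(
        min(t1, t2) <= 0
        or abs(comps.rp) >= 1 - 1e-4
        or (np.isfinite(comps.rg) and abs(comps.rg) >= 1 - 1e-4)
        or abs(obj.sample_cross_correlation()) >= 0.999
    )
    fit = FitResult(
        loglik=-float(best.fun),
        model="AE-bivariate",
        kind="bivariate",
        params=params,
        n_free=obj.n_free,
        converged=bool(best.fun < _BIG),
        gradient_norm=float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan,
        n_complete=obj.n_complete,
        n_single=obj.n_partial,
        _objective=obj,
        _theta=theta,
    )
    return BivariateResult(components=comps, fit=fit, boundary=boundary)


def _corr_quantity(obj: BivariateObjective, which: str):
    i0 = 2 * obj.p

    def fn(th):
        A1, E1, A2, E2, A12, E12 = th[i0: i0 + 6]
        if which == "rg":
            return A12 / np.sqrt(max(A1 * A2, 1e-12))
        if which == "re":
            return E12 / np.sqrt(max(E1 * E2, 1e-12))
        if which == "rp":
            return (A12 + E12) / np.sqrt(max((A1 + E1) * (A2 + E2), 1e-12))
        raise KeyError(which)

    return fn


def profile_ci_bivariate(result: BivariateResult, which: str,
                         level: float = 0.95) -> ProfileCI:
    """Profile CI for rg, re or rp on the correlation scale."""
    obj = result.fit._objective
    ci = profile_interval(obj.negloglik, result.fit._theta,
                          _corr_quantity(obj, which), level=level)
    result.profile_cis[which] = ci
    return ci
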