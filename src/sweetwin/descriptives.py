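"""Twin-pair resemblance statistics and the phenotype correlation screen.

Continuous traits get a double-entry Pearson intraclass correlation (each
family contributes (x1, x2) and (x2, x1), removing the arbitrary twin
ordering).  Ordinal sweet-liking status gets a polychoric correlation: the
latent-normal correlation maximizing the multinomial likelihood of the
double-entered 3x3 contingency table, with thresholds fixed at the margins
(two-step estimator).

The numerical kernel :func:`bvn_rect` — standard bivariate normal rectangle
masses — is shared with the ordinal twin likelihood.  It is built on Owen's
T function, which is accurate to near machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import owens_t
from scipy.stats import norm, pearsonr

from .classify import STATUS_ORDER, status_codes
from .data import PairTable

__all__ = [
    "CorrelationEstimate",
    "bvn_cdf",
    "bvn_rect",
    "intraclass_pearson",
    "polychoric",
    "polychoric_from_table",
    "correlation_screen",
]


@dataclass
class CorrelationEstimate:
    r: float
    n_pairs: int
    method: str
    ci: tuple | None = None  # 95% CI (Pearson)
    se: float | None = None  # standard error (polychoric)
    boundary: bool = False


# ----------------------------------------------------------------------
# bivariate normal kernel
# ----------------------------------------------------------------------

def _phi2_finite(h, k, rho: float):
    """P(X<=h, Y<=k) for standard bivariate normal, finite h, k, |rho|<1.

    Owen (1956): Phi2 = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - beta with
    a_h = (k - rho*h)/(h*sqrt(1-rho^2)) and beta = 1/2 iff h*k < 0 (or one of
    them is 0 with h+k < 0).  Exact zeros are nudged by +1e-13, which is far
    below the 1e-8 accuracy contract (Phi2 is continuous there).
    """
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    denom = np.sqrt(1.0 - rho * rho)
    hs = np.where(h == 0.0, 1e-13, h)
    ks = np.where(k == 0.0, 1e-13, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = (ks / hs - rho) / denom
        ak = (hs / ks - rho) / denom
    beta = np.where(hs * ks < 0.0, 0.5, 0.0)
    val = 0.5 * (norm.cdf(h) + norm.cdf(k)) - owens_t(hs, ah) - owens_t(ks, ak) - beta
    return np.clip(val, 0.0, 1.0)


def bvn_cdf(h, k, rho: float):
    """P(X<=h, Y<=k) for a standard bivariate normal with correlation rho.

    Vectorized in ``h`` and ``k``; infinite limits allowed.
    """
    h, k = np.broadcast_arrays(np.asarray(h, float), np.asarray(k, float))
    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            val = np.minimum(norm.cdf(h), norm.cdf(k))
        else:
            val = np.maximum(norm.cdf(h) + norm.cdf(k) - 1.0, 0.0)
        return val if val.shape else float(val)
    neg = np.isneginf(h) | np.isneginf(k)
    h_inf = np.isposinf(h)
    k_inf = np.isposinf(k)
    hf = np.where(np.isfinite(h), h, 0.0)
    kf = np.where(np.isfinite(k), k, 0.0)
    val = _phi2_finite(hf, kf, rho)
    val = np.where(h_inf & k_inf, 1.0, val)
    val = np.where(h_inf & ~k_inf, norm.cdf(kf), val)
    val = np.where(k_inf & ~h_inf, norm.cdf(hf), val)
    val = np.where(neg, 0.0, val)
    return val if val.shape else float(val)


def bvn_rect(lower, upper, rho: float):
    """Standard bivariate normal mass over the rectangle [lower, upper].

    ``lower`` and ``upper`` are (x, y) pairs of scalars or arrays; +/-inf
    limits are allowed and degenerate rectangles return 0.  Absolute error
    is far below 1e-8 (Owen's T based).
    """
    l1, l2 = lower
    u1, u2 = upper
    l1, l2, u1, u2 = np.broadcast_arrays(
        np.asarray(l1, float), np.asarray(l2, float),
        np.asarray(u1, float), np.asarray(u2, float),
    )
    val = (
        bvn_cdf(u1, u2, rho)
        - bvn_cdf(l1, u2, rho)
        - bvn_cdf(u1, l2, rho)
        + bvn_cdf(l1, l2, rho)
    )
    val = np.where((u1 <= l1) | (u2 <= l2), 0.0, np.clip(val, 0.0, 1.0))
    return val if val.shape else float(val)


# ----------------------------------------------------------------------
# intraclass (twin-pair) correlations
# ----------------------------------------------------------------------

def intraclass_pearson(pairs: PairTable, trait: str | None = None) -> CorrelationEstimate:
    """Double-entry Pearson intraclass correlation with a Fisher-z 95% CI.

    The effective sample size for the CI is the number of complete pairs,
    not the doubled count.
    """
    y1, y2 = pairs.values(trait)
    ok = np.isfinite(y1) & np.isfinite(y2)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >=3 complete pairs (got {n})")
    x = np.concatenate([y1[ok], y2[ok]])
    y = np.concatenate([y2[ok], y1[ok]])
    if np.std(x) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    ci = None
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        hw = norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    return CorrelationEstimate(r=r, n_pairs=n, method="pearson", ci=ci)


# ----------------------------------------------------------------------
# polychoric correlation
# ----------------------------------------------------------------------

RHO_BOUND = 0.999


def polychoric_from_table(counts) -> CorrelationEstimate:
    """Two-step polychoric correlation from a twin1 x twin2 category table.

    The table is symmetrized by double entry; thresholds come from the
    double-entered margins, then the latent correlation maximizes the
    multinomial likelihood whose cells are bivariate-normal rectangle
    masses.  SE from the observed curvature at the optimum; the estimate is
    clipped to +/-0.999 with a boundary flag.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1] or counts.shape[0] > 3:
        raise ValueError("need a square category table of size <= 3")
    if np.any(counts < 0) or counts.sum() == 0:
        raise ValueError("invalid contingency table")
    sym = 0.5 * (counts + counts.T)  # double entry, kept on the n-pairs scale
    n = sym.sum()
    margins = sym.sum(axis=1)
    keep = margins > 0
    if keep.sum() < 2:
        # all mass in one category: latent correlation unidentified
        return CorrelationEstimate(
            r=np.nan, n_pairs=int(round(n)), method="polychoric", boundary=True
        )
    sym = sym[np.ix_(keep, keep)]
    margins = margins[keep]
    p = margins / margins.sum()
    cuts = norm.ppf(np.cumsum(p)[:-1])
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    k = len(margins)
    lo1, lo2 = np.meshgrid(edges[:-1], edges[:-1], indexing="ij")
    hi1, hi2 = np.meshgrid(edges[1:], edges[1:], indexing="ij")

    def negll(rho):
        cell = bvn_rect((lo1, lo2), (hi1, hi2), float(rho))
        cell = np.clip(cell, 1e-300, 1.0)
        return -float((sym * np.log(cell)).sum())

    res = minimize_scalar(negll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-8})
    rho = float(res.x)
    boundary = abs(rho) >= RHO_BOUND - 1e-4
    # degenerate concordant tables push to the boundary; report the clip
    if boundary:
        rho = float(np.sign(rho) * RHO_BOUND)
        return CorrelationEstimate(
            r=rho, n_pairs=int(round(n)), method="polychoric", boundary=True
        )
    h = 1e-4
    curv = (negll(rho + h) - 2.0 * negll(rho) + negll(rho - h)) / (h * h)
    se = float(1.0 / np.sqrt(curv)) if curv > 0 else None
    return CorrelationEstimate(
        r=rho, n_pairs=int(round(n)), method="polychoric", se=se
    )


def contingency_table(pairs: PairTable, trait: str | None = None) -> np.ndarray:
    """3x3 twin1 x twin2 status count table over complete pairs."""
    trait = trait or pairs.traits[0]
    c1 = status_codes(pairs.frame[f"{trait}_1"])
    c2 = status_codes(pairs.frame[f"{trait}_2"])
    ok = np.isfinite(c1) & np.isfinite(c2)
    tab = np.zeros((3, 3))
    for i, j in zip(c1[ok].astype(int), c2[ok].astype(int)):
        tab[i, j] += 1
    return tab


def polychoric(pairs: PairTable, trait: str | None = None) -> CorrelationEstimate:
    """Polychoric twin-pair correlation of an ordinal status trait."""
    return polychoric_from_table(contingency_table(pairs, trait))


# ----------------------------------------------------------------------
# phenotype correlation screen
# ----------------------------------------------------------------------

def correlation_screen(cohort, focal: str, others, alpha: float = 0.05) -> pd.DataFrame:
    """Individual-level Pearson screen of candidate traits against ``focal``.

    Returns a DataFrame (trait, n, r, p, selected) with ``selected = p < alpha``
    and no multiplicity correction.  Constant traits are excluded with a
    warning.  Pair non-independence is deliberately ignored (the screen is a
    selection device, not an inferential endpoint).
    """
    if focal not in cohort.trait_registry:
        raise KeyError(f"unknown trait {focal!r}")
    x_all = cohort.data[focal].to_numpy(float)
    rows = []
    for t in others:
        if t not in cohort.trait_registry:
            raise KeyError(f"unknown trait {t!r}")
        y_all = cohort.data[t].to_numpy(float)
        ok = np.isfinite(x_all) & np.isfinite(y_all)
        n = int(ok.sum())
        if n < 3 or np.std(y_all[ok]) == 0 or np.std(x_all[ok]) == 0:
            warnings.warn(f"trait {t!r} constant or too sparse; excluded from screen")
            continue
        x, y = x_all[ok], y_all[ok]
        if t == focal:
            r, p = 1.0, 0.0
        else:
            r, p = pearsonr(x, y)
        rows.append((t, n, float(r), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["trait", "n", "r", "p", "selected"])
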