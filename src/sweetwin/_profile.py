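"""Profile-likelihood confidence intervals for smooth scalar quantities.

Given a fitted negative log-likelihood and a scalar quantity g(theta), the
profile deviance at value v is 2*(min_nll(g=v) - nll_hat).  The CI bound at
level L solves deviance = chi2_1(L); we bracket outward from the estimate by
doubling steps and bisect.  Constrained minima use SLSQP warm-started from
the previous profile point, so the bisection path stays cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2


@dataclass
class ProfileCI:
    lower: float
    upper: float
    level: float
    open_lower: bool = False
    open_upper: bool = False

    def as_tuple(self):
        return (self.lower, self.upper)

    def contains(self, v: float) -> bool:
        return self.lower <= v <= self.upper


def _constrained_min(negloglik, quantity, value, theta_start):
    cons = [{"type": "eq", "fun": lambda th: quantity(th) - value}]
    res = minimize(
        negloglik,
        theta_start,
        method="SLSQP",
        constraints=cons,
        options={"maxiter": 300, "ftol": 1e-11},
    )
    return float(res.fun), np.asarray(res.x, float)


def profile_interval(
    negloglik,
    theta_hat,
    quantity,
    level: float = 0.95,
    xtol_scale: float = 1e-4,
    max_doublings: int = 40,
) -> ProfileCI:
    theta_hat = np.asarray(theta_hat, float)
    f_hat = float(negloglik(theta_hat))
    g_hat = float(quantity(theta_hat))
    crit = 0.5 * chi2.ppf(level, 1)  # on the negloglik scale
    scale = max(1.0, abs(g_hat))
    xtol = xtol_scale * scale

    def deviance(v, th_start):
        f, th = _constrained_min(negloglik, quantity, v, th_start)
        return f - f_hat, th

    bounds = []
    flags = []
    for direction in (-1.0, +1.0):
        step = 0.25 * scale
        v_in, th = g_hat, theta_hat
        v_out = None
        for _ in range(max_doublings):
            v = v_in + direction * step
            d, th_v = deviance(v, th)
            if d > crit:
                v_out = v
                break
            v_in, th = v, th_v
            step *= 2.0
        if v_out is None:
            bounds.append(direction * np.inf)
            flags.append(True)
            continue
        lo_v, hi_v = (v_in, v_out)
        while abs(hi_v - lo_v) > xtol:
            mid = 0.5 * (lo_v + hi_v)
            d, th_mid = deviance(mid, th)
            if d > crit:
                hi_v = mid
            else:
                lo_v, th = mid, th_mid
        bounds.append(0.5 * (lo_v + hi_v))
        flags.append(False)
    return ProfileCI(
        lower=float(bounds[0]),
        upper=float(bounds[1]),
        level=level,
        open_lower=flags[0],
        open_upper=flags[1],
    )
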