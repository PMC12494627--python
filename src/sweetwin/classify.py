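"""Sweet-liking status: rescaling, cut-off classification, thresholds.

Liking ratings of a sucrose solution on the 120-mm Labeled Affective
Magnitude (LAM) scale are rescaled to a centered 100-point score
(-50..+50) and cut into three ordered hedonic groups:

* ``SD``  sweet-disliker        score < 0
* ``MSL`` moderate sweet-liker  0 <= score <= 15
* ``ESL`` extreme sweet-liker   score > 15

Boundary scores (exactly 0 or exactly +15) are moderate likers; the cut-offs
are configurable.  Under a liability-threshold reading, the three observed
categories correspond to a standard-normal latent liking liability cut at
two thresholds, which :func:`thresholds_from_proportions` recovers from
category proportions (category order SD < MSL < ESL throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

STATUS_ORDER = ("SD", "MSL", "ESL")
#: default cut-offs on the -50..+50 score: (SD/MSL boundary, MSL/ESL boundary)
DEFAULT_CUTOFFS = (0.0, 15.0)


@dataclass(frozen=True)
class ThresholdSet:
    """Two increasing liability thresholds (z-scores)."""

    tau1: float
    tau2: float

    def __post_init__(self):
        if not (np.isfinite(self.tau1) and np.isfinite(self.tau2)):
            raise ValueError("thresholds must be finite")
        if not self.tau1 < self.tau2:
            raise ValueError(f"thresholds must increase: {self.tau1} >= {self.tau2}")

    def as_tuple(self) -> tuple[float, float]:
        return (self.tau1, self.tau2)


def rescale_to_centered_100(rating):
    """Map a 0-120 mm LAM rating linearly onto the -50..+50 score.

    ``score = rating * (100/120) - 50``; missing values pass through.
    """
    arr = np.asarray(rating, dtype=float)
    bad = (arr < 0) | (arr > 120)
    if np.any(bad & np.isfinite(arr)):
        raise ValueError("rating outside the 0-120 LAM range")
    out = arr * (100.0 / 120.0) - 50.0
    return float(out) if np.isscalar(rating) else out


def classify_status(score, cutoffs=DEFAULT_CUTOFFS):
    """Assign SD/MSL/ESL labels from -50..+50 scores.

    Scalar input returns a string (or None when missing); array input
    returns an ordered :class:`pandas.Categorical`.
    """
    low, high = cutoffs
    if not low < high:
        raise ValueError("cutoffs must increase")
    scalar = np.isscalar(score)
    arr = np.asarray(score, dtype=float)
    labels = np.where(arr < low, "SD", np.where(arr > high, "ESL", "MSL"))
    labels = np.where(np.isnan(arr), None, labels)
    if scalar:
        return labels.item()
    return pd.Categorical(labels, categories=list(STATUS_ORDER), ordered=True)


@dataclass(frozen=True)
class StatusCounts:
    counts: dict
    proportions: dict
    n: int


def status_proportions(labels) -> StatusCounts:
    """Counts and proportions of the three status groups (missing excluded)."""
    ser = pd.Series(labels)
    ser = ser[ser.notna()]
    if len(ser) == 0:
        raise ValueError("no non-missing status labels")
    counts = {k: int((ser == k).sum()) for k in STATUS_ORDER}
    unknown = set(ser.unique()) - set(STATUS_ORDER)
    if unknown:
        raise ValueError(f"unknown status labels: {sorted(unknown)}")
    n = len(ser)
    props = {k: counts[k] / n for k in STATUS_ORDER}
    return StatusCounts(counts=counts, proportions=props, n=n)


def thresholds_from_proportions(p) -> ThresholdSet:
    """Liability thresholds implied by (SD, MSL, ESL) proportions.

    tau1 = Phi^-1(p_SD), tau2 = Phi^-1(p_SD + p_MSL) with the latent liking
    liability standard normal.  Inverse of integrating a standard normal
    between the thresholds.
    """
    if isinstance(p, dict):
        p = tuple(p[k] for k in STATUS_ORDER)
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise ValueError("need a (SD, MSL, ESL) proportion triple")
    if np.any(p <= 0):
        raise ValueError("zero-probability category puts a threshold at infinity")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"proportions must sum to 1 (got {p.sum()})")
    return ThresholdSet(float(norm.ppf(p[0])), float(norm.ppf(p[0] + p[1])))


def proportions_from_thresholds(ts: ThresholdSet) -> tuple[float, float, float]:
    """Category masses of a standard normal between the thresholds."""
    c1, c2 = norm.cdf(ts.tau1), norm.cdf(ts.tau2)
    return (float(c1), float(c2 - c1), float(1.0 - c2))


def classify_cohort(
    cohort,
    trait: str,
    mode: str = "cutoffs",
    rescale: bool = True,
    cutoffs=DEFAULT_CUTOFFS,
    thresholds: ThresholdSet | None = None,
    out: str = "sweet_status",
):
    """Append a status column to a cohort.

    ``mode="cutoffs"``: optionally rescale the raw LAM rating to -50..+50 and
    apply fixed score cut-offs.  ``mode="quantile"``: z-score the trait within
    the cohort and cut at liability ``thresholds`` — used when the trait is
    not on the raw LAM scale (e.g. simulated liabilities).
    """
    from .data import TwinCohort  # local import to avoid cycle

    if trait not in cohort.trait_registry:
        raise KeyError(f"unknown trait {trait!r}")
    vals = cohort.data[trait].to_numpy(dtype=float)
    if mode == "cutoffs":
        score = rescale_to_centered_100(vals) if rescale else vals
        labels = classify_status(score, cutoffs=cutoffs)
    elif mode == "quantile":
        if thresholds is None:
            raise ValueError("quantile mode needs thresholds")
        mu = np.nanmean(vals)
        sd = np.nanstd(vals)
        if sd == 0:
            raise ValueError("constant trait cannot be classified")
        z = (vals - mu) / sd
        labels = classify_status(z, cutoffs=thresholds.as_tuple())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    new = cohort.copy()
    new.data[out] = np.asarray(labels).astype(object)
    new.trait_registry[out] = None
    return TwinCohort(new.data, new.trait_registry, new.age_centered)


def status_codes(values) -> np.ndarray:
    """Map SD/MSL/ESL labels (or 0/1/2 codes) to float codes with NaN missing."""
    ser = pd.Series(values)
    if ser.dtype.kind in "if":
        arr = ser.to_numpy(float)
        ok = np.isin(arr[np.isfinite(arr)], [0.0, 1.0, 2.0]).all()
        if not ok:
            raise ValueError("numeric status codes must be 0, 1 or 2")
        return arr
    mapping = {k: float(i) for i, k in enumerate(STATUS_ORDER)}
    out = ser.map(lambda v: mapping.get(v, np.nan)).to_numpy(float)
    bad = ser.notna() & ~ser.isin(STATUS_ORDER)
    if bad.any():
        raise ValueError(f"unknown status labels: {sorted(ser[bad].unique())}")
    return out
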