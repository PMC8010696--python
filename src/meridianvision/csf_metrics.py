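"""CSF summary metrics: AULCSF, CSF acuity, and SF threshold at 80% contrast.

Per-spatial-frequency contrast thresholds are mapped to points
(log10 sf, log10 sensitivity) and summarized by

* AULCSF — trapezoidal area under log10 sensitivity (floored at 0) over
  log10 sf from 1.5 to 18 cpd, with log-linear extrapolation from the
  outermost measured points to reach the integration bounds;
* CSF acuity — the log10 spatial frequency where the descending limb
  crosses sensitivity 1 (contrast threshold 100%);
* SF threshold at 80% contrast — the linear spatial frequency (cpd) where
  the limb crosses sensitivity 1/0.80.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
from sklearn.base import BaseEstimator

AULCSF_RANGE = (1.5, 18.0)


class Crossing(NamedTuple):
    value: float
    extrapolated: bool


@dataclass(frozen=True)
class CSFSummary:
    """Per-eye CSF summary: measured log-log points and the three scalars."""

    points: np.ndarray            # (n, 2): log10 sf, log10 sensitivity
    aulcsf: float
    csf_acuity: float             # log10 cpd
    sf_threshold_80: float        # cpd
    extrapolated: dict            # per-summary flags
    omitted_sfs: tuple = ()       # non-converged cells left out


def thresholds_to_csf(thresholds: Mapping[float, float]) -> np.ndarray:
    """Map {sf (cpd): contrast threshold} to sorted (log10 sf, log10 S) points.

    Non-finite thresholds (non-converged staircases) are omitted; thresholds
    must lie in (0, 1].
    """
    pts = []
    for sf, thr in thresholds.items():
        if sf <= 0:
            raise ValueError("spatial frequencies must be positive")
        if not np.isfinite(thr):
            continue
        if not 0.0 < thr <= 1.0:
            raise ValueError(f"contrast threshold {thr} outside (0, 1]")
        pts.append((math.log10(sf), math.log10(1.0 / thr)))
    if not pts:
        raise ValueError("no converged thresholds")
    return np.asarray(sorted(pts))


def _check_points(points) -> tuple:
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n>=2, 2) array of (log10 sf, log10 S) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(x) <= 0):
        raise ValueError("points must be sorted by sf without duplicates")
    return x, y


def _piecewise_eval(x, y, xq, clamp_high_slope: bool = True):
    """Piecewise-linear interpolation with log-linear extrapolation from the
    outermost two points; the high-side extrapolation slope is clamped <= 0."""
    xq = np.asarray(xq, float)
    yq = np.interp(xq, x, y)
    lo_slope = (y[1] - y[0]) / (x[1] - x[0])
    hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
    if clamp_high_slope:
        hi_slope = min(hi_slope, 0.0)
    below, above = xq < x[0], xq > x[-1]
    yq = np.where(below, y[0] + lo_slope * (xq - x[0]), yq)
    yq = np.where(above, y[-1] + hi_slope * (xq - x[-1]), yq)
    return yq


def compute_aulcsf(points, sf_range: tuple = AULCSF_RANGE,
                   floor_at_zero: bool = True) -> float:
    """Trapezoidal area under the log CSF over ``sf_range`` (default 1.5-18 cpd).

    The integrand is log10 sensitivity (floored at 0 unless disabled) and the
    integration variable log10 spatial frequency; between measured points the
    curve is linear in log-log coordinates, and it is extended log-linearly
    from the outermost pairs to the bounds. Exact on each linear piece (zero
    crossings are inserted as knots before flooring).
    """
    x, y = _check_points(points)
    if x.size < 3:
        raise ValueError("need >= 3 converged points for AULCSF")
    lo, hi = math.log10(sf_range[0]), math.log10(sf_range[1])
    if x[0] > hi or x[-1] < lo:
        raise ValueError("measured points do not overlap the AULCSF range")
    knots = np.unique(np.concatenate([[lo, hi], x[(x > lo) & (x < hi)]]))
    vals = _piecewise_eval(x, y, knots)
    if floor_at_zero:
        # insert exact zero crossings so the clipped integral stays exact
        extra = []
        for i in range(len(knots) - 1):
            y0, y1 = vals[i], vals[i + 1]
            if y0 * y1 < 0:
                extra.append(knots[i] - y0 * (knots[i + 1] - knots[i]) / (y1 - y0))
        if extra:
            knots = np.sort(np.concatenate([knots, extra]))
            vals = _piecewise_eval(x, y, knots)
        vals = np.maximum(vals, 0.0)
    return float(np.trapezoid(vals, knots))


def _descending_crossing(points, level: float) -> Crossing:
    """log10 sf where the descending high-frequency limb crosses ``level``.

    Scans segments from the highest frequency downward; when every measured
    value exceeds ``level`` the limb is extended log-linearly past the last
    point and the result flagged as extrapolated.
    """
    x, y = _check_points(points)
    if y[-1] >= y[-2]:
        raise ValueError("no descending high-frequency limb; crossing undefined")
    if y[-1] == level:
        return Crossing(float(x[-1]), False)
    if y[-1] > level:
        slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
        return Crossing(float(x[-1] + (level - y[-1]) / slope), True)
    for i in range(len(x) - 2, -1, -1):
        y0, y1 = y[i], y[i + 1]
        if y0 >= level >= y1 and y0 != y1:
            return Crossing(float(x[i] + (level - y0) * (x[i + 1] - x[i]) / (y1 - y0)),
                            False)
    raise ValueError(f"no crossing of level {level} on the measured limb")


def compute_csf_acuity(points) -> Crossing:
    """CSF acuity: log10 cpd where log10 sensitivity crosses 0."""
    return _descending_crossing(points, 0.0)


def compute_sf_threshold_at_contrast(points, contrast: float = 0.80) -> Crossing:
    """Spatial frequency (linear cpd) detectable at the given grating contrast."""
    if not 0.0 < contrast <= 1.0:
        raise ValueError("contrast must be in (0, 1]")
    level = math.log10(1.0 / contrast)
    log_sf, flag = _descending_crossing(points, level)
    return Crossing(10.0 ** log_sf, flag)


class CSFSummarizer(BaseEstimator):
    """Summarize per-SF contrast thresholds into AULCSF, CSF acuity and the
    SF threshold at a reference contrast.

    Parameters
    ----------
    aulcsf_range : tuple of float
        Spatial-frequency band (cpd) of the AULCSF integral.
    reference_contrast : float
        Grating contrast (fraction) of the SF-threshold summary.
    floor_at_zero : bool
        Whether the AULCSF integrand is floored at log sensitivity 0.

    Attributes (after :meth:`fit`)
    ------------------------------
    points_ : ndarray, (n, 2) log10 sf / log10 sensitivity
    aulcsf_ : float
    csf_acuity_ : float (log10 cpd)
    sf_threshold_ : float (cpd)
    extrapolated_ : dict of bool per summary
    omitted_sfs_ : tuple of sf whose threshold was non-converged
    """

    def __init__(self, aulcsf_range: tuple = AULCSF_RANGE,
                 reference_contrast: float = 0.80, floor_at_zero: bool = True):
        self.aulcsf_range = aulcsf_range
        self.reference_contrast = reference_contrast
        self.floor_at_zero = floor_at_zero

    def fit(self, X, y=None) -> "CSFSummarizer":
        """Fit from ``{sf: contrast threshold}`` or an (n, 2) [sf, threshold] array."""
        if isinstance(X, Mapping):
            thresholds = dict(X)
        else:
            arr = np.asarray(X, float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("X must be a mapping or an (n, 2) array")
            thresholds = {float(sf): float(t) for sf, t in arr}
        self.omitted_sfs_ = tuple(sf for sf, t in sorted(thresholds.items())
                                  if not np.isfinite(t))
        self.points_ = thresholds_to_csf(thresholds)
        self.aulcsf_ = compute_aulcsf(self.points_, self.aulcsf_range,
                                      self.floor_at_zero)
        acuity = compute_csf_acuity(self.points_)
        sf80 = compute_sf_threshold_at_contrast(self.points_,
                                                self.reference_contrast)
        self.csf_acuity_ = acuity.value
        self.sf_threshold_ = sf80.value
        self.extrapolated_ = {"csf_acuity": acuity.extrapolated,
                              "sf_threshold": sf80.extrapolated}
        return self

    def summary(self) -> CSFSummary:
        return CSFSummary(points=self.points_, aulcsf=self.aulcsf_,
                          csf_acuity=self.csf_acuity_,
                          sf_threshold_80=self.sf_threshold_,
                          extrapolated=dict(self.extrapolated_),
                          omitted_sfs=self.omitted_sfs_)


def generative_aulcsf(csf, sf_range: tuple = AULCSF_RANGE, n: int = 2001) -> float:
    """AULCSF of a generative CSF curve, on a dense log grid (oracle helper)."""
    x = np.linspace(math.log10(sf_range[0]), math.log10(sf_range[1]), n)
    y = np.maximum(np.asarray(csf.log_sensitivity(10.0 ** x)), 0.0)
    return float(np.trapezoid(y, x))
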