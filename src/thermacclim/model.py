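"""Two-threshold smooth broken-line model for acclimation trajectories.

The mean response over days ``d`` around a heat-challenge onset (day 0) is

    Y(d) = y0 + v1*d - r1*(v1 - v2)*softplus((d - td1)/r1)
                     - r2*v2*softplus((d - td2)/r2)

with softplus(x) = ln(1 + exp(x)).  The curve is linear with slope ``v1``
well before the first threshold day ``td1``, slope ``v2`` between ``td1``
and the second threshold day ``td2``, and slope 0 (a plateau) after
``td2``; ``r1`` and ``r2`` set the width (in days) of the smooth
transitions around the thresholds.  ``y0`` is the value at day 0, the day
ambient temperature switches from thermoneutral (22 degC) to the challenge
level (32 degC).

For feed intake the typical pattern is a sharp drop at onset (v1 << 0,
td1 near 0) followed by gradual recovery (v2 > 0); for core temperature a
rise (v1 > 0) followed by a slow decline (v2 < 0) once acclimation sets
in.  The r -> 0 limit is an exact piecewise-linear "broken stick"
(:func:`evaluate_sharp`), used throughout as a verification oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "AcclimationParams",
    "TrajectorySummaries",
    "evaluate",
    "evaluate_sharp",
    "slope",
    "gradient",
    "derived_summaries",
]

#: order of the estimable mean parameters throughout the package
MEAN_PARAM_NAMES = ("y0", "v1", "v2", "td1", "td2")


@dataclass(frozen=True)
class AcclimationParams:
    """Parameters of the two-threshold mean function for one group.

    Attributes
    ----------
    y0 : response value at day 0 (g/d/kg^0.60 or degC).
    v1 : linear slope before the first threshold (units/d).
    v2 : linear slope between the two thresholds (units/d).
    td1 : first threshold day (d, relative to challenge onset).
    td2 : second threshold day (d); must exceed ``td1``.
    r1, r2 : transition smoothness at td1 / td2 (d, > 0).
    """

    y0: float
    v1: float
    v2: float
    td1: float
    td2: float
    r1: float = 0.25
    r2: float = 0.25

    def __post_init__(self) -> None:
        vals = dataclasses.astuple(self)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite parameter in {vals}")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("smoothness parameters r1, r2 must be > 0")
        if not self.td1 < self.td2:
            raise ValueError(f"threshold ordering violated: td1={self.td1} >= td2={self.td2}")

    def replace(self, **changes: float) -> "AcclimationParams":
        return dataclasses.replace(self, **changes)

    def mean_array(self) -> np.ndarray:
        """The five estimable mean parameters as (y0, v1, v2, td1, td2)."""
        return np.array([self.y0, self.v1, self.v2, self.td1, self.td2], dtype=float)

    @classmethod
    def from_mean_array(cls, x, r1: float = 0.25, r2: float = 0.25) -> "AcclimationParams":
        y0, v1, v2, td1, td2 = (float(v) for v in x)
        return cls(y0, v1, v2, td1, td2, r1=r1, r2=r2)


def _softplus(x):
    # ln(1+e^x) = max(x,0) + ln(1+e^-|x|); np.logaddexp does this stably
    return np.logaddexp(0.0, x)


def _maybe_scalar(arr, d):
    return float(arr) if np.ndim(d) == 0 else arr


def evaluate(params: AcclimationParams, d):
    """Smooth two-threshold mean response at day(s) ``d``."""
    dd = np.asarray(d, dtype=float)
    y = (
        params.y0
        + params.v1 * dd
        - params.r1 * (params.v1 - params.v2) * _softplus((dd - params.td1) / params.r1)
        - params.r2 * params.v2 * _softplus((dd - params.td2) / params.r2)
    )
    return _maybe_scalar(y, d)


def evaluate_sharp(params: AcclimationParams, d):
    """Piecewise-linear r -> 0 limit of :func:`evaluate`.

    Slope v1 below td1, v2 between td1 and td2, 0 beyond td2, with the
    first segment anchored so the line passes through (0, y0).
    """
    dd = np.asarray(d, dtype=float)
    g1 = np.minimum(dd, params.td1)
    g2 = np.clip(dd, params.td1, params.td2) - params.td1
    y = params.y0 + params.v1 * g1 + params.v2 * g2
    return _maybe_scalar(y, d)


def slope(params: AcclimationParams, d):
    """dY/dd of the smooth model: a blend of v1, v2 and 0 via logistics."""
    dd = np.asarray(d, dtype=float)
    s1 = expit((dd - params.td1) / params.r1)
    s2 = expit((dd - params.td2) / params.r2)
    y = params.v1 - (params.v1 - params.v2) * s1 - params.v2 * s2
    return _maybe_scalar(y, d)


def gradient(params: AcclimationParams, d) -> np.ndarray:
    """Partials of Y(d) w.r.t. (y0, v1, v2, td1, td2); r1, r2 held fixed.

    Returns an array of shape ``(5,)`` for scalar ``d``, else ``d.shape + (5,)``.
    """
    dd = np.asarray(d, dtype=float)
    sp1 = _softplus((dd - params.td1) / params.r1)
    sp2 = _softplus((dd - params.td2) / params.r2)
    s1 = expit((dd - params.td1) / params.r1)
    s2 = expit((dd - params.td2) / params.r2)
    g = np.stack(
        [
            np.ones_like(dd),
            dd - params.r1 * sp1,
            params.r1 * sp1 - params.r2 * sp2,
            (params.v1 - params.v2) * s1,
            params.v2 * s2,
        ],
        axis=-1,
    )
    return g


@dataclass(frozen=True)
class TrajectorySummaries:
    """Sharp-limit summaries of one fitted trajectory over a day window."""

    defined: bool
    window: tuple[float, float]
    extremum_day: float  # td1: the turning point between the two phases
    extremum_value: float  # response at td1 (peak if v1>0>v2, trough if v1<0<v2)
    earliest_min_day: float
    min_value: float
    earliest_max_day: float
    max_value: float
    contrast: float  # Y(day_hi) - Y(day_lo)


def derived_summaries(
    params: AcclimationParams, window: tuple[float, float] = (-1.0, 10.0)
) -> TrajectorySummaries:
    """Descriptive summaries of the piecewise-linear limit trajectory.

    Computed on :func:`evaluate_sharp`.  The extremum at td1 is the
    between-phase turning point (e.g. the core-temperature peak, or the
    feed-intake trough, during short-term acclimation); the earliest
    min/max days locate the window-wide extrema, with ties resolved to
    the earliest day — under this convention the plateau onset td2 is
    the earliest minimiser of a rise-then-fall temperature curve.
    """
    lo, hi = float(window[0]), float(window[1])
    if not (lo <= params.td1 and params.td2 <= hi):
        nan = float("nan")
        return TrajectorySummaries(False, (lo, hi), nan, nan, nan, nan, nan, nan, nan)
    candidates = np.array([lo, params.td1, params.td2])
    vals = evaluate_sharp(params, candidates)
    i_min = int(np.argmin(vals))  # argmin/argmax take the first hit: earliest day
    i_max = int(np.argmax(vals))
    return TrajectorySummaries(
        defined=True,
        window=(lo, hi),
        extremum_day=params.td1,
        extremum_value=float(evaluate_sharp(params, params.td1)),
        earliest_min_day=float(candidates[i_min]),
        min_value=float(vals[i_min]),
        earliest_max_day=float(candidates[i_max]),
        max_value=float(vals[i_max]),
        contrast=float(evaluate_sharp(params, hi) - evaluate_sharp(params, lo)),
    )
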