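"""Global time transformation onto the Nelson-Aalen scale.

A piecewise-exponential model needs many intervals when the marginal
survival curve is far from exponential.  The monotone recoding
``phi: t -> t~`` used here (after LeBlanc and Crowley) maps each event
time to the Nelson-Aalen estimate of the marginal cumulative hazard, so
that on the transformed axis a *unit-rate* exponential already
reproduces the nonparametric survival estimate.  Interval boundaries
are then only needed to express non-proportional hazards.

Censored times are mapped by linear interpolation between the
surrounding event-time knots, with (0, 0) as the left anchor; beyond
the last event time the transform continues linearly with the slope of
the last knot segment (optionally: constant).  Survival probabilities
are invariant under this monotone reparameterization, so predictions at
an original time t are simply read off at phi(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nonparametric import nelson_aalen

__all__ = ["TimeTransform", "fit_time_transform", "apply_time_transform"]


@dataclass(frozen=True)
class TimeTransform:
    """Piecewise-linear monotone map through (0,0) and the given knots."""

    knot_times: np.ndarray
    knot_values: np.ndarray
    extrapolation: str = "linear"  # "linear" | "constant"

    def __post_init__(self) -> None:
        t = np.asarray(self.knot_times, dtype=float)
        v = np.asarray(self.knot_values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 1:
            raise ValueError("knots must be non-empty 1-D arrays of equal length")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be positive and strictly increasing")
        if np.any(v < 0) or np.any(np.diff(v) <= 0):
            raise ValueError("knot values must be non-negative and strictly increasing")
        if self.extrapolation not in ("linear", "constant"):
            raise ValueError(f"unknown extrapolation {self.extrapolation!r}")
        object.__setattr__(self, "knot_times", t)
        object.__setattr__(self, "knot_values", v)

    @property
    def _slope_beyond(self) -> float:
        t, v = self.knot_times, self.knot_values
        if self.extrapolation == "constant":
            return 0.0
        if t.size >= 2:
            return float((v[-1] - v[-2]) / (t[-1] - t[-2]))
        return float(v[-1] / t[-1])  # single knot: slope of the (0,0) segment

    def __call__(self, t) -> np.ndarray:
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time transform is defined for t >= 0 only")
        xp = np.concatenate(([0.0], self.knot_times))
        fp = np.concatenate(([0.0], self.knot_values))
        out = np.interp(t_arr, xp, fp)
        beyond = t_arr > self.knot_times[-1]
        if np.any(beyond):
            out = np.where(
                beyond,
                self.knot_values[-1] + self._slope_beyond * (t_arr - self.knot_times[-1]),
                out,
            )
        return out if t_arr.ndim else float(out)


def fit_time_transform(times, events, extrapolation: str = "linear") -> TimeTransform:
    """Build phi from the Nelson-Aalen estimate of the pooled data.

    Knots sit at the distinct event times, with values equal to the
    cumulative-hazard estimate there; at least two distinct event times
    are required for the interpolation to be meaningful.
    """
    na = nelson_aalen(times, events)
    if na.times.size < 2:
        raise ValueError("need at least two distinct event times to fit the transform")
    return TimeTransform(na.times, na.values, extrapolation)


def apply_time_transform(tt: TimeTransform, t):
    """Evaluate phi(t); equivalent to calling the transform."""
    return tt(t)
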