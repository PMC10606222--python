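"""Kaplan-Meier and Nelson-Aalen step estimators.

These are deliberately implemented here rather than delegated, because
the time transformation and the inverse-probability-of-censoring (IPCW)
weights depend on exact tie and left-limit conventions:

* at a tied time, events are processed before censorings;
* the censoring survival function G supports left-limit evaluation
  G(t-), returning the pre-jump value when t coincides with a jump.

Test code cross-checks the estimators against lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepEstimate", "kaplan_meier", "nelson_aalen", "censoring_km"]


@dataclass(frozen=True)
class StepEstimate:
    """Right-continuous step function with jumps at ``times``.

    ``values[i]`` is the function value at and after ``times[i]``;
    ``baseline`` is the value before the first jump (1 for survival
    curves, 0 for cumulative hazards).
    """

    times: np.ndarray
    values: np.ndarray
    baseline: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def at(self, t) -> np.ndarray:
        """Evaluate the right-continuous step function at t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate(([self.baseline], self.values))
        return vals[idx]

    def at_left(self, t) -> np.ndarray:
        """Left limit: the value strictly before t (pre-jump value at a jump)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate(([self.baseline], self.values))
        return vals[idx]

    def __call__(self, t) -> np.ndarray:
        return self.at(t)


def _tally(times, events):
    """Per distinct time: event count d, total exits, number at risk n."""
    t = np.asarray(times, dtype=float).ravel()
    d = np.asarray(events, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != d.shape:
        raise ValueError("times and events length mismatch")
    uniq, inv = np.unique(t, return_inverse=True)
    n_events = np.bincount(inv, weights=d, minlength=uniq.size)
    n_total = np.bincount(inv, minlength=uniq.size).astype(float)
    # at risk at time s: everyone with t_i >= s
    at_risk = n_total[::-1].cumsum()[::-1]
    return uniq, n_events, n_total, at_risk


def kaplan_meier(times, events) -> StepEstimate:
    """Product-limit estimator S(t) = prod_{s<=t} (1 - d_s/n_s).

    Jumps are recorded only at event times; censored exits reduce later
    risk sets.  At a tied event/censoring time both contribute to the
    same risk set (censorings are processed after events).
    """
    uniq, d, _, n = _tally(times, events)
    has_event = d > 0
    surv = np.cumprod(1.0 - d[has_event] / n[has_event])
    return StepEstimate(uniq[has_event], surv, baseline=1.0)


def nelson_aalen(times, events) -> StepEstimate:
    """Cumulative-hazard estimator H(t) = sum_{event times s<=t} d_s/n_s."""
    uniq, d, _, n = _tally(times, events)
    has_event = d > 0
    if not np.any(has_event):
        raise ValueError("Nelson-Aalen requires at least one event")
    haz = np.cumsum(d[has_event] / n[has_event])
    return StepEstimate(uniq[has_event], haz, baseline=0.0)


def censoring_km(times, events) -> StepEstimate:
    """Kaplan-Meier estimate G(t) of the censoring distribution.

    The event indicator is flipped (censorings become the events of
    interest).  At a tied time, true events are processed first, so the
    risk set for a censoring jump at s excludes the subjects whose event
    occurred at s.
    """
    uniq, d_event, n_total, n = _tally(times, events)
    d_cens = n_total - d_event
    has_cens = d_cens > 0
    n_for_cens = n - d_event  # events leave the risk set first
    surv = np.cumprod(1.0 - d_cens[has_cens] / n_for_cens[has_cens])
    return StepEstimate(uniq[has_cens], surv, baseline=1.0)
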