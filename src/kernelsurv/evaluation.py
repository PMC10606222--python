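"""Predictive-performance metrics for survival models.

Discrimination is measured with Antolini's time-dependent concordance
index: among all test pairs that can be ordered in time (t_i < t_j with
delta_i = 1), the proportion for which the model assigns the earlier
subject the lower survival probability at the earlier subject's time,
S(t_i|x_i) < S(t_i|x_j).  A value of 0.5 means the predictions carry no
discriminative information.

Calibration is measured with the Brier score under inverse probability
of censoring weighting (IPCW): at horizon t, the weighted mean squared
difference between the predicted survival probability and the observed
vital status, with weights 1/G(t_i-) for subjects who had the event by
t and 1/G(t) for subjects still under observation, where G is the
Kaplan-Meier estimate of the censoring distribution.  The Brier score
is integrated numerically up to the 95% quantile of the test event
times, and summarized as the explained residual variation relative to
the Kaplan-Meier marginal curve, R^2 = 1 - BI(model)/BI(KM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import SurvivalDataset
from .nonparametric import StepEstimate, censoring_km, kaplan_meier

__all__ = [
    "SurvivalPredictionSet",
    "antolini_concordance",
    "brier_score",
    "integrated_brier",
    "r_squared",
    "evaluate_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalPredictionSet:
    """Survival curves for a test cohort, evaluable at arbitrary times.

    ``curves(t_grid)`` returns the matrix S[i, g] = S(t_g | x_i) for
    every test subject i; times/events are the observed test outcomes.
    """

    curves: Callable[[np.ndarray], np.ndarray]
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float).ravel())
        object.__setattr__(self, "events", np.asarray(self.events).astype(np.int8).ravel())
        if self.times.shape != self.events.shape:
            raise ValueError("times and events length mismatch")

    @property
    def n(self) -> int:
        return self.times.size

    def survival_matrix(self, t_grid) -> np.ndarray:
        t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
        S = np.asarray(self.curves(t_grid), dtype=float)
        if S.shape != (self.n, t_grid.size):
            raise ValueError(
                f"curve evaluator returned shape {S.shape}, "
                f"expected {(self.n, t_grid.size)}"
            )
        return S

    @classmethod
    def from_model(cls, model, test: SurvivalDataset) -> "SurvivalPredictionSet":
        return cls(
            curves=lambda grid: np.atleast_2d(
                model.predict_survival(test.covariates, grid)
            ),
            times=test.times,
            events=test.events,
        )

    @classmethod
    def from_step_estimate(
        cls, curve: StepEstimate, times, events
    ) -> "SurvivalPredictionSet":
        """Assign one marginal curve (e.g. Kaplan-Meier) to every subject."""
        times = np.asarray(times, dtype=float)
        return cls(
            curves=lambda grid: np.tile(curve.at(grid), (times.size, 1)),
            times=times,
            events=events,
        )


def antolini_concordance(pred: SurvivalPredictionSet) -> float:
    """Time-dependent concordance over pairs t_i < t_j with delta_i = 1.

    A pair counts as concordant when S(t_i|x_i) < S(t_i|x_j); exact
    ties between the two predicted values contribute 1/2.
    """
    t, d = pred.times, pred.events
    ev_idx = np.flatnonzero(d > 0)
    if ev_idx.size == 0:
        raise ValueError("no comparable pairs: no events in the test set")
    ev_times = t[ev_idx]
    S = pred.survival_matrix(ev_times)  # S[j, a] = S(t_{ev a} | x_j)

    n_pairs = 0
    n_conc = 0.0
    for a, i in enumerate(ev_idx):
        later = t > ev_times[a]
        if not np.any(later):
            continue
        s_i = S[i, a]
        s_j = S[later, a]
        n_pairs += s_j.size
        n_conc += np.count_nonzero(s_j > s_i) + 0.5 * np.count_nonzero(s_j == s_i)
    if n_pairs == 0:
        raise ValueError("no comparable pairs (all events at the latest time)")
    return n_conc / n_pairs


def _brier_from_matrix(S_col, t, times, events, G: StepEstimate) -> float:
    """IPCW Brier score at one horizon given predicted S(t|x_i) per subject."""
    died = (times <= t) & (events > 0)
    alive = times > t
    G_death = np.asarray(G.at_left(times), dtype=float)
    G_t = float(G.at(t))

    contrib = np.zeros(times.size)
    ok_died = died & (G_death > 0)
    dropped = int(np.count_nonzero(died & (G_death <= 0)))
    contrib[ok_died] = (S_col[ok_died] ** 2) / G_death[ok_died]
    if np.any(alive):
        if G_t > 0:
            contrib[alive] = ((1.0 - S_col[alive]) ** 2) / G_t
        else:
            dropped += int(np.count_nonzero(alive))
    if dropped:
        logger.info("IPCW truncation: dropped %d zero-weight terms at t=%g", dropped, t)
    return float(contrib.sum() / times.size)


def brier_score(pred: SurvivalPredictionSet, t: float, G: StepEstimate) -> float:
    """IPCW Brier score BS(t); censored subjects with t_i <= t contribute 0."""
    if t < 0:
        raise ValueError("t must be >= 0")
    S = pred.survival_matrix([t])[:, 0]
    return _brier_from_matrix(S, float(t), pred.times, pred.events, G)


def _integration_grid(pred: SurvivalPredictionSet, upper: float) -> np.ndarray:
    grid = np.unique(pred.times)
    grid = grid[(grid > 0) & (grid < upper)]
    return np.concatenate(([0.0], grid, [upper]))


def integrated_brier(
    pred: SurvivalPredictionSet, G: StepEstimate, upper: float | None = None
) -> float:
    """Trapezoidal integral of BS(t) over [0, upper], divided by upper.

    The default upper limit is the 95% quantile of the test *event*
    times; the grid is the set of unique observed test times augmented
    with the endpoints.
    """
    if upper is None:
        ev = pred.times[pred.events > 0]
        if ev.size == 0:
            raise ValueError("no events to set the default upper limit")
        upper = float(np.quantile(ev, 0.95))
    if upper <= 0:
        raise ValueError("upper must be > 0")
    grid = _integration_grid(pred, upper)
    S = pred.survival_matrix(grid)
    bs = np.array(
        [
            _brier_from_matrix(S[:, g], float(t), pred.times, pred.events, G)
            for g, t in enumerate(grid)
        ]
    )
    return float(np.trapezoid(bs, grid) / upper)


def r_squared(
    pred: SurvivalPredictionSet,
    G: StepEstimate,
    km_baseline: StepEstimate | None = None,
    upper: float | None = None,
) -> float:
    """Explained residual variation R^2 = 1 - BI(model)/BI(Kaplan-Meier).

    The baseline assigns the marginal Kaplan-Meier curve of the test
    outcomes to every subject; R^2 <= 1, and 0 means no improvement
    over the covariate-free baseline.
    """
    if km_baseline is None:
        km_baseline = kaplan_meier(pred.times, pred.events)
    base = SurvivalPredictionSet.from_step_estimate(
        km_baseline, pred.times, pred.events
    )
    bi_km = integrated_brier(base, G, upper)
    if bi_km <= 0:
        raise ValueError("Kaplan-Meier integrated Brier score is zero (degenerate test set)")
    bi_model = integrated_brier(pred, G, upper)
    return 1.0 - bi_model / bi_km


def evaluate_model(model, test: SurvivalDataset) -> dict:
    """Concordance, integrated Brier score and R^2 of a model on test data."""
    pred = SurvivalPredictionSet.from_model(model, test)
    G = censoring_km(test.times, test.events)
    ev = test.times[test.events > 0]
    if ev.size == 0:
        raise ValueError("test set has no events")
    upper = float(np.quantile(ev, 0.95))
    return {
        "concordance": antolini_concordance(pred),
        "integrated_brier": integrated_brier(pred, G, upper),
        "r_squared": r_squared(pred, G, upper=upper),
        "upper_time": upper,
        "n": test.n_samples,
        "n_events": test.n_events,
    }
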