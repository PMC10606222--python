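"""Kernel-weighted piecewise-exponential survival model.

Prediction for a query ``x`` proceeds in two steps.  First every
training instance receives a similarity weight through a Gaussian
radial basis kernel under a learned Mahalanobis-type metric,

    w_i(U, x) = exp(-||U x - U x_i||^2),

where ``U`` is upper triangular and ``A = U'U`` is the positive
semi-definite matrix inducing the metric.  Second, the weighted
training outcomes are pooled into the closed-form maximum-likelihood
hazard of a piecewise-exponential distribution on k intervals of the
transformed time axis,

    lambda_j(x) = sum_i w_i d_ij / sum_i w_i r_j(t_i),

with ``d_ij`` indicating an event of subject i in interval j and
``r_j(t)`` the time at risk spent in interval j.  The survival curve is
then S(t|x) = exp(-sum_j lambda_j(x) r_j(phi(t))).  Because the rates
are interval-specific, hazard ratios between two queries may differ
across intervals: the model is not restricted to proportional hazards.

Each prediction is explained by its most influential training
instances - the nearest neighbors under the learned metric and their
weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import SurvivalDataset, Standardizer
from .timescale import TimeTransform

__all__ = [
    "MetricTransform",
    "IntervalPartition",
    "HazardProfile",
    "FittedKernelModel",
    "ModelLoadError",
    "make_partition",
    "interval_index",
    "risk_time",
    "risk_matrix",
    "compute_weights",
    "hazard_profile",
    "predict_survival",
    "explain_prediction",
    "build_model",
    "save_model",
    "load_model",
]

_ARCHIVE_FORMAT = "kernelsurv-model"
_ARCHIVE_VERSION = 1


class ModelLoadError(RuntimeError):
    """Model archive is missing, corrupted, or of an unsupported version."""


@dataclass(frozen=True)
class MetricTransform:
    """Upper-triangular U; d^2(x, x') = ||Ux - Ux'||^2 = (x-x')'U'U(x-x')."""

    U: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        if U.ndim != 2 or U.shape[0] != U.shape[1]:
            raise ValueError("U must be square")
        if not np.allclose(U, np.triu(U)):
            raise ValueError("U must be upper triangular")
        object.__setattr__(self, "U", U)

    @property
    def matrix(self) -> np.ndarray:
        """The induced PSD matrix A = U'U."""
        return self.U.T @ self.U


@dataclass(frozen=True)
class IntervalPartition:
    """Half-open partition (tau_0, tau_1], ..., (tau_{k-1}, inf) of (0, inf).

    ``boundaries`` holds tau_0 = 0 through tau_k = inf, strictly
    increasing, on the transformed-time axis.
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need boundaries tau_0..tau_k")
        if b[0] != 0.0 or not np.isinf(b[-1]):
            raise ValueError("boundaries must start at 0 and end at inf")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def k(self) -> int:
        return self.boundaries.size - 1


@dataclass(frozen=True)
class HazardProfile:
    """Per-interval hazard rates (events per unit transformed time)."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.rates, dtype=float)
        if lam.ndim != 1 or np.any(lam < 0) or not np.all(np.isfinite(lam)):
            raise ValueError("rates must be finite and non-negative")
        object.__setattr__(self, "rates", lam)


def make_partition(transformed_times, events, k: int) -> IntervalPartition:
    """Interval boundaries at the j/k quantiles of the event times.

    Placing the interior boundaries tau_1..tau_{k-1} at the empirical
    event-time quantiles (linear-interpolation rule) guarantees a
    comparable number of events in every interval.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    t = np.asarray(transformed_times, dtype=float)
    d = np.asarray(events)
    event_times = t[d.astype(bool)]
    n_distinct = np.unique(event_times).size
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct event times for k={k} intervals; "
            "reduce k"
        )
    if k == 1:
        interior = np.empty(0)
    else:
        interior = np.quantile(event_times, np.arange(1, k) / k)
        if np.any(np.diff(interior) <= 0) or interior[0] <= 0:
            raise ValueError(
                "tied event-time quantiles produce degenerate boundaries; reduce k"
            )
    p = IntervalPartition(np.concatenate(([0.0], interior, [np.inf])))
    # every interval must contain at least one event
    counts = np.bincount(interval_index(p, event_times) - 1, minlength=p.k)
    if np.any(counts == 0):
        raise ValueError("an interval contains no events; reduce k")
    return p


def interval_index(p: IntervalPartition, t) -> np.ndarray:
    """1-based index j(t) of the interval (tau_{j-1}, tau_j] containing t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("interval index defined for t > 0")
    j = np.searchsorted(p.boundaries[1:-1], t_arr, side="left") + 1
    return j if t_arr.ndim else int(j)


def risk_time(p: IntervalPartition, t, j: int) -> float:
    """Time at risk r_j(t) = |(0, t] intersected with (tau_{j-1}, tau_j]|."""
    lo, hi = p.boundaries[j - 1], p.boundaries[j]
    return float(np.clip(min(t, hi) - lo, 0.0, None))


def risk_matrix(p: IntervalPartition, t) -> np.ndarray:
    """r_j(t) for all intervals at once; rows sum to t."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    lo = p.boundaries[:-1]
    hi = p.boundaries[1:]
    return np.clip(np.minimum(t_arr[:, None], hi[None, :]) - lo[None, :], 0.0, None)


def compute_weights(
    metric: MetricTransform | np.ndarray,
    x: np.ndarray,
    X_train: np.ndarray,
    exclude: int | None = None,
) -> np.ndarray:
    """Radial-basis-function weights of one query against the training rows.

    With ``exclude=i`` the i-th weight is forced to 0 (the
    leave-self-out rule used when learning the metric).
    """
    U = metric.U if isinstance(metric, MetricTransform) else np.asarray(metric, float)
    x = np.asarray(x, dtype=float).ravel()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    if x.size != X_train.shape[1] or U.shape[1] != x.size:
        raise ValueError(
            f"dimension mismatch: query {x.size}, training {X_train.shape[1]}, "
            f"U {U.shape[1]}"
        )
    diff = (X_train - x) @ U.T
    w = np.exp(-np.einsum("ij,ij->i", diff, diff))
    if exclude is not None:
        w = w.copy()
        w[exclude] = 0.0
    return w


def _batch_weights(U: np.ndarray, Q: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Weight matrix W[q, i] = exp(-||U x_q - U x_i||^2) for query rows Q."""
    Zq = Q @ U.T
    Zt = X @ U.T
    sq_q = np.einsum("ij,ij->i", Zq, Zq)
    sq_t = np.einsum("ij,ij->i", Zt, Zt)
    d2 = sq_q[:, None] + sq_t[None, :] - 2.0 * (Zq @ Zt.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2)


def hazard_profile(
    weights: np.ndarray,
    transformed_times,
    events,
    p: IntervalPartition,
) -> HazardProfile:
    """Closed-form weighted occurrence/exposure rates per interval.

    lambda_j = sum_i w_i d_ij / sum_i w_i r_j(t_i); an interval with
    zero weighted events *and* zero weighted exposure gets rate 0
    (the 0/0 convention), which keeps the prediction defined.
    """
    w = np.asarray(weights, dtype=float).ravel()
    num, den = _profile_terms(w[None, :], transformed_times, events, p)
    return HazardProfile(_safe_rates(num, den)[0])


def _event_interval_matrix(p, transformed_times, events):
    """D[i, j] = delta_i * 1(t_i in interval j)."""
    t = np.asarray(transformed_times, dtype=float)
    d = np.asarray(events, dtype=float)
    j = interval_index(p, t) - 1
    D = np.zeros((t.size, p.k))
    D[np.arange(t.size), j] = d
    return D


def _profile_terms(W, transformed_times, events, p):
    D = _event_interval_matrix(p, transformed_times, events)
    R = risk_matrix(p, transformed_times)
    return W @ D, W @ R


def _safe_rates(num, den):
    pos = den > 0
    if np.any((num > 0) & ~pos):  # event in j implies exposure in j
        raise AssertionError("positive weighted events with zero exposure")
    if np.any(np.all(den == 0, axis=-1)):
        warnings.warn(
            "all kernel weights underflowed to zero for some query; "
            "its hazard is reported as 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.where(pos, num / np.where(pos, den, 1.0), 0.0)


@dataclass
class FittedKernelModel:
    """A fitted model: learned metric plus the retained training data.

    The method is instance-based, so prediction needs the standardized
    training covariates, their transformed times and event flags, in
    addition to U, the standardizer, the time transform and the
    interval partition.
    """

    metric: MetricTransform
    standardizer: Standardizer
    time_transform: TimeTransform
    partition: IntervalPartition
    train_covariates: np.ndarray  # standardized
    train_times: np.ndarray  # original scale
    train_transformed_times: np.ndarray
    train_events: np.ndarray
    eta: float
    feature_names: tuple[str, ...] | None = None
    seed: int | None = None
    fit_info: dict | None = None

    # -- prediction ---------------------------------------------------

    def hazard_profiles(self, X_raw: np.ndarray) -> np.ndarray:
        """Per-query interval rates, shape (n_queries, k)."""
        Q = self.standardizer.transform(np.atleast_2d(np.asarray(X_raw, float)))
        W = _batch_weights(self.metric.U, Q, self.train_covariates)
        num, den = _profile_terms(
            W, self.train_transformed_times, self.train_events, self.partition
        )
        return _safe_rates(num, den)

    def cumulative_hazard(self, X_raw: np.ndarray, times) -> np.ndarray:
        """Lambda(t|x) on the original time scale, shape (n_queries, n_times)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        lam = self.hazard_profiles(X_raw)
        R = risk_matrix(self.partition, self.time_transform(t))
        return lam @ R.T

    def predict_survival(self, X_raw: np.ndarray, times) -> np.ndarray:
        """S(t|x) = exp(-Lambda(t|x)); valid survival curve per query."""
        X_arr = np.asarray(X_raw, dtype=float)
        t_arr = np.asarray(times, dtype=float)
        S = np.exp(-self.cumulative_hazard(X_arr, t_arr))
        if X_arr.ndim == 1:
            S = S[0]
        if t_arr.ndim == 0:
            S = S[..., 0]
        return S

    def explain(self, x_raw: np.ndarray, top_k: int) -> list[tuple[int, float, float, int]]:
        """The top_k most influential training instances for a query.

        Returns (training index, weight, original time, event flag),
        ordered by descending weight with ties broken by index.
        """
        n = self.train_covariates.shape[0]
        if not 1 <= top_k <= n:
            raise ValueError(f"top_k must be in [1, {n}]")
        q = self.standardizer.transform(np.asarray(x_raw, float).reshape(1, -1))[0]
        w = compute_weights(self.metric, q, self.train_covariates)
        order = np.argsort(-w, kind="stable")[:top_k]
        return [
            (int(i), float(w[i]), float(self.train_times[i]), int(self.train_events[i]))
            for i in order
        ]


def predict_survival(model: FittedKernelModel, x, times):
    """Survival probabilities S(t|x) for raw covariates and original times."""
    return model.predict_survival(x, times)


def explain_prediction(model: FittedKernelModel, x, top_k: int):
    """Nearest training neighbors under the learned metric, with weights."""
    return model.explain(x, top_k)


def build_model(
    dataset: SurvivalDataset,
    U: np.ndarray,
    k: int = 4,
    eta: float = 0.0,
    extrapolation: str = "linear",
) -> FittedKernelModel:
    """Assemble a model around a *given* U (no optimization).

    Standardizes the covariates, fits the time transform on the pooled
    data, and builds the event-quantile partition; used for fixed-metric
    baselines (e.g. U = 0, the pooled piecewise-exponential fit) and by
    the trainer.
    """
    from .data import fit_standardizer
    from .timescale import fit_time_transform

    std = fit_standardizer(dataset)
    tt = fit_time_transform(dataset.times, dataset.events, extrapolation)
    ttimes = tt(dataset.times)
    part = make_partition(ttimes, dataset.events, k)
    return FittedKernelModel(
        metric=MetricTransform(np.asarray(U, dtype=float)),
        standardizer=std,
        time_transform=tt,
        partition=part,
        train_covariates=std.transform(dataset.covariates),
        train_times=dataset.times.copy(),
        train_transformed_times=ttimes,
        train_events=dataset.events.copy(),
        eta=eta,
        feature_names=dataset.feature_names,
    )


# -- serialization ----------------------------------------------------


def save_model(model: FittedKernelModel, path: str | Path) -> None:
    """Write a fitted model to a self-describing versioned JSON archive.

    Floats are serialized with full ``repr`` precision, so a reloaded
    model reproduces predictions bit-identically.
    """
    payload = {
        "format": _ARCHIVE_FORMAT,
        "version": _ARCHIVE_VERSION,
        "U": model.metric.U.tolist(),
        "standardizer_mean": model.standardizer.mean_.tolist(),
        "standardizer_scale": model.standardizer.scale_.tolist(),
        "transform_knot_times": model.time_transform.knot_times.tolist(),
        "transform_knot_values": model.time_transform.knot_values.tolist(),
        "transform_extrapolation": model.time_transform.extrapolation,
        "partition_boundaries": model.partition.boundaries[:-1].tolist(),
        "train_covariates": model.train_covariates.tolist(),
        "train_times": model.train_times.tolist(),
        "train_transformed_times": model.train_transformed_times.tolist(),
        "train_events": model.train_events.tolist(),
        "eta": model.eta,
        "feature_names": list(model.feature_names) if model.feature_names else None,
        "seed": model.seed,
        "fit_info": model.fit_info,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> FittedKernelModel:
    """Load a model archive written by :func:`save_model`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelLoadError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _ARCHIVE_FORMAT:
        raise ModelLoadError(f"{path} is not a kernelsurv model archive")
    if payload.get("version") != _ARCHIVE_VERSION:
        raise ModelLoadError(
            f"unsupported archive version {payload.get('version')!r}"
        )
    try:
        std = Standardizer(
            np.asarray(payload["standardizer_mean"], dtype=float),
            np.asarray(payload["standardizer_scale"], dtype=float),
        )
        names = payload["feature_names"]
        return FittedKernelModel(
            metric=MetricTransform(np.asarray(payload["U"], dtype=float)),
            standardizer=std,
            time_transform=TimeTransform(
                np.asarray(payload["transform_knot_times"], dtype=float),
                np.asarray(payload["transform_knot_values"], dtype=float),
                payload["transform_extrapolation"],
            ),
            partition=IntervalPartition(
                np.concatenate(
                    (np.asarray(payload["partition_boundaries"], float), [np.inf])
                )
            ),
            train_covariates=np.asarray(payload["train_covariates"], dtype=float),
            train_times=np.asarray(payload["train_times"], dtype=float),
            train_transformed_times=np.asarray(
                payload["train_transformed_times"], dtype=float
            ),
            train_events=np.asarray(payload["train_events"], dtype=np.int8),
            eta=float(payload["eta"]),
            feature_names=tuple(names) if names else None,
            seed=payload.get("seed"),
            fit_info=payload.get("fit_info"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelLoadError(f"corrupted model archive {path}: {exc}") from exc
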