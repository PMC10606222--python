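"""Survival datasets, covariate standardization and CSV input.

The package operates on right-censored time-to-event data: each subject
contributes a numeric covariate vector ``x`` in R^m, an observed time
``t > 0`` (time to event or to loss of follow-up) and an event indicator
``delta`` (1 = event observed, 0 = censored).  Covariates must already be
numeric; categorical encoding is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "Standardizer",
    "SchemaError",
    "DataValidationError",
    "read_survival_csv",
    "write_survival_csv",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class DataValidationError(ValueError):
    """Row-level contents violate the survival-data invariants."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data: covariates, observed times, event flags.

    Invariants enforced on construction: at least two rows, strictly
    positive times, events in {0, 1}, no missing covariates, and equal
    row counts across the three arrays.
    """

    covariates: np.ndarray
    times: np.ndarray
    events: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        t = np.asarray(self.times, dtype=float).ravel()
        d = np.asarray(self.events)

        if X.shape[0] != t.shape[0] or t.shape[0] != d.shape[0]:
            raise DataValidationError(
                f"row count mismatch: covariates {X.shape[0]}, "
                f"times {t.shape[0]}, events {d.shape[0]}"
            )
        if X.shape[0] < 2:
            raise DataValidationError("need at least 2 subjects")
        if not np.all(np.isfinite(X)):
            bad = int(np.argwhere(~np.isfinite(X).all(axis=1))[0, 0])
            raise DataValidationError(f"missing/non-finite covariate in row {bad}")
        if not np.all(np.isfinite(t) & (t > 0)):
            bad = int(np.argwhere(~(np.isfinite(t) & (t > 0)))[0, 0])
            raise DataValidationError(f"non-positive or non-finite time in row {bad}")

        d_arr = np.asarray(d)
        if d_arr.dtype == bool:
            d_int = d_arr.astype(np.int8)
        else:
            d_float = np.asarray(d_arr, dtype=float)
            if not np.all(np.isin(d_float, (0.0, 1.0))):
                bad = int(np.argwhere(~np.isin(d_float, (0.0, 1.0)))[0, 0])
                raise DataValidationError(
                    f"event indicator not in {{0,1}} in row {bad}"
                )
            d_int = d_float.astype(np.int8)

        names = self.feature_names
        if names is not None:
            names = tuple(str(c) for c in names)
            if len(names) != X.shape[1]:
                raise DataValidationError(
                    f"{len(names)} feature names for {X.shape[1]} columns"
                )

        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", d_int)
        object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_features(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset (fold splitting etc.); preserves feature names."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.covariates[idx], self.times[idx], self.events[idx],
            self.feature_names,
        )

    def to_frame(self, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
        names = self.feature_names or tuple(
            f"x{i + 1}" for i in range(self.n_features)
        )
        df = pd.DataFrame(self.covariates, columns=list(names))
        df[time_col] = self.times
        df[event_col] = self.events
        return df


@dataclass
class Standardizer:
    """Per-column location/scale transform fitted on training data.

    Uses the population standard deviation (denominator ``n``); the
    choice only rescales the effective grid of the kernel bandwidth and
    of the regularization weight, but it is fixed and documented so that
    fitted models are reproducible.
    """

    mean_: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale_: np.ndarray = field(default=None)  # type: ignore[assignment]

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise DataValidationError("need at least 2 rows to standardize")
        mean = X.mean(axis=0)
        scale = X.std(axis=0)  # ddof=0
        if np.any(scale <= 0):
            bad = int(np.argwhere(scale <= 0)[0, 0])
            raise DataValidationError(f"constant covariate column {bad}")
        self.mean_, self.scale_ = mean, scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_

    def _check_fitted(self) -> None:
        if self.mean_ is None or self.scale_ is None:
            raise RuntimeError("Standardizer is not fitted")


def fit_standardizer(data: SurvivalDataset) -> Standardizer:
    """Fit column means and population standard deviations on training data."""
    return Standardizer().fit(data.covariates)


def apply_standardizer(s: Standardizer, X: np.ndarray) -> np.ndarray:
    """Transform covariates with *training* location/scale parameters."""
    return s.transform(X)


def read_survival_csv(
    path: str | Path,
    time_col: str = "time",
    event_col: str = "event",
    feature_cols: Sequence[str] | None = None,
) -> SurvivalDataset:
    """Read a survival dataset from a headered CSV file.

    Parameters
    ----------
    path:
        CSV file with a header row.
    time_col, event_col:
        Names of the observed-time and event-indicator columns.
    feature_cols:
        Covariate columns; defaults to every other column, in file order.

    Raises
    ------
    SchemaError
        If a named column is absent or non-numeric.
    DataValidationError
        If a row violates the survival-data invariants (the offending
        row is named in the message).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")

    for col in (time_col, event_col):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not found in {path.name}")
    if feature_cols is None:
        feature_cols = [c for c in df.columns if c not in (time_col, event_col)]
    missing = [c for c in feature_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"feature columns not found: {missing}")
    if not feature_cols:
        raise SchemaError("no covariate columns")

    try:
        X = df[list(feature_cols)].to_numpy(dtype=float)
        t = df[time_col].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric values: {exc}") from exc

    return SurvivalDataset(X, t, df[event_col].to_numpy(), tuple(feature_cols))


def write_survival_csv(
    data: SurvivalDataset,
    path: str | Path,
    time_col: str = "time",
    event_col: str = "event",
) -> None:
    """Write a dataset as CSV with full float round-trip precision."""
    data.to_frame(time_col, event_col).to_csv(
        path, index=False, float_format="%.17g"
    )
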