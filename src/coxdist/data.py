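"""Survival datasets: CSV I/O, preprocessing, fold splitting and simulation.

The universal container is :class:`SurvivalDataset` — a covariate matrix with
an observed time and a right-censoring event indicator per subject. The
synthetic generator draws cohorts with a known linear log-hazard and a
configurable baseline hazard family, so that model-recovery tests have access
to the generative truth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

_FAMILIES = ("exponential", "weibull", "gompertz")


@dataclass
class SurvivalDataset:
    """Right-censored survival data: covariates, observed time, event flag.

    Parameters
    ----------
    covariates
        ``(n, p)`` float matrix. After :func:`rescale_unit_interval` every
        column lies in ``[0, 1]``.
    feature_names
        ``p`` column labels.
    time
        ``(n,)`` strictly positive observed times (event or censoring time),
        in whatever unit the study uses (carried opaquely).
    event
        ``(n,)`` indicator, 1 = event observed, 0 = right-censored.
    """

    covariates: np.ndarray
    feature_names: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.feature_names = list(self.feature_names)
        n = self.covariates.shape[0]
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError(
                f"misaligned dataset: {n} rows of covariates, "
                f"{self.time.shape[0]} times, {self.event.shape[0]} events"
            )
        if len(self.feature_names) != self.covariates.shape[1]:
            raise ValidationError("feature_names length does not match covariate columns")
        if np.any(self.time <= 0):
            raise ValidationError("times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        """Row-subset by integer or boolean index, preserving alignment."""
        return SurvivalDataset(
            self.covariates[idx], self.feature_names, self.time[idx], self.event[idx]
        )

    def to_frame(self, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.feature_names)
        df[time_col] = self.time
        df[event_col] = self.event
        return df


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative ground truth for a simulated censored cohort.

    The cohort follows a proportional-hazards model: each subject's hazard is
    the baseline family's hazard multiplied by ``exp(beta . x)`` with
    covariates drawn uniformly on ``[0, 1]``.

    ``baseline_params`` by family:

    - ``exponential``: ``{"scale": mean}``
    - ``weibull``: ``{"shape": k, "scale": lam}`` (cumulative hazard ``(t/lam)**k``)
    - ``gompertz``: ``{"shape": eta, "rate": b}`` (hazard ``b * exp(eta t)``)
    """

    n: int
    beta: tuple[float, ...]
    baseline: str = "exponential"
    baseline_params: dict = field(default_factory=lambda: {"scale": 100.0})
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline not in _FAMILIES:
            raise ConfigurationError(f"unknown baseline family {self.baseline!r}")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValidationError("censor_rate must lie in [0, 1)")
        if any(v <= 0 for v in self.baseline_params.values()):
            raise ConfigurationError("baseline parameters must be strictly positive")
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))


@dataclass(frozen=True)
class CohortTruth:
    """Hidden generative quantities returned alongside a simulated cohort."""

    linear_predictor: np.ndarray  # beta . x per subject
    true_time: np.ndarray  # uncensored event time per subject
    censor_time: np.ndarray


@dataclass(frozen=True)
class FoldSplit:
    """Assignment of ``n`` subjects to ``k`` cross-validation folds."""

    k: int
    assignments: np.ndarray
    seed: int

    def folds(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (train_idx, test_idx) for each fold in order."""
        for f in range(self.k):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield train, test


def read_survival_csv(path, time_col: str, event_col: str) -> SurvivalDataset:
    """Read a survival table from CSV.

    All columns other than ``time_col`` and ``event_col`` are features.
    Categorical (non-numeric) columns are label-encoded by sorted label order;
    rows with missing values are dropped (with a logged count).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in {path}")
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info("dropped %d rows with missing values", n_before - len(df))
    feature_cols = [c for c in df.columns if c not in (time_col, event_col)]
    encoded = {}
    for c in feature_cols:
        col = df[c]
        if not pd.api.types.is_numeric_dtype(col):
            levels = sorted(col.astype(str).unique())
            mapping = {lev: i for i, lev in enumerate(levels)}
            col = col.astype(str).map(mapping)
        encoded[c] = col.to_numpy(dtype=float)
    time = df[time_col].to_numpy(dtype=float)
    if np.any(time <= 0):
        raise ValidationError(f"non-positive times in column {time_col!r}")
    X = (
        np.column_stack([encoded[c] for c in feature_cols])
        if feature_cols
        else np.empty((len(df), 0))
    )
    return SurvivalDataset(X, feature_cols, time, df[event_col].to_numpy(dtype=int))


def write_survival_csv(
    dataset: SurvivalDataset, path, time_col: str = "time", event_col: str = "event"
) -> None:
    """Write a dataset back to CSV in the same dialect read_survival_csv expects."""
    dataset.to_frame(time_col, event_col).to_csv(path, index=False)


def rescale_unit_interval(dataset: SurvivalDataset) -> SurvivalDataset:
    """Map every covariate column onto [0, 1] by (x - min) / (max - min).

    Constant columns map to 0. Times and events are untouched.
    """
    if dataset.n == 0:
        raise ValidationError("cannot rescale an empty dataset")
    X = dataset.covariates
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    out = np.zeros_like(X)
    nonconst = span > 0
    out[:, nonconst] = (X[:, nonconst] - lo[nonconst]) / span[nonconst]
    return dataclasses.replace(dataset, covariates=out)


def _inverse_cumulative_hazard(family: str, params: dict, u: np.ndarray) -> np.ndarray:
    """Solve H0(t) = u for t, for each baseline family."""
    if family == "exponential":
        return params["scale"] * u
    if family == "weibull":
        return params["scale"] * u ** (1.0 / params["shape"])
    if family == "gompertz":
        eta, b = params["shape"], params["rate"]
        return np.log1p(eta * u / b) / eta
    raise ConfigurationError(f"unknown baseline family {family!r}")


def simulate_cohort(spec: SyntheticSpec) -> tuple[SurvivalDataset, CohortTruth]:
    """Draw a right-censored cohort under a proportional-hazards model.

    Covariates are uniform on [0, 1]; the event time comes from the baseline
    family with hazard multiplied by ``exp(beta . x)`` (inverse-transform via
    the cumulative hazard). Censoring is independent exponential, with the
    rate solved numerically so the expected censored fraction matches
    ``spec.censor_rate``. Returns the observed dataset and the hidden truth.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.beta)
    X = rng.uniform(size=(spec.n, p))
    lp = X @ np.asarray(spec.beta)
    # S(t|x) = exp(-H0(t) e^lp)  =>  T = H0^{-1}(Exp(1)/e^lp)
    e = rng.exponential(size=spec.n)
    true_time = _inverse_cumulative_hazard(spec.baseline, spec.baseline_params, e / np.exp(lp))
    true_time = np.maximum(true_time, np.finfo(float).tiny)

    if spec.censor_rate == 0.0:
        censor_time = np.full(spec.n, np.inf)
    else:
        # P(C < T_i) = 1 - exp(-c T_i) for exponential censoring at rate c;
        # choose c so the mean over the realized true times hits censor_rate.
        def expected_censored(log_c: float) -> float:
            return float(np.mean(-np.expm1(-np.exp(log_c) * true_time))) - spec.censor_rate

        scale = float(np.mean(true_time))
        log_c = brentq(expected_censored, np.log(1e-12 / scale), np.log(1e12 / scale))
        censor_time = rng.exponential(scale=np.exp(-log_c), size=spec.n)

    observed = np.minimum(true_time, censor_time)
    event = (true_time <= censor_time).astype(int)
    names = [f"x{j}" for j in range(p)]
    ds = SurvivalDataset(X, names, observed, event)
    return ds, CohortTruth(lp, true_time, censor_time)


def kfold_split(n: int, k: int, seed: int) -> FoldSplit:
    """Randomly partition ``n`` subjects into ``k`` near-equal folds."""
    if k < 2:
        raise ValidationError("k must be at least 2")
    if n < k:
        raise ValidationError(f"cannot split n={n} subjects into k={k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    # cycle fold labels over the permutation: sizes differ by at most one
    assignments[perm] = np.arange(n) % k
    return FoldSplit(k=k, assignments=assignments, seed=seed)
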