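"""Kaplan-Meier estimation and evaluation metrics.

The headline metric is an intersection-over-union between two Kaplan-Meier
curves: the area under the pointwise minimum of the curves divided by the
area under the pointwise maximum, with areas approximated by left-endpoint
rectangle sums on a grid of spacing ``dx`` (default 0.1). RMSE and Lin's
concordance correlation coefficient complement it on uncensored subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .errors import ValidationError

DEFAULT_DX = 0.1


@dataclass(frozen=True)
class StepCurve:
    """A non-increasing, right-continuous step function S(t) starting at 1.

    ``values[i]`` is the survival probability on ``[breakpoints[i],
    breakpoints[i+1])``; S is 1 before the first breakpoint and stays at
    ``values[-1]`` beyond the last. ``domain_end`` records the largest time
    the curve was estimated over (the last observed time, event or censored).
    """

    breakpoints: np.ndarray
    values: np.ndarray
    domain_end: float

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", v)
        if bp.shape != v.shape or bp.ndim != 1:
            raise ValidationError("breakpoints and values must be aligned 1-d arrays")
        if bp.size and (np.any(np.diff(bp) <= 0) or bp[0] <= 0):
            raise ValidationError("breakpoints must be strictly increasing and positive")
        if np.any(np.diff(v) > 1e-12) or np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValidationError("values must be non-increasing within [0, 1]")

    def __call__(self, t) -> np.ndarray:
        """Evaluate S at times ``t`` (right-continuous step convention)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breakpoints, t, side="right")
        padded = np.concatenate(([1.0], self.values))
        return padded[idx]

    def to_tsv(self, path) -> None:
        """Export as two-column TSV (time, survival) including the t=0 point."""
        times = np.concatenate(([0.0], self.breakpoints))
        surv = np.concatenate(([1.0], self.values))
        np.savetxt(path, np.column_stack([times, surv]), delimiter="\t",
                   header="time\tsurvival", comments="")


def kaplan_meier(time, event) -> StepCurve:
    """Product-limit survival estimate from right-censored data.

    At each distinct event time t_j with d_j events among n_j subjects at
    risk, the curve multiplies by (1 - d_j / n_j); censored observations only
    shrink the risk set.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0 or time.shape != event.shape:
        raise ValidationError("time and event must be nonempty aligned arrays")
    if np.any(time <= 0):
        raise ValidationError("times must be strictly positive")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return StepCurve(times[keep], np.minimum.accumulate(vals[keep]),
                     domain_end=float(time.max()))


def _grid(t_max: float, dx: float) -> tuple[np.ndarray, float]:
    """Left endpoints of the full rectangles covering [0, t_max], plus the
    width of the final partial rectangle."""
    m = int(np.floor(t_max / dx + 1e-9))
    return np.arange(m) * dx, t_max - m * dx


def curve_area(curve: StepCurve, dx: float = DEFAULT_DX, t_max: float | None = None) -> float:
    """Left-endpoint rectangle-sum area under the curve over [0, t_max]."""
    if t_max is None:
        t_max = curve.domain_end
    if t_max <= 0 or dx <= 0:
        raise ValidationError("t_max and dx must be positive")
    grid, rem = _grid(t_max, dx)
    area = float(np.sum(curve(grid)) * dx)
    if rem > 1e-12:  # partial rectangle at the right edge
        area += float(curve(grid[-1] + dx) * rem) if grid.size else float(rem)
    return area


def curve_iou(pred: StepCurve, truth: StepCurve, dx: float = DEFAULT_DX) -> float:
    """IoU of two survival curves: area(min) / area(max) on a shared grid.

    The shared horizon is the larger of the two domain ends; each curve is
    extended beyond its last breakpoint at its final value.
    """
    t_max = max(pred.domain_end, truth.domain_end)
    if t_max <= 0:
        raise ValidationError("curves have an empty common domain")
    grid, rem = _grid(t_max, dx)
    sp, st = pred(grid), truth(grid)
    inter = float(np.sum(np.minimum(sp, st)) * dx)
    union = float(np.sum(np.maximum(sp, st)) * dx)
    if rem > 1e-12 and grid.size:
        te = grid[-1] + dx
        inter += float(min(pred(te), truth(te))) * rem
        union += float(max(pred(te), truth(te))) * rem
    return inter / union


def rmse(pred, truth) -> float:
    """Root mean squared error between predictions and ground truth."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValidationError("pred and truth must be nonempty and equal-length")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def ccc(pred, truth) -> float:
    """Lin's concordance correlation coefficient.

    2 cov(pred, truth) / (var(pred) + var(truth) + (mean gap)^2); 1 means
    perfect agreement with the 45-degree line, 0 no concordance.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValidationError("pred and truth must be equal-length with n >= 2")
    vp, vt = pred.var(), truth.var()
    if vp == 0 or vt == 0:
        raise ValidationError("concordance undefined for zero-variance input")
    cov = np.mean((pred - pred.mean()) * (truth - truth.mean()))
    return float(2 * cov / (vp + vt + (pred.mean() - truth.mean()) ** 2))
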