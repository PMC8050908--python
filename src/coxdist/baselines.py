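"""Classical survival-time generation through fixed distributions.

The comparator methods draw a positive random numerator u from a fixed
family (exponential, Weibull or Gompertz) and emit T = u / exp(h) where
exp(h) is a subject's predicted hazard ratio. Samplers use closed-form
inverse-transform from uniforms so runs are reproducible under a seed.

Parameterizations (all parameters strictly positive):

- exponential(scale mu): density exp(-t/mu)/mu, mean mu.
- weibull(shape k, scale lam): survival exp(-(t/lam)^k).
- gompertz(shape eta, rate b): hazard b*exp(eta*t), so
  survival exp(-(b/eta)(exp(eta*t)-1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import SurvivalDataset
from .errors import ConfigurationError, FitError, TrainingError
from .hazard_net import LOG_RISK_CLIP

_REQUIRED = {
    "exponential": ("scale",),
    "weibull": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
}


@dataclass(frozen=True)
class DistributionConfig:
    """A fixed generating family with its parameters and a sampling seed."""

    family: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _REQUIRED:
            raise ConfigurationError(f"unknown family {self.family!r}")
        missing = [k for k in _REQUIRED[self.family] if k not in self.parameters]
        if missing:
            raise ConfigurationError(
                f"{self.family} requires parameters {missing}"
            )
        if any(v <= 0 for v in self.parameters.values()):
            raise ConfigurationError("distribution parameters must be strictly positive")


def _sample_u(config: DistributionConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform sample of size n from the configured family."""
    u = rng.uniform(size=n)
    p = config.parameters
    if config.family == "exponential":
        return -p["scale"] * np.log1p(-u)
    if config.family == "weibull":
        return p["scale"] * (-np.log1p(-u)) ** (1.0 / p["shape"])
    # gompertz: F(t) = 1 - exp(-(b/eta)(e^{eta t} - 1))
    eta, b = p["shape"], p["rate"]
    return np.log1p(-eta / b * np.log1p(-u)) / eta


def generate_times(config: DistributionConfig, log_risks) -> np.ndarray:
    """Draw survival times T_i = u_i / exp(h_i), u_i from the family."""
    h = np.clip(np.asarray(log_risks, dtype=float), -LOG_RISK_CLIP, LOG_RISK_CLIP)
    rng = np.random.default_rng(config.seed)
    u = _sample_u(config, h.size, rng)
    return u / np.exp(h)


def fit_distribution_params(
    train_dataset: SurvivalDataset, family: str, log_risks=None, seed: int = 0
) -> DistributionConfig:
    """Fit a family's parameters to a training cohort by maximum likelihood.

    The numerator variable u is reconstructed for each uncensored training
    subject as observed_time * exp(h) (u = T e^h inverts the generation
    rule), and the family is fitted to those values. ``log_risks`` defaults
    to zero, i.e. fitting the raw times.
    """
    if family not in _REQUIRED:
        raise ConfigurationError(f"unknown family {family!r}")
    mask = train_dataset.event == 1
    if mask.sum() == 0:
        raise TrainingError("no uncensored subjects to fit on")
    t = train_dataset.time[mask]
    h = np.zeros(train_dataset.n) if log_risks is None else np.asarray(log_risks, float)
    u = t * np.exp(np.clip(h[mask], -LOG_RISK_CLIP, LOG_RISK_CLIP))
    if np.unique(u).size < 2:
        raise FitError("degenerate training times: a single distinct value")
    if family == "exponential":
        params = {"scale": float(np.mean(u))}
    elif family == "weibull":
        shape, _, scale = stats.weibull_min.fit(u, floc=0)
        params = {"shape": float(shape), "scale": float(scale)}
    else:
        # scipy's gompertz(c, scale s): F = 1 - exp(-c (e^{t/s} - 1));
        # ours has eta = 1/s, b = c/s.
        c, _, s = stats.gompertz.fit(u, floc=0)
        params = {"shape": float(1.0 / s), "rate": float(c / s)}
    if any(not np.isfinite(v) or v <= 0 for v in params.values()):
        raise FitError(f"{family} fit produced invalid parameters {params}")
    return DistributionConfig(family=family, parameters=params, seed=seed)
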