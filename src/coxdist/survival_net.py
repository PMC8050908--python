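"""The distribution function network and the integrated survival-time model.

A second MLP is trained on top of a frozen, pre-trained hazard ratio network.
Its per-subject output y_pred plays the role of the random numerator u in the
classical generation rule T = u / exp(h): the training loss is a variant of
mean squared error,

    loss = mean_i ( y_i - y_pred_i / exp(h_hat(x_i)) )^2,

over subjects whose death time y_i was actually observed, and the predicted
survival time is y_pred / exp(h_hat(x)). Censored subjects are excluded from
this loss by default (a censored time is only a lower bound on the death
time); an opt-in flag includes them as if they were events, for ablation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._nn import MLP, Adam
from .data import SurvivalDataset
from .errors import TrainingError, ValidationError
from .hazard_net import LOG_RISK_CLIP, HazardModel, NetworkSpec, _train_val_split

logger = logging.getLogger(__name__)


def _softplus(z):
    return np.logaddexp(0.0, z)


def _sigmoid(z):
    return 0.5 * (np.tanh(0.5 * z) + 1.0)


def dist_loss(y_pred, y_true_time, log_risks) -> float:
    """Variant-MSE loss: mean of (y_true - y_pred / exp(log_risk))^2.

    Log-risks are clipped at +/-50 before exponentiation as an overflow
    guard; the ratio y_pred/exp(h) is the generated survival time.
    """
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true_time, dtype=float)
    h = np.asarray(log_risks, dtype=float)
    if not (y_pred.shape == y_true.shape == h.shape):
        raise ValidationError("y_pred, y_true_time and log_risks must be aligned")
    if not np.isfinite(h).all():
        raise ValidationError("non-finite log-risks")
    ratio = y_pred / np.exp(np.clip(h, -LOG_RISK_CLIP, LOG_RISK_CLIP))
    return float(np.mean((y_true - ratio) ** 2))


class SurvivalTimeModel:
    """Frozen hazard network + trained distribution network.

    ``predict_time`` implements the survival generation function
    y_pred / exp(h_hat(x)). The distribution net's raw output is passed
    through softplus and multiplied by a fixed data-derived scale so y_pred
    is strictly positive and starts near the magnitude of the observed
    targets.
    """

    def __init__(self, hazard: HazardModel, net: MLP, scale: float,
                 spec: NetworkSpec, train_trace: np.ndarray,
                 val_trace: np.ndarray | None = None):
        self.hazard = hazard
        self._net = net
        self.scale = float(scale)
        self.spec = spec
        self.train_trace = np.asarray(train_trace, dtype=float)
        self.val_trace = None if val_trace is None else np.asarray(val_trace, dtype=float)

    def predict_y_pred(self, covariates) -> np.ndarray:
        """The distribution network's positive output y_pred per subject."""
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[1] != self.hazard.n_features:
            raise ValidationError(
                f"expected {self.hazard.n_features} features, got {X.shape[1]}"
            )
        raw, _ = self._net.forward(X, train=False)
        return _softplus(raw) * self.scale

    def predict_time(self, covariates) -> np.ndarray:
        h = self.hazard.predict(covariates)
        return self.predict_y_pred(covariates) / np.exp(h)

    def save(self, path) -> None:
        """Serialize both networks, specs and the output scale to one .npz."""
        import json
        from dataclasses import asdict

        arrays = {f"hW{l}": W for l, W in enumerate(self.hazard._net.weights)}
        arrays |= {f"hb{l}": b for l, b in enumerate(self.hazard._net.biases)}
        arrays |= {f"dW{l}": W for l, W in enumerate(self._net.weights)}
        arrays |= {f"db{l}": b for l, b in enumerate(self._net.biases)}
        meta = {
            "hazard_spec": asdict(self.hazard.spec),
            "dist_spec": asdict(self.spec),
            "feature_names": self.hazard.feature_names,
            "scale": self.scale,
        }
        np.savez(path, meta=json.dumps(meta), train_trace=self.train_trace, **arrays)

    @classmethod
    def load(cls, path) -> "SurvivalTimeModel":
        import json

        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            names = meta["feature_names"]
            hspec = NetworkSpec(**{**meta["hazard_spec"],
                                   "layer_widths": tuple(meta["hazard_spec"]["layer_widths"])})
            dspec = NetworkSpec(**{**meta["dist_spec"],
                                   "layer_widths": tuple(meta["dist_spec"]["layer_widths"])})
            hnet = MLP(len(names), hspec.layer_widths, hspec.activation,
                       hspec.dropout_layer, hspec.dropout_rate)
            hnet.weights = [f[f"hW{l}"] for l in range(len(hnet.weights))]
            hnet.biases = [f[f"hb{l}"] for l in range(len(hnet.biases))]
            hazard = HazardModel(hspec, hnet, names, np.array([]))
            dnet = MLP(len(names), dspec.layer_widths, dspec.activation,
                       dspec.dropout_layer, dspec.dropout_rate)
            dnet.weights = [f[f"dW{l}"] for l in range(len(dnet.weights))]
            dnet.biases = [f[f"db{l}"] for l in range(len(dnet.biases))]
            return cls(hazard, dnet, meta["scale"], dspec, f["train_trace"])


def train_distribution_net(
    dataset: SurvivalDataset,
    hazard: HazardModel,
    spec: NetworkSpec,
    include_censored: bool = False,
) -> SurvivalTimeModel:
    """Train the distribution function network against a frozen hazard net.

    Full-batch Adam minimizes :func:`dist_loss` on the uncensored subjects
    (all subjects when ``include_censored``), with early stopping on a
    held-out split of the same subjects. The hazard network's parameters are
    never touched; callers can verify via ``hazard.weights_hash()``.
    """
    mask = np.ones(dataset.n, bool) if include_censored else dataset.event == 1
    if include_censored:
        logger.warning("censored times treated as death times in the loss (ablation mode)")
    if mask.sum() == 0:
        raise TrainingError("no uncensored subjects to train the distribution network on")
    X = dataset.covariates[mask]
    y = dataset.time[mask]
    h = hazard.predict(X)
    eh = np.exp(h)
    scale = float(np.mean(y * eh))

    rng = np.random.default_rng(spec.seed)
    tr, val = _train_val_split(X.shape[0], spec.val_fraction, rng)
    if tr.size == 0:
        tr, val = np.arange(X.shape[0]), np.array([], dtype=int)
    net = MLP(dataset.p, spec.layer_widths, spec.activation,
              spec.dropout_layer, spec.dropout_rate, rng)
    opt = Adam(net, spec.learning_rate)
    monitor = val.size > 0

    def _loss_grad(raw, y_, eh_):
        y_pred = _softplus(raw) * scale
        resid = y_ - y_pred / eh_
        loss = float(np.mean(resid**2))
        dout = (-2.0 / y_.size) * resid / eh_ * _sigmoid(raw) * scale
        return loss, dout

    train_trace, val_trace = [], []
    best_loss, best_params, since_best = np.inf, net.get_flat(), 0
    for _ in range(spec.epochs):
        raw, cache = net.forward(X[tr], train=True, rng=rng)
        loss, dout = _loss_grad(raw, y[tr], eh[tr])
        if not np.isfinite(loss):
            raise TrainingError("non-finite distribution loss during training")
        gW, gb, _ = net.backward(cache, dout)
        opt.step(gW, gb)
        train_trace.append(loss)
        if monitor:
            vraw, _ = net.forward(X[val], train=False)
            vloss = dist_loss(_softplus(vraw) * scale, y[val], h[val])
            val_trace.append(vloss)
        else:
            vloss = loss
        if vloss < best_loss - 1e-12:
            best_loss, best_params, since_best = vloss, net.get_flat(), 0
        else:
            since_best += 1
            if spec.patience and since_best >= spec.patience:
                break
    net.set_flat(best_params)
    return SurvivalTimeModel(hazard, net, scale, spec,
                             np.asarray(train_trace),
                             np.asarray(val_trace) if monitor else None)


def predict_survival_time(model: SurvivalTimeModel, covariates) -> np.ndarray:
    """Predicted survival time per subject: y_pred / exp(h_hat(x))."""
    return model.predict_time(covariates)


def predicted_time_histogram(
    model: SurvivalTimeModel, covariates, bins: int = 20, which: str = "y_pred"
) -> pd.DataFrame:
    """Histogram of the model's outputs across a cohort.

    ``which`` selects the distribution-net output ``"y_pred"`` (the shape of
    the learned distribution) or the final ``"survival_time"`` predictions.
    Returns a table with bin_left, bin_right, count; counts sum to the
    cohort size and the edges cover [min, max] of the outputs.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] == 0:
        raise ValidationError("empty cohort")
    if which == "y_pred":
        values = model.predict_y_pred(X)
    elif which == "survival_time":
        values = model.predict_time(X)
    else:
        raise ValidationError(f"unknown histogram target {which!r}")
    counts, edges = np.histogram(values, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
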