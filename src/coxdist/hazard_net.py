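"""DeepSurv-style hazard ratio network.

A multilayer perceptron maps a subject's covariates to a scalar log-risk
h(x); exp(h(x)) is the hazard ratio multiplying an (unestimated) baseline
hazard. Training minimizes the Cox negative log partial likelihood, which
eliminates the baseline hazard entirely, with the Breslow convention for
tied event times (ties share one risk set).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import MLP, Adam
from .data import SurvivalDataset
from .errors import ConfigurationError, TrainingError, ValidationError

# log-risks are clipped here before exponentiation anywhere downstream
LOG_RISK_CLIP = 50.0


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and optimization settings shared by both networks.

    Defaults follow the reference configuration: hidden widths 64-32-32 with
    ReLU, scalar linear output, Xavier initialization, dropout 0.5 on the
    third layer only, Adam with learning rate 1e-5. ``epochs`` is an upper
    bound; training stops early when the validation objective has not
    improved for ``patience`` epochs (set ``val_fraction=0`` to disable).
    """

    layer_widths: tuple[int, ...] = (64, 32, 32, 1)
    activation: str = "relu"
    dropout_rate: float = 0.5
    dropout_layer: int = 3
    learning_rate: float = 1e-5
    epochs: int = 2000
    seed: int = 0
    patience: int = 100
    val_fraction: float = 0.2
    normalize_loss: bool = False

    def __post_init__(self) -> None:
        if not self.layer_widths or self.layer_widths[-1] != 1:
            raise ConfigurationError("layer_widths must end in 1 (scalar output)")
        if any(w < 1 for w in self.layer_widths):
            raise ConfigurationError("layer widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        object.__setattr__(self, "layer_widths", tuple(int(w) for w in self.layer_widths))


def _risk_set_quantities(log_risks, time):
    """Sorted-order helpers for the partial likelihood under Breslow ties.

    Returns (order, e, r, idx_last, shift): ``order`` sorts times descending,
    ``e`` are shifted exp(log-risks), ``r[i]`` the risk-set sum for sorted
    subject i, ``idx_last[i]`` the last sorted position in i's tie group.
    """
    order = np.argsort(-time, kind="stable")
    h_s = log_risks[order]
    t_s = time[order]
    shift = np.max(h_s)
    e = np.exp(h_s - shift)
    csum = np.cumsum(e)
    idx_last = np.searchsorted(-t_s, -t_s, side="right") - 1
    r = csum[idx_last]
    return order, e, r, idx_last, shift


def cox_npll(log_risks, time, event, normalize: bool = False) -> float:
    """Cox negative log partial likelihood.

    sum over subjects with an observed event of
    ``log( sum_{j: T_j >= T_i} exp(h_j) ) - h_i``, evaluated with a
    log-sum-exp shift. Tied event times share the full risk set (Breslow).
    ``normalize=True`` divides by the number of events.
    """
    log_risks = np.asarray(log_risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (log_risks.shape == time.shape == event.shape):
        raise ValidationError("log_risks, time and event must be aligned")
    if event.sum() == 0:
        raise TrainingError("partial likelihood undefined with no observed events")
    order, _, r, _, shift = _risk_set_quantities(log_risks, time)
    h_s = log_risks[order]
    ev_s = event[order].astype(bool)
    loss = float(np.sum((np.log(r[ev_s]) + shift) - h_s[ev_s]))
    return loss / event.sum() if normalize else loss


def cox_npll_grad(log_risks, time, event, normalize: bool = False) -> np.ndarray:
    """Analytic gradient of :func:`cox_npll` with respect to the log-risks."""
    log_risks = np.asarray(log_risks, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order, e, r, idx_last, _ = _risk_set_quantities(log_risks, time)
    ev_s = event[order].astype(float)
    # each event i contributes weight 1/r_i to every sorted position <= idx_last[i]
    c = np.zeros(log_risks.size)
    np.add.at(c, idx_last, ev_s / r)
    acc = np.cumsum(c[::-1])[::-1]
    grad_s = e * acc - ev_s
    grad = np.empty_like(grad_s)
    grad[order] = grad_s
    return grad / event.sum() if normalize else grad


class HazardModel:
    """A trained hazard ratio network: covariates -> scalar log-risk."""

    def __init__(self, spec: NetworkSpec, net: MLP, feature_names: list[str],
                 train_trace: np.ndarray, val_trace: np.ndarray | None = None):
        self.spec = spec
        self._net = net
        self.feature_names = list(feature_names)
        self.train_trace = np.asarray(train_trace, dtype=float)
        self.val_trace = None if val_trace is None else np.asarray(val_trace, dtype=float)

    @property
    def n_features(self) -> int:
        return self._net.weights[0].shape[0]

    def predict(self, covariates) -> np.ndarray:
        """Deterministic log-risk per row (dropout disabled)."""
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        out, _ = self._net.forward(X, train=False)
        return np.clip(out, -LOG_RISK_CLIP, LOG_RISK_CLIP)

    def weights_hash(self) -> int:
        return self._net.state_hash()

    def save(self, path) -> None:
        """Serialize spec, weights and feature names to one .npz file."""
        arrays = {f"W{l}": W for l, W in enumerate(self._net.weights)}
        arrays.update({f"b{l}": b for l, b in enumerate(self._net.biases)})
        meta = {"spec": asdict(self.spec), "feature_names": self.feature_names}
        np.savez(path, meta=json.dumps(meta), train_trace=self.train_trace, **arrays)

    @classmethod
    def load(cls, path) -> "HazardModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            spec = NetworkSpec(**{**meta["spec"],
                                  "layer_widths": tuple(meta["spec"]["layer_widths"])})
            names = meta["feature_names"]
            net = MLP(len(names), spec.layer_widths, spec.activation,
                      spec.dropout_layer, spec.dropout_rate)
            net.weights = [f[f"W{l}"] for l in range(len(net.weights))]
            net.biases = [f[f"b{l}"] for l in range(len(net.biases))]
            return cls(spec, net, names, f["train_trace"])


def _train_val_split(n: int, val_fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_val = int(round(n * val_fraction))
    return perm[n_val:], perm[:n_val]


def train_hazard(dataset: SurvivalDataset, spec: NetworkSpec) -> HazardModel:
    """Train the hazard ratio network on a censored cohort.

    Full-batch Adam on the Cox negative log partial likelihood (risk sets
    couple all rows, so minibatching would bias the objective). A fraction of
    the data is held out for early stopping; the parameters achieving the
    best validation loss are restored. Reproducible for a fixed spec seed.
    """
    if dataset.event.sum() == 0:
        raise TrainingError("dataset contains no observed events")
    rng = np.random.default_rng(spec.seed)
    tr_idx, val_idx = _train_val_split(dataset.n, spec.val_fraction, rng)
    if val_idx.size and dataset.event[val_idx].sum() == 0:
        tr_idx, val_idx = np.arange(dataset.n), np.array([], dtype=int)
    if dataset.event[tr_idx].sum() == 0:
        tr_idx, val_idx = np.arange(dataset.n), np.array([], dtype=int)

    net = MLP(dataset.p, spec.layer_widths, spec.activation,
              spec.dropout_layer, spec.dropout_rate, rng)
    opt = Adam(net, spec.learning_rate)
    Xtr, ttr, etr = dataset.covariates[tr_idx], dataset.time[tr_idx], dataset.event[tr_idx]
    monitor = val_idx.size > 0
    if monitor:
        Xv, tv, ev = dataset.covariates[val_idx], dataset.time[val_idx], dataset.event[val_idx]

    train_trace, val_trace = [], []
    best_loss, best_params, since_best = np.inf, net.get_flat(), 0
    for _ in range(spec.epochs):
        out, cache = net.forward(Xtr, train=True, rng=rng)
        loss = cox_npll(out, ttr, etr, normalize=spec.normalize_loss)
        if not np.isfinite(loss):
            raise TrainingError("non-finite Cox loss encountered during training")
        dout = cox_npll_grad(out, ttr, etr, normalize=spec.normalize_loss)
        gW, gb, _ = net.backward(cache, dout)
        opt.step(gW, gb)
        train_trace.append(loss)
        if monitor:
            vout, _ = net.forward(Xv, train=False)
            vloss = cox_npll(vout, tv, ev, normalize=spec.normalize_loss)
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
    return HazardModel(spec, net, dataset.feature_names,
                       np.asarray(train_trace),
                       np.asarray(val_trace) if monitor else None)


def predict_log_risk(model: HazardModel, covariates) -> np.ndarray:
    """Log-risk per row; exp of it is the hazard ratio used downstream."""
    return model.predict(covariates)
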