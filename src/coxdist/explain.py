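"""1D Grad-CAM feature attribution for the survival networks.

Grad-CAM was designed for convolutional feature maps; for a dense network on
tabular covariates the first hidden layer plays the role of the last
convolutional layer — it is the only layer with a direct linear relation to
the named input features. For each patient the scalar output's gradient with
respect to the first-hidden-layer activations weights those activations,
the product is rectified, and the resulting unit importances are projected
back onto input features through the absolute first-layer weights. Each
patient's attribution vector is L1-normalized before averaging so every
patient contributes equally to the cohort-level feature importances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hazard_net import HazardModel
from .survival_net import SurvivalTimeModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttributionResult:
    """Per-patient and cohort-averaged nonnegative feature attributions."""

    per_patient: np.ndarray  # (n, p), rows L1-normalized (or all-zero)
    per_feature_mean: np.ndarray  # (p,), column mean of per_patient
    sort_order: np.ndarray  # patients by descending predicted survival time
    feature_names: list[str]

    def to_tsv(self, path) -> None:
        """Export the mean importances as two-column TSV (feature, importance)."""
        pd.DataFrame(
            {"feature": self.feature_names, "importance": self.per_feature_mean}
        ).to_csv(path, sep="\t", index=False)


def _normalize_rows(A: np.ndarray) -> np.ndarray:
    s = A.sum(axis=1, keepdims=True)
    out = np.zeros_like(A)
    np.divide(A, s, out=out, where=s > 0)
    return out


def gradcam_1d(model, covariates) -> AttributionResult:
    """Grad-CAM attributions over input features for a trained model.

    Accepts a :class:`HazardModel` or a :class:`SurvivalTimeModel` (for the
    latter, the distribution network is attributed and patients are ordered
    by the integrated model's predicted survival time; hazard models order
    by ascending log-risk, i.e. descending implied survival).

    Networks without a hidden layer have no activation map; they fall back
    to rectified gradient-times-input.
    """
    if isinstance(model, SurvivalTimeModel):
        net = model._net
        names = model.hazard.feature_names
        sort_key = -model.predict_time(covariates)
    elif isinstance(model, HazardModel):
        net = model._net
        names = model.feature_names
        sort_key = model.predict(covariates)  # high risk ~ short survival
    else:
        raise ValidationError("model must be a HazardModel or SurvivalTimeModel")
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[1] != len(names):
        raise ValidationError(f"expected {len(names)} features, got {X.shape[1]}")

    if net.n_layers == 1:
        logger.info("no hidden layer: falling back to rectified gradient x input")
        grad = np.broadcast_to(net.weights[0][:, 0], X.shape)
        per_patient = np.maximum(grad * X, 0.0)
    else:
        _, activations, grads = net.output_and_hidden_grad(X, layer=1)
        cam = np.maximum(grads * activations, 0.0)  # (n, H1)
        per_patient = cam @ np.abs(net.weights[0]).T  # project to (n, p)
    per_patient = _normalize_rows(per_patient)
    order = np.argsort(sort_key, kind="stable")
    return AttributionResult(per_patient, per_patient.mean(axis=0), order, list(names))


def heatmap_table(attr: AttributionResult, predicted_times) -> pd.DataFrame:
    """Patient-by-feature attribution table sorted by predicted survival time
    descending (ties broken by original patient index).

    The returned frame's index is the original patient position; export with
    ``df.to_csv(path, sep="\\t")`` for plotting.
    """
    t = np.asarray(predicted_times, dtype=float)
    if t.shape[0] != attr.per_patient.shape[0]:
        raise ValidationError("predicted_times length does not match attributions")
    order = np.argsort(-t, kind="stable")
    return pd.DataFrame(
        attr.per_patient[order], index=order, columns=attr.feature_names
    )
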