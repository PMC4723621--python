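"""PLS-DA core: class coding, NIPALS PLS2 fitting, prediction, assignment.

PLS-DA regresses a 0/1 class-indicator matrix Y on the predictors X through
latent variables chosen to maximize the X-Y covariance. The NIPALS PLS2
variant used here deflates X after each component and leaves Y intact; the
regression coefficients have the closed form B = W (P^T W)^-1 Q^T, which
this module checks against the sequential deflation prediction in tests.

Class assignment is the argmax of the predicted indicator values, ties
broken toward the earliest class in the declared class order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = ["ClassCoding", "PLSModel", "dummy_code", "pls_fit", "pls_predict", "classify"]


@dataclass
class ClassCoding:
    """Ordered class names plus the 0/1 indicator matrix (one 1 per row)."""

    classes: list[str]
    indicator: np.ndarray  # (n, K)

    def labels(self) -> list[str]:
        idx = np.argmax(self.indicator, axis=1)
        return [self.classes[i] for i in idx]


def dummy_code(labels: list[str], class_order: list[str]) -> ClassCoding:
    """0/1 indicator coding of class labels in the given class order."""
    pos = {c: k for k, c in enumerate(class_order)}
    unknown = [l for l in labels if l not in pos]
    if unknown:
        raise ValueError(f"label {unknown[0]!r} not in class_order {class_order}")
    Y = np.zeros((len(labels), len(class_order)))
    for i, l in enumerate(labels):
        Y[i, pos[l]] = 1.0
    return ClassCoding(list(class_order), Y)


@dataclass
class PLSModel:
    """Fitted NIPALS PLS2 model with its training scaling parameters."""

    n_components: int
    weights: np.ndarray      # W (p, A)
    x_loadings: np.ndarray   # P (p, A)
    x_scores: np.ndarray     # T (n, A)
    y_loadings: np.ndarray   # Q (K, A)
    coef: np.ndarray         # B (p, K)
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    class_order: list[str] | None = None

    @property
    def n_variables(self) -> int:
        return self.weights.shape[0]


def pls_fit(
    X: np.ndarray,
    Y: np.ndarray | ClassCoding,
    n_components: int,
    scale: bool = True,
) -> PLSModel:
    """Fit NIPALS PLS2 of (centered) Y on (autoscaled) X.

    ``X`` and ``Y`` are taken on the raw scale; column scaling of X (mean 0,
    sample SD 1; constant columns centered only) and centering of Y happen
    here and the parameters are stored on the model so held-out samples can
    be projected consistently. With ``scale=False`` X is centered only.

    ``n_components`` must not exceed min(n-1, p); if X runs out of rank
    earlier the model is fitted up to the achievable rank with a warning.
    """
    X = np.asarray(X, dtype=float)
    class_order = None
    if isinstance(Y, ClassCoding):
        class_order = Y.classes
        Y = Y.indicator
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    x_mean, x_sd = _kernels.scale_columns(X)
    if not scale:
        x_sd = np.ones(p)
    Xs = (X - x_mean) / x_sd
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    W, P, Q, T = _kernels.nipals_pls2(
        Xs, Yc, n_components, _kernels.NIPALS_TOL, _kernels.NIPALS_MAX_ITER
    )
    if W.shape[1] < n_components:
        warnings.warn(
            f"X exhausted after {W.shape[1]} of {n_components} requested "
            "components; model fitted up to the achievable rank",
            stacklevel=2,
        )
    B = _kernels.pls_coefficients(W, P, Q)
    return PLSModel(
        n_components=W.shape[1],
        weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=Q,
        coef=B,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        class_order=class_order,
    )


def pls_predict(model: PLSModel, x_new: np.ndarray) -> np.ndarray:
    """Continuous per-class predictions for raw-scale sample(s).

    ``x_new`` is scaled with the model's stored training parameters,
    multiplied by B, and the training Y means are added back. Accepts a
    single sample vector or a samples x variables matrix.
    """
    x_new = np.asarray(x_new, dtype=float)
    single = x_new.ndim == 1
    X = np.atleast_2d(x_new)
    if X.shape[1] != model.n_variables:
        raise ValueError(
            f"expected {model.n_variables} variables, got {X.shape[1]}"
        )
    Xs = (X - model.x_mean) / model.x_sd
    Yhat = Xs @ model.coef + model.y_mean
    return Yhat[0] if single else Yhat


def classify(
    predictions: np.ndarray, class_order: list[str]
) -> str | list[str]:
    """Argmax class assignment; ties go to the earliest class in order."""
    pred = np.asarray(predictions, dtype=float)
    single = pred.ndim == 1
    P = np.atleast_2d(pred)
    if P.shape[1] != len(class_order):
        raise ValueError("prediction width does not match class_order")
    idx = np.argmax(P, axis=1)  # argmax takes the first maximum: earliest class
    out = [class_order[i] for i in idx]
    return out[0] if single else out
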