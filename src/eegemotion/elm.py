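"""Extreme learning machine: random sigmoid hidden layer + one-shot solve.

A single-hidden-layer feedforward network whose input-to-hidden weights
``alpha`` (k x d) and biases ``beta`` (k) are drawn i.i.d. uniform on
[-1, 1] and never trained.  The hidden activation of sample x is the
sigmoid m_j(x) = 1 / (1 + exp(-(alpha_j . x + beta_j))).  Stacking the
activations of N samples gives the hidden-layer output matrix M (N x k);
the only learned parameters are the hidden-to-output weights, obtained in
a single non-iterative step as the minimum-norm least-squares solution

    gamma = pinv(M) @ L

against 0/1 one-hot targets L (N x n_classes).  With a ridge penalty
lambda > 0 the solve becomes (M'M + lambda I)^{-1} M' L instead.  Class
scores are M gamma; they are not probabilities and carry no normalisation.
Prediction is the argmax score, ties broken toward the lowest class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, InputError

DEFAULT_HIDDEN = 500
_SERIAL_VERSION = 1


def init_hidden(d: int, k: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw the fixed random hidden layer: alpha (k x d), beta (k,)."""
    if d < 1 or k < 1:
        raise ConfigurationError("input dimension d and hidden count k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = rng.uniform(-1.0, 1.0, size=(k, d))
    beta = rng.uniform(-1.0, 1.0, size=k)
    return alpha, beta


def hidden_map(X: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Sigmoid hidden activations M (N x k); entries strictly in (0, 1)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != alpha.shape[1]:
        raise InputError(
            f"input dimension {X.shape[1]} does not match hidden layer ({alpha.shape[1]})"
        )
    return expit(X @ alpha.T + beta)


@dataclass(frozen=True)
class ElmModel:
    """Immutable fitted classifier."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma_out: np.ndarray
    classes: tuple
    seed: int
    k: int
    ridge: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("hidden count k must be >= 1")
        if self.alpha.shape[0] != self.k or self.beta.shape != (self.k,):
            raise InputError("alpha/beta shapes inconsistent with k")
        if self.gamma_out.shape != (self.k, len(self.classes)):
            raise InputError("gamma_out shape inconsistent with (k, n_classes)")


def one_hot(labels, classes) -> np.ndarray:
    """0/1 target matrix, one column per class, exactly one 1 per row."""
    classes = list(classes)
    index = {c: j for j, c in enumerate(classes)}
    L = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        L[i, index[lab]] = 1.0
    return L


def fit(
    X: np.ndarray,
    labels,
    k: int = DEFAULT_HIDDEN,
    seed: int = 0,
    ridge: float | None = None,
) -> ElmModel:
    """Fit output weights in one pseudoinverse step.

    The hidden layer is drawn from ``seed``; ``gamma_out`` is the
    minimum-norm least-squares solution (SVD, singular values below
    max(N, k) x eps x s_max treated as zero), or the ridge solution when
    ``ridge`` > 0 is given.
    """
    X = np.atleast_2d(np.asarray(X, float))
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise InputError("label count must match row count")
    if len(labels) == 0:
        raise InputError("training data is empty")
    if not np.all(np.isfinite(X)):
        raise InputError("training features must be finite")
    if ridge is not None and ridge < 0:
        raise ConfigurationError("ridge must be nonnegative")

    classes = tuple(sorted(set(labels), key=str))
    L = one_hot(labels, classes)
    alpha, beta = init_hidden(X.shape[1], k, seed)
    M = hidden_map(X, alpha, beta)
    if ridge:
        A = M.T @ M + ridge * np.eye(k)
        gamma = np.linalg.solve(A, M.T @ L)
    else:
        rcond = max(M.shape) * np.finfo(float).eps
        gamma, *_ = np.linalg.lstsq(M, L, rcond=rcond)
    return ElmModel(
        alpha=alpha,
        beta=beta,
        gamma_out=gamma,
        classes=classes,
        seed=int(seed) if np.isscalar(seed) else -1,
        k=k,
        ridge=ridge,
    )


def predict_scores(X: np.ndarray, model: ElmModel) -> np.ndarray:
    """Raw class scores g(x) = M(x) gamma; unnormalised by construction."""
    return hidden_map(X, model.alpha, model.beta) @ model.gamma_out


def predict(X: np.ndarray, model: ElmModel):
    """Predicted labels: argmax score, ties to the lowest class index."""
    scores = predict_scores(X, model)
    idx = np.argmax(scores, axis=1)  # first maximum = lowest class index
    return [model.classes[i] for i in idx]


def save_model(model: ElmModel, path) -> None:
    """Serialise a fitted model to a self-describing JSON archive."""
    payload = {
        "format": "eegemotion-elm",
        "version": _SERIAL_VERSION,
        "k": model.k,
        "seed": model.seed,
        "ridge": model.ridge,
        "classes": list(model.classes),
        "alpha": model.alpha.tolist(),
        "beta": model.beta.tolist(),
        "gamma_out": model.gamma_out.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> ElmModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "eegemotion-elm":
        raise InputError(f"{path}: not an eegemotion ELM model archive")
    return ElmModel(
        alpha=np.array(payload["alpha"], float),
        beta=np.array(payload["beta"], float),
        gamma_out=np.array(payload["gamma_out"], float),
        classes=tuple(payload["classes"]),
        seed=payload["seed"],
        k=payload["k"],
        ridge=payload["ridge"],
    )
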