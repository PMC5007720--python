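"""Generalized linear classifier trained by IRLS or scaled conjugate gradient.

The model is a single linear layer with a bias row and either a softmax
output (one-hot targets, multinomial cross-entropy) or elementwise logistic
outputs (binary targets, Bernoulli cross-entropy).  Both objectives are
convex, so the two trainers converge to the same optimum when a small weight
decay makes it unique.

IRLS here is damped Newton / Fisher scoring on the cross-entropy: the exact
Hessian is assembled and each step is halved until the error does not
increase, which makes the error sequence non-increasing by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError, NumericError
from .activations import apply_output, cross_entropy
from .config import TrainConfig
from .scg import scg_minimize

logger = logging.getLogger(__name__)

_WEIGHT_CAP = 1e6
_MAX_HALVINGS = 30


@dataclass
class TrainingRecord:
    algorithm: str
    n_iterations: int
    final_error: float
    converged: bool
    error_history: list[float] = field(default_factory=list)


@dataclass
class GLMModel:
    weights: np.ndarray          # (n_features + 1, n_outputs), bias last row
    output_function: str
    training: TrainingRecord | None = None

    @property
    def n_features(self) -> int:
        return self.weights.shape[0] - 1

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[1]

    def to_dict(self) -> dict:
        return {
            "kind": "glm",
            "weights": self.weights.tolist(),
            "output_function": self.output_function,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GLMModel":
        return cls(np.asarray(d["weights"], dtype=float), d["output_function"])


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.hstack([X, np.ones((X.shape[0], 1))])


def init_glm(n_features: int, n_outputs: int, output_function: str,
             rng: np.random.Generator) -> GLMModel:
    """Random initial weights ~ N(0, 1/(n_features+1))."""
    w = rng.standard_normal((n_features + 1, n_outputs)) / np.sqrt(n_features + 1)
    return GLMModel(w, output_function)


def predict_glm(model: GLMModel, features: np.ndarray) -> np.ndarray:
    """Model outputs (probabilities), shape (n_samples, n_outputs)."""
    return apply_output(_augment(features) @ model.weights, model.output_function)


def glm_error(model: GLMModel, features: np.ndarray, targets: np.ndarray,
              weight_decay: float = 0.0) -> float:
    y = predict_glm(model, features)
    err = cross_entropy(y, targets, model.output_function)
    if weight_decay:
        err += 0.5 * weight_decay * float((model.weights ** 2).sum())
    return err


def _check_targets(targets: np.ndarray, output_function: str) -> None:
    t = np.asarray(targets)
    if output_function == "softmax":
        if not (np.all((t == 0) | (t == 1)) and np.allclose(t.sum(axis=1), 1)):
            raise ConfigurationError("softmax outputs need one-hot target rows")
    elif not np.all((t >= 0) & (t <= 1)):
        raise ConfigurationError("logistic outputs need targets in [0, 1]")


def _softmax_hessian(Xa: np.ndarray, Y: np.ndarray, decay: float) -> np.ndarray:
    """Exact multinomial Hessian, shape (d*m, d*m), d = n_features+1."""
    n, d = Xa.shape
    m = Y.shape[1]
    H = np.empty((m, d, m, d))
    for k in range(m):
        for l in range(k, m):
            w = -Y[:, k] * Y[:, l]
            if k == l:
                w = w + Y[:, k]
            block = Xa.T @ (w[:, None] * Xa)
            H[k, :, l, :] = block
            if l != k:
                H[l, :, k, :] = block
    H = H.reshape(m * d, m * d)
    H[np.diag_indices_from(H)] += decay
    return H


def _irls(model: GLMModel, X: np.ndarray, T: np.ndarray,
          config: TrainConfig) -> GLMModel:
    Xa = _augment(X)
    n, d = Xa.shape
    m = model.n_outputs
    W = model.weights.copy()
    decay = config.weight_decay

    def error(Wc):
        y = apply_output(Xa @ Wc, model.output_function)
        e = cross_entropy(y, T, model.output_function)
        return e + 0.5 * decay * float((Wc ** 2).sum())

    history = [error(W)]
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        Y = apply_output(Xa @ W, model.output_function)
        G = Xa.T @ (Y - T) + decay * W  # (d, m)
        if model.output_function == "softmax":
            H = _softmax_hessian(Xa, Y, decay)
            try:
                step = np.linalg.solve(
                    H + 1e-10 * np.eye(H.shape[0]),
                    G.T.reshape(-1),  # (m*d,) matching H's (m, d) blocks
                ).reshape(m, d).T
            except np.linalg.LinAlgError as exc:
                raise NumericError("singular IRLS Hessian") from exc
        else:
            step = np.empty_like(W)
            for j in range(m):
                w = Y[:, j] * (1.0 - Y[:, j])
                Hj = Xa.T @ (w[:, None] * Xa)
                Hj[np.diag_indices_from(Hj)] += decay + 1e-10
                try:
                    step[:, j] = np.linalg.solve(Hj, G[:, j])
                except np.linalg.LinAlgError as exc:
                    raise NumericError("singular IRLS Hessian") from exc
        # damped Newton: halve the step until the error does not increase
        scale = 1.0
        e_old = history[-1]
        for _ in range(_MAX_HALVINGS):
            W_new = W - scale * step
            e_new = error(W_new)
            if e_new <= e_old + 1e-12:
                break
            scale *= 0.5
        else:
            converged = True  # no downhill step left at machine precision
            history.append(e_old)
            break
        if np.abs(W_new).max() > _WEIGHT_CAP:
            logger.warning("IRLS weights exceeded %.0e; capped", _WEIGHT_CAP)
            W_new = np.clip(W_new, -_WEIGHT_CAP, _WEIGHT_CAP)
            e_new = error(W_new)
        W = W_new
        history.append(e_new)
        if e_old - e_new < config.tol_error * max(1.0, abs(e_new)):
            converged = True
            break
    model.weights = W
    model.training = TrainingRecord("irls", it, history[-1], converged, history)
    return model


def _scg(model: GLMModel, X: np.ndarray, T: np.ndarray,
         config: TrainConfig) -> GLMModel:
    Xa = _augment(X)
    shape = model.weights.shape
    decay = config.weight_decay

    def fun(wf):
        y = apply_output(Xa @ wf.reshape(shape), model.output_function)
        return cross_entropy(y, T, model.output_function) + \
            0.5 * decay * float((wf ** 2).sum())

    def grad(wf):
        W = wf.reshape(shape)
        Y = apply_output(Xa @ W, model.output_function)
        return (Xa.T @ (Y - T) + decay * W).ravel()

    res = scg_minimize(fun, grad, model.weights.ravel(),
                       max_iterations=config.max_iterations,
                       sigma0=config.sigma0, lambda0=config.lambda0,
                       tol_error=config.tol_error, tol_param=config.tol_param)
    model.weights = res.w.reshape(shape)
    model.training = TrainingRecord("scg", res.n_iterations, res.error,
                                    res.converged, res.error_history)
    return model


def train_glm(features: np.ndarray, targets: np.ndarray, output_function: str,
              algorithm: str = "irls", config: TrainConfig | None = None,
              initial: GLMModel | None = None) -> GLMModel:
    """Train a GLM on 0/1 targets with the named algorithm.

    ``targets`` must be one-hot rows for softmax outputs and binary matrices
    for logistic outputs.  Training is reproducible from
    ``config.rng_seed`` (which seeds the weight initialization).
    """
    config = config or TrainConfig()
    X = np.asarray(features, dtype=float)
    T = np.asarray(targets, dtype=float)
    _check_targets(T, output_function)
    if initial is None:
        rng = np.random.default_rng(config.rng_seed)
        initial = init_glm(X.shape[1], T.shape[1], output_function, rng)
    if algorithm == "irls":
        return _irls(initial, X, T, config)
    if algorithm == "scg":
        return _scg(initial, X, T, config)
    raise ConfigurationError(f"unknown GLM training algorithm {algorithm!r}")
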