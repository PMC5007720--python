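"""Feed-forward multi-layer perceptron with two interchangeable trainers.

The network has one or two hidden layers of logistic units and either a
softmax or an elementwise-logistic output layer; the error is the matched
cross-entropy, so the output delta of backpropagation is ``y - t`` for both
output functions.  Training is full batch with either

``gradient_descent``
    plain backpropagation steps ``w -= lr/n * grad`` (optional momentum), or
``scg``
    the scaled conjugate gradient scheme from :mod:`.scg`.

Both trainers stop at ``max_iterations`` (default 200) or at the
convergence tolerances, and both are reproducible from the initialization
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError, NumericError
from .activations import apply_output, cross_entropy, sigmoid
from .config import TrainConfig
from .glm import TrainingRecord
from .scg import scg_minimize


@dataclass
class MLPModel:
    layer_sizes: list[int]                 # [inputs, hidden..., outputs]
    weights: list[np.ndarray]              # per layer, (fan_in, fan_out)
    biases: list[np.ndarray]               # per layer, (fan_out,)
    output_function: str
    trainer: str = ""
    training: TrainingRecord | None = None

    def __post_init__(self):
        if not 1 <= len(self.layer_sizes) - 2 <= 2:
            raise ConfigurationError("MLP supports 1 or 2 hidden layers")

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    # -- flat parameter vector for generic optimizers ----------------------

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [w.ravel() for w in self.weights] + [b.ravel() for b in self.biases]
        )

    def unpack(self, flat: np.ndarray) -> None:
        pos = 0
        for i, w in enumerate(self.weights):
            self.weights[i] = flat[pos : pos + w.size].reshape(w.shape)
            pos += w.size
        for i, b in enumerate(self.biases):
            self.biases[i] = flat[pos : pos + b.size].reshape(b.shape)
            pos += b.size

    def to_dict(self) -> dict:
        return {
            "kind": "mlp",
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "output_function": self.output_function,
            "trainer": self.trainer,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            list(d["layer_sizes"]),
            [np.asarray(w, dtype=float) for w in d["weights"]],
            [np.asarray(b, dtype=float) for b in d["biases"]],
            d["output_function"],
            d.get("trainer", ""),
        )


def init_mlp(layer_sizes, output_function: str,
             rng: np.random.Generator) -> MLPModel:
    """Gaussian init scaled by 1/sqrt(fan_in + 1), reproducible from ``rng``."""
    sizes = list(int(s) for s in layer_sizes)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        scale = 1.0 / np.sqrt(fan_in + 1)
        weights.append(rng.standard_normal((fan_in, fan_out)) * scale)
        biases.append(rng.standard_normal(fan_out) * scale)
    return MLPModel(sizes, weights, biases, output_function)


def forward(model: MLPModel, features: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer; the last entry is the network output."""
    acts = [np.asarray(features, dtype=float)]
    for i in range(model.n_layers):
        a = acts[-1] @ model.weights[i] + model.biases[i]
        if i < model.n_layers - 1:
            acts.append(sigmoid(a))
        else:
            acts.append(apply_output(a, model.output_function))
    return acts


def predict_mlp(model: MLPModel, features: np.ndarray) -> np.ndarray:
    return forward(model, features)[-1]


def mlp_error(model: MLPModel, features: np.ndarray, targets: np.ndarray,
              weight_decay: float = 0.0) -> float:
    err = cross_entropy(predict_mlp(model, features), targets,
                        model.output_function)
    if weight_decay:
        err += 0.5 * weight_decay * float((model.pack() ** 2).sum())
    return err


def backprop_gradient(model: MLPModel, features: np.ndarray,
                      targets: np.ndarray, weight_decay: float = 0.0
                      ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the summed cross-entropy w.r.t. weights and biases."""
    acts = forward(model, features)
    delta = acts[-1] - np.asarray(targets, dtype=float)  # matched CE output delta
    grads_w = [None] * model.n_layers
    grads_b = [None] * model.n_layers
    for i in range(model.n_layers - 1, -1, -1):
        grads_w[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if weight_decay:
            grads_w[i] = grads_w[i] + weight_decay * model.weights[i]
            grads_b[i] = grads_b[i] + weight_decay * model.biases[i]
        if i > 0:
            delta = (delta @ model.weights[i].T) * acts[i] * (1.0 - acts[i])
    return grads_w, grads_b


def _train_gd(model: MLPModel, X: np.ndarray, T: np.ndarray,
              config: TrainConfig) -> MLPModel:
    n = X.shape[0]
    lr = config.learning_rate / n
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    history = [mlp_error(model, X, T, config.weight_decay)]
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        gw, gb = backprop_gradient(model, X, T, config.weight_decay)
        step_max = 0.0
        for i in range(model.n_layers):
            vel_w[i] = config.momentum * vel_w[i] - lr * gw[i]
            vel_b[i] = config.momentum * vel_b[i] - lr * gb[i]
            model.weights[i] = model.weights[i] + vel_w[i]
            model.biases[i] = model.biases[i] + vel_b[i]
            step_max = max(step_max, np.abs(vel_w[i]).max(),
                           np.abs(vel_b[i]).max())
        err = mlp_error(model, X, T, config.weight_decay)
        if not np.isfinite(err):
            raise NumericError(
                f"gradient descent diverged at iteration {it} "
                f"(learning_rate={config.learning_rate})"
            )
        df = history[-1] - err
        history.append(err)
        if step_max < config.tol_param and abs(df) < config.tol_error:
            converged = True
            break
    model.trainer = "gradient_descent"
    model.training = TrainingRecord("gradient_descent", it, history[-1],
                                    converged, history)
    return model


def _train_scg(model: MLPModel, X: np.ndarray, T: np.ndarray,
               config: TrainConfig) -> MLPModel:
    def fun(flat):
        model.unpack(flat)
        return mlp_error(model, X, T, config.weight_decay)

    def grad(flat):
        model.unpack(flat)
        gw, gb = backprop_gradient(model, X, T, config.weight_decay)
        return np.concatenate([g.ravel() for g in gw] + [g.ravel() for g in gb])

    res = scg_minimize(fun, grad, model.pack(),
                       max_iterations=config.max_iterations,
                       sigma0=config.sigma0, lambda0=config.lambda0,
                       tol_error=config.tol_error, tol_param=config.tol_param)
    model.unpack(res.w)
    model.trainer = "scg"
    model.training = TrainingRecord("scg", res.n_iterations, res.error,
                                    res.converged, res.error_history)
    return model


def train_mlp(features: np.ndarray, targets: np.ndarray, architecture,
              trainer: str = "scg", config: TrainConfig | None = None,
              output_function: str = "softmax",
              initial: MLPModel | None = None) -> MLPModel:
    """Train an MLP whose ``architecture`` lists all layer sizes.

    The first and last entries of ``architecture`` must match the feature
    and target dimensions.
    """
    config = config or TrainConfig()
    X = np.asarray(features, dtype=float)
    T = np.asarray(targets, dtype=float)
    sizes = list(int(s) for s in architecture)
    if sizes[0] != X.shape[1] or sizes[-1] != T.shape[1]:
        raise ConfigurationError(
            f"architecture {sizes} inconsistent with data "
            f"({X.shape[1]} features, {T.shape[1]} targets)"
        )
    if initial is None:
        rng = np.random.default_rng(config.rng_seed)
        initial = init_mlp(sizes, output_function, rng)
    if trainer == "gradient_descent":
        return _train_gd(initial, X, T, config)
    if trainer == "scg":
        return _train_scg(initial, X, T, config)
    raise ConfigurationError(f"unknown MLP trainer {trainer!r}")
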