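"""Output functions and matched cross-entropy errors.

Softmax outputs pair with the multinomial cross-entropy (one-hot targets);
logistic outputs pair with a sum of independent Bernoulli cross-entropy
terms (binary targets, several may be active at once).  Pairing the output
function with its canonical error keeps the output-layer delta of
backpropagation equal to ``y - t`` in both cases.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError

OUTPUT_FUNCTIONS = ("softmax", "logistic")

_EPS = 1e-12


def sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a, dtype=float)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def softmax(a: np.ndarray) -> np.ndarray:
    a = a - a.max(axis=-1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=-1, keepdims=True)


def apply_output(a: np.ndarray, output_function: str) -> np.ndarray:
    if output_function == "softmax":
        return softmax(a)
    if output_function == "logistic":
        return sigmoid(a)
    raise ConfigurationError(f"unknown output function {output_function!r}")


def cross_entropy(y: np.ndarray, t: np.ndarray, output_function: str) -> float:
    """Total (summed) cross-entropy matched to the output function."""
    y = np.clip(y, _EPS, 1.0 - _EPS)
    if output_function == "softmax":
        return float(-(t * np.log(y)).sum())
    if output_function == "logistic":
        return float(-(t * np.log(y) + (1.0 - t) * np.log(1.0 - y)).sum())
    raise ConfigurationError(f"unknown output function {output_function!r}")
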