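"""Classic pooled-covariance linear discriminant analysis.

The discriminant score of class ``k`` for a sample ``x`` is

    delta_k(x) = x' S^-1 mu_k - 1/2 mu_k' S^-1 mu_k + log pi_k

with ``S`` the pooled within-class covariance, ``mu_k`` the class mean and
``pi_k`` the prior.  Argmax over scores gives the predicted class.  The
pooled covariance is ridge-regularized by ``1e-8 * trace(S)/p`` on the
diagonal to keep degenerate fixtures invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, NumericError

_RIDGE = 1e-8


@dataclass
class LDAModel:
    class_means: np.ndarray          # (n_classes, n_features)
    pooled_covariance: np.ndarray    # (n_features, n_features)
    priors: np.ndarray               # (n_classes,)
    class_values: np.ndarray         # original class codes, (n_classes,)

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]

    def discriminant_coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """Linear coefficients (p x K) and intercepts (K,) of the scores."""
        A = np.linalg.solve(self.pooled_covariance, self.class_means.T)
        b = -0.5 * np.sum(self.class_means.T * A, axis=0) + np.log(self.priors)
        return A, b

    def to_dict(self) -> dict:
        return {
            "kind": "lda",
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
            "class_values": self.class_values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            np.asarray(d["class_means"], dtype=float),
            np.asarray(d["pooled_covariance"], dtype=float),
            np.asarray(d["priors"], dtype=float),
            np.asarray(d["class_values"]),
        )


def fit_lda(features: np.ndarray, class_indices: np.ndarray,
            priors: np.ndarray | None = None) -> LDAModel:
    """Fit pooled-covariance LDA.

    Requires at least two classes; classes with a single sample contribute
    nothing to the pooled covariance but still get a mean and a prior.
    Priors default to empirical class frequencies.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(class_indices)
    classes, counts = np.unique(y, return_counts=True)
    n, p = X.shape
    if classes.size < 2:
        raise ConfigurationError("LDA needs at least 2 classes")
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    for c, m in zip(classes, means):
        d = X[y == c] - m
        pooled += d.T @ d
    dof = max(n - classes.size, 1)
    pooled /= dof
    pooled = (pooled + pooled.T) / 2.0
    pooled[np.diag_indices_from(pooled)] += _RIDGE * np.trace(pooled) / p
    if priors is None:
        priors = counts / counts.sum()
    else:
        priors = np.asarray(priors, dtype=float)
        priors = priors / priors.sum()
    model = LDAModel(means, pooled, priors, classes)
    # fail fast if still singular
    try:
        model.discriminant_coefficients()
    except np.linalg.LinAlgError as exc:
        raise NumericError("pooled covariance is singular") from exc
    return model


def predict_lda(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Linear discriminant scores, shape (n_samples, n_classes)."""
    A, b = model.discriminant_coefficients()
    return np.asarray(features, dtype=float) @ A + b


def classify_lda(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Predicted class codes (argmax of scores, ties to lowest index)."""
    scores = predict_lda(model, features)
    return model.class_values[np.argmax(scores, axis=1)]
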