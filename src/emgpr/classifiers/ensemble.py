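"""Per-DoF ensembles of linear classifiers.

A single multi-class LDA cannot emit the multiple-unit output coding, so
simultaneous movements are handled by training one small 4-class model per
degree of freedom: its classes are agonist, antagonist, "other movement"
(some other DoF active) and rest.  The k block predictions are combined into
a full movement label by :func:`emgpr.coding.decode_per_dof`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..coding import MovementLabel, encode_targets
from ..errors import ConfigurationError
from .config import TrainConfig
from .glm import GLMModel, predict_glm, train_glm
from .lda import LDAModel, fit_lda, predict_lda

PER_DOF_BASES = ("lda", "glm-irls", "glm-scg")


@dataclass
class PerDofEnsemble:
    base: str
    models: list = field(default_factory=list)

    @property
    def n_dof(self) -> int:
        return len(self.models)

    def to_dict(self) -> dict:
        return {
            "kind": "per_dof_ensemble",
            "base": self.base,
            "models": [m.to_dict() for m in self.models],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerDofEnsemble":
        models = [
            LDAModel.from_dict(m) if m["kind"] == "lda" else GLMModel.from_dict(m)
            for m in d["models"]
        ]
        return cls(d["base"], models)


def _per_dof_classes(labels: list[MovementLabel], n_dof: int) -> np.ndarray:
    """4-way class codes per DoF (0 agonist, 1 antagonist, 2 other, 3 rest)."""
    enc = encode_targets(labels, "per_dof", n_dof)
    blocks = enc.targets.reshape(len(labels), n_dof, 4)
    return np.argmax(blocks, axis=2)


def fit_per_dof_ensemble(features: np.ndarray, labels: list[MovementLabel],
                         base: str = "lda", config: TrainConfig | None = None,
                         n_dof: int | None = None) -> PerDofEnsemble:
    """Train k independent 4-class models, one per degree of freedom.

    A window whose DoF is active trains that DoF's agonist/antagonist class
    regardless of co-active DoF; windows active only elsewhere train the
    "other" class; all-inactive windows train rest.  Classes absent from the
    training data (e.g. an all-rest dataset) are padded so every model still
    scores four units, with absent classes forced to -inf.
    """
    if base not in PER_DOF_BASES:
        raise ConfigurationError(f"per-DoF base must be one of {PER_DOF_BASES}")
    config = config or TrainConfig()
    X = np.asarray(features, dtype=float)
    if n_dof is None:
        n_dof = len(labels[0].dof_state)
    codes = _per_dof_classes(labels, n_dof)
    models = []
    for d in range(n_dof):
        y = codes[:, d]
        present = np.unique(y)
        if base == "lda":
            if present.size < 2:
                models.append(_ConstantBlock(int(present[0])))
                continue
            models.append(fit_lda(X, y))
        else:
            onehot = np.zeros((X.shape[0], 4))
            onehot[np.arange(X.shape[0]), y] = 1.0
            if present.size < 2:
                models.append(_ConstantBlock(int(present[0])))
                continue
            algo = base.split("-", 1)[1]
            models.append(train_glm(X, onehot, "softmax", algo, config))
    return PerDofEnsemble(base, models)


@dataclass
class _ConstantBlock:
    """Degenerate single-class block: always predicts its one seen class."""

    klass: int

    def to_dict(self) -> dict:
        return {"kind": "constant", "class": self.klass}


def predict_per_dof(ensemble: PerDofEnsemble, features: np.ndarray) -> np.ndarray:
    """Stacked block scores, shape (n_samples, n_dof, 4)."""
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    blocks = np.full((n, ensemble.n_dof, 4), -np.inf)
    for d, model in enumerate(ensemble.models):
        if isinstance(model, _ConstantBlock):
            blocks[:, d, model.klass] = 0.0
        elif isinstance(model, LDAModel):
            scores = predict_lda(model, X)
            blocks[:, d, model.class_values.astype(int)] = scores
        else:
            blocks[:, d, :] = predict_glm(model, X)
    return blocks
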