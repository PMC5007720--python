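"""Trainable end-to-end pipelines: normalization + classifier + decoder.

A :class:`MethodSpec` names one of the five model/trainer combinations under
comparison (``lda``, ``glm-irls``, ``glm-scg``, ``mlp-gd``, ``mlp-scg``) and
an output type.  The ``single`` output type poses one 3**k-way
classification problem (softmax / argmax); the ``multiple`` output type maps
to one logistic unit per individual movement for MLPs and, because a linear
discriminant cannot emit unit combinations, to a per-DoF ensemble of 4-class
models for the linear methods.

A fitted :class:`TrainedPipeline` owns the normalization parameters (fitted
on its training partition only), the model and the label table, and can be
serialized to a single self-describing JSON document.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .classifiers import (
    GLMModel,
    LDAModel,
    MLPModel,
    PerDofEnsemble,
    TrainConfig,
    fit_lda,
    fit_per_dof_ensemble,
    predict_glm,
    predict_lda,
    predict_mlp,
    predict_per_dof,
    train_glm,
    train_mlp,
)
from .coding import MovementLabel, decode_batch, encode_targets, enumerate_labels
from .errors import ConfigurationError
from .features import NormalizationSpec, apply_normalization, fit_normalization

METHODS = ("lda", "glm-irls", "glm-scg", "mlp-gd", "mlp-scg")
OUTPUT_TYPES = ("single", "multiple")


@dataclass
class MethodSpec:
    """One model/trainer combination plus its output type."""

    method: str
    output_type: str = "single"
    hidden: tuple[int, ...] = (32,)
    normalization: str = "zscore"
    train: TrainConfig = field(default_factory=TrainConfig)
    decode_threshold: float = 0.5

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown method {self.method!r}; choose from {METHODS}"
            )
        if self.output_type not in OUTPUT_TYPES:
            raise ConfigurationError(
                f"unknown output type {self.output_type!r}"
            )
        self.hidden = tuple(int(h) for h in self.hidden)

    @property
    def is_linear(self) -> bool:
        return not self.method.startswith("mlp")

    @property
    def scheme(self) -> str:
        """Target-encoding scheme this method trains against."""
        if self.output_type == "single":
            return "single"
        return "per_dof" if self.is_linear else "multiple"

    @property
    def name(self) -> str:
        return f"{self.method}/{self.output_type}"

    def with_seed(self, seed: int) -> "MethodSpec":
        return replace(self, train=replace(self.train, rng_seed=int(seed)))


@dataclass
class TrainedPipeline:
    spec: MethodSpec
    normalization: NormalizationSpec
    model: object
    label_table: list[MovementLabel]
    n_dof: int
    train_seconds: float = 0.0

    # -- prediction --------------------------------------------------------

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Raw decoder inputs for each window (scores or probabilities)."""
        X = apply_normalization(features, self.normalization)
        model = self.model
        if isinstance(model, LDAModel):
            scores = predict_lda(model, X)
            out = np.full((X.shape[0], len(self.label_table)), -np.inf)
            out[:, model.class_values.astype(int)] = scores
            return out
        if isinstance(model, GLMModel):
            return predict_glm(model, X)
        if isinstance(model, MLPModel):
            return predict_mlp(model, X)
        if isinstance(model, PerDofEnsemble):
            return predict_per_dof(model, X)
        raise ConfigurationError(f"cannot predict with {type(model).__name__}")

    def classify(self, features: np.ndarray) -> list[MovementLabel]:
        outputs = self.predict(features)
        return decode_batch(outputs, self.spec.scheme, self.label_table,
                            self.spec.decode_threshold)

    def accuracy(self, features: np.ndarray, class_indices: np.ndarray) -> float:
        """Fraction of windows whose full decoded state matches the truth."""
        pred = np.array([lab.class_index for lab in self.classify(features)])
        return float(np.mean(pred == np.asarray(class_indices)))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "emgpr-pipeline-v1",
            "method": self.spec.method,
            "output_type": self.spec.output_type,
            "hidden": list(self.spec.hidden),
            "decode_threshold": self.spec.decode_threshold,
            "normalization": self.normalization.to_dict(),
            "model": self.model.to_dict(),
            "n_dof": self.n_dof,
            "label_table": [
                {"class_index": lab.class_index, "name": lab.name,
                 "dof_state": list(lab.dof_state)}
                for lab in self.label_table
            ],
            "train_seconds": self.train_seconds,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedPipeline":
        spec = MethodSpec(d["method"], d["output_type"],
                          tuple(d.get("hidden", (32,))),
                          d["normalization"]["kind"],
                          decode_threshold=d.get("decode_threshold", 0.5))
        kind = d["model"]["kind"]
        loader = {"lda": LDAModel, "glm": GLMModel, "mlp": MLPModel,
                  "per_dof_ensemble": PerDofEnsemble}
        model = loader[kind].from_dict(d["model"])
        labels = [
            MovementLabel(tuple(e["dof_state"]), e["class_index"], e["name"])
            for e in d["label_table"]
        ]
        return cls(spec, NormalizationSpec.from_dict(d["normalization"]),
                   model, labels, d["n_dof"], d.get("train_seconds", 0.0))

    @classmethod
    def load(cls, path) -> "TrainedPipeline":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_pipeline(train_values: np.ndarray, train_class_indices: np.ndarray,
                 spec: MethodSpec,
                 label_table: list[MovementLabel] | None = None) -> TrainedPipeline:
    """Fit normalization (training rows only) and the requested model."""
    X_raw = np.asarray(train_values, dtype=float)
    y = np.asarray(train_class_indices, dtype=int)
    if label_table is None:
        n_dof = 1
        while 3 ** n_dof <= y.max():
            n_dof += 1
        label_table = enumerate_labels(n_dof)
    n_dof = len(label_table[0].dof_state)
    norm = fit_normalization(X_raw, spec.normalization)
    X = apply_normalization(X_raw, norm)
    labels = [label_table[i] for i in y]
    t0 = time.perf_counter()
    if spec.method == "lda":
        if spec.output_type == "single":
            model = fit_lda(X, y)
        else:
            model = fit_per_dof_ensemble(X, labels, "lda", spec.train, n_dof)
    elif spec.method.startswith("glm"):
        algo = spec.method.split("-", 1)[1]
        if spec.output_type == "single":
            targets = encode_targets(labels, "single", n_dof).targets
            model = train_glm(X, targets, "softmax", algo, spec.train)
        else:
            model = fit_per_dof_ensemble(X, labels, spec.method, spec.train,
                                         n_dof)
    else:  # mlp
        trainer = {"mlp-gd": "gradient_descent", "mlp-scg": "scg"}[spec.method]
        scheme = spec.scheme
        targets = encode_targets(labels, scheme, n_dof).targets
        out_fun = "softmax" if scheme == "single" else "logistic"
        arch = [X.shape[1], *spec.hidden, targets.shape[1]]
        model = train_mlp(X, targets, arch, trainer, spec.train, out_fun)
    seconds = time.perf_counter() - t0
    return TrainedPipeline(spec, norm, model, label_table, n_dof, seconds)
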