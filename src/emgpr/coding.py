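"""Movement label enumeration, target encodings and output decoding.

A movement label describes the state of ``k`` degrees of freedom (DoF), each
of which can be inactive (0), driven by its agonist (+1) or by its antagonist
(-1).  With the default three DoF of the hand/wrist (open/close,
flexion/extension, pronation/supination) this gives 3**3 = 27 labels: 26
movements (6 individual, 20 simultaneous combinations) plus rest.

Three target encodings are supported:

``single``
    one output unit per label (3**k units), one-hot; decoded by argmax.
``multiple``
    one unit per individual movement (2k units); a simultaneous movement
    activates several units; decoded by thresholding.
``per_dof``
    k blocks of four units (agonist, antagonist, other movement, rest), the
    scheme used by per-DoF ensembles of linear classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Canonical DoF directions, agonist first.
DEFAULT_DOF_NAMES: tuple[tuple[str, str], ...] = (
    ("open", "close"),
    ("flex", "extend"),
    ("pronation", "supination"),
)

REST_NAME = "rest"

PER_DOF_UNITS = ("agonist", "antagonist", "other", "rest")


@dataclass(frozen=True)
class MovementLabel:
    """One movement class: a per-DoF state vector plus its canonical index."""

    dof_state: tuple[int, ...]
    class_index: int
    name: str

    @property
    def is_rest(self) -> bool:
        return all(s == 0 for s in self.dof_state)

    @property
    def n_active_dof(self) -> int:
        return sum(1 for s in self.dof_state if s != 0)


def class_index_of(dof_state) -> int:
    """Mixed-radix index of a state vector: digit ``state+1`` in base 3,
    first DoF most significant."""
    idx = 0
    for s in dof_state:
        if s not in (-1, 0, 1):
            raise ConfigurationError(f"DoF state must be in {{-1,0,1}}, got {s}")
        idx = idx * 3 + (s + 1)
    return idx


def _label_name(dof_state, dof_names) -> str:
    parts = []
    for s, (ago, anta) in zip(dof_state, dof_names):
        if s == 1:
            parts.append(ago)
        elif s == -1:
            parts.append(anta)
    return " + ".join(parts) if parts else REST_NAME


def enumerate_labels(n_dof: int = 3, dof_names=None) -> list[MovementLabel]:
    """All 3**n_dof movement labels in canonical mixed-radix order.

    The returned order is the canonical class order used everywhere
    downstream (target encodings, confusion matrices, session movement
    lists).
    """
    if n_dof < 1:
        raise ConfigurationError("n_dof must be >= 1")
    if dof_names is None:
        if n_dof <= len(DEFAULT_DOF_NAMES):
            dof_names = DEFAULT_DOF_NAMES[:n_dof]
        else:
            dof_names = tuple(
                (f"dof{i+1}+", f"dof{i+1}-") for i in range(n_dof)
            )
    if len(dof_names) != n_dof:
        raise ConfigurationError("dof_names length must equal n_dof")
    labels = []
    for idx in range(3 ** n_dof):
        digits = []
        rem = idx
        for _ in range(n_dof):
            digits.append(rem % 3)
            rem //= 3
        state = tuple(d - 1 for d in reversed(digits))
        labels.append(
            MovementLabel(state, idx, _label_name(state, dof_names))
        )
    return labels


def individual_movement_names(dof_names=DEFAULT_DOF_NAMES) -> list[str]:
    """The 2k individual movement names in unit order (agonist, antagonist
    per DoF)."""
    return [name for pair in dof_names for name in pair]


@dataclass
class TargetEncoding:
    """Classifier target matrix for one encoding scheme."""

    scheme: str
    targets: np.ndarray
    n_outputs: int
    n_dof: int = 3
    label_table: list[MovementLabel] = field(default_factory=list)


def n_outputs_for(scheme: str, n_dof: int) -> int:
    if scheme == "single":
        return 3 ** n_dof
    if scheme == "multiple":
        return 2 * n_dof
    if scheme == "per_dof":
        return 4 * n_dof
    raise ConfigurationError(f"unknown encoding scheme: {scheme!r}")


def encode_targets(labels, scheme: str, n_dof: int | None = None) -> TargetEncoding:
    """Build the 0/1 target matrix for a list of :class:`MovementLabel`.

    ``per_dof`` rows carry one one-hot block of four units per DoF; a DoF's
    "other" unit fires for windows where some other DoF is active but this
    one is not.
    """
    labels = list(labels)
    if n_dof is None:
        n_dof = len(labels[0].dof_state) if labels else 3
    m = n_outputs_for(scheme, n_dof)
    targets = np.zeros((len(labels), m))
    for row, lab in enumerate(labels):
        if scheme == "single":
            targets[row, lab.class_index] = 1.0
        elif scheme == "multiple":
            for d, s in enumerate(lab.dof_state):
                if s == 1:
                    targets[row, 2 * d] = 1.0
                elif s == -1:
                    targets[row, 2 * d + 1] = 1.0
        else:  # per_dof
            rest = lab.is_rest
            for d, s in enumerate(lab.dof_state):
                if s == 1:
                    unit = 0
                elif s == -1:
                    unit = 1
                elif rest:
                    unit = 3
                else:
                    unit = 2
                targets[row, 4 * d + unit] = 1.0
    return TargetEncoding(scheme, targets, m, n_dof, labels)


def _label_by_state(state, label_table) -> MovementLabel:
    return label_table[class_index_of(state)]


def decode_single(outputs, label_table) -> MovementLabel:
    """Argmax decoding of a ``single`` output vector; ties break to the
    lowest class index."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape[-1] != len(label_table):
        raise ConfigurationError(
            f"expected {len(label_table)} outputs, got {outputs.shape[-1]}"
        )
    return label_table[int(np.argmax(outputs))]


def decode_multiple(outputs, label_table, threshold: float = 0.5) -> MovementLabel:
    """Threshold decoding of a ``multiple`` output vector.

    A unit is active iff its output exceeds ``threshold``.  If both units of
    one DoF are active the larger output wins (ties go to the agonist); no
    active unit decodes to rest.
    """
    outputs = np.asarray(outputs, dtype=float)
    k = outputs.shape[-1] // 2
    if outputs.shape[-1] != 2 * k or 3 ** k != len(label_table):
        raise ConfigurationError("output length inconsistent with label table")
    state = []
    for d in range(k):
        ago, anta = outputs[2 * d], outputs[2 * d + 1]
        a_on, b_on = ago > threshold, anta > threshold
        if a_on and b_on:
            state.append(1 if ago >= anta else -1)
        elif a_on:
            state.append(1)
        elif b_on:
            state.append(-1)
        else:
            state.append(0)
    return _label_by_state(state, label_table)


def decode_per_dof(block_outputs, label_table) -> MovementLabel:
    """Combine per-DoF blocks of (agonist, antagonist, other, rest) scores.

    Each block is decoded by argmax (ties to the lowest unit index); the
    "other" and "rest" units both map the DoF to inactive, so an all-"other"
    prediction is equivalent to rest.
    """
    blocks = np.asarray(block_outputs, dtype=float)
    if blocks.ndim == 1:
        blocks = blocks.reshape(-1, 4)
    k = blocks.shape[0]
    if blocks.shape != (k, 4) or 3 ** k != len(label_table):
        raise ConfigurationError("block shape inconsistent with label table")
    state = []
    for d in range(k):
        unit = int(np.argmax(blocks[d]))
        state.append({0: 1, 1: -1, 2: 0, 3: 0}[unit])
    return _label_by_state(state, label_table)


def decode_batch(outputs, scheme: str, label_table, threshold: float = 0.5):
    """Decode a matrix of classifier outputs row by row."""
    outputs = np.asarray(outputs, dtype=float)
    if scheme == "single":
        return [decode_single(row, label_table) for row in outputs]
    if scheme == "multiple":
        return [decode_multiple(row, label_table, threshold) for row in outputs]
    if scheme == "per_dof":
        return [decode_per_dof(row, label_table) for row in outputs]
    raise ConfigurationError(f"unknown encoding scheme: {scheme!r}")


def export_label_table(label_table, path) -> None:
    """Write the label table (index, name, state vector) as tab-delimited text."""
    with open(path, "w", encoding="utf-8") as fh:
        k = len(label_table[0].dof_state)
        cols = "\t".join(f"dof{i+1}" for i in range(k))
        fh.write(f"class_index\tname\t{cols}\n")
        for lab in label_table:
            state = "\t".join(str(s) for s in lab.dof_state)
            fh.write(f"{lab.class_index}\t{lab.name}\t{state}\n")
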