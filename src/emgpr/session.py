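"""Recording-session container and I/O.

A :class:`RecordingSession` holds raw multi-channel surface-EMG for a set of
movements: a ``[time x channels x movements]`` tensor in which the
repetitions of each movement are concatenated along the time axis, plus the
timing metadata needed to cut them apart again.

Two on-disk dialects are supported:

``fixture``
    a directory containing ``metadata.json`` and one delimited-text file per
    channel (``channel_01.tsv`` ... , each ``[time x movements]``).  Pure
    text, round-trips bit-for-bit; intended for tests and portability.
``mat``
    a MAT-file v5 with a single struct whose field names mirror the session
    containers used by Matlab-based prosthetics research platforms
    (sampling frequency ``sF``, contraction time ``cT``, repetitions ``nR``,
    channel count ``nCh``, movement names ``mvs``, sample tensor ``tdata``).
    Field names vary between releases of those platforms, so the reader and
    writer accept a configurable field map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.io

from .errors import DataError, StructuralError

#: session attribute -> MAT struct field name
DEFAULT_MAT_FIELD_MAP: dict[str, str] = {
    "sampling_rate": "sF",
    "contraction_time": "cT",
    "n_repetitions": "nR",
    "channel_count": "nCh",
    "movement_names": "mvs",
    "samples": "tdata",
    "subject_id": "sbj",
}

MAT_STRUCT_NAME = "recSession"

_REQUIRED = (
    "sampling_rate",
    "contraction_time",
    "n_repetitions",
    "channel_count",
    "movement_names",
    "samples",
)


@dataclass
class RecordingSession:
    """Raw multi-channel EMG for a list of movements.

    Parameters
    ----------
    sampling_rate : float
        Sampling frequency in Hz.
    contraction_time : float
        Duration of one repetition in seconds.
    n_repetitions : int
        Repetitions per movement, concatenated along time.
    channel_count : int
        Number of electrode channels.
    movement_names : list of str
        Ordered movement names; this order is the canonical class order.
    samples : ndarray, shape (time, channels, movements)
        Raw samples; repetitions concatenated along the first axis.
    subject_id : str
        Opaque subject identifier.
    repetition_boundaries : tuple of int, optional
        Start index of each repetition within the time axis.  When absent the
        time axis is divided into ``n_repetitions`` equal segments.
    """

    sampling_rate: float
    contraction_time: float
    n_repetitions: int
    channel_count: int
    movement_names: list[str]
    samples: np.ndarray
    subject_id: str = ""
    repetition_boundaries: tuple[int, ...] | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.movement_names = list(self.movement_names)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "RecordingSession":
        """Check every structural invariant; raise on the first violation."""
        if not self.movement_names:
            raise StructuralError("movement_names is empty")
        if self.sampling_rate <= 0:
            raise DataError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.contraction_time <= 0:
            raise DataError("contraction_time must be positive")
        if self.n_repetitions < 1:
            raise DataError("n_repetitions must be >= 1")
        if self.channel_count < 1:
            raise DataError("channel_count must be >= 1")
        if self.samples.ndim != 3:
            raise DataError(
                f"samples must be [time x channels x movements], got ndim={self.samples.ndim}"
            )
        t, ch, mv = self.samples.shape
        if ch != self.channel_count:
            raise DataError(
                f"samples have {ch} channels but channel_count={self.channel_count}"
            )
        if mv != len(self.movement_names):
            raise DataError(
                f"samples have {mv} movements but {len(self.movement_names)} names"
            )
        if not np.isfinite(self.samples).all():
            raise DataError("samples contain non-finite values")
        expected = self.sampling_rate * self.contraction_time * self.n_repetitions
        if expected > t + 1e-9:
            raise DataError(
                f"time axis ({t} samples) shorter than "
                f"sampling_rate*contraction_time*n_repetitions ({expected:g})"
            )
        bounds = self.effective_boundaries()
        if len(bounds) != self.n_repetitions or bounds[0] != 0 or any(
            b <= a for a, b in zip(bounds, bounds[1:])
        ) or bounds[-1] >= t:
            raise DataError(f"invalid repetition boundaries {bounds}")
        return self

    def effective_boundaries(self) -> tuple[int, ...]:
        """Repetition start indices (explicit if stored, else equal split)."""
        if self.repetition_boundaries is not None:
            return tuple(int(b) for b in self.repetition_boundaries)
        t = self.samples.shape[0]
        step = t // self.n_repetitions
        return tuple(i * step for i in range(self.n_repetitions))

    def repetition_segments(self, movement: int) -> list[np.ndarray]:
        """Per-repetition ``[time x channels]`` slices of one movement."""
        bounds = list(self.effective_boundaries()) + [self.samples.shape[0]]
        return [
            self.samples[a:b, :, movement] for a, b in zip(bounds, bounds[1:])
        ]

    def allclose(self, other: "RecordingSession", rtol: float = 1e-12) -> bool:
        meta_equal = (
            np.isclose(self.sampling_rate, other.sampling_rate, rtol=rtol)
            and np.isclose(self.contraction_time, other.contraction_time, rtol=rtol)
            and self.n_repetitions == other.n_repetitions
            and self.channel_count == other.channel_count
            and self.movement_names == other.movement_names
            and self.subject_id == other.subject_id
        )
        return meta_equal and np.allclose(self.samples, other.samples, rtol=rtol, atol=0)


# -- fixture dialect --------------------------------------------------------

def _write_fixture(session: RecordingSession, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "sampling_rate": session.sampling_rate,
        "contraction_time": session.contraction_time,
        "n_repetitions": session.n_repetitions,
        "channel_count": session.channel_count,
        "movement_names": session.movement_names,
        "subject_id": session.subject_id,
        "repetition_boundaries": list(session.effective_boundaries()),
        "n_time_samples": int(session.samples.shape[0]),
    }
    (path / "metadata.json").write_text(
        json.dumps(meta, indent=2), encoding="utf-8"
    )
    # %.17g preserves float64 exactly through a text round trip
    for ch in range(session.channel_count):
        np.savetxt(
            path / f"channel_{ch + 1:02d}.tsv",
            session.samples[:, ch, :],
            fmt="%.17g",
            delimiter="\t",
        )


def _read_fixture(path: Path) -> RecordingSession:
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise StructuralError(f"fixture metadata not found: {meta_path}")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))
    for key in _REQUIRED:
        if key != "samples" and key not in meta:
            raise StructuralError(f"fixture metadata missing required field {key!r}")
    n_ch = int(meta["channel_count"])
    channels = []
    for ch in range(n_ch):
        f = path / f"channel_{ch + 1:02d}.tsv"
        if not f.exists():
            raise StructuralError(f"fixture missing channel file {f.name}")
        data = np.loadtxt(f, delimiter="\t", ndmin=2)
        channels.append(data)
    samples = np.stack(channels, axis=1)  # (time, channels, movements)
    session = RecordingSession(
        sampling_rate=float(meta["sampling_rate"]),
        contraction_time=float(meta["contraction_time"]),
        n_repetitions=int(meta["n_repetitions"]),
        channel_count=n_ch,
        movement_names=[str(m) for m in meta["movement_names"]],
        samples=samples,
        subject_id=str(meta.get("subject_id", "")),
        repetition_boundaries=tuple(meta["repetition_boundaries"])
        if meta.get("repetition_boundaries") is not None
        else None,
    )
    return session.validate()


# -- MAT-file v5 dialect ----------------------------------------------------

def _write_mat(session: RecordingSession, path: Path, field_map) -> None:
    struct = {
        field_map["sampling_rate"]: session.sampling_rate,
        field_map["contraction_time"]: session.contraction_time,
        field_map["n_repetitions"]: session.n_repetitions,
        field_map["channel_count"]: session.channel_count,
        field_map["movement_names"]: np.array(session.movement_names, dtype=object),
        field_map["samples"]: session.samples,
        field_map["subject_id"]: session.subject_id,
    }
    scipy.io.savemat(str(path), {MAT_STRUCT_NAME: struct}, format="5")


def _mat_scalar(value) -> float:
    return float(np.asarray(value).ravel()[0])


def _read_mat(path: Path, field_map) -> RecordingSession:
    try:
        contents = scipy.io.loadmat(str(path), squeeze_me=False)
    except (OSError, ValueError) as exc:
        raise StructuralError(f"cannot read MAT file {path}: {exc}") from exc
    struct = None
    for key, value in contents.items():
        if not key.startswith("__"):
            struct = value
            break
    if struct is None:
        raise StructuralError("MAT file contains no session struct")
    fields = struct.dtype.names or ()
    record = struct.ravel()[0]

    def get(attr, required=True):
        name = field_map[attr]
        if name not in fields:
            if required:
                raise StructuralError(f"MAT session struct missing field {name!r}")
            return None
        return record[name]

    names_raw = np.asarray(get("movement_names")).ravel()
    movement_names = [str(np.asarray(n).ravel()[0]) for n in names_raw]
    subject = get("subject_id", required=False)
    samples = np.asarray(get("samples"), dtype=float)
    if samples.ndim == 2:
        samples = samples[:, :, np.newaxis]
    session = RecordingSession(
        sampling_rate=_mat_scalar(get("sampling_rate")),
        contraction_time=_mat_scalar(get("contraction_time")),
        n_repetitions=int(_mat_scalar(get("n_repetitions"))),
        channel_count=int(_mat_scalar(get("channel_count"))),
        movement_names=movement_names,
        samples=samples,
        subject_id="" if subject is None else str(np.asarray(subject).ravel()[0]),
    )
    return session.validate()


# -- public API -------------------------------------------------------------

def infer_dialect(path) -> str:
    """Guess the dialect from the path: ``.mat`` file vs fixture directory."""
    p = Path(path)
    return "mat" if p.suffix.lower() == ".mat" else "fixture"


def read_session(path, dialect: str | None = None, field_map=None) -> RecordingSession:
    """Read and validate a session from ``path`` in the given dialect."""
    p = Path(path)
    if dialect is None:
        dialect = infer_dialect(p)
    if dialect == "fixture":
        return _read_fixture(p)
    if dialect == "mat":
        return _read_mat(p, field_map or DEFAULT_MAT_FIELD_MAP)
    raise StructuralError(f"unknown session dialect {dialect!r}")


def write_session(session: RecordingSession, path, dialect: str | None = None,
                  field_map=None) -> None:
    """Validate ``session`` and write it to ``path``; refuses invalid sessions."""
    session.validate()
    p = Path(path)
    if dialect is None:
        dialect = infer_dialect(p)
    if dialect == "fixture":
        _write_fixture(session, p)
    elif dialect == "mat":
        _write_mat(session, p, field_map or DEFAULT_MAT_FIELD_MAP)
    else:
        raise StructuralError(f"unknown session dialect {dialect!r}")


def copy_session(session: RecordingSession, **changes) -> RecordingSession:
    """Shallow copy with field overrides."""
    return replace(session, **changes)
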