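"""Windowing, time-domain feature extraction and normalization.

The signal treatment follows the standard offline myoelectric pipeline: each
repetition of a movement is trimmed at both ends to keep only the isotonic
part of the contraction, fixed-length windows are slid over the remainder,
and four classic time-domain features are computed per window and channel:

MAV
    mean absolute value, ``mean(|x|)``.
WL
    waveform length, ``sum(|x[k+1] - x[k]|)``.
ZC
    zero crossings: sign changes between consecutive samples whose amplitude
    step exceeds a deadband threshold.
SSC
    slope sign changes: interior samples where the slope changes sign with
    both adjacent steps exceeding a deadband threshold.

With 8 channels this yields the familiar 32-dimensional feature vector.
Feature columns are normalized with parameters fitted on the training
partition only (z-score, or a midrange-0/range-2 map onto [-1, 1]).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np

from .coding import MovementLabel, enumerate_labels
from .errors import ConfigurationError, DataError
from .session import RecordingSession

logger = logging.getLogger(__name__)

FEATURE_SHORT_NAMES = ("mav", "wl", "zc", "ssc")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds plus the per-repetition trim."""

    window_length: float = 0.2
    increment: float = 0.05
    trim_fraction: float = 0.15

    def __post_init__(self):
        if self.window_length <= 0:
            raise ConfigurationError("window_length must be positive")
        if not 0 < self.increment <= self.window_length:
            raise ConfigurationError("require 0 < increment <= window_length")
        if not 0 <= self.trim_fraction < 0.5:
            raise ConfigurationError("trim_fraction must lie in [0, 0.5)")

    def in_samples(self, sampling_rate: float) -> tuple[int, int]:
        return (
            int(round(self.window_length * sampling_rate)),
            int(round(self.increment * sampling_rate)),
        )


def trim_recording(samples: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Remove the first and last ``trim_fraction`` of one repetition.

    Boundaries are floored: a 1000-sample repetition trimmed at 0.15 keeps
    samples 150..849.  Works on 1-D vectors or [time x channels] arrays.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ConfigurationError("trim_fraction must lie in [0, 0.5)")
    samples = np.asarray(samples)
    n = samples.shape[0]
    cut = int(np.floor(trim_fraction * n))
    out = samples[cut : n - cut]
    if out.shape[0] == 0:
        raise ConfigurationError("trimming removed the entire repetition")
    return out


def window_count(segment_length: int, window: int, increment: int) -> int:
    """Number of full windows in a contiguous segment: floor((L-w)/i) + 1."""
    if segment_length < window:
        return 0
    return (segment_length - window) // increment + 1


def slice_windows(samples: np.ndarray, spec: WindowSpec,
                  sampling_rate: float) -> np.ndarray:
    """Slide fixed windows over one contiguous ``[time x channels]`` segment.

    Returns an array ``(n_windows, window_samples, channels)`` of half-open
    sample intervals ``[start, start + w)``.  Windows never span segment
    boundaries because each repetition segment is sliced separately.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.ndim == 2 and samples.shape[0] < samples.shape[1] and samples.shape[0] == 1:
        samples = samples.T  # accept a plain vector
    w, inc = spec.in_samples(sampling_rate)
    n = window_count(samples.shape[0], w, inc)
    if n == 0:
        raise ConfigurationError(
            f"segment of {samples.shape[0]} samples shorter than window ({w})"
        )
    idx = np.arange(n)[:, None] * inc + np.arange(w)[None, :]
    return samples[idx]  # (n, w, channels)


def extract_td_features(window: np.ndarray, zc_threshold: float = 0.0,
                        ssc_threshold: float = 0.0) -> np.ndarray:
    """MAV, WL, ZC and SSC of a single-channel window (length >= 3)."""
    window = np.asarray(window, dtype=float).ravel()
    if window.size < 3:
        raise DataError("window must contain at least 3 samples")
    return _td_features_batch(window[None, :, None], zc_threshold,
                              ssc_threshold)[0, :, 0]


def _td_features_batch(windows: np.ndarray, zc_threshold: float,
                       ssc_threshold: float) -> np.ndarray:
    """Vectorized features for ``(n, w, ch)`` windows -> ``(n, 4, ch)``."""
    x = np.asarray(windows, dtype=float)
    mav = np.mean(np.abs(x), axis=1)
    dx = np.diff(x, axis=1)
    wl = np.sum(np.abs(dx), axis=1)
    zc = np.sum(
        (x[:, :-1] * x[:, 1:] < 0) & (np.abs(dx) > zc_threshold), axis=1
    ).astype(float)
    back = x[:, 1:-1] - x[:, :-2]
    fwd = x[:, 1:-1] - x[:, 2:]
    ssc = np.sum(
        (back * fwd > 0)
        & (np.abs(back) > ssc_threshold)
        & (np.abs(fwd) > ssc_threshold),
        axis=1,
    ).astype(float)
    return np.stack([mav, wl, zc, ssc], axis=1)


@dataclass
class FeatureMatrix:
    """Windowed feature vectors with movement labels.

    ``values`` is ``[n_windows x (channels * 4)]`` with per-channel feature
    blocks ordered (MAV, WL, ZC, SSC); ``class_indices`` maps each row into
    ``label_table`` (the canonical movement order).
    """

    values: np.ndarray
    class_indices: np.ndarray
    feature_names: list[str]
    label_table: list[MovementLabel]
    subject_id: str = ""

    @property
    def labels(self) -> list[MovementLabel]:
        return [self.label_table[i] for i in self.class_indices]

    @property
    def n_channels(self) -> int:
        return len(self.feature_names) // 4

    def validate(self) -> "FeatureMatrix":
        if self.values.shape[1] != len(self.feature_names):
            raise DataError("feature name count does not match columns")
        if self.values.shape[1] % 4 != 0:
            raise DataError("column count must be channels x 4")
        if self.values.shape[0] != self.class_indices.shape[0]:
            raise DataError("label count does not match rows")
        if not np.isfinite(self.values).all():
            raise DataError("feature matrix contains non-finite entries")
        return self

    def windows_per_class(self) -> dict[int, int]:
        idx, counts = np.unique(self.class_indices, return_counts=True)
        return dict(zip(idx.tolist(), counts.tolist()))

    # -- delimited-text export / import ------------------------------------

    def to_tsv(self, path) -> None:
        header = "class_index\t" + "\t".join(self.feature_names)
        data = np.column_stack([self.class_indices.astype(float), self.values])
        np.savetxt(path, data, fmt="%.17g", delimiter="\t", header=header,
                   comments="")

    @classmethod
    def from_tsv(cls, path, label_table=None, subject_id: str = "") -> "FeatureMatrix":
        if hasattr(path, "read"):
            text = path.read()
        else:
            with open(path, "r", encoding="utf-8") as fh:
                text = fh.read()
        lines = text.splitlines()
        names = lines[0].split("\t")[1:]
        data = np.loadtxt(io.StringIO("\n".join(lines[1:])), delimiter="\t",
                          ndmin=2)
        cls_idx = data[:, 0].astype(int)
        if label_table is None:
            n_dof = int(round(np.log(cls_idx.max() + 1) / np.log(3))) if cls_idx.size else 3
            n_dof = max(n_dof, 1)
            while 3 ** n_dof <= cls_idx.max():
                n_dof += 1
            label_table = enumerate_labels(n_dof)
        return cls(data[:, 1:], cls_idx, names, label_table, subject_id).validate()


def default_feature_names(n_channels: int) -> list[str]:
    return [
        f"ch{ch + 1}_{name}"
        for ch in range(n_channels)
        for name in FEATURE_SHORT_NAMES
    ]


def extract_features(session: RecordingSession, spec: WindowSpec = WindowSpec(),
                     zc_threshold: float = 0.0, ssc_threshold: float = 0.0,
                     label_table: list[MovementLabel] | None = None) -> FeatureMatrix:
    """Run the full trimming/windowing/feature pipeline over a session.

    Each repetition of each movement is trimmed independently and windowed
    without crossing repetition boundaries; per window, the four features of
    every channel are concatenated into one row.

    When ``label_table`` is omitted it is rebuilt from the number of
    movements (assumed to be a full 3**k enumeration in canonical order).
    """
    session.validate()
    n_mov = len(session.movement_names)
    if label_table is None:
        n_dof = 1
        while 3 ** n_dof < n_mov:
            n_dof += 1
        if 3 ** n_dof != n_mov:
            raise ConfigurationError(
                f"{n_mov} movements is not a full DoF enumeration; "
                "pass an explicit label_table"
            )
        label_table = enumerate_labels(n_dof)
    rows, labels = [], []
    for mov in range(n_mov):
        for segment in session.repetition_segments(mov):
            trimmed = trim_recording(segment, spec.trim_fraction)
            windows = slice_windows(trimmed, spec, session.sampling_rate)
            feats = _td_features_batch(windows, zc_threshold, ssc_threshold)
            # (n, 4, ch) -> rows of ch-major blocks [ch1 mav wl zc ssc, ch2 ...]
            rows.append(feats.transpose(0, 2, 1).reshape(feats.shape[0], -1))
            labels.extend([mov] * feats.shape[0])
    values = np.vstack(rows)
    fm = FeatureMatrix(
        values=values,
        class_indices=np.asarray(labels, dtype=int),
        feature_names=default_feature_names(session.channel_count),
        label_table=label_table,
        subject_id=session.subject_id,
    )
    return fm.validate()


# -- normalization ----------------------------------------------------------

NORMALIZATION_KINDS = ("zscore", "midrange0range2")


@dataclass
class NormalizationSpec:
    """Per-column affine normalization fitted on training data."""

    kind: str
    location: np.ndarray
    scale: np.ndarray

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "location": np.asarray(self.location).tolist(),
            "scale": np.asarray(self.scale).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(d["kind"], np.asarray(d["location"], dtype=float),
                   np.asarray(d["scale"], dtype=float))


def fit_normalization(training_features: np.ndarray, kind: str = "zscore") -> NormalizationSpec:
    """Fit column location/scale parameters on the training partition.

    ``zscore`` uses the column mean and sample standard deviation (ddof=1);
    ``midrange0range2`` maps the training column minimum to -1 and maximum
    to +1.  Degenerate (constant) columns get scale 1 with a logged warning.
    """
    X = np.asarray(training_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("need a 2-D matrix with at least 2 rows")
    if kind == "zscore":
        loc = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
    elif kind == "midrange0range2":
        lo, hi = X.min(axis=0), X.max(axis=0)
        loc = (hi + lo) / 2.0
        scale = (hi - lo) / 2.0
    else:
        raise ConfigurationError(f"unknown normalization kind {kind!r}")
    degenerate = scale <= 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance feature column(s); scale forced to 1",
            int(degenerate.sum()),
        )
        scale = np.where(degenerate, 1.0, scale)
    return NormalizationSpec(kind, loc, scale)


def apply_normalization(features: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    return (np.asarray(features, dtype=float) - spec.location) / spec.scale
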