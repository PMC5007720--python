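"""Seeded synthetic surface-EMG session generator.

Surface EMG during an isotonic contraction is well approximated, for the
purposes of time-domain pattern recognition, by band-limited Gaussian noise
whose envelope depends on which muscles are active.  The generator emulates
an 8-electrode forearm recording protocol: for each movement label every
channel carries band-limited noise (default 20–450 Hz) whose amplitude is

    amplitude = baseline * sqrt(1 + activation * snr)

so ``snr`` is the excess power of a fully active channel over the baseline.
Class structure comes from a ``[6 individual movements x channels]``
activation matrix with distinct, partially overlapping channel supports;
simultaneous movements combine the activation rows of their constituent
movements (``max`` by default: co-contraction saturates rather than sums).
``snr = 0`` makes all movements statistically identical (a chance-level
regime); large ``snr`` makes them separable by construction.

Sessions are fully reproducible from ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .coding import enumerate_labels
from .errors import ConfigurationError
from .session import RecordingSession


def default_activation_matrix() -> np.ndarray:
    """Per-movement channel activation patterns (6 movements x 8 channels).

    Each movement dominates 2–3 electrodes with partial overlap between
    movements, mimicking the spatial mixing of a circumferential forearm
    array; agonist/antagonist pairs of one DoF have different supports.
    Rows follow the canonical individual-movement order
    (open, close, flex, extend, pronation, supination).
    """
    return np.array(
        [
            # ch1   ch2   ch3   ch4   ch5   ch6   ch7   ch8
            [1.00, 0.60, 0.00, 0.00, 0.20, 0.00, 0.00, 0.30],  # open
            [0.00, 0.30, 1.00, 0.60, 0.00, 0.20, 0.00, 0.00],  # close
            [0.30, 0.00, 0.00, 0.20, 1.00, 0.60, 0.00, 0.00],  # flex
            [0.00, 0.00, 0.30, 0.00, 0.00, 0.20, 1.00, 0.60],  # extend
            [0.60, 0.00, 0.20, 0.00, 0.30, 0.00, 0.00, 1.00],  # pronation
            [0.00, 1.00, 0.00, 0.30, 0.00, 0.00, 0.60, 0.20],  # supination
        ]
    )


@dataclass
class SynthConfig:
    """Recording-protocol and signal parameters for the generator."""

    channel_count: int = 8
    sampling_rate: float = 2000.0
    contraction_time: float = 3.0
    n_repetitions: int = 3
    n_dof: int = 3
    activation_matrix: np.ndarray = field(default_factory=default_activation_matrix)
    combination_rule: str = "max"
    band: tuple[float, float] = (20.0, 450.0)
    filter_order: int = 4
    snr: float = 10.0
    baseline: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        self.activation_matrix = np.asarray(self.activation_matrix, dtype=float)
        rows, cols = self.activation_matrix.shape
        if rows != 2 * self.n_dof or cols != self.channel_count:
            raise ConfigurationError(
                f"activation matrix must be [{2 * self.n_dof} x "
                f"{self.channel_count}], got [{rows} x {cols}]"
            )
        if self.activation_matrix.min() < 0 or self.activation_matrix.max() > 1:
            raise ConfigurationError("activation entries must lie in [0, 1]")
        if self.snr < 0:
            raise ConfigurationError("snr must be >= 0")
        if self.combination_rule not in ("max", "sum"):
            raise ConfigurationError("combination_rule must be 'max' or 'sum'")
        lo, hi = self.band
        if not 0 < lo < hi < self.sampling_rate / 2:
            raise ConfigurationError(
                "band must satisfy 0 < low < high < Nyquist"
            )


def _combined_activation(dof_state, config: SynthConfig) -> np.ndarray:
    """Channel activation row for one movement label."""
    rows = []
    for d, s in enumerate(dof_state):
        if s == 1:
            rows.append(config.activation_matrix[2 * d])
        elif s == -1:
            rows.append(config.activation_matrix[2 * d + 1])
    if not rows:
        return np.zeros(config.channel_count)
    stacked = np.vstack(rows)
    if config.combination_rule == "max":
        return stacked.max(axis=0)
    return np.minimum(stacked.sum(axis=0), 1.0)


def _band_limited_noise(rng: np.random.Generator, n: int, config: SynthConfig
                        ) -> np.ndarray:
    """Unit-variance zero-phase band-passed Gaussian noise."""
    white = rng.standard_normal(n)
    nyq = config.sampling_rate / 2.0
    b, a = butter(config.filter_order,
                  [config.band[0] / nyq, config.band[1] / nyq], btype="band")
    x = filtfilt(b, a, white)
    return x / max(x.std(), 1e-12)


def generate_session(config: SynthConfig | None = None) -> RecordingSession:
    """Generate one synthetic recording session covering all 3**k labels.

    Each movement holds ``n_repetitions`` concatenated repetitions of
    ``contraction_time`` seconds; every channel of every movement is an
    independent band-limited noise realization scaled by the label's channel
    activation.
    """
    config = config or SynthConfig()
    labels = enumerate_labels(config.n_dof)
    rng = np.random.default_rng(config.rng_seed)
    n_per_rep = int(round(config.sampling_rate * config.contraction_time))
    n_time = n_per_rep * config.n_repetitions
    samples = np.empty((n_time, config.channel_count, len(labels)))
    for m, lab in enumerate(labels):
        activation = _combined_activation(lab.dof_state, config)
        amplitude = config.baseline * np.sqrt(1.0 + activation * config.snr)
        for ch in range(config.channel_count):
            noise = _band_limited_noise(rng, n_time, config)
            samples[:, ch, m] = amplitude[ch] * noise
    session = RecordingSession(
        sampling_rate=config.sampling_rate,
        contraction_time=config.contraction_time,
        n_repetitions=config.n_repetitions,
        channel_count=config.channel_count,
        movement_names=[lab.name for lab in labels],
        samples=samples,
        subject_id=f"synthetic-seed{config.rng_seed}",
    )
    return session.validate()
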