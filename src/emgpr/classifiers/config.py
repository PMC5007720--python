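"""Shared training configuration for the iterative trainers."""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import ConfigurationError


@dataclass
class TrainConfig:
    """Hyperparameters common to the GLM and MLP trainers.

    Parameters
    ----------
    max_iterations : int
        Hard cap on training iterations (default 200).
    learning_rate, momentum : float
        Full-batch gradient-descent parameters.  The cross-entropy is summed
        over samples, so the effective step is ``learning_rate / n_samples``
        times the summed gradient (making the default 0.1 roughly
        sample-size independent).
    sigma0, lambda0 : float
        Scaled-conjugate-gradient constants: finite-difference step scale
        and initial Levenberg-Marquardt regularizer.
    weight_decay : float
        L2 penalty coefficient on all weights (0 disables it).
    rng_seed : int
        Seed for weight initialization; training is fully reproducible
        from it.
    tol_error, tol_param : float
        Convergence tolerances on the error decrease and parameter step.
    """

    max_iterations: int = 200
    learning_rate: float = 0.1
    momentum: float = 0.0
    sigma0: float = 1e-4
    lambda0: float = 1e-6
    weight_decay: float = 0.0
    rng_seed: int = 0
    tol_error: float = 1e-8
    tol_param: float = 1e-8

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be >= 0")
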