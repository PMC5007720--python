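"""Scaled conjugate gradient minimizer (Møller's algorithm).

A batch second-order trainer for differentiable objectives: conjugate search
directions combined with a Levenberg–Marquardt-style scale ``lambda`` that is
adapted from the comparison parameter (the ratio of the actual to the
predicted error decrease), so no line search is needed.  The curvature along
the search direction is estimated by a one-sided finite difference of the
gradient with step ``sigma0 / |d|``.

The implementation follows the canonical published scheme and its standard
constants (sigma0 = 1e-4, initial lambda = 1e-6); the error sequence over
accepted steps is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import NumericError

_LAMBDA_MAX = 1e100
_LAMBDA_MIN = 1e-15


@dataclass
class ScgResult:
    w: np.ndarray
    error: float
    n_iterations: int
    error_history: list[float] = field(default_factory=list)
    converged: bool = False


def scg_minimize(fun, grad, w0: np.ndarray, max_iterations: int = 200,
                 sigma0: float = 1e-4, lambda0: float = 1e-6,
                 tol_error: float = 1e-8, tol_param: float = 1e-8) -> ScgResult:
    """Minimize ``fun`` starting at ``w0``.

    ``error_history`` records the objective after every iteration (the
    current point's error, so rejected steps repeat the previous value);
    accepted steps never increase it.  Convergence requires both the
    parameter step and the error decrease of an accepted step to fall below
    their tolerances.
    """
    w = np.asarray(w0, dtype=float).copy()
    dim = w.size
    fnow = float(fun(w))
    if not np.isfinite(fnow):
        raise NumericError("objective not finite at the initial point")
    gradnew = np.asarray(grad(w), dtype=float)
    gradold = gradnew
    d = -gradnew
    success = True
    nsuccess = 0
    lam = lambda0
    history = [fnow]
    converged = False
    theta = kappa = mu = 0.0
    j = 0
    while j < max_iterations:
        j += 1
        if success:
            mu = float(d @ gradnew)
            if mu >= 0:
                d = -gradnew
                mu = float(d @ gradnew)
            kappa = float(d @ d)
            if kappa < np.finfo(float).eps:
                converged = True
                break
            sigma = sigma0 / np.sqrt(kappa)
            gplus = np.asarray(grad(w + sigma * d), dtype=float)
            theta = float(d @ (gplus - gradnew)) / sigma
        # second-order step size with LM regularization of the curvature
        delta = theta + lam * kappa
        if delta <= 0:
            delta = lam * kappa
            lam = lam - theta / kappa
        alpha = -mu / delta
        wnew = w + alpha * d
        fnew = float(fun(wnew))
        if not np.isfinite(fnew):
            raise NumericError("objective became non-finite during training")
        Delta = 2.0 * (fnew - fnow) / (alpha * mu)  # comparison parameter
        if Delta >= 0:
            success = True
            nsuccess += 1
            step_norm = float(np.max(np.abs(alpha * d)))
            df = fnow - fnew
            w, fnow = wnew, fnew
            gradold = gradnew
            gradnew = np.asarray(grad(w), dtype=float)
            if step_norm < tol_param and df < tol_error:
                converged = True
                history.append(fnow)
                break
        else:
            success = False
        history.append(fnow)
        if Delta < 0.25:
            lam = min(4.0 * lam, _LAMBDA_MAX)
        elif Delta > 0.75:
            lam = max(0.5 * lam, _LAMBDA_MIN)
        if success:
            if nsuccess == dim:  # restart with steepest descent
                d = -gradnew
                nsuccess = 0
            else:
                gamma = float((gradold - gradnew) @ gradnew) / mu
                d = gamma * d - gradnew
    return ScgResult(w, fnow, j, history, converged)
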