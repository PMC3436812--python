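"""Scaled conjugate gradient (SCG) minimizer.

Møller's SCG avoids line searches by estimating second-order curvature
information along the search direction from one extra gradient evaluation and
a Levenberg–Marquardt style scale parameter lambda. The update rules follow
Møller's published algorithm with the Netlab conventions (sigma0 = 1e-4,
initial lambda = 1e-6); one deliberate extension is that a non-finite
objective or gradient encountered during a trial step is treated as a failed
step (the scale is increased and the step rejected) instead of aborting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, OptimizerStallError

_LAMBDA_MAX = 1e100
_LAMBDA_MIN = 1e-15
_MAX_CONSECUTIVE_FAILURES = 100


@dataclass(frozen=True)
class OptimizerSettings:
    max_iterations: int = 1000
    objective_tolerance: float = 1e-6
    parameter_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be positive")
        if not (self.objective_tolerance > 0 and self.parameter_tolerance > 0):
            raise InvalidInputError("tolerances must be positive")


def scg_minimize(objective, gradient, x0, settings: OptimizerSettings | None = None):
    """Minimize ``objective`` from ``x0``; returns (x_best, objective trace).

    The trace records the accepted objective value at each iteration (the
    previous value is repeated on rejected steps), so it is non-increasing.
    """
    if settings is None:
        settings = OptimizerSettings()
    x = np.asarray(x0, dtype=float).copy()
    n = x.size

    fnow = float(objective(x))
    gradnew = np.asarray(gradient(x), dtype=float)
    if not (np.isfinite(fnow) and np.all(np.isfinite(gradnew))):
        raise InvalidInputError("objective or gradient non-finite at x0")
    fold = fnow
    gradold = gradnew
    d = -gradnew
    success = True
    nsuccess = 0
    lam = 1.0e-6
    sigma0 = 1.0e-4
    trace = [fnow]
    consecutive_failures = 0
    theta = 0.0
    mu = 0.0
    kappa = 0.0

    for _ in range(settings.max_iterations):
        if success:
            mu = float(d @ gradnew)
            if mu >= 0:
                d = -gradnew
                mu = float(d @ gradnew)
            kappa = float(d @ d)
            if kappa < np.finfo(float).eps:
                break  # gradient numerically zero
            sigma = sigma0 / np.sqrt(kappa)
            gplus = np.asarray(gradient(x + sigma * d), dtype=float)
            if np.all(np.isfinite(gplus)):
                theta = float(d @ (gplus - gradnew)) / sigma
            else:
                theta = np.inf  # forces a huge step penalty -> rejection

        # Make the local quadratic model positive definite (Møller's step 4):
        # on negative curvature, set delta = -theta and raise the scale.
        delta = theta + lam * kappa
        if not np.isfinite(delta):
            delta = _LAMBDA_MAX * kappa
        elif delta <= 0:
            lam = 2.0 * (lam - delta / kappa)
            delta = -theta
        alpha = -mu / delta

        xnew = x + alpha * d
        fnew = float(objective(xnew))
        if np.isfinite(fnew):
            comparison = 2.0 * (fnew - fold) / (alpha * mu)
        else:
            comparison = -1.0  # reject

        if comparison >= 0:
            success = True
            nsuccess += 1
            consecutive_failures = 0
            x = xnew
            fnow = fnew
        else:
            success = False
            fnow = fold
            consecutive_failures += 1
            if consecutive_failures >= _MAX_CONSECUTIVE_FAILURES:
                raise OptimizerStallError(
                    "SCG made no progress over "
                    f"{consecutive_failures} consecutive trial steps",
                    best_x=x,
                    best_f=fold,
                    trace=np.asarray(trace),
                )

        trace.append(fnow)

        if success:
            if (
                np.max(np.abs(alpha * d)) < settings.parameter_tolerance
                and abs(fnew - fold) < settings.objective_tolerance
            ):
                return x, np.asarray(trace)
            fold = fnew
            gradold = gradnew
            gradnew = np.asarray(gradient(x), dtype=float)
            if not np.all(np.isfinite(gradnew)):
                raise OptimizerStallError(
                    "gradient became non-finite at an accepted iterate",
                    best_x=x,
                    best_f=fnow,
                    trace=np.asarray(trace),
                )
            if float(gradnew @ gradnew) == 0.0:
                return x, np.asarray(trace)

        if comparison < 0.25:
            lam = min(4.0 * lam, _LAMBDA_MAX)
        if comparison > 0.75:
            lam = max(0.5 * lam, _LAMBDA_MIN)

        if nsuccess == n:
            d = -gradnew
            nsuccess = 0
        elif success:
            beta = float(gradold @ gradold - gradnew @ gradold) / mu
            d = beta * d - gradnew

    return x, np.asarray(trace)
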