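"""Covariance functions on latent points, with analytic derivatives.

Three kernels are supported, each of the form

    k(x, x') = k_base(x, x') + bias_variance + [x is x'] / noise_precision

with base parts

    linear               signal_variance * <x, x'>
    rbf                  signal_variance * exp(-||x - x'||^2 / (2 * lengthscale^2))
    rational_quadratic   signal_variance * (1 + ||x - x'||^2 / (2 * rq_shape *
                         lengthscale^2)) ** (-rq_shape)

The latent-variable model marginalizes the linear map from latent to data
space under a Gaussian prior, so with the linear kernel the Gram matrix is
K = alpha * X X^T + beta^{-1} I (probabilistic PCA in its dual form); here
``signal_variance`` plays the role of alpha and ``noise_precision`` of beta.
Swapping in the rbf or rational-quadratic base part gives the nonlinear model.

All hyperparameters are exposed on the natural scale but optimized on the
log scale (see :meth:`KernelParams.to_log_vector`), which enforces positivity
without constrained optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InvalidInputError, ParameterDomainError, UnsupportedKernelError

KERNEL_KINDS = ("linear", "rbf", "rational_quadratic")


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of one covariance function.

    ``noise_precision`` is the precision (inverse variance) of the i.i.d.
    observation noise; the noise variance is its reciprocal.
    """

    kind: str = "rbf"
    signal_variance: float = 1.0
    lengthscale: float = 1.0
    rq_shape: float = 2.0
    bias_variance: float = 0.0
    noise_precision: float = 100.0

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ParameterDomainError(
                f"unknown kernel kind {self.kind!r}; expected one of {KERNEL_KINDS}"
            )
        if not self.signal_variance >= 0:
            raise ParameterDomainError("signal_variance must be nonnegative")
        if self.kind != "linear" and not self.lengthscale > 0:
            raise ParameterDomainError("lengthscale must be positive")
        if self.kind == "rational_quadratic" and not self.rq_shape > 0:
            raise ParameterDomainError("rq_shape must be positive")
        if not self.bias_variance >= 0:
            raise ParameterDomainError("bias_variance must be nonnegative")
        if not self.noise_precision > 0:
            raise ParameterDomainError("noise_precision must be positive")

    @property
    def noise_variance(self) -> float:
        return 1.0 / self.noise_precision

    def free_names(self) -> list[str]:
        """Hyperparameters optimized on the log scale, in a fixed order.

        A zero ``bias_variance`` has no finite logarithm and is treated as
        structurally absent: it is excluded and stays at zero.
        """
        names = ["signal_variance"]
        if self.kind in ("rbf", "rational_quadratic"):
            names.append("lengthscale")
        if self.kind == "rational_quadratic":
            names.append("rq_shape")
        if self.bias_variance > 0:
            names.append("bias_variance")
        names.append("noise_precision")
        return names

    def to_log_vector(self) -> np.ndarray:
        return np.log([getattr(self, n) for n in self.free_names()])

    def with_log_vector(self, v: np.ndarray) -> "KernelParams":
        names = self.free_names()
        v = np.asarray(v, dtype=float)
        if v.shape != (len(names),):
            raise InvalidInputError(
                f"expected log-parameter vector of length {len(names)}, got {v.shape}"
            )
        return replace(self, **{n: float(np.exp(vi)) for n, vi in zip(names, v)})


def _check_latents(X: np.ndarray, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError(f"{name} must be 2-D (points x latent dims)")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError(f"{name} contains non-finite latent coordinates")
    return X


def _sqdist(X: np.ndarray, X2: np.ndarray) -> np.ndarray:
    D = cdist(X, X2, metric="sqeuclidean")
    return np.maximum(D, 0.0)


def _base_matrix(X: np.ndarray, X2: np.ndarray, params: KernelParams) -> np.ndarray:
    """Base (signal) part of the kernel, without bias or noise."""
    if params.kind == "linear":
        return params.signal_variance * (X @ X2.T)
    r2 = _sqdist(X, X2)
    if params.kind == "rbf":
        return params.signal_variance * np.exp(-r2 / (2.0 * params.lengthscale**2))
    # rational_quadratic
    u = 1.0 + r2 / (2.0 * params.rq_shape * params.lengthscale**2)
    return params.signal_variance * u ** (-params.rq_shape)


def kernel_matrix(
    X: np.ndarray, params: KernelParams, include_noise: bool = True
) -> np.ndarray:
    """Symmetric positive-(semi)definite Gram matrix over the latent points."""
    X = _check_latents(X)
    K = _base_matrix(X, X, params) + params.bias_variance
    if include_noise:
        K = K + params.noise_variance * np.eye(X.shape[0])
    return 0.5 * (K + K.T)  # exact symmetry despite cdist round-off


def kernel_diag(Xstar: np.ndarray, params: KernelParams) -> np.ndarray:
    """k(x*, x*) for each row of ``Xstar`` (no noise term)."""
    Xstar = _check_latents(Xstar, "Xstar")
    if params.kind == "linear":
        base = params.signal_variance * np.sum(Xstar**2, axis=1)
    else:
        base = np.full(Xstar.shape[0], params.signal_variance)
    return base + params.bias_variance


def cross_covariance(
    X: np.ndarray, Xstar: np.ndarray, params: KernelParams
) -> np.ndarray:
    """N x M matrix of covariances k(x_n, x*_m); never carries the noise term."""
    X = _check_latents(X)
    Xstar = _check_latents(Xstar, "Xstar")
    if X.shape[1] != Xstar.shape[1]:
        raise InvalidInputError(
            f"latent dimension mismatch: {X.shape[1]} vs {Xstar.shape[1]}"
        )
    return _base_matrix(X, Xstar, params) + params.bias_variance


def _pair_weight(X: np.ndarray, params: KernelParams) -> np.ndarray:
    """E such that d k_base(x_m, x_n) / d x_mq = -(1/l^2) E_mn (x_mq - x_nq).

    Defined for the stationary kernels only.
    """
    if params.kind == "rbf":
        return _base_matrix(X, X, params)
    if params.kind == "rational_quadratic":
        r2 = _sqdist(X, X)
        u = 1.0 + r2 / (2.0 * params.rq_shape * params.lengthscale**2)
        return params.signal_variance * u ** (-params.rq_shape - 1.0)
    raise UnsupportedKernelError(f"no pairwise weight for kernel {params.kind!r}")


def grad_wrt_latents(
    X: np.ndarray, params: KernelParams, dL_dK: np.ndarray
) -> np.ndarray:
    """Chain-rule gradient of a scalar objective through the Gram matrix.

    Given dL/dK (symmetric), returns dL/dX of shape N x Q.
    """
    X = _check_latents(X)
    dL_dK = np.asarray(dL_dK, dtype=float)
    if dL_dK.shape != (X.shape[0], X.shape[0]):
        raise InvalidInputError("dL_dK not conformable with X")
    if not np.allclose(dL_dK, dL_dK.T, rtol=0.0, atol=1e-10 * (1 + np.abs(dL_dK).max())):
        raise InvalidInputError("dL_dK must be symmetric")
    if params.signal_variance == 0.0:
        return np.zeros_like(X)
    if params.kind == "linear":
        return 2.0 * params.signal_variance * (dL_dK @ X)
    A = dL_dK * _pair_weight(X, params)
    inv_l2 = 1.0 / params.lengthscale**2
    return 2.0 * inv_l2 * (A @ X - A.sum(axis=1)[:, None] * X)


def grad_wrt_params(
    X: np.ndarray, params: KernelParams, dL_dK: np.ndarray
) -> dict[str, float]:
    """Gradient for each free hyperparameter, on the unconstrained log scale.

    Keys follow :meth:`KernelParams.free_names`. The noise term enters through
    the precision beta: dK/dbeta = -beta^{-2} I, so the log-scale entry is
    -trace(dL_dK)/beta.
    """
    X = _check_latents(X)
    dL_dK = np.asarray(dL_dK, dtype=float)
    if dL_dK.shape != (X.shape[0], X.shape[0]):
        raise InvalidInputError("dL_dK not conformable with X")
    if not np.allclose(dL_dK, dL_dK.T, rtol=0.0, atol=1e-10 * (1 + np.abs(dL_dK).max())):
        raise InvalidInputError("dL_dK must be symmetric")

    base = _base_matrix(X, X, params)
    out: dict[str, float] = {}
    # d K / d log(signal_variance) = base part itself (base is linear in s)
    out["signal_variance"] = float(np.sum(dL_dK * base))
    if params.kind in ("rbf", "rational_quadratic"):
        r2 = _sqdist(X, X)
        l2 = params.lengthscale**2
        if params.kind == "rbf":
            dK_dlogl = base * r2 / l2
        else:
            a = params.rq_shape
            u = 1.0 + r2 / (2.0 * a * l2)
            E = params.signal_variance * u ** (-a - 1.0)
            dK_dlogl = E * r2 / l2
        out["lengthscale"] = float(np.sum(dL_dK * dK_dlogl))
    if params.kind == "rational_quadratic":
        a = params.rq_shape
        l2 = params.lengthscale**2
        r2 = _sqdist(X, X)
        u = 1.0 + r2 / (2.0 * a * l2)
        dK_da = params.signal_variance * u ** (-a) * (-np.log(u) + r2 / (2.0 * a * l2 * u))
        out["rq_shape"] = float(a * np.sum(dL_dK * dK_da))
    if params.bias_variance > 0:
        out["bias_variance"] = float(params.bias_variance * np.sum(dL_dK))
    out["noise_precision"] = float(-np.trace(dL_dK) / params.noise_precision)
    return out


def cross_grad_wrt_xstar(
    X: np.ndarray, xstar: np.ndarray, params: KernelParams
) -> np.ndarray:
    """d k(x_n, x*) / d x*: N x Q matrix of partials of the cross-covariances."""
    X = _check_latents(X)
    xstar = np.asarray(xstar, dtype=float).reshape(-1)
    if xstar.shape[0] != X.shape[1]:
        raise InvalidInputError("xstar dimension does not match the latent space")
    if params.kind == "linear":
        return params.signal_variance * X
    E = _pair_weight_vec(X, xstar, params)
    return E[:, None] * (X - xstar[None, :]) / params.lengthscale**2


def _pair_weight_vec(X: np.ndarray, xstar: np.ndarray, params: KernelParams) -> np.ndarray:
    r2 = np.sum((X - xstar[None, :]) ** 2, axis=1)
    if params.kind == "rbf":
        return params.signal_variance * np.exp(-r2 / (2.0 * params.lengthscale**2))
    if params.kind == "rational_quadratic":
        a = params.rq_shape
        u = 1.0 + r2 / (2.0 * a * params.lengthscale**2)
        return params.signal_variance * u ** (-a - 1.0)
    raise UnsupportedKernelError(f"no pairwise weight for kernel {params.kind!r}")


def derivative_prior_variance(params: KernelParams) -> float:
    """Prior variance of each component of the derivative process at a point.

    This is d^2 k(x, x') / (d x_q d x'_q) evaluated at x = x'. For all three
    kernels the cross-dimension second derivatives vanish at coincidence, so
    the prior derivative covariance is this scalar times the identity.
    """
    if params.kind == "linear":
        return params.signal_variance
    # Both stationary kernels: -2 g'(0) with k = g(r^2); g'(0) = -s / (2 l^2).
    return params.signal_variance / params.lengthscale**2
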