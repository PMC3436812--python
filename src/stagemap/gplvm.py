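"""Marginalized GPLVM: likelihood, gradients, initialization and fitting.

The model treats each of the D genes as an independent zero-mean Gaussian
process over the N latent points, sharing one kernel, so the log marginal
likelihood of the (per-gene centered) data Y is

    L = -(D N / 2) ln 2 pi - (D / 2) ln |K| - (1/2) tr(K^{-1} Y Y^T)

with K the Gram matrix of the latent coordinates X under the chosen kernel
(noise included). Both X and the log-scale kernel hyperparameters are
optimized jointly by scaled conjugate gradients, starting from the PCA
projection of Y scaled to unit variance per latent dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from . import kernels
from .exceptions import InvalidInputError, NumericalError
from .kernels import KernelParams
from .optimize import OptimizerSettings, scg_minimize

_LN_2PI = float(np.log(2.0 * np.pi))


def chol_with_jitter(K: np.ndarray):
    """Lower Cholesky factor of K, adding 1e-6 x mean-diagonal jitter only if
    the plain factorization fails; escalates the jitter up to three times."""
    try:
        return linalg.cholesky(K, lower=True)
    except linalg.LinAlgError:
        pass
    jitter = 1e-6 * float(np.mean(np.diag(K)))
    if jitter <= 0:
        jitter = 1e-12
    for _ in range(3):
        try:
            return linalg.cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter *= 100.0
    raise NumericalError(
        "kernel matrix not positive definite even after jitter "
        f"(final jitter {jitter:.3g}); check latent coordinates and parameters"
    )


@dataclass
class GPLVMModel:
    """A fitted (or directly constructed) GPLVM.

    ``Y`` is stored centered per gene; ``gene_means`` holds the removed
    means so predictions can be reported on the original scale. The cached
    Cholesky factor of K and the matrix K^{-1} Y are kept consistent with
    (X, params) via :meth:`refresh_cache`.
    """

    X: np.ndarray
    params: KernelParams
    Y: np.ndarray
    gene_means: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    optimizer_trace: np.ndarray | None = None
    _chol: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise InvalidInputError("X and Y must have the same number of rows")
        if self.X.shape[1] >= self.Y.shape[1]:
            raise InvalidInputError("latent dimension Q must be smaller than D")
        if not self.gene_names:
            self.gene_names = [f"gene_{j}" for j in range(self.Y.shape[1])]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.Y.shape[0])]
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        if self._chol is None:
            self.refresh_cache()

    @classmethod
    def from_data(cls, X, params, Y_raw, gene_names=None, cell_ids=None):
        """Build a model from uncentered data, centering per gene."""
        Y_raw = np.asarray(Y_raw, dtype=float)
        means = Y_raw.mean(axis=0)
        return cls(
            X=np.asarray(X, dtype=float),
            params=params,
            Y=Y_raw - means,
            gene_means=means,
            gene_names=list(gene_names) if gene_names is not None else [],
            cell_ids=list(cell_ids) if cell_ids is not None else [],
        )

    def refresh_cache(self):
        K = kernels.kernel_matrix(self.X, self.params, include_noise=True)
        self._chol = chol_with_jitter(K)
        self._alpha = linalg.cho_solve((self._chol, True), self.Y)

    def solve_K(self, B: np.ndarray) -> np.ndarray:
        """K^{-1} B through the cached factorization."""
        return linalg.cho_solve((self._chol, True), B)

    @property
    def n_cells(self) -> int:
        return self.Y.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Y.shape[1]

    @property
    def latent_dim(self) -> int:
        return self.X.shape[1]


def log_marginal_likelihood(X, params: KernelParams, Y) -> float:
    """Log marginal likelihood of centered data Y under the GPLVM."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("X and Y row counts differ")
    N, D = Y.shape
    K = kernels.kernel_matrix(X, params, include_noise=True)
    L = chol_with_jitter(K)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Kinv_Y = linalg.cho_solve((L, True), Y)
    quad = float(np.sum(Y * Kinv_Y))
    return -0.5 * D * N * _LN_2PI - 0.5 * D * logdet - 0.5 * quad


def likelihood_gradients(X, params: KernelParams, Y):
    """Gradients of the log marginal likelihood.

    Returns ``(dL_dX, dL_dparams)`` with the parameter gradient keyed by the
    free (log-scale) hyperparameter names. Uses
    dL/dK = -(D/2) K^{-1} + (1/2) K^{-1} Y Y^T K^{-1}.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    N, D = Y.shape
    K = kernels.kernel_matrix(X, params, include_noise=True)
    L = chol_with_jitter(K)
    Kinv = linalg.cho_solve((L, True), np.eye(N))
    A = linalg.cho_solve((L, True), Y)  # K^{-1} Y
    dL_dK = -0.5 * D * Kinv + 0.5 * (A @ A.T)
    dL_dK = 0.5 * (dL_dK + dL_dK.T)
    dX = kernels.grad_wrt_latents(X, params, dL_dK)
    dp = kernels.grad_wrt_params(X, params, dL_dK)
    return dX, dp


def initialize_latents(Y, Q: int, seed: int = 0) -> np.ndarray:
    """Deterministic PCA initialization of the latent coordinates.

    Projects centered Y onto its top-Q principal directions and rescales each
    latent dimension to unit variance. Directions are sign-fixed (largest
    absolute loading positive) so the result is reproducible. ``seed`` is part
    of the signature for interface symmetry; the computation is deterministic.
    """
    Y = np.asarray(Y, dtype=float)
    if Q >= Y.shape[1]:
        raise InvalidInputError("Q must be smaller than the data dimension")
    Yc = Y - Y.mean(axis=0)
    if np.allclose(Yc, 0.0):
        raise InvalidInputError("Y has zero variance; cannot initialize latents")
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    # sign convention: largest-|value| loading of each direction positive
    for k in range(min(Q, Vt.shape[0])):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    X = U[:, :Q] * s[:Q]
    sd = X.std(axis=0)
    degenerate = sd < 1e-12 * max(1.0, float(s[0]))
    if np.any(degenerate):
        warnings.warn(
            "some requested latent dimensions have (numerically) zero variance "
            "in the data; leaving them at zero",
            stacklevel=2,
        )
    out = np.zeros_like(X)
    nz = ~degenerate
    out[:, nz] = X[:, nz] / sd[nz]
    return out


def _pack(X: np.ndarray, params: KernelParams, fixed_params: bool) -> np.ndarray:
    if fixed_params:
        return X.ravel().copy()
    return np.concatenate([X.ravel(), params.to_log_vector()])


def _unpack(v: np.ndarray, shape, params: KernelParams, fixed_params: bool):
    n_lat = shape[0] * shape[1]
    X = v[:n_lat].reshape(shape)
    if fixed_params:
        return X, params
    return X, params.with_log_vector(v[n_lat:])


def fit_gplvm(
    Y,
    Q: int = 2,
    params: KernelParams | None = None,
    settings: OptimizerSettings | None = None,
    fixed_params: bool = False,
    X0: np.ndarray | None = None,
    gene_names=None,
    cell_ids=None,
) -> GPLVMModel:
    """Fit the plain GPLVM by maximizing the marginal likelihood.

    Y is centered per gene before fitting; the per-gene means are retained on
    the returned model. ``fixed_params`` freezes the kernel hyperparameters so
    only the latent coordinates are optimized.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < Q + 1:
        raise InvalidInputError("need at least Q + 1 cells to fit")
    if params is None:
        params = KernelParams()
    if settings is None:
        settings = OptimizerSettings()
    means = Y.mean(axis=0)
    Yc = Y - means
    if X0 is None:
        X0 = initialize_latents(Yc, Q, seed=settings.seed)
    X0 = np.asarray(X0, dtype=float)
    shape = X0.shape

    def objective(v):
        X, p = _unpack(v, shape, params, fixed_params)
        try:
            return -log_marginal_likelihood(X, p, Yc)
        except NumericalError:
            return np.inf

    def gradient(v):
        X, p = _unpack(v, shape, params, fixed_params)
        try:
            dX, dp = likelihood_gradients(X, p, Yc)
        except NumericalError:
            return np.full_like(v, np.nan)
        if fixed_params:
            return -dX.ravel()
        dpvec = np.array([dp[name] for name in p.free_names()])
        return -np.concatenate([dX.ravel(), dpvec])

    v0 = _pack(X0, params, fixed_params)
    v_opt, trace = scg_minimize(objective, gradient, v0, settings)
    X_opt, p_opt = _unpack(v_opt, shape, params, fixed_params)
    model = GPLVMModel(
        X=X_opt,
        params=p_opt,
        Y=Yc,
        gene_means=means,
        gene_names=list(gene_names) if gene_names is not None else [],
        cell_ids=list(cell_ids) if cell_ids is not None else [],
        optimizer_trace=trace,
    )
    return model
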