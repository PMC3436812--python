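"""Interpretability layer: predictive mapping and gene relevance maps.

The GPLVM defines an explicit probabilistic map from latent to data space.
At a new latent point x* the predicted expression of the genes is Gaussian
with mean

    mu(x*) = m + Y^T K^{-1} k(x*)

(m the per-gene training means, k(x*) the vector of covariances to the
training latents) and a shared variance

    sigma^2(x*) = k(x*, x*) - k(x*)^T K^{-1} k(x*) + noise variance.

The Jacobian d mu / d x* quantifies how strongly each gene changes when
moving in the latent space; the gene with the greatest gradient norm at a
location is the locally "most relevant" gene. Evaluating this on a regular
grid (default 20 x 20) yields the gene relevance map, a nonlinear analogue
of PCA loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kernels
from .exceptions import InvalidInputError, UnsupportedDimensionError
from .gplvm import GPLVMModel


def predictive_mean(model: GPLVMModel, Xstar) -> np.ndarray:
    """M x D predicted expression at the latent points ``Xstar``.

    Per-gene training means (removed at fit time) are added back.
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    Kstar = kernels.cross_covariance(model.X, Xstar, model.params)  # N x M
    return model.gene_means[None, :] + Kstar.T @ model._alpha


def predictive_variance(model: GPLVMModel, Xstar) -> np.ndarray:
    """Predictive variance at each row of ``Xstar`` (shared across genes).

    Includes the observation-noise variance. Small negative round-off values
    are clipped at zero with a warning.
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    Kstar = kernels.cross_covariance(model.X, Xstar, model.params)  # N x M
    kss = kernels.kernel_diag(Xstar, model.params)
    explained = np.sum(Kstar * model.solve_K(Kstar), axis=0)
    var = kss - explained + model.params.noise_variance
    if np.any(var < 0):
        if np.any(var < -1e-8 * max(1.0, float(kss.max()))):
            warnings.warn("predictive variance negative beyond round-off; clipping at 0",
                          stacklevel=2)
        var = np.maximum(var, 0.0)
    return var


def mean_jacobian(model: GPLVMModel, xstar) -> np.ndarray:
    """D x Q Jacobian of the predictive mean at a single latent point."""
    xstar = np.asarray(xstar, dtype=float).reshape(-1)
    dk = kernels.cross_grad_wrt_xstar(model.X, xstar, model.params)  # N x Q
    return model._alpha.T @ dk


@dataclass
class RelevanceMap:
    """Per-grid-point gene relevance over a regular latent grid.

    ``top_gene_index`` is the argmax of ``gradient_norms`` per grid point,
    ties broken by the smallest gene index.
    """

    grid_points: np.ndarray          # G x 2
    grid_shape: tuple[int, int]
    gradient_norms: np.ndarray       # G x D
    top_gene_index: np.ndarray       # G
    predictive_sd: np.ndarray        # G
    gene_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "z1": self.grid_points[:, 0],
                "z2": self.grid_points[:, 1],
                "top_gene": [self.gene_names[i] for i in self.top_gene_index],
                "predictive_sd": self.predictive_sd,
            }
        )
        for j, name in enumerate(self.gene_names):
            df[f"norm_{name}"] = self.gradient_norms[:, j]
        return df

    def write(self, path, sep: str = "\t"):
        self.to_frame().to_csv(path, sep=sep, index=False)


def latent_grid(X, resolution: int = 20, margin_fraction: float = 0.05):
    """Regular grid over the bounding box of X, expanded by a margin per side."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    pad = margin_fraction * (hi - lo)
    g1 = np.linspace(lo[0] - pad[0], hi[0] + pad[0], resolution)
    g2 = np.linspace(lo[1] - pad[1], hi[1] + pad[1], resolution)
    G1, G2 = np.meshgrid(g1, g2, indexing="xy")
    return np.column_stack([G1.ravel(), G2.ravel()])


def gene_relevance_map(
    model: GPLVMModel, grid_resolution: int = 20, margin_fraction: float = 0.05
) -> RelevanceMap:
    """Gene relevance map on a ``grid_resolution`` x ``grid_resolution`` grid.

    Defined for two latent dimensions. The most relevant gene at each grid
    point is the one with the greatest Euclidean norm of its predictive-mean
    gradient.
    """
    if model.latent_dim != 2:
        raise UnsupportedDimensionError(
            f"relevance maps are defined for Q = 2 latent dimensions, got {model.latent_dim}"
        )
    grid = latent_grid(model.X, grid_resolution, margin_fraction)
    norms = np.empty((grid.shape[0], model.n_genes))
    for i, x in enumerate(grid):
        J = mean_jacobian(model, x)
        norms[i] = np.linalg.norm(J, axis=1)
    top = np.argmax(norms, axis=1)  # argmax takes the smallest index on ties
    sd = np.sqrt(predictive_variance(model, grid))
    return RelevanceMap(
        grid_points=grid,
        grid_shape=(grid_resolution, grid_resolution),
        gradient_norms=norms,
        top_gene_index=top,
        predictive_sd=sd,
        gene_names=list(model.gene_names),
    )


@dataclass
class GradientProfile:
    """Per-gene gradient of the predictive mean at one latent location.

    Under the shared-kernel model the derivative-process uncertainty is the
    same for every gene: ``direction_sd[q]`` is the posterior SD of the
    partial derivative along latent dimension q, and ``sd`` combines the
    directions (root sum of the per-direction variances).
    """

    xstar: np.ndarray
    gradients: np.ndarray      # D x Q
    norms: np.ndarray          # D
    direction_sd: np.ndarray   # Q
    sd: float
    gene_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.gradients, index=self.gene_names,
                          columns=[f"d_z{q + 1}" for q in range(self.gradients.shape[1])])
        df["norm"] = self.norms
        df["sd"] = self.sd
        return df


def gene_gradient_profile(model: GPLVMModel, xstar) -> GradientProfile:
    """Gradient of every gene's predictive mean at ``xstar`` with uncertainty.

    The derivative of a GP is itself a GP; its posterior variance along
    latent dimension q is the prior derivative variance (from the second
    kernel derivative at coincidence) minus the data-explained part
    (dk/dx_q)^T K^{-1} (dk/dx_q).
    """
    xstar = np.asarray(xstar, dtype=float).reshape(-1)
    dk = kernels.cross_grad_wrt_xstar(model.X, xstar, model.params)  # N x Q
    J = model._alpha.T @ dk
    norms = np.linalg.norm(J, axis=1)
    prior = kernels.derivative_prior_variance(model.params)
    explained = np.sum(dk * model.solve_K(dk), axis=0)
    var_q = np.maximum(prior - explained, 0.0)
    return GradientProfile(
        xstar=xstar,
        gradients=J,
        norms=norms,
        direction_sd=np.sqrt(var_q),
        sd=float(np.sqrt(var_q.sum())),
        gene_names=list(model.gene_names),
    )


def plot_relevance_map(rmap: RelevanceMap, path, model: GPLVMModel | None = None,
                       gradient_gene: str | None = None):
    """Write a figure of the relevance map: top gene per grid cell, predictive-SD
    shading, and optionally a quiver of one gene's gradient field."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = rmap.grid_shape[0]
    Z1 = rmap.grid_points[:, 0].reshape(rmap.grid_shape)
    Z2 = rmap.grid_points[:, 1].reshape(rmap.grid_shape)
    fig, ax = plt.subplots(figsize=(8, 7))
    ax.pcolormesh(Z1, Z2, rmap.predictive_sd.reshape(rmap.grid_shape),
                  shading="nearest", cmap="Greys", alpha=0.6)
    genes_present = sorted(set(rmap.top_gene_index.tolist()))
    cmap = plt.get_cmap("tab20")
    for k, g in enumerate(genes_present):
        mask = rmap.top_gene_index == g
        ax.scatter(rmap.grid_points[mask, 0], rmap.grid_points[mask, 1],
                   s=14, color=cmap(k % 20), label=rmap.gene_names[g])
    if gradient_gene is not None and model is not None:
        j = rmap.gene_names.index(gradient_gene)
        U = np.empty(rmap.grid_points.shape[0])
        V = np.empty_like(U)
        for i, x in enumerate(rmap.grid_points):
            grad = mean_jacobian(model, x)[j]
            U[i], V[i] = grad[0], grad[1]
        ax.quiver(rmap.grid_points[:, 0], rmap.grid_points[:, 1], U, V,
                  angles="xy", color="k", alpha=0.7, width=0.002)
    if model is not None:
        ax.plot(model.X[:, 0], model.X[:, 1], ".", color="crimson", ms=4)
    ax.legend(fontsize=7, ncol=2, loc="upper right")
    ax.set_xlabel("latent dim 1")
    ax.set_ylabel("latent dim 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
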