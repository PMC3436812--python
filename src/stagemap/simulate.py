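"""Synthetic staged single-cell expression data.

The generator emulates the statistical structure of staged single-cell qPCR
panels: an ordered series of developmental stages whose cells sit along a
smooth nonlinear trajectory in a low-dimensional latent space, mapped to a
higher-dimensional expression panel, with within-stage heterogeneity, a
planted two-way subcluster split at one designated stage, a pair of
housekeeping control genes (high mean, low variance, no latent dependence)
and additive Gaussian observation noise. Ground truth (latents, stage
labels, subcluster labels) is returned alongside the expression matrix so
recovery can be measured.

Two latent-to-expression maps are provided: a fixed random sinusoidal basis
mix (smooth, deliberately outside the model family, used for robustness) and
exact Gaussian-process draws (:func:`sample_gp_mapping`, matching the model's
generative assumption, used for parameter-recovery tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InvalidInputError
from .io import ExpressionMatrix

#: Default fixture: 6 stages x 16 cells, 24 genes (2 controls, 2 planted
#: markers), split at the 4th stage with effect 4 against noise SD 0.5.
FIXTURE_BLASTOCYST = dict(
    n_stages=6,
    cells_per_stage=16,
    n_genes=24,
    latent_dim=2,
    split_stage=4,
    split_effect=4.0,
    noise_sd=0.5,
    n_control_genes=2,
    seed=20120903,
)


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator.

    ``subcluster_of_cell`` is 0/1 inside the designated split stage and -1
    elsewhere.
    """

    latents_true: np.ndarray
    stage_of_cell: np.ndarray
    subcluster_of_cell: np.ndarray
    control_gene_indices: np.ndarray
    marker_gene_indices: np.ndarray


def _trajectory(t: np.ndarray, latent_dim: int) -> np.ndarray:
    """Smooth nonlinear 1-D curve through the latent space, t in [0, 1]."""
    base = np.column_stack([4.0 * t, 1.6 * np.sin(1.5 * np.pi * t)])
    if latent_dim > 2:
        base = np.column_stack([base, np.zeros((t.size, latent_dim - 2))])
    return base[:, :latent_dim]


def generate_staged_expression(
    n_stages: int = 6,
    cells_per_stage: int = 16,
    n_genes: int = 24,
    latent_dim: int = 2,
    split_stage: int | None = 4,
    split_effect: float = 4.0,
    noise_sd: float = 0.5,
    n_control_genes: int = 2,
    seed: int = 20120903,
    n_marker_genes: int = 2,
    marker_loading: float = 2.0,
    mapping: str = "sinusoid",
):
    """Generate one staged expression dataset; returns (ExpressionMatrix, SyntheticTruth).

    Cells of stage s are scattered around position s/(n_stages - 1) of a
    smooth latent trajectory. At ``split_stage`` (1-based stage index) the
    cells divide into two branches displaced by +/- split_effect / 2 along
    the local normal of the trajectory; the planted marker genes carry an
    additional linear loading (``marker_loading``) on that normal direction,
    so they respond strongly to the branch split. All randomness flows from
    ``seed``.
    """
    if n_genes <= latent_dim:
        raise InvalidInputError("n_genes must exceed latent_dim")
    if split_effect < 0:
        raise InvalidInputError("split_effect must be nonnegative")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be nonnegative")
    if split_stage is not None:
        if not 1 <= split_stage <= n_stages:
            raise InvalidInputError("split_stage out of range")
        if cells_per_stage < 4:
            raise InvalidInputError("need at least 4 cells per stage to plant a split")
    if n_control_genes + n_marker_genes > n_genes:
        raise InvalidInputError("too many special genes for n_genes")

    rng = np.random.default_rng(seed)
    N = n_stages * cells_per_stage
    stage_idx = np.repeat(np.arange(n_stages), cells_per_stage)
    stage_labels = np.array([f"stage{s + 1}" for s in stage_idx])
    stage_order = [f"stage{s + 1}" for s in range(n_stages)]

    t_centers = stage_idx / max(n_stages - 1, 1)
    t = t_centers + rng.normal(0.0, 0.03, size=N)
    latents = _trajectory(t, latent_dim)
    latents += rng.normal(0.0, 0.15, size=latents.shape)

    subcluster = np.full(N, -1, dtype=int)
    if split_stage is not None:
        s = split_stage - 1
        members = np.flatnonzero(stage_idx == s)
        # balanced-ish random branch assignment, both branches nonempty
        branch = rng.permutation(members.size) % 2
        subcluster[members] = branch
        # local normal of the trajectory at the stage center
        tc = s / max(n_stages - 1, 1)
        h = 1e-4
        tang = (_trajectory(np.array([tc + h]), latent_dim)
                - _trajectory(np.array([tc - h]), latent_dim))[0]
        tang = tang / np.linalg.norm(tang)
        normal = np.zeros(latent_dim)
        normal[0], normal[1] = -tang[1], tang[0]
        signs = np.where(branch == 0, -1.0, 1.0)
        latents[members] += (split_effect / 2.0) * signs[:, None] * normal[None, :]

    # gene roles: markers first, controls last, ordinary genes in between
    marker_idx = np.arange(n_marker_genes) if split_stage is not None else np.arange(0)
    control_idx = np.arange(n_genes - n_control_genes, n_genes)
    ordinary = np.setdiff1d(np.arange(n_genes), np.concatenate([control_idx, marker_idx]))

    values = np.zeros((N, n_genes))
    if mapping == "sinusoid":
        # smooth random sinusoidal basis mix: 3 components per gene
        n_basis = 3
        amps = rng.normal(0.0, 1.0, size=(ordinary.size, n_basis))
        freqs = rng.uniform(0.4, 1.0, size=(ordinary.size, n_basis, latent_dim))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(ordinary.size, n_basis))
        proj = np.einsum("nq,gbq->ngb", latents, freqs)
        values[:, ordinary] = np.einsum("gb,ngb->ng", amps, np.sin(proj + phases[None]))
    elif mapping == "gp":
        values[:, ordinary] = sample_gp_mapping(
            latents, ordinary.size, lengthscale=1.5, amplitude=1.0,
            seed=int(rng.integers(2**31 - 1)),
        )
    else:
        raise InvalidInputError(f"unknown mapping {mapping!r}")

    if marker_idx.size:
        # Planted markers are dedicated branch reporters: their expression is
        # dominated by the branch-normal coordinate (alternating sign across
        # markers) plus a mild trend along the trajectory, emulating lineage
        # markers whose variance is driven by the split itself.
        branch_coord = latents @ normal
        branch_coord = branch_coord - branch_coord.mean()
        tangent_coord = latents @ tang
        tangent_coord = tangent_coord - tangent_coord.mean()
        for k, j in enumerate(marker_idx):
            sign = 1.0 if k % 2 == 0 else -1.0
            trend = rng.normal(0.0, 0.3)
            values[:, j] = sign * marker_loading * branch_coord + trend * tangent_coord

    noise = rng.normal(0.0, noise_sd, size=(N, n_genes))
    noise[:, control_idx] = 0.0
    values += noise

    values[:, control_idx] = 12.0 + rng.normal(0.0, 0.05, size=(N, control_idx.size))

    gene_names = []
    for j in range(n_genes):
        if j in marker_idx:
            gene_names.append(f"marker_{j + 1}")
        elif j in control_idx:
            gene_names.append(f"ctrl_{j - (n_genes - n_control_genes) + 1}")
        else:
            gene_names.append(f"gene_{j + 1:02d}")

    matrix = ExpressionMatrix(
        values=values,
        cell_ids=[f"cell_{i + 1:04d}" for i in range(N)],
        gene_names=gene_names,
        stage_of_cell=stage_labels,
        stage_order=stage_order,
        provenance=[f"generate_staged_expression(seed={seed})"],
    )
    truth = SyntheticTruth(
        latents_true=latents,
        stage_of_cell=stage_labels,
        subcluster_of_cell=subcluster,
        control_gene_indices=control_idx,
        marker_gene_indices=marker_idx,
    )
    return matrix, truth


def fixture_blastocyst(**overrides):
    """The default staged fixture (see :data:`FIXTURE_BLASTOCYST`)."""
    kw = dict(FIXTURE_BLASTOCYST)
    kw.update(overrides)
    return generate_staged_expression(**kw)


def sample_gp_mapping(latents, n_genes: int, lengthscale: float = 1.0,
                      amplitude: float = 1.0, seed: int = 0) -> np.ndarray:
    """Draw ``n_genes`` independent zero-mean GP functions over the latents.

    Each gene column is a draw from a GP with rbf covariance
    amplitude^2 * exp(-r^2 / (2 lengthscale^2)). The matrix square root is
    taken by eigendecomposition with negative eigenvalues clipped at zero,
    so duplicated latent rows yield exactly duplicated expression rows.
    """
    if lengthscale <= 0 or amplitude <= 0:
        raise InvalidInputError("lengthscale and amplitude must be positive")
    latents = np.asarray(latents, dtype=float)
    r2 = cdist(latents, latents, metric="sqeuclidean")
    K = amplitude**2 * np.exp(-r2 / (2.0 * lengthscale**2))
    w, U = np.linalg.eigh(K)
    L = U * np.sqrt(np.maximum(w, 0.0))[None, :]
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((latents.shape[0], n_genes))
    return L @ Z
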