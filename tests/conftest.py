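import numpy as np
import pytest

from stagemap import (
    KernelParams,
    OptimizerSettings,
    fixture_blastocyst,
    normalize_to_controls,
)
from stagemap.gplvm import GPLVMModel, initialize_latents
from stagemap.structure import fit_structured_gplvm

GAMMA_GRID = (0.0, 1.0, 10.0, 100.0)


@pytest.fixture(scope="session")
def blastocyst():
    """Default staged fixture: 6 stages x 16 cells, 24 genes, planted split."""
    return fixture_blastocyst()


@pytest.fixture(scope="session")
def blastocyst_norm(blastocyst):
    matrix, truth = blastocyst
    return normalize_to_controls(matrix, ["ctrl_1", "ctrl_2"]), truth


@pytest.fixture(scope="session")
def gamma_fits(blastocyst_norm):
    """Structured fits of the fixture at several locality weights, from one
    shared PCA initialization (expensive; shared across tests)."""
    matrix, _ = blastocyst_norm
    Y = matrix.values
    Yc = Y - Y.mean(axis=0)
    X0 = initialize_latents(Yc, 2, seed=0)
    settings = OptimizerSettings(max_iterations=800, seed=0)
    fits = {}
    for gamma in GAMMA_GRID:
        fits[gamma] = fit_structured_gplvm(
            Y,
            matrix.stage_of_cell,
            Q=2,
            params=KernelParams(),
            gamma=gamma,
            settings=settings,
            X0=X0,
            gene_names=matrix.gene_names,
            cell_ids=matrix.cell_ids,
        )
    return fits


@pytest.fixture(scope="session")
def one_gene_model():
    """Model in which exactly one gene (index 0) varies over the latent space;
    the other genes are constant."""
    rng = np.random.default_rng(3)
    X = rng.uniform(-2.0, 2.0, size=(30, 2))
    Y = np.full((30, 5), 3.0)
    Y[:, 0] = np.sin(X[:, 0]) + 0.5 * X[:, 1]
    params = KernelParams(kind="rbf", signal_variance=1.0, lengthscale=1.2,
                          noise_precision=100.0)
    return GPLVMModel.from_data(X, params, Y,
                                gene_names=[f"g{j}" for j in range(5)])


@pytest.fixture(scope="session")
def gp_model():
    """Small model fitted-by-construction on exact GP draws (cache populated)."""
    from stagemap import sample_gp_mapping

    rng = np.random.default_rng(12)
    X = rng.normal(size=(12, 2))
    params = KernelParams(kind="rbf", signal_variance=1.0, lengthscale=1.0,
                          noise_precision=100.0)
    Y = sample_gp_mapping(X, 4, lengthscale=1.0, amplitude=1.0, seed=5)
    Y += rng.normal(0.0, 0.1, size=Y.shape)
    return GPLVMModel.from_data(X, params, Y)
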