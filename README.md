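# stagemap

Structure-preserving Gaussian-process latent variable model (GPLVM)
embeddings for single-cell expression panels measured across ordered
developmental stages — with gene relevance maps for interpretability and the
evaluation toolkit (nearest-neighbour error, within-stage subclustering,
distance tests) needed to compare embeddings and discover subpopulations.

The intended user analyses log-scale expression matrices (e.g. ΔCt-normalized
single-cell qPCR panels, tens of genes × hundreds of cells) from staged
samples — zygote-to-blastocyst timecourses and the like — and wants a
nonlinear 2-D map that (i) separates stages and lineages better than
PCA/ICA, (ii) respects the known stage structure without tearing the map
apart, and (iii) remains interpretable gene-by-gene.

## Model

Expression `Y` (N cells × D genes, centered per gene) is modelled as D
independent Gaussian processes over latent coordinates `X` (N × Q, usually
Q = 2) sharing one kernel `K = K(X, θ)`:

    L(X, θ) = −(DN/2) ln 2π − (D/2) ln|K| − (1/2) tr(K⁻¹ Y Yᵀ)

With a linear kernel `K = α X Xᵀ + β⁻¹ I` this is the dual form of
probabilistic PCA; swapping in an RBF or rational-quadratic kernel gives the
nonlinear model. `X` and the log-scale hyperparameters are optimized jointly
by scaled conjugate gradients (Møller's SCG).

**Stage-structure prior.** Cells are grouped by stage; for each group g with
index set I_g a grouped Sammon stress compares within-group distances in
data space (d\*) and latent space (d):

    C_g = (1/c_g) Σ_{m<n ∈ I_g} (d*_{mn} − d_{mn})² / d*_{mn},   c_g = Σ_{m<n ∈ I_g} d*_{mn}

The prior p(X) ∝ exp(−γ C) turns the fit into maximization of the log
posterior `L − Σ_g γ_g C_g`. The locality weight γ (scalar or per stage)
controls the trade-off: γ = 0 recovers the plain GPLVM; very large γ
fragments the map into isolated within-stage clusters.

**Gene relevance maps.** The fitted model gives an explicit predictive map
μ(x\*) = m + Yᵀ K⁻¹ k(x\*) with variance σ²(x\*). The Jacobian ∂μ/∂x\*,
evaluated on a 20×20 grid over the map, names at each location the gene with
the greatest gradient norm — a nonlinear analogue of PCA loadings. Gradient
profiles at chosen locations report all genes' local changes with the
derivative-process SD as uncertainty.

## Worked example

Synthetic staged data (6 stages × 16 cells, 24 genes, two housekeeping
controls, a planted two-branch split at stage 4) are bundled as a generator,
so the whole pipeline runs without any download:

```python
import numpy as np
from stagemap import (fixture_blastocyst, normalize_to_controls, KernelParams,
                      OptimizerSettings, nearest_neighbour_error,
                      baseline_embedding, gmm_subclusters,
                      subcluster_expression_profile)
from stagemap.structure import fit_structured_gplvm
from stagemap.evaluation import accuracy_up_to_swap

matrix, truth = fixture_blastocyst()
mat = normalize_to_controls(matrix, ["ctrl_1", "ctrl_2"])

fit = fit_structured_gplvm(mat.values, mat.stage_of_cell, Q=2,
                           params=KernelParams(), gamma=10.0,
                           settings=OptimizerSettings(max_iterations=800, seed=0))
print(round(fit.log_likelihood, 1), round(fit.stress, 3))
# -1862.4 4.573

print(nearest_neighbour_error(fit.model.X, mat.stage_of_cell),
      nearest_neighbour_error(baseline_embedding(mat.values, "pca", 2),
                              mat.stage_of_cell))
# 21 19

mask = mat.stage_of_cell == "stage4"
assign = gmm_subclusters(fit.model.X[mask], seed=0)
print(accuracy_up_to_swap(assign, truth.subcluster_of_cell[mask]))
# 1.0

prof = subcluster_expression_profile(mat.values[mask], assign)
top = np.argsort(-np.abs(prof.mean_difference))[:3]
print([(mat.gene_names[i], round(prof.mean_difference[i], 2)) for i in top])
# [('marker_1', 7.97), ('marker_2', -7.88), ('gene_08', 5.78)]
```

Reading the output: the structured fit reaches log likelihood −1862.4 with a
within-stage Sammon stress of 4.573; its leave-one-out nearest-neighbour
error over stage labels (21 of 96 cells) is comparable to the PCA baseline
(19) on this mildly nonlinear fixture. A two-component Gaussian mixture on
the latent coordinates of the split stage recovers the planted branch
assignment perfectly (accuracy 1.0), and the per-gene profile ranks the two
planted marker genes as the strongest expression differences between the
branches (±8 on the log scale) — the analysis that, on real embryo data,
singles out early lineage markers such as Id2 and Gata4.

The same pipeline is scriptable from the shell:

```bash
stagemap simulate --out expr.tsv --seed 20120903
stagemap fit --input expr.tsv --out model/ --seed 0 \
             --gamma 10 --controls ctrl_1,ctrl_2
stagemap evaluate --model model/ --out eval/ --split-stage stage4 \
                  --reference-stage stage6
stagemap relevance --model model/ --out rel/ --plot
stagemap sweep-gamma --input expr.tsv --out sweep/ --seed 0 --gammas 0,10,100,1000
```

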