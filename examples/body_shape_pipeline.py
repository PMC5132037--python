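"""Body-shape morphometrics: superimposition, allometry, ordination, tests.

Simulates a three-species landmark dataset, removes size and orientation by
generalized Procrustes analysis, regresses shape on log10 centroid size, and
tests species separation with PCA, CVA, and NPMANOVA.
"""

import numpy as np

import ecomorph as em

cfg = em.default_config(seed=1)
data = em.simulate_landmarks(cfg)
print(f"simulated {data.n_specimens} specimens x {data.n_landmarks} landmarks")

fit = em.gpa(data)
print(f"GPA converged in {fit.iterations_used} iterations")

reg = em.regress_shape_on_size(fit)
print(f"allometry explains {reg.percent_predicted:.1f}% of shape variance")
print("(size-corrected residuals feed every downstream analysis)")

ordn = em.pca(reg.residuals)
explained = 100 * ordn.eigenvalues[:2] / ordn.eigenvalues.sum()
print(f"PC1/PC2 explain {explained[0]:.1f}% / {explained[1]:.1f}% of residual shape")

species = [r.species for r in data.records]
_, cva_res = em.cva(reg.residuals, species, n_perm=999, rng=1)
print(f"CVA global test: statistic={cva_res.statistic:.2f}, p={cva_res.p_value:.4f}")
print(cva_res.pairwise[["group_a", "group_b", "mahalanobis", "p_euclidean_adj"]])

d = np.linalg.norm(reg.residuals[:, None] - reg.residuals[None, :], axis=-1)
dm = em.DistanceMatrix([r.specimen_id for r in data.records], d)
np_res = em.npmanova(dm, species, n_perm=999, rng=1)
print(f"NPMANOVA: pseudo-F={np_res.statistic:.2f}, p={np_res.p_value:.4f}")
print("small p-values: species occupy distinct regions of shape space")
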