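"""Estimate multiplicative bias factors from a synthetic capture experiment.

Simulates a 6-viewpoint experiment on an ideal Gaussian chain with known
viewpoint (C) and experiment (K) biases, fits each viewpoint's contact decay,
and solves the log-linear system for the factors.  The observed
inter-viewpoint matrix F_IJ is asymmetric because each capture experiment
carries its own bias K_I; dividing the biases out restores the symmetry the
underlying contact probability must have.
"""

import numpy as np

import fourcpoly as fp
from fourcpoly import bias

rng = np.random.default_rng(0)
model = fp.GaussianChainModel.uniform(3000, 5000, nu=-1.5)   # 15 Mb chain
n = 6
beads = np.linspace(300, 2700, n).astype(int).tolist()
C_true = np.exp(rng.uniform(np.log(0.5), np.log(2), n))
K_true = np.exp(rng.uniform(np.log(0.5), np.log(2), n))

cfg = fp.SyntheticExperimentConfig(viewpoint_beads=beads, C=C_true,
                                   K=K_true, depth=1e6, n_replicates=1)
table, viewpoints = fp.generate_capture_counts(model, cfg, seed=1)

fits = {}
for vp in viewpoints:
    profile = bias.compute_bcp(table.counts(vp.id, "rep1", "WT"), vp,
                               model.frags)
    fits[vp.id] = bias.fit_loglog_decay(profile)

pair_matrix = bias.interviewpoint_bcp(fits, viewpoints)
factors, corrected = bias.solve_bias_factors(pair_matrix)

# The product C_I*K_I is what divides each viewpoint's profile in Phase 2;
# it is the robustly identified combination (gauge: geometric mean 1).
true_ck = C_true * K_true
true_ck /= np.exp(np.mean(np.log(true_ck)))
est_ck = factors.C * factors.K
est_ck /= np.exp(np.mean(np.log(est_ck)))
print("viewpoint   C*K true   C*K estimated")
for i, vid in enumerate(factors.viewpoint_ids):
    print(f"{vid:>9}   {true_ck[i]:8.3f}   {est_ck[i]:13.3f}")
r = np.corrcoef(np.log(est_ck), np.log(true_ck))[0, 1]
print(f"log-factor correlation with truth: r = {r:.4f}")

before = bias.median_relative_asymmetry(pair_matrix.F)
after = bias.median_relative_asymmetry(corrected.P_directional)
print(f"\nmedian relative asymmetry of F_IJ (observed):  {before:.4f}")
print(f"median relative asymmetry of P_IJ (corrected): {after:.4f}")
print("\nThe corrected matrix is near-symmetric: the experiment-level")
print("biases, not the underlying contacts, caused the asymmetry.")
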