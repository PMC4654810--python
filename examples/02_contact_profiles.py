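"""From raw capture counts to a smoothed contact probability profile.

Counts are thresholded (<= 5 reads zeroed) and floored with a pseudo-count
of 1, length-normalized to the biased contact probability, divided by the
viewpoint's bias factors, and kernel-smoothed (Gaussian sigma 20 kb,
80 kb filter) onto a 20 kb grid — the genomic resolution of the assay.
"""

import numpy as np

import fourcpoly as fp
from fourcpoly import bias, cpp

model = fp.GaussianChainModel.uniform(2000, 5000, nu=-1.5)   # 10 Mb chain
cfg = fp.SyntheticExperimentConfig(viewpoint_beads=[1000], depth=1e6,
                                   n_replicates=1)
table, (vp,) = fp.generate_capture_counts(model, cfg, seed=2)

raw_counts = table.counts(vp.id, "rep1", "WT")
counts = cpp.threshold_and_pseudocount(raw_counts)   # threshold 5, pseudo 1
print(f"fragments with <=5 reads floored to the pseudo-count: "
      f"{int(np.sum(raw_counts <= 5))} of {raw_counts.size}")

bcp = bias.compute_bcp(counts, vp, model.frags)
unity = fp.BiasFactors([vp.id], np.ones(1), np.ones(1), 0.0)
profile = cpp.compute_cpp(bcp, unity, model.frags)
track = cpp.smooth_cpp(profile, grid=cpp.make_grid(model.frags))

print(f"grid points: {track.grid.size} (20 kb spacing), "
      f"covered: {int(track.covered.sum())}")
for offset_kb in (100, 500, 2000):
    g = np.argmin(np.abs(track.grid - (vp.midpoint + offset_kb * 1000)))
    print(f"smoothed CPP {offset_kb:>5} kb from the viewpoint: "
          f"{track.values[g]:.3e}")
print("\nContact probability falls roughly as s^(-3/2) with separation s,")
print("the ideal Gaussian-chain decay used as the entropic null.")
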