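"""Run all four analysis phases from files, as the CLI would.

Simulates a two-condition (WT vs deletion-like test), two-replicate,
five-viewpoint experiment with realistic biases and one injected
interaction, writes the standard input files (fragment BED, viewpoint BED,
counts TSV), and drives the full pipeline: bias factors, smoothed CPP
tracks, DRCP tracks, DIR calls and compaction exponents, all persisted to
an output directory with a JSON report.
"""

import json
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import fourcpoly as fp
from fourcpoly.fragments import viewpoints_to_bed
from fourcpoly.pipeline import RunConfig, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="fourcpoly_demo_"))
model = fp.GaussianChainModel.uniform(1500, 5000, nu=-1.5)   # 7.5 Mb
beads = np.linspace(150, 1350, 5).astype(int).tolist()
rng = np.random.default_rng(20)
C = np.exp(rng.uniform(np.log(0.7), np.log(1.4), 5))
K = np.exp(rng.uniform(np.log(0.7), np.log(1.4), 5))

frames, vps = [], None
for cond, spikes in (("WT", []), ("del", [(None, 380, 440, 2.5)])):
    cfg = fp.SyntheticExperimentConfig(
        viewpoint_beads=beads, C=C, K=K, depth=4e5, n_replicates=2,
        spikes=spikes, condition=cond)
    table, vps = fp.generate_capture_counts(model, cfg, seed=rng)
    p = workdir / f"counts_{cond}.tsv"
    table.to_tsv(p)
    frames.append(pd.read_csv(p, sep="\t"))
pd.concat(frames).to_csv(workdir / "counts.tsv", sep="\t", index=False)
model.frags.to_bed(workdir / "fragments.bed")
viewpoints_to_bed(vps, workdir / "viewpoints.bed")

config = RunConfig(counts=str(workdir / "counts.tsv"),
                   fragments=str(workdir / "fragments.bed"),
                   viewpoints=str(workdir / "viewpoints.bed"),
                   out_dir=str(workdir / "out"))
result = run_pipeline(config)

report = json.loads((result.out_dir / "report.json").read_text())
print(f"outputs in {result.out_dir}")
print(f"DIRs: {report['dirs']}")
print("asymmetry before/after bias correction (per experiment):")
for key, val in report["median_asymmetry"].items():
    print(f"  {key}: {val['before']:.3f} -> {val['after']:.3f}")
nus = [row["nu"] for row in report["nu"]]
print(f"compaction exponents: median {np.median(nus):.2f} "
      f"(ideal Gaussian chain: -1.50)")
print("\nThe injected 2.5-fold block (1.9-2.2 Mb) should appear among the")
print("increase-direction DIRs; exponents sit near the ideal-chain -3/2,")
print("pulled slightly toward zero by the read-count threshold, which")
print("keeps only upward count fluctuations in the sparse far tail.")
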