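# fourcpoly

Polymer-physics analysis of multi-viewpoint 4C / PE-4Cseq chromatin contact
data: bias correction, contact probability profiles, differential
interacting regions, and local compaction exponents, with a Gaussian-chain
null model that doubles as a synthetic-data generator and Maxwell-model
fits for 3D DNA FISH cross-validation.

## The problem

Circular chromosome conformation capture (4C) measures how often a fixed
"viewpoint" fragment touches every other restriction fragment on its
chromosome.  Comparing such contact profiles between conditions — most
acutely across a large heterozygous deletion — requires separating three
things that purely statistical pipelines conflate:

1. **multiplicative technical biases**, both of the viewpoint sequence and
   of each capture experiment;
2. **entropic physics**: a polymer's contacts fall off as a power law
   `P(s) ~ s^ν` of genomic separation `s`, and a deletion that juxtaposes
   two distant regions raises their contact frequency for purely physical
   reasons;
3. **genuine biology**: gained or lost specific interactions and changes in
   local chromatin compaction.

`fourcpoly` grounds the analysis in a generalized Gaussian
"beads-on-a-string" chain.  Beads (restriction fragments) are joined by
springs `k_{i,i+1} ~ s^{2ν/3}`, giving contact probabilities `P ~ s^ν`
with `ν = -3/2` for the ideal chain; the local slope of a log-log
smoothing-spline fit at 100 kb is the per-viewpoint compaction measure
`ν_I`.

## The four phases

1. **Bias correction.**  Counts are normalized by viewpoint × fragment
   length (the *biased contact probability*, BCP).  Between viewpoints,
   `F_IJ = C_I · C_J · K_I · P_IJ` with `P_IJ` symmetric; the matrix
   asymmetry `log F_IJ − log F_JI = log K_I − log K_J` identifies the
   experiment factors and an ordinary least-squares solve in log space
   (nearest and next-nearest viewpoint pairs, power-law null for `P`)
   recovers all factors.  With `n` viewpoints there are `n(n−1)`
   observables against `2n` parameters, so **at least 4 viewpoints** are
   required.
2. **Contact probability profiles.**  Counts ≤ 5 are zeroed, a pseudo-count
   of 1 added, the BCP divided by `C_I·K_I`, and the raw profile smoothed
   with a Gaussian kernel (σ = 20 kb, 80 kb filter) onto a 20 kb grid.
3. **Differential regions (DIRs).**  The DRCP signal
   `(log P_test − log P_ref)/|log P_ref|` flags candidate sites (≥ 5 %);
   each must pass a two-sided Mann–Whitney U test on raw per-fragment
   values in an 80 kb window (p < 0.05) in **both** biological replicates.
4. **Compaction.**  `ν_I` per viewpoint from the spline slope at 100 kb,
   with replicate-based uncertainty and condition comparisons.

FISH cross-validation: probe-pair distances follow
`P(r) = 4πr²(k/2π)^{3/2}·exp(−k r²/2)`; the MLE `k = 3/⟨r²⟩` and the
differential `(k_df − k_wt)/k_wt` compare tethering strength across
genotypes at the sign/strength level.

## Worked example

`examples/` contains one short script per capability.  Bias correction on
a six-viewpoint synthetic experiment with known factors
(`examples/01_bias_correction.py`) prints:

```
viewpoint   C*K true   C*K estimated
      vp1      1.301           1.297
      vp2      0.927           0.921
      vp3      0.522           0.516
      vp4      0.868           0.874
      vp5      2.220           2.259
      vp6      0.825           0.822
log-factor correlation with truth: r = 0.9999

median relative asymmetry of F_IJ (observed):  0.2615
median relative asymmetry of P_IJ (corrected): 0.0070
```

The observed inter-viewpoint matrix is strongly asymmetric (26 % median
relative asymmetry) because each experiment carries its own bias; after
correction the contact matrix is symmetric to well under 1 %, as a true
contact probability must be, and the per-viewpoint correction factor
`C_I·K_I` matches its ground-truth value to a few parts per thousand.  DIR calling on a 20 Mb chromosome with an
injected 2-fold, 300 kb interaction gain
(`examples/03_differential_regions.py`) prints:

```
DIRs called: 1
  chrS:11.47-11.83 Mb  increase  |DRCP|max=0.085  p=(1.5e-06, 1.5e-06)
```

— exactly one region, coinciding with the injected block (11.5–11.8 Mb),
in the correct direction, and nothing else chromosome-wide.

A thin CLI wraps the same functions:

```bash
4cpoly simulate --n-beads 2000 --viewpoints 6 --out simdir/
4cpoly run --config run.yaml
4cpoly fish-fit --distances d.tsv --out k.tsv
4cpoly digest --fasta genome.fa --site AAGCTT --out frags.bed
4cpoly enrich --query dirs.bed --annot ctcf.bed --chrom-len 156000000
```

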