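# Methods

## The generalized Gaussian chain

Chromatin is modeled as beads joined by Gaussian springs.  The joint
density of bead positions factorizes over segments,

    P({x_i}) = ∏_i (k_{i,i+1}/2π)^{3/2} exp[−k_{i,i+1}(x_i − x_{i+1})²/2],

so successive displacements are independent isotropic 3D Gaussians with
per-axis variance `1/k_{i,i+1}`.  A pure Gaussian chain has `k ~ 1/s` for a
segment of genomic length `s`, which yields the classic contact-probability
decay `P(s) ~ s^{−3/2}`; the generalized scaling `k ~ s^{2ν/3}` corresponds
to `P ~ s^ν`.  Spatial units are arbitrary throughout — only exponents and
ratios carry meaning.

Two facts about this family shape the simulator:

- **A uniform chain can only express ν = −3/2.**  Springs in series add
  variances, so for equal segments the pair variance grows linearly in bead
  count whatever per-segment constant is chosen.  The uniform constructor
  is therefore the ideal-chain reference used to validate the exponent
  estimator at −3/2.
- **Geometric chains express any ν.**  When segment lengths grow
  geometrically away from a reference bead, the pair variance — a geometric
  sum dominated by its largest term — scales as `s^{−2ν/3}` while each
  segment individually obeys `k ~ s^{2ν/3}`.  `GaussianChainModel.geometric`
  realizes exponent-recovery tests at ν ∈ {−1.8, −1.5, −1.0}.  The scaling
  is asymptotic; with growth 1.07 from a 100 bp first segment the residual
  finite-size slope error at 100 kb is below ~0.07, inside the ±0.15
  tolerance used in the tests.

**Contacts** are operationalized as a hard sphere: two beads touch when
their distance is below a capture radius.  The default radius makes a
typical adjacent pair (median spring constant) touch in half the sampled
configurations.  For strongly heterogeneous chains that default can
saturate the profile, so `capture_radius_for` pins the radius to a target
contact probability at a chosen separation instead.  A saturation bias is
intrinsic to any finite radius: where the radius is not small against the
pair distance scale, the measured decay flattens slightly (the uniform
2500-bead chain measures ≈ −1.45 rather than −1.50 at 100 kb with the
default radius, well inside tolerance).

## Phase 1 — bias model and solver

Counts are normalized by viewpoint length × fragment length to the biased
contact probability (BCP).  Between viewpoints the model is
`F_IJ = C_I C_J K_I P_IJ` with `P_IJ` symmetric: `C` is a property of the
viewpoint sequence, `K` of the individual capture experiment.  The
inter-viewpoint BCP is *not* read off the raw captures at the partner
viewpoint's fragments (which may be dominated by specific interactions) but
evaluated from each experiment's log-log smoothing-spline decay fit at the
pair separation.

Identifiability requires care.  The antisymmetric part of the log matrix,
`log F_IJ − log F_JI = log K_I − log K_J`, pins the experiment factors up
to a constant.  The symmetric part confounds `C_I + C_J` with `P_IJ`: if
`P` were an unconstrained symmetric matrix the viewpoint factors would be
invisible, because `C_I + C_J` is itself symmetric.  The solver therefore
substitutes the polymer null `log P_IJ = b₀ + b₁ log s_IJ` and solves the
stacked system by ordinary least squares (unweighted; residuals reported).
By default only nearest and next-nearest viewpoint pairs in chromosomal
order enter the fit, and the resulting factors correct all pairs.

Gauge fixing: geometric means of `C` and `K` are set to 1; `b₀` (i.e. the
scale of `P`) absorbs the remainder.  The corrected matrix is reported both
directionally (`F_IJ/(C_I C_J K_I)`, whose residual asymmetry is the
diagnostic of correction quality) and symmetrized by geometric mean.

The parameter count — `2n` bias factors against at most `n(n−1)`
observables — requires `n ≥ 4`; the solver refuses fewer viewpoints.

Separations for deletion-carrying conditions can be computed in deleted
coordinates via `compress_coordinates`, implementing the entropic-null view
of a junction: reference distance minus deletion length when a pair
straddles the deletion.

## Phase 2 — profiles and smoothing

Counts ≤ 5 are zeroed, then a pseudo-count of 1 is added everywhere — in
that fixed order, so low-coverage fragments carry exactly the floor value
and missing data cannot imitate differential signal.  The raw unbiased
profile `P = F/(C_I K_I)` lives on irregular fragment midpoints and is
smoothed by Nadaraya–Watson kernel regression (Gaussian σ = 20 kb,
truncated at ±2σ, i.e. an 80 kb filter) onto a uniform 20 kb grid — the
measurement's genomic resolution, hence grid step = σ.  Kernel regression
on midpoints, each fragment contributing once and unweighted by length,
avoids the aliasing that binning variable-size fragments would introduce;
being a weighted mean it cannot overshoot the raw value range, and grid
points with no fragment in the window are missing, not zero.

Before any cross-sample comparison the two smoothed profiles are rescaled
to **unit sum** over their shared covered grid points.  This removes
residual experiment scale (without it the differential signal would be
gauge-dependent) while keeping every value well below 1, so the
`|log P_ref|` denominator used in Phase 3 stays bounded away from zero — a
unit-*mean* normalization would drive values through 1, where that
denominator vanishes.

## Phase 3 — differential regions

The differential relative contact probability is

    DRCP = (log P_test − log P_ref) / |log P_ref|.

Dividing by the magnitude (the raw log of a probability is negative) makes
positive DRCP mean enrichment in the test condition.  Grid points where
either profile is missing, the reference sits at the pseudo-count floor, or
`P_ref` approaches 1 are masked.

A grid point seeds a DIR when |DRCP| ≥ 0.05 with the same sign in both
replicates (a same-sign supra-threshold point within ±80 kb in the second
replicate), and a two-sided Mann–Whitney U test on the *raw* per-fragment
values inside the 80 kb window bracketing the point rejects at α = 0.05 in
both replicates independently.  Windows with fewer than 3 fragments per
side are untestable and recorded as such.  Runs of seed windows of one sign
merge into maximal intervals (each seed spans ±40 kb, so a single seed
yields 80 kb).  No multiple-testing correction is applied; the
both-replicate intersection is the false-positive guard, taking the
per-window rate from α to about α².  Grid points inside a declared deletion
are excluded; the default comparison runs on reference coordinates with
that masking, and deleted-coordinate comparison is available through
`compress_coordinates` for the entropic-null view.

## Phase 4 — compaction exponents

`ν_I` is the analytic derivative, at 100 kb, of a smoothing spline fitted
to log contact probability against log separation over 10 kb–10 Mb (the
typically linear regime; the scaling form breaks down at the measurement
resolution below and toward confinement scales above).  The spline's
penalty is chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`); fits require ≥ 30 positive
points spanning at least a decade, and duplicate separations are averaged
in log space.  Uncertainty comes from the spread across biological
replicates; condition comparisons flag `|Δν| > 1.96·SE` (the criterion is
this package's choice of a replicate-spread z-test).

In the pipeline, Phase-4 fits use thresholded counts *without* the
pseudo-count: floor values are missing data, and treating them as
observations flattens the tail slope.  A residual truncation bias remains —
the threshold keeps only upward count fluctuations in the sparse far
tail — pulling ν slightly toward zero at low depth; at the default
simulation depths the effect is ≲ 0.15.

## FISH spring constants

Probe-pair distances under the model follow the Maxwell-type density
`P(r) = 4πr²(k/2π)^{3/2} exp(−k r²/2)` — the norm of a 3D Gaussian with
per-axis variance `1/k`.  The score equation `3n/(2k) = Σr²/2` gives the
closed-form MLE `k = 3/⟨r²⟩`, cross-checked in the tests against numeric
root-finding on the score; uncertainty is a seeded nonparametric bootstrap
(1000 resamples by default — the data carry no replicate structure that
would support a spread-based error).  Genotype comparisons report the
relative differential `(k_df − k_wt)/k_wt` with a delta-method standard
error.  No conversion between FISH distances and 4C contact probabilities
is attempted: the interaction volume defining a 4C contact is unknown, so
comparisons are at the sign/strength level only.  WT samples pool both
homologues (indistinguishable by FISH); in the deletion genotype the two
chromosomes are fitted separately.

## Enrichment testing

Overlap between DIRs and an annotation set is tested by uniformly
re-placing the annotation intervals (lengths preserved, independent
placements, excluded regions such as the deletion honored by rejection
sampling) and computing the upper-tail empirical p-value
`(1 + #{null ≥ observed})/(n_perm + 1)`.  Both the base-pair overlap
(primary) and the count of query intervals touched (secondary) are
reported; sites are permuted, queries held fixed.  A 20 kb running-coverage
density track of the annotation supports visual alignment with DIR calls.

## The synthetic generator

The generator realizes the bias model forward: expected BCP
`= C_I · C_fragment · K_I · P`, with `P` the chain's exact contact
probability (3D-Gaussian tail integral), spikes multiplied in, converted to
expected counts by the length product, and counts drawn as independent
Poisson per replicate.  Two modeling choices matter:

- The count scale is anchored to a *bias-free* experiment of the target
  depth, so the bias factors modulate each experiment's realized yield —
  as in a real experiment, and necessary for `K` to be observable at all.
- The sequence bias `C_J` acts regionally (default 200 kb around the
  viewpoint): a bias confined to the single anchoring fragment would be
  invisible to the smoothed inter-viewpoint estimate that Phase 1 uses.

Default study conditions: depth 10⁶ reads per viewpoint, two replicates,
bias factors log-uniform in [0.5, 2], 5 kb uniform fragments.  Deletions
remove whole fragments and rejoin the flanks with a segment equal to the
two severed half-fragments, its spring constant from the same scaling law;
surviving beads retain their reference coordinates for cross-coordinate
comparison.

What the generator does **not** emulate: excluded-volume and confinement
effects, fragment-length heterogeneity of real digests, GC/mappability
bias structure (biases are multiplicative scalars by design — the method
removes biases without modeling their sources), trans contacts, and
ligation artifacts near the viewpoint.  Passing tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to every artifact of real 4C libraries.

## Problem sizes and numerical choices

- Ideal-chain exponent validation: 2500 beads × 5 kb, 8000 configurations
  sampled in 500-configuration chunks, slope averaged over three interior
  viewpoints, fitted over 10–500 kb — the window where expected contact
  counts stay ≥ ~5, so log-fit truncation (zero-count fragments dropping
  out) does not bias the tail.
- DIR calibration: 20 Mb chromosome (4000 × 5 kb), depth 10⁶; null rates
  measured on 250 non-overlapping 80 kb windows per replicate; spike
  recovery (2-fold over 300 kb, ~1.5 Mb from the viewpoint) across 20
  seeded replicate-pair simulations.
- Deletion entropics: 400-bead chain, 100 beads removed, 20 000 paired
  configurations with shared seeds.
- All simulations accept a single integer seed; derived streams use
  `numpy.random.SeedSequence` spawning.
- Mann–Whitney p-values use scipy's implementation (exact for small
  tie-free windows, midrank-corrected asymptotics otherwise); the
  degenerate all-tied window returns p = 1.
- Log-log fits are natural-log throughout; slopes are base-invariant.

## Known limitations

- The power-law substitution for `P_IJ` in the bias solver makes viewpoint
  factors `C` identifiable only insofar as the decay really is a common
  power law across viewpoints.  Through the smoothed-profile route the
  spline partially absorbs the partner viewpoint's regional bias, so the
  individual C/K split can be confounded; the product `C_I K_I` — the
  quantity that actually divides each profile in Phase 2 — is pinned by
  the matrix antisymmetry essentially exactly (log-correlation ≈ 1 in the
  synthetic validations), and symmetry restoration holds regardless of the
  split.
- DRCP values depend mildly on the unit-sum normalization span, since the
  denominator `|log P_ref|` is scale-dependent; the 5 % threshold is
  calibrated to the default 20 kb grid over megabase-scale profiles.
- The spring-constant comparison between FISH and 4C is directional only.
- Compaction estimates at low sequencing depth inherit the threshold
  truncation bias described above.
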