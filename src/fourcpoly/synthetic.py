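"""Generalized Gaussian "beads-on-a-string" chain: null model and simulator.

Chromatin is modeled as beads (restriction fragments) joined by Gaussian
springs.  The joint distribution of bead positions {x_i} factorizes over
segments,

    P({x_i}) = prod_i (k_{i,i+1} / 2 pi)^{3/2} exp[-k_{i,i+1} (x_i - x_{i+1})^2 / 2],

so successive displacements are independent 3D Gaussians with per-axis
variance 1/k_{i,i+1}.  For a purely Gaussian chain k ~ 1/s (s the genomic
segment length), giving the classic contact-probability fall-off P ~ s^{-3/2};
allowing a local exponent nu generalizes this to k ~ s^{2 nu / 3} and
P ~ s^{nu}.  Spatial units are arbitrary — only exponents and ratios are
compared with theory.

The same model drives the synthetic-data generator: multi-viewpoint capture
counts with power-law decay, multiplicative viewpoint (C) and experiment (K)
biases, injected interaction spikes, Poisson read noise, replicates, and
heterozygous deletions (fragment removal plus chain rejoining).  A "contact"
is operationalized as a hard sphere of configurable capture radius; the
default radius makes adjacent beads touch in about half the configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi as chi_dist

from .fish import DistanceSample
from .fragments import CaptureTable, FragmentMap, Viewpoint

__all__ = [
    "GaussianChainModel",
    "SyntheticExperimentConfig",
    "sample_chain",
    "contact_probabilities",
    "contact_profile",
    "simulate_contact_profile",
    "theoretical_contact_profile",
    "default_capture_radius",
    "apply_deletion",
    "generate_capture_counts",
    "sample_fish_distances",
    "compress_coordinates",
]

_CHI3 = chi_dist(3)


@dataclass(frozen=True)
class GaussianChainModel:
    """Bead-spring chain anchored to a restriction-fragment map.

    One bead per fragment, placed at the fragment midpoint; the segment
    between beads i and i+1 has genomic length ``segments[i]`` bp and spring
    constant ``k[i] = (segments[i] / s_ref)^(2 nu_i / 3)``.
    ``reference_midpoints`` retains original-genome coordinates across
    deletions for cross-coordinate comparisons.
    """

    frags: FragmentMap
    nu: np.ndarray                  # per-segment scaling exponent
    s_ref: float                    # segment length with unit spring constant
    reference_midpoints: np.ndarray

    def __post_init__(self):
        nu = np.broadcast_to(np.asarray(self.nu, dtype=float),
                             (self.n_beads - 1,)).copy()
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "reference_midpoints",
                           np.asarray(self.reference_midpoints, dtype=float))

    @property
    def n_beads(self) -> int:
        return self.frags.n_fragments

    @property
    def positions(self) -> np.ndarray:
        """Bead genomic positions in the model's own (current) coordinates."""
        return self.frags.midpoints

    @property
    def segments(self) -> np.ndarray:
        return np.diff(self.positions)

    @property
    def spring_constants(self) -> np.ndarray:
        k = (self.segments / self.s_ref) ** (2.0 * self.nu / 3.0)
        if np.any(~np.isfinite(k)) or np.any(k <= 0):
            raise ValueError("spring constants must be positive and finite")
        return k

    @classmethod
    def from_fragment_map(cls, frags: FragmentMap, nu: float | np.ndarray = -1.5,
                          s_ref: float | None = None) -> "GaussianChainModel":
        mids = frags.midpoints
        if s_ref is None:
            s_ref = float(np.median(np.diff(mids)))
        return cls(frags, np.asarray(nu, dtype=float), float(s_ref), mids)

    @classmethod
    def uniform(cls, n_beads: int, segment_bp: int = 10_000,
                nu: float = -1.5, chromosome: str = "chrS"
                ) -> "GaussianChainModel":
        frags = FragmentMap.uniform(chromosome, n_beads, segment_bp)
        return cls.from_fragment_map(frags, nu=nu, s_ref=float(segment_bp))

    @classmethod
    def geometric(cls, n_beads: int, first_segment_bp: int = 2_000,
                  growth: float = 1.02, nu: float = -1.5,
                  chromosome: str = "chrG") -> "GaussianChainModel":
        """Chain whose segments grow geometrically away from bead 0.

        Because the pair variance is a sum of per-segment variances
        (s_i/s_ref)^(-2 nu/3) and a geometric series is dominated by its
        largest term, the variance between bead 0 and a bead at genomic
        distance s scales as s^(-2 nu/3), so bead 0's contact profile decays
        as s^nu for *any* exponent — unlike a uniform chain, where springs in
        series force the pure-Gaussian -3/2 regardless of nu.  Use bead 0 as
        the viewpoint when validating exponent recovery.
        """
        if growth <= 1.0:
            raise ValueError("growth must exceed 1")
        lengths = np.maximum(
            1, np.round(first_segment_bp * growth **
                        np.arange(n_beads)).astype(np.int64))
        edges = np.concatenate(([0], np.cumsum(lengths)))
        frags = FragmentMap(chromosome, edges[:-1], edges[1:])
        return cls.from_fragment_map(frags, nu=nu,
                                     s_ref=float(first_segment_bp))

    def pair_variance(self, i: int, j: int) -> float:
        """Per-axis spatial variance between beads i and j."""
        if i == j:
            return 0.0
        lo, hi = min(i, j), max(i, j)
        return float(np.sum(1.0 / self.spring_constants[lo:hi]))


def default_capture_radius(model: GaussianChainModel,
                           adjacent_contact: float = 0.5) -> float:
    """Capture radius giving the requested contact frequency for a typical
    adjacent bead pair (median spring constant)."""
    k_typ = float(np.median(model.spring_constants))
    return float(_CHI3.ppf(adjacent_contact) / np.sqrt(k_typ))


def capture_radius_for(model: GaussianChainModel, bead: int,
                       separation: float, contact_probability: float) -> float:
    """Capture radius that makes ``bead``'s theoretical contact probability
    equal ``contact_probability`` at genomic ``separation`` (bp).

    Useful for strongly heterogeneous chains, where the median-spring default
    may saturate (or starve) the profile over the separations of interest.
    """
    if not (0 < contact_probability < 1):
        raise ValueError("contact probability must be in (0, 1)")
    pos = model.positions
    j = int(np.argmin(np.abs(np.abs(pos - pos[bead]) - separation)))
    if j == bead:
        raise ValueError("separation resolves to the viewpoint bead itself")
    var = model.pair_variance(bead, j)
    return float(_CHI3.ppf(contact_probability) * np.sqrt(var))


def sample_chain(model: GaussianChainModel, n_config: int,
                 seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Independent chain configurations, shape (n_config, N, 3).

    The first bead sits at the origin; each subsequent displacement is an
    isotropic 3D Gaussian with per-axis variance 1/k of its segment.
    """
    if n_config < 0:
        raise ValueError("n_config must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    N = model.n_beads
    out = np.zeros((n_config, N, 3))
    if n_config == 0:
        return out
    sd = 1.0 / np.sqrt(model.spring_constants)
    steps = rng.standard_normal((n_config, N - 1, 3)) * sd[None, :, None]
    np.cumsum(steps, axis=1, out=steps)
    out[:, 1:, :] = steps
    return out


def contact_probabilities(configs: np.ndarray, radius: float,
                          chunk: int = 200) -> np.ndarray:
    """Empirical pairwise contact frequency matrix from sampled chains:
    fraction of configurations with |x_i - x_j| < radius.  Symmetric; the
    diagonal is 1 by definition."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if configs.ndim != 3 or configs.shape[0] == 0:
        raise ValueError("need at least one configuration")
    n_config, N, _ = configs.shape
    counts = np.zeros((N, N), dtype=np.int64)
    r2 = radius ** 2
    for lo in range(0, n_config, chunk):
        block = configs[lo:lo + chunk]
        diff = block[:, :, None, :] - block[:, None, :, :]
        d2 = np.einsum("cijk,cijk->cij", diff, diff)
        counts += np.sum(d2 < r2, axis=0)
    return counts / float(n_config)


def contact_profile(configs: np.ndarray, bead: int, radius: float
                    ) -> np.ndarray:
    """Empirical contact frequency of one bead against every bead."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    diff = configs - configs[:, bead:bead + 1, :]
    d2 = np.einsum("cjx,cjx->cj", diff, diff)
    return np.mean(d2 < radius ** 2, axis=0)


def simulate_contact_profile(model: GaussianChainModel, beads, n_config: int,
                             radius: float | None = None,
                             seed: int | np.random.Generator | None = None,
                             chunk: int = 500) -> np.ndarray:
    """Monte-Carlo contact profiles for selected beads, shape
    (len(beads), N), accumulated in chunks so large chains fit in memory."""
    beads = np.atleast_1d(np.asarray(beads, dtype=int))
    if radius is None:
        radius = default_capture_radius(model)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    counts = np.zeros((beads.size, model.n_beads), dtype=np.int64)
    r2 = radius ** 2
    done = 0
    while done < n_config:
        m = min(chunk, n_config - done)
        configs = sample_chain(model, m, rng)
        for b, bead in enumerate(beads):
            diff = configs - configs[:, bead:bead + 1, :]
            d2 = np.einsum("cjx,cjx->cj", diff, diff)
            counts[b] += np.sum(d2 < r2, axis=0)
        done += m
    return counts / float(n_config)


def theoretical_contact_profile(model: GaussianChainModel, bead: int,
                                radius: float | None = None) -> np.ndarray:
    """Exact model contact probability of ``bead`` with every other bead:
    P(|x_i - x_j| < R) for the 3D Gaussian with the chain's pair variance."""
    if radius is None:
        radius = default_capture_radius(model)
    inv_k = 1.0 / model.spring_constants
    cum = np.concatenate(([0.0], np.cumsum(inv_k)))
    var = np.abs(cum - cum[bead])
    out = np.ones(model.n_beads)
    nz = var > 0
    out[nz] = _CHI3.cdf(radius / np.sqrt(var[nz]))
    return out


def apply_deletion(model: GaussianChainModel, bead_range: tuple[int, int]
                   ) -> GaussianChainModel:
    """Heterozygous-deletion chain: remove beads in ``bead_range`` (half-open)
    and rejoin the flanks.

    The joined segment's genomic length is the sum of the two severed
    half-segments (in fragment terms: half of each junction fragment), and
    its spring constant follows the same scaling law.  The range must lie
    strictly inside the chain.  Remaining beads keep their original
    coordinates in ``reference_midpoints``.
    """
    a, b = bead_range
    if a == b:
        return model
    if not (0 < a < b < model.n_beads):
        raise ValueError("deletion range must lie strictly inside the chain")
    keep = np.ones(model.n_beads, dtype=bool)
    keep[a:b] = False
    old_starts, old_ends = model.frags.starts, model.frags.ends
    deleted_bp = int(np.sum((old_ends - old_starts)[a:b]))
    new_starts = old_starts[keep].copy()
    new_ends = old_ends[keep].copy()
    shift = new_starts >= old_starts[b]
    new_starts[shift] -= deleted_bp
    new_ends[new_ends >= old_ends[b - 1]] -= deleted_bp
    frags = FragmentMap(model.frags.chromosome, new_starts, new_ends)
    # per-segment exponent: drop deleted segments, junction takes the mean of
    # its two severed neighbours
    nu_left = model.nu[:a - 1] if a > 1 else np.empty(0)
    nu_join = np.array([(model.nu[a - 1] + model.nu[b - 1]) / 2.0])
    nu_right = model.nu[b:]
    nu = np.concatenate([nu_left, nu_join, nu_right])
    return GaussianChainModel(frags, nu, model.s_ref,
                              model.reference_midpoints[keep])


def compress_coordinates(positions: np.ndarray,
                         deletion: tuple[float, float]) -> np.ndarray:
    """Map reference-genome positions to deleted-genome coordinates: spans
    beyond the deletion shift left by the deleted length (positions inside
    the deletion map onto its start)."""
    lo, hi = deletion
    pos = np.asarray(positions, dtype=float)
    out = pos.copy()
    out[pos >= hi] -= hi - lo
    inside = (pos >= lo) & (pos < hi)
    out[inside] = lo
    return out


def sample_fish_distances(k: float, n: int,
                          seed: int | np.random.Generator | None = None,
                          probe_pair: str = "pair", label: str = "sim"
                          ) -> DistanceSample:
    """i.i.d. probe-pair distances from the Maxwell-type model density:
    the norm of a 3D Gaussian with per-axis variance 1/k."""
    if k <= 0:
        raise ValueError("k must be positive")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    xyz = rng.standard_normal((n, 3)) / np.sqrt(k)
    return DistanceSample(probe_pair, label, np.linalg.norm(xyz, axis=1))


@dataclass
class SyntheticExperimentConfig:
    """Forward model of a multi-viewpoint capture experiment.

    ``spikes`` inject specific interactions: each (viewpoint_index,
    bead_start, bead_stop, fold) multiplies that viewpoint's contact
    probability over the bead range by ``fold`` (> 0); viewpoint_index None
    applies to every viewpoint.

    ``depth`` is the expected total read count of a bias-free experiment;
    the bias factors then modulate the realized yield, as in a real capture
    experiment (an experiment with K_I = 2 returns twice the reads).  The
    sequence bias C_J acts on fragments within ``c_region_bp`` of viewpoint
    J's midpoint — viewpoint sequence biases are regional, not confined to
    the single anchoring fragment.
    """

    viewpoint_beads: list[int]
    C: np.ndarray | None = None          # per-viewpoint sequence bias
    K: np.ndarray | None = None          # per-experiment bias
    depth: float = 1e6                   # expected reads per bias-free experiment
    c_region_bp: float = 200_000.0
    n_replicates: int = 2
    spikes: list[tuple] = field(default_factory=list)
    capture_radius: float | None = None
    condition: str = "WT"
    seed: int | None = None

    def __post_init__(self):
        n = len(self.viewpoint_beads)
        self.C = np.ones(n) if self.C is None else np.asarray(self.C, float)
        self.K = np.ones(n) if self.K is None else np.asarray(self.K, float)
        if self.C.size != n or self.K.size != n:
            raise ValueError("C and K must have one entry per viewpoint")
        if np.any(self.C <= 0) or np.any(self.K <= 0):
            raise ValueError("bias factors must be positive")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        for spike in self.spikes:
            if spike[3] <= 0:
                raise ValueError("spike fold-changes must be positive")


def _viewpoint_for_bead(model: GaussianChainModel, bead: int,
                        index: int) -> Viewpoint:
    return Viewpoint(f"vp{index + 1}", model.frags.chromosome,
                     int(model.frags.starts[bead]),
                     int(model.frags.ends[bead]))


def expected_counts(model: GaussianChainModel, cfg: SyntheticExperimentConfig
                    ) -> tuple[np.ndarray, list[Viewpoint]]:
    """Expected read counts per (viewpoint, fragment) under the bias model:
    BCP = C_I * C_fragment * K_I * P, converted back to counts by the
    viewpoint x fragment length product.

    The count scale is set so a *bias-free* experiment (C = K = 1) would
    yield ``depth`` expected reads; the realized yield of each experiment
    therefore carries its bias factors, which is what makes them observable.
    """
    radius = cfg.capture_radius or default_capture_radius(model)
    n_vp = len(cfg.viewpoint_beads)
    viewpoints = [_viewpoint_for_bead(model, b, i)
                  for i, b in enumerate(cfg.viewpoint_beads)]
    c_frag = np.ones(model.n_beads)
    mids = model.positions
    for j, bead in enumerate(cfg.viewpoint_beads):
        region = np.abs(mids - mids[bead]) <= cfg.c_region_bp / 2.0
        c_frag[region] *= cfg.C[j]
    lengths = model.frags.lengths.astype(float)
    mu = np.zeros((n_vp, model.n_beads))
    for i, bead in enumerate(cfg.viewpoint_beads):
        P = theoretical_contact_profile(model, bead, radius)
        P[bead] = 0.0  # self-fragment carries no capture signal
        for spike in cfg.spikes:
            vp_idx, lo, hi, fold = spike
            if vp_idx is None or vp_idx == i:
                P[lo:hi] = P[lo:hi] * fold
        baseline = P * viewpoints[i].length * lengths
        total = baseline.sum()
        if total > 0 and cfg.depth > 0:
            scale = cfg.depth / total
            mu[i] = scale * cfg.C[i] * c_frag * cfg.K[i] * baseline
    return mu, viewpoints


def generate_capture_counts(model: GaussianChainModel,
                            cfg: SyntheticExperimentConfig,
                            seed: int | np.random.Generator | None = None
                            ) -> tuple[CaptureTable, list[Viewpoint]]:
    """Poisson capture counts for every viewpoint and replicate.

    Replicates share the expectation and differ only by the Poisson draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(cfg.seed if seed is None else seed)
    mu, viewpoints = expected_counts(model, cfg)
    table = CaptureTable(model.frags)
    for r in range(cfg.n_replicates):
        rep = f"rep{r + 1}"
        for i, vp in enumerate(viewpoints):
            counts = rng.poisson(mu[i])
            table.set_counts(vp.id, rep, cfg.condition, counts)
    return table, viewpoints
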