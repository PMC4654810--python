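"""Phase 2 — unbiased contact probability profiles (CPP) and smoothing.

Raw per-fragment contact probabilities are obtained from the BCP by dividing
out the viewpoint's bias factors, P = F / (C_I K_I), after read-count
thresholding and pseudo-count addition.  The raw profile, defined on the
irregular restriction-fragment midpoints, is then smoothed onto a uniform
genomic grid by Nadaraya-Watson kernel regression with a Gaussian kernel
(sigma 20 kb, truncated at a total filter size of 80 kb).  The smoothing
scale is the genomic resolution of the measurement, so the default grid step
equals sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bias import BiasedContactProfile, BiasFactors
from .fragments import FragmentMap

__all__ = [
    "ContactProbabilityProfile",
    "SmoothedTrack",
    "threshold_and_pseudocount",
    "compute_cpp",
    "smooth_cpp",
    "make_grid",
    "normalize_pair",
]

DEFAULT_SIGMA = 20_000
DEFAULT_WINDOW = 80_000
DEFAULT_GRID_STEP = 20_000
DEFAULT_THRESHOLD = 5
DEFAULT_PSEUDOCOUNT = 1


@dataclass
class SmoothedTrack:
    """Kernel-smoothed values on a uniform genomic grid.

    ``values`` is NaN at grid points with no fragment inside the window
    (missing, not zero)."""

    grid: np.ndarray
    values: np.ndarray
    sigma: float
    window: float

    @property
    def covered(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class ContactProbabilityProfile:
    """Raw (per-fragment) and smoothed unbiased contact probabilities for one
    viewpoint experiment."""

    viewpoint_id: str
    raw: np.ndarray             # per-fragment P, aligned to the fragment map
    midpoints: np.ndarray       # fragment midpoints, bp
    separations: np.ndarray     # |viewpoint - fragment| separations, bp
    self_mask: np.ndarray
    smoothed: SmoothedTrack | None = None
    replicate: str = ""
    condition: str = ""


def threshold_and_pseudocount(counts: np.ndarray,
                              threshold: int = DEFAULT_THRESHOLD,
                              pseudo: int = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Zero out counts <= threshold, then add the pseudo-count everywhere.

    The fixed order (threshold first, floor second) means low-count fragments
    carry exactly the pseudo-count, so missing data cannot masquerade as
    differential signal.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if pseudo < 0:
        raise ValueError("pseudo-count must be non-negative")
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    out = np.where(counts <= threshold, 0, counts) + pseudo
    return out


def compute_cpp(bcp: BiasedContactProfile, factors: BiasFactors,
                frags: FragmentMap) -> ContactProbabilityProfile:
    """Unbiased raw CPP: P = F / (C_I K_I) elementwise."""
    C, K = factors.for_viewpoint(bcp.viewpoint_id)
    raw = bcp.bcp / (C * K)
    return ContactProbabilityProfile(
        viewpoint_id=bcp.viewpoint_id, raw=raw, midpoints=frags.midpoints,
        separations=bcp.separations, self_mask=bcp.self_mask,
        replicate=bcp.replicate, condition=bcp.condition)


def make_grid(frags: FragmentMap, step: int = DEFAULT_GRID_STEP) -> np.ndarray:
    """Uniform grid of evaluation points covering the fragment map span."""
    lo, hi = frags.span
    return np.arange(lo + step / 2.0, hi, step)


def smooth_cpp(profile: ContactProbabilityProfile,
               sigma: float = DEFAULT_SIGMA, window: float = DEFAULT_WINDOW,
               grid: np.ndarray | None = None,
               grid_step: int = DEFAULT_GRID_STEP,
               frags: FragmentMap | None = None,
               exclude_self: bool = True) -> SmoothedTrack:
    """Nadaraya-Watson Gaussian kernel regression of the raw CPP onto a grid.

    Each fragment contributes its raw value once, at its midpoint, unweighted
    by length (length bias is already removed in the BCP).  The kernel is
    truncated at +-window/2 around each grid point; grid points with no
    fragment inside the window are NaN.  Being a weighted mean, the output is
    bounded by the extremes of the contributing raw values.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if window < 2 * sigma:
        raise ValueError("window must be at least 2*sigma")
    x = np.asarray(profile.midpoints, dtype=float)
    v = np.asarray(profile.raw, dtype=float)
    keep = np.isfinite(v)
    if exclude_self:
        keep &= ~profile.self_mask
    x, v = x[keep], v[keep]
    if x.size == 0:
        raise ValueError("no raw values to smooth")
    if grid is None:
        if frags is None:
            lo, hi = float(x.min()), float(x.max())
            grid = np.arange(lo, hi + grid_step, grid_step)
        else:
            grid = make_grid(frags, grid_step)
    half = window / 2.0
    out = np.full(grid.size, np.nan)
    order = np.argsort(x)
    x, v = x[order], v[order]
    lo_idx = np.searchsorted(x, grid - half, side="left")
    hi_idx = np.searchsorted(x, grid + half, side="right")
    for g in range(grid.size):
        a, b = lo_idx[g], hi_idx[g]
        if b <= a:
            continue
        d = x[a:b] - grid[g]
        w = np.exp(-0.5 * (d / sigma) ** 2)
        out[g] = np.sum(w * v[a:b]) / np.sum(w)
    track = SmoothedTrack(grid=grid, values=out, sigma=sigma, window=window)
    profile.smoothed = track
    return track


def normalize_pair(a: SmoothedTrack, b: SmoothedTrack
                   ) -> tuple[SmoothedTrack, SmoothedTrack, np.ndarray]:
    """Rescale two smoothed profiles to unit sum over their shared covered
    grid points, removing residual experiment scale before comparison.

    The common probability-like scale keeps every value well below 1, so the
    log-ratio denominator used downstream stays bounded away from zero.
    Returns the two rescaled tracks and the shared-coverage mask.
    """
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("tracks are not on the same grid")
    shared = a.covered & b.covered
    if not np.any(shared):
        raise ValueError("tracks share no covered grid points")
    sa = float(np.nansum(a.values[shared]))
    sb = float(np.nansum(b.values[shared]))
    if sa <= 0 or sb <= 0:
        raise ValueError("cannot normalize a non-positive profile")
    na = SmoothedTrack(a.grid, a.values / sa, a.sigma, a.window)
    nb = SmoothedTrack(b.grid, b.values / sb, b.sigma, b.window)
    return na, nb, shared
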