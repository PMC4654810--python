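"""Phase 3 — differential contact signals (DRCP) and DIR calling.

The differential relative contact probability between a test (e.g. deletion)
and a reference (WT) profile is the signed relative change of the log
profiles, DRCP = (log P_test - log P_ref) / |log P_ref|; dividing by the
magnitude makes positive values mean *higher* contact probability in the
test condition.  Candidate sites (|DRCP| above a signal threshold, default
5 %) are validated with a two-sided Mann-Whitney U test on the raw
per-fragment CPPs inside an 80 kb window bracketing the site, independently
in two biological replicates; only sites significant in both replicates,
with consistent sign, become differentially interacting regions (DIRs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .cpp import ContactProbabilityProfile, SmoothedTrack, normalize_pair

__all__ = [
    "DRCPTrack",
    "DIRCall",
    "compute_drcp",
    "test_window",
    "call_dirs",
    "write_dirs",
    "read_dirs",
]

DEFAULT_SIGNAL_THRESHOLD = 0.05
DEFAULT_ALPHA = 0.05
DEFAULT_WINDOW = 80_000

# guard against a vanishing |log P_ref| denominator (P_ref -> 1)
_MAX_REF_P = 0.9


@dataclass
class DRCPTrack:
    """Signed relative contact difference on the smoothing grid.

    NaN where either profile is missing or the reference sits at the
    pseudo-count floor."""

    grid: np.ndarray
    values: np.ndarray


@dataclass
class DIRCall:
    """A differentially interacting region supported by both replicates."""

    chromosome: str
    start: float
    end: float
    direction: str                  # "increase" | "decrease"
    max_drcp: float                 # max |DRCP| over the seed points
    p_rep1: float                   # smallest window p-value, replicate 1
    p_rep2: float
    n_seeds: int = 1

    @property
    def span(self) -> float:
        return self.end - self.start


def compute_drcp(p_test: SmoothedTrack, p_ref: SmoothedTrack,
                 ref_floor: float | None = None,
                 normalize: bool = True) -> DRCPTrack:
    """DRCP = (ln P_test - ln P_ref) / |ln P_ref| on a shared grid.

    With ``normalize`` (default) both tracks are first rescaled to unit sum
    over their shared coverage.  ``ref_floor`` masks grid points where the
    reference is at or below the pseudo-count floor (pass the floor value on
    the *normalized* scale).
    """
    if p_test.grid.shape != p_ref.grid.shape or \
            not np.allclose(p_test.grid, p_ref.grid):
        raise ValueError("DRCP requires both profiles on the same grid")
    if normalize:
        p_test, p_ref, _ = normalize_pair(p_test, p_ref)
    t = p_test.values
    r = p_ref.values
    values = np.full(t.shape, np.nan)
    ok = np.isfinite(t) & np.isfinite(r) & (t > 0) & (r > 0) & (r < _MAX_REF_P)
    if ref_floor is not None:
        ok &= r > ref_floor
    lt, lr = np.log(t[ok]), np.log(r[ok])
    values[ok] = (lt - lr) / np.abs(lr)
    return DRCPTrack(grid=p_test.grid, values=values)


def test_window(raw_test: np.ndarray, raw_ref: np.ndarray,
                min_per_side: int = 3) -> float | None:
    """Two-sided Mann-Whitney U p-value on raw per-fragment CPPs in a window.

    Returns None (untestable) when either side has fewer than
    ``min_per_side`` values.
    """
    raw_test = np.asarray(raw_test, dtype=float)
    raw_ref = np.asarray(raw_ref, dtype=float)
    raw_test = raw_test[np.isfinite(raw_test)]
    raw_ref = raw_ref[np.isfinite(raw_ref)]
    if raw_test.size < min_per_side or raw_ref.size < min_per_side:
        return None
    if np.all(raw_test == raw_test[0]) and np.all(raw_ref == raw_ref[0]) \
            and raw_test[0] == raw_ref[0]:
        return 1.0  # all values tied across both sides
    res = mannwhitneyu(raw_test, raw_ref, alternative="two-sided",
                       method="auto")
    return float(res.pvalue)


def _window_values(profile: ContactProbabilityProfile, center: float,
                   window: float) -> np.ndarray:
    half = window / 2.0
    keep = (np.abs(profile.midpoints - center) <= half) & ~profile.self_mask
    return profile.raw[keep]


def _same_sign_seed_nearby(drcp: DRCPTrack, center: float, sign: float,
                           threshold: float, window: float) -> bool:
    near = np.abs(drcp.grid - center) <= window
    vals = drcp.values[near]
    vals = vals[np.isfinite(vals)]
    return bool(np.any((np.sign(vals) == sign) & (np.abs(vals) >= threshold)))


def call_dirs(drcp_rep1: DRCPTrack, drcp_rep2: DRCPTrack,
              raw_test_rep1: ContactProbabilityProfile,
              raw_ref_rep1: ContactProbabilityProfile,
              raw_test_rep2: ContactProbabilityProfile,
              raw_ref_rep2: ContactProbabilityProfile,
              chromosome: str = "chr",
              signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
              alpha: float = DEFAULT_ALPHA,
              window: float = DEFAULT_WINDOW,
              deletion: tuple[float, float] | None = None
              ) -> list[DIRCall]:
    """Assemble DIRs from two replicate DRCP tracks plus raw profiles.

    A grid point seeds a DIR when |DRCP| >= threshold with the same sign in
    both replicates (within one window), and the windowed Mann-Whitney test
    rejects at ``alpha`` in both replicates.  Runs of seed windows of one
    sign are merged into maximal intervals; grid points inside a declared
    deletion are masked.
    """
    if drcp_rep1.grid.shape != drcp_rep2.grid.shape or \
            not np.allclose(drcp_rep1.grid, drcp_rep2.grid):
        raise ValueError("replicate DRCP tracks are on different grids")
    grid = drcp_rep1.grid
    half = window / 2.0

    seeds = []  # (grid index, sign, |drcp| max, p1, p2)
    for g in range(grid.size):
        v1 = drcp_rep1.values[g]
        if not np.isfinite(v1) or np.abs(v1) < signal_threshold:
            continue
        center = grid[g]
        if deletion is not None and deletion[0] <= center < deletion[1]:
            continue
        sign = np.sign(v1)
        if not _same_sign_seed_nearby(drcp_rep2, center, sign,
                                      signal_threshold, window):
            continue
        p1 = test_window(_window_values(raw_test_rep1, center, window),
                         _window_values(raw_ref_rep1, center, window))
        if p1 is None or p1 >= alpha:
            continue
        p2 = test_window(_window_values(raw_test_rep2, center, window),
                         _window_values(raw_ref_rep2, center, window))
        if p2 is None or p2 >= alpha:
            continue
        v2_near = drcp_rep2.values[np.abs(drcp_rep2.grid - center) <= window]
        v2_near = v2_near[np.isfinite(v2_near)]
        strength = max(np.abs(v1),
                       np.max(np.abs(v2_near)) if v2_near.size else 0.0)
        seeds.append((g, sign, strength, p1, p2))

    calls: list[DIRCall] = []
    for (g, sign, strength, p1, p2) in seeds:
        start, end = grid[g] - half, grid[g] + half
        direction = "increase" if sign > 0 else "decrease"
        if calls and calls[-1].direction == direction and \
                start <= calls[-1].end:
            last = calls[-1]
            calls[-1] = DIRCall(chromosome, last.start, max(last.end, end),
                                direction,
                                max(last.max_drcp, strength),
                                min(last.p_rep1, p1), min(last.p_rep2, p2),
                                last.n_seeds + 1)
        else:
            calls.append(DIRCall(chromosome, start, end, direction,
                                 strength, p1, p2))
    return calls


def write_dirs(calls: list[DIRCall], path: str | Path) -> None:
    """Serialize calls as BED6+ (score = 1000*min(1, |DRCP|)), sorted by
    start, with the extra columns needed for a lossless round-trip."""
    calls = sorted(calls, key=lambda c: c.start)
    for a, b in zip(calls, calls[1:]):
        assert not (a.direction == b.direction and b.start < a.end), \
            "overlapping same-direction calls must be merged upstream"
    header = ("#chrom\tstart\tend\tname\tscore\tstrand\tdirection\t"
              "max_drcp\tp_rep1\tp_rep2\tn_seeds\n")
    with open(path, "w") as fh:
        fh.write(header)
        for i, c in enumerate(calls):
            score = int(round(1000 * min(1.0, abs(c.max_drcp))))
            strand = "+" if c.direction == "increase" else "-"
            fh.write(f"{c.chromosome}\t{int(c.start)}\t{int(c.end)}\t"
                     f"DIR_{i + 1}\t{score}\t{strand}\t{c.direction}\t"
                     f"{c.max_drcp:.10g}\t{c.p_rep1:.10g}\t{c.p_rep2:.10g}\t"
                     f"{c.n_seeds}\n")


def read_dirs(path: str | Path) -> list[DIRCall]:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return [DIRCall(str(r["chrom"]), float(r["start"]), float(r["end"]),
                    str(r["direction"]), float(r["max_drcp"]),
                    float(r["p_rep1"]), float(r["p_rep2"]), int(r["n_seeds"]))
            for _, r in df.iterrows()]
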