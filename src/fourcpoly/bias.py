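"""Phase 1 — multiplicative bias correction for multi-viewpoint 4C data.

A capture count between viewpoint I and fragment alpha, normalized by the
product of viewpoint and fragment lengths, is the *biased* contact
probability (BCP) F.  Between two viewpoints the BCP is modeled as

    F_IJ = C_I * C_J * K_I * P_IJ

where C_I, C_J are sequence-level viewpoint bias factors, K_I is the bias of
the capture *experiment* anchored at I, and P_IJ is the unbiased contact
probability, which must be symmetric in I and J.  Because C_I + C_J enters
symmetrically, the asymmetry of the observed matrix, log F_IJ - log F_JI =
log K_I - log K_J, identifies the experiment factors; separating C from P
additionally requires the polymer null P_IJ ~ s_IJ^nu, which makes the whole
system an ordinary log-linear least-squares problem.

With n viewpoints the model has 2n bias parameters against at most n(n-1)
observable F_IJ, so n(n-1) > 2n, i.e. at least four viewpoints, is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import FragmentMap, Viewpoint, CaptureTable
from .scaling import LogLogSplineFit, fit_loglog

__all__ = [
    "BiasedContactProfile",
    "ViewpointPairMatrix",
    "BiasFactors",
    "CorrectedPairMatrix",
    "IdentifiabilityError",
    "compute_bcp",
    "compute_all_bcp",
    "fit_loglog_decay",
    "interviewpoint_bcp",
    "solve_bias_factors",
    "relative_asymmetry",
    "median_relative_asymmetry",
    "min_viewpoints_required",
]


class IdentifiabilityError(ValueError):
    """The bias system has more parameters than usable observations."""


@dataclass
class BiasedContactProfile:
    """Length-normalized capture profile for one viewpoint experiment.

    ``bcp[i] = count[i] / (viewpoint_length * fragment_length[i])`` in
    counts per bp^2; ``separations[i]`` is |viewpoint midpoint - fragment
    midpoint| in bp.  Fragments overlapping the viewpoint are flagged in
    ``self_mask`` and excluded from decay fits.
    """

    viewpoint_id: str
    bcp: np.ndarray
    separations: np.ndarray
    self_mask: np.ndarray
    viewpoint_midpoint: float
    replicate: str = ""
    condition: str = ""

    def fit_values(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.self_mask
        return self.separations[keep], self.bcp[keep]


@dataclass
class ViewpointPairMatrix:
    """Average inter-viewpoint BCP F_IJ (rows = anchoring experiment I)."""

    viewpoint_ids: list[str]
    positions: np.ndarray      # viewpoint midpoints, bp
    F: np.ndarray              # (n, n), NaN on the diagonal
    s: np.ndarray              # (n, n) pair separations, symmetric
    extrapolated: np.ndarray   # (n, n) bool: s outside the fit support

    @property
    def n(self) -> int:
        return len(self.viewpoint_ids)


@dataclass
class BiasFactors:
    """Estimated per-viewpoint C and per-experiment K, gauge-fixed to
    geometric mean 1; the symmetric P absorbs the remaining scale."""

    viewpoint_ids: list[str]
    C: np.ndarray
    K: np.ndarray
    residual_norm: float
    gauge: str = "geometric-mean(C)=geometric-mean(K)=1"

    def for_viewpoint(self, viewpoint_id: str) -> tuple[float, float]:
        try:
            i = self.viewpoint_ids.index(viewpoint_id)
        except ValueError:
            raise KeyError(f"no bias factors for viewpoint {viewpoint_id!r}")
        return float(self.C[i]), float(self.K[i])


@dataclass
class CorrectedPairMatrix:
    """Unbiased P_IJ estimates: the directional estimate F_IJ/(C_I C_J K_I)
    and its geometric-mean symmetrization."""

    viewpoint_ids: list[str]
    P_directional: np.ndarray
    P: np.ndarray


def compute_bcp(counts: np.ndarray, viewpoint: Viewpoint, frags: FragmentMap,
                replicate: str = "", condition: str = "") -> BiasedContactProfile:
    """Normalize raw counts by viewpoint length x fragment length."""
    counts = np.asarray(counts, dtype=float)
    lengths = frags.lengths.astype(float)
    if np.any(lengths <= 0):
        raise ValueError("fragment map contains zero-length fragments")
    if viewpoint.length <= 0:
        raise ValueError(f"viewpoint {viewpoint.id} has non-positive length")
    bcp = counts / (viewpoint.length * lengths)
    self_mask = np.zeros(frags.n_fragments, dtype=bool)
    self_mask[viewpoint.fragment_indices(frags)] = True
    seps = np.abs(frags.midpoints - viewpoint.midpoint)
    return BiasedContactProfile(viewpoint.id, bcp, seps, self_mask,
                                viewpoint.midpoint, replicate, condition)


def compute_all_bcp(table: CaptureTable, viewpoints: list[Viewpoint],
                    frags: FragmentMap) -> dict[tuple[str, str, str],
                                                BiasedContactProfile]:
    """BCP for every (viewpoint, replicate, condition) experiment present."""
    by_id = {v.id: v for v in viewpoints}
    out = {}
    for (vp, rep, cond) in table.keys:
        if vp not in by_id:
            continue
        out[(vp, rep, cond)] = compute_bcp(table.counts(vp, rep, cond),
                                           by_id[vp], frags, rep, cond)
    return out


def fit_loglog_decay(profile: BiasedContactProfile,
                     fit_range=(1e4, 1e7), min_points: int = 30
                     ) -> LogLogSplineFit:
    """Smoothing-spline fit of log BCP against log separation."""
    s, f = profile.fit_values()
    return fit_loglog(s, f, fit_range=fit_range, min_points=min_points,
                      label=f"viewpoint {profile.viewpoint_id}")


def interviewpoint_bcp(fits: dict[str, LogLogSplineFit],
                       viewpoints: list[Viewpoint]) -> ViewpointPairMatrix:
    """Average BCP between every ordered viewpoint pair, from the smoothed
    decay fits (never from the raw captures at the partner's fragments, which
    may be dominated by specific interactions)."""
    ids = [v.id for v in viewpoints]
    missing = [i for i in ids if i not in fits]
    if missing:
        raise ValueError(f"no decay fit for viewpoints {missing}")
    pos = np.array([v.midpoint for v in viewpoints], dtype=float)
    n = len(ids)
    F = np.full((n, n), np.nan)
    s = np.abs(pos[:, None] - pos[None, :])
    extrap = np.zeros((n, n), dtype=bool)
    for i, vid in enumerate(ids):
        fit = fits[vid]
        for j in range(n):
            if i == j:
                continue
            F[i, j] = float(fit(s[i, j]))
            extrap[i, j] = not bool(fit.in_support(s[i, j]))
    return ViewpointPairMatrix(ids, pos, F, s, extrap)


def min_viewpoints_required() -> int:
    """Smallest n for which the observable count n(n-1) exceeds the 2n bias
    parameters, found by direct enumeration."""
    n = 2
    while n * (n - 1) <= 2 * n:
        n += 1
    return n


def _selected_pairs(order: np.ndarray, selection: str) -> list[tuple[int, int]]:
    n = order.size
    if selection == "all":
        return [(int(order[a]), int(order[b]))
                for a in range(n) for b in range(a + 1, n)]
    if selection in ("nn2", "nearest+next-nearest"):
        pairs = [(int(order[a]), int(order[a + 1])) for a in range(n - 1)]
        pairs += [(int(order[a]), int(order[a + 2])) for a in range(n - 2)]
        return pairs
    raise ValueError(f"unknown pair selection {selection!r}")


def solve_bias_factors(pair_matrix: ViewpointPairMatrix,
                       pair_selection: str = "nn2"
                       ) -> tuple[BiasFactors, CorrectedPairMatrix]:
    """Estimate C and K by least squares on the stacked log equations.

    Each selected unordered pair {I, J} contributes two equations,

        log F_IJ = log C_I + log C_J + log K_I + b0 + b1 log s_IJ
        log F_JI = log C_I + log C_J + log K_J + b0 + b1 log s_IJ,

    where ``b0 + b1 log s`` is the power-law polymer null for log P_IJ.  By
    default only nearest and next-nearest neighbor pairs (in chromosomal
    order) enter the fit; the correction is then applied to all pairs.
    Gauge: geometric means of C and of K fixed to 1.
    """
    n = pair_matrix.n
    n_min = min_viewpoints_required()
    if n < n_min:
        raise IdentifiabilityError(
            f"bias correction needs at least {n_min} viewpoints "
            f"(n(n-1) > 2n); got {n}")
    order = np.argsort(pair_matrix.positions)
    pairs = _selected_pairs(order, pair_selection)

    rows, y = [], []
    n_par = 2 * n + 2  # c (n), kappa (n), b0, b1
    for (i, j) in pairs:
        for (a, b) in ((i, j), (j, i)):
            Fab = pair_matrix.F[a, b]
            if not np.isfinite(Fab) or Fab <= 0:
                raise ValueError(
                    f"non-positive F for selected pair "
                    f"({pair_matrix.viewpoint_ids[a]}, "
                    f"{pair_matrix.viewpoint_ids[b]})")
            row = np.zeros(n_par)
            row[i] += 1.0          # log C_I
            row[j] += 1.0          # log C_J
            row[n + a] = 1.0       # log K of the anchoring experiment
            row[2 * n] = 1.0       # b0
            row[2 * n + 1] = np.log(pair_matrix.s[a, b])
            rows.append(row)
            y.append(np.log(Fab))
    A = np.vstack(rows)
    y = np.asarray(y)
    sol, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    residual = float(np.linalg.norm(A @ sol - y))
    c = sol[:n] - np.mean(sol[:n])          # gauge: geometric mean C = 1
    kappa = sol[n:2 * n] - np.mean(sol[n:2 * n])  # gauge: geometric mean K = 1
    C = np.exp(c)
    K = np.exp(kappa)

    denom = C[:, None] * C[None, :] * K[:, None]
    P_dir = pair_matrix.F / denom
    P_sym = np.sqrt(P_dir * P_dir.T)
    factors = BiasFactors(pair_matrix.viewpoint_ids, C, K, residual)
    corrected = CorrectedPairMatrix(pair_matrix.viewpoint_ids, P_dir, P_sym)
    return factors, corrected


def relative_asymmetry(M: np.ndarray) -> np.ndarray:
    """|M_IJ - M_JI| / (M_IJ + M_JI); NaN where both entries vanish or are
    undefined.  Symmetric with values in [0, 1]."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("relative asymmetry needs a square matrix")
    total = M + M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.abs(M - M.T) / total
    out[~np.isfinite(total) | (total == 0)] = np.nan
    np.fill_diagonal(out, np.nan)
    return out


def median_relative_asymmetry(M: np.ndarray) -> float:
    """Median of the defined off-diagonal relative-asymmetry entries."""
    asym = relative_asymmetry(M)
    vals = asym[np.triu_indices_from(asym, k=1)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined asymmetry entries")
    return float(np.median(vals))
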