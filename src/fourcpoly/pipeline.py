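"""End-to-end orchestration of the four analysis phases.

Given per-experiment capture-count tables, a fragment map and viewpoint
definitions, the pipeline runs bias correction (Phase 1), smoothed contact
probability profiles (Phase 2), differential-region calling between a test
and a reference condition (Phase 3) and local compaction exponents
(Phase 4), persisting every intermediate.  All tunables default to the
values used throughout the package; the configuration is serialized into
the output directory so a run is reproducible from its artifacts alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias, compaction, cpp, dirs as dirmod
from .fragments import (CaptureTable, FragmentMap, Viewpoint,
                        read_capture_table, viewpoints_from_bed, write_track)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "make_report",
           "ConfigError", "DataError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class DataError(ValueError):
    """Input data that cannot be analyzed as configured."""


@dataclass
class RunConfig:
    counts: str                       # TSV of capture counts (all experiments)
    fragments: str                    # BED fragment map
    viewpoints: str                   # BED viewpoint definitions
    out_dir: str
    test_condition: str = "del"
    ref_condition: str = "WT"
    replicates: list[str] = field(default_factory=lambda: ["rep1", "rep2"])
    deletion: tuple[float, float] | None = None
    sigma: float = cpp.DEFAULT_SIGMA
    window: float = cpp.DEFAULT_WINDOW
    grid_step: int = cpp.DEFAULT_GRID_STEP
    count_threshold: int = cpp.DEFAULT_THRESHOLD
    pseudocount: int = cpp.DEFAULT_PSEUDOCOUNT
    signal_threshold: float = dirmod.DEFAULT_SIGNAL_THRESHOLD
    alpha: float = dirmod.DEFAULT_ALPHA
    eval_scale: float = compaction.DEFAULT_EVAL_SCALE
    fit_range: tuple[float, float] = compaction.DEFAULT_FIT_RANGE
    pair_selection: str = "nn2"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.deletion is not None:
            cfg.deletion = tuple(float(x) for x in cfg.deletion)
        cfg.fit_range = tuple(float(x) for x in cfg.fit_range)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fit_range"] = list(self.fit_range)
        if self.deletion is not None:
            data["deletion"] = list(self.deletion)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate(self) -> None:
        for attr in ("counts", "fragments", "viewpoints"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise ConfigError(f"missing input: {attr} = {p}")
        if len(self.replicates) != 2:
            raise ConfigError("DIR calling is defined on exactly two "
                              "biological replicates")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    config: RunConfig
    factors: dict                     # (condition, replicate) -> BiasFactors
    asymmetry_before: dict            # (condition, replicate) -> float
    asymmetry_after: dict
    profiles: dict                    # (vp, rep, cond) -> ContactProbabilityProfile
    drcp: dict                        # (vp, rep) -> DRCPTrack
    dir_calls: dict                   # vp -> list[DIRCall]
    nu: list                          # CompactionEstimate records
    out_dir: Path


def _phase1(table: CaptureTable, viewpoints: list[Viewpoint],
            frags: FragmentMap, condition: str, replicate: str,
            pair_selection: str):
    profiles = {}
    fits = {}
    for vp in viewpoints:
        counts = table.counts(vp.id, replicate, condition)
        prof = bias.compute_bcp(counts, vp, frags, replicate, condition)
        profiles[vp.id] = prof
        fits[vp.id] = bias.fit_loglog_decay(prof)
    pm = bias.interviewpoint_bcp(fits, viewpoints)
    factors, corrected = bias.solve_bias_factors(pm, pair_selection)
    asym_before = bias.median_relative_asymmetry(pm.F)
    asym_after = bias.median_relative_asymmetry(corrected.P_directional)
    return factors, asym_before, asym_after


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run Phases 1-4 and persist all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: list[str] = [f"seed={config.seed}"]

    frags = FragmentMap.from_bed(config.fragments)
    viewpoints = viewpoints_from_bed(config.viewpoints)
    n_min = bias.min_viewpoints_required()
    if len(viewpoints) < n_min:
        raise DataError(f"bias correction needs at least {n_min} viewpoints; "
                        f"got {len(viewpoints)}")
    table, rejects = read_capture_table(config.counts, frags)
    if len(rejects):
        rejects.to_csv(out / "rejected_rows.tsv", sep="\t", index=False)
        log.append(f"rejected rows: {len(rejects)}")

    conditions = (config.test_condition, config.ref_condition)
    factors_all, asym_before, asym_after = {}, {}, {}
    factor_rows = []
    for cond in conditions:
        for rep in config.replicates:
            factors, a_before, a_after = _phase1(
                table, viewpoints, frags, cond, rep, config.pair_selection)
            factors_all[(cond, rep)] = factors
            asym_before[(cond, rep)] = a_before
            asym_after[(cond, rep)] = a_after
            for i, vid in enumerate(factors.viewpoint_ids):
                factor_rows.append((cond, rep, vid, factors.C[i],
                                    factors.K[i], factors.residual_norm))
    pd.DataFrame(factor_rows, columns=["condition", "replicate", "viewpoint",
                                       "C", "K", "residual_norm"]) \
      .to_csv(out / "factors.tsv", sep="\t", index=False)

    # Phase 2: thresholded, bias-divided, smoothed profiles
    grid = cpp.make_grid(frags, config.grid_step)
    profiles = {}
    for cond in conditions:
        for rep in config.replicates:
            factors = factors_all[(cond, rep)]
            for vp in viewpoints:
                counts = cpp.threshold_and_pseudocount(
                    table.counts(vp.id, rep, cond),
                    config.count_threshold, config.pseudocount)
                bcp_prof = bias.compute_bcp(counts, vp, frags, rep, cond)
                prof = cpp.compute_cpp(bcp_prof, factors, frags)
                cpp.smooth_cpp(prof, config.sigma, config.window, grid=grid)
                profiles[(vp.id, rep, cond)] = prof
                write_track(frags.chromosome,
                            (grid - config.grid_step / 2).astype(int),
                            (grid + config.grid_step / 2).astype(int),
                            prof.smoothed.values,
                            out / f"cpp_{vp.id}_{rep}_{cond}.bedGraph")

    # Phase 3: DRCP and DIR calling per viewpoint
    drcp_tracks = {}
    dir_calls = {}
    for vp in viewpoints:
        per_rep = []
        for rep in config.replicates:
            track = dirmod.compute_drcp(
                profiles[(vp.id, rep, config.test_condition)].smoothed,
                profiles[(vp.id, rep, config.ref_condition)].smoothed)
            drcp_tracks[(vp.id, rep)] = track
            per_rep.append(track)
            write_track(frags.chromosome,
                        (grid - config.grid_step / 2).astype(int),
                        (grid + config.grid_step / 2).astype(int),
                        track.values, out / f"drcp_{vp.id}_{rep}.bedGraph")
        rep1, rep2 = config.replicates
        calls = dirmod.call_dirs(
            per_rep[0], per_rep[1],
            profiles[(vp.id, rep1, config.test_condition)],
            profiles[(vp.id, rep1, config.ref_condition)],
            profiles[(vp.id, rep2, config.test_condition)],
            profiles[(vp.id, rep2, config.ref_condition)],
            chromosome=frags.chromosome,
            signal_threshold=config.signal_threshold, alpha=config.alpha,
            window=config.window, deletion=config.deletion)
        dir_calls[vp.id] = calls
        dirmod.write_dirs(calls, out / f"dirs_{vp.id}.bed")

    # Phase 4: compaction exponents.  Fit on bias-divided profiles without
    # the pseudo-count: floor values are missing data, and a log-log fit
    # that treats them as observations flattens the tail slope.
    by_id = {v.id: v for v in viewpoints}
    nu_rows = []
    nu_records = []
    for (vpid, rep, cond) in profiles:
        factors = factors_all[(cond, rep)]
        counts = cpp.threshold_and_pseudocount(
            table.counts(vpid, rep, cond), config.count_threshold, pseudo=0)
        bcp_prof = bias.compute_bcp(counts, by_id[vpid], frags, rep, cond)
        prof = cpp.compute_cpp(bcp_prof, factors, frags)
        try:
            est = compaction.fit_scaling_exponent(
                prof, config.eval_scale, config.fit_range)
        except Exception as exc:  # span too small on tiny runs
            log.append(f"nu fit skipped for {vpid}/{rep}/{cond}: {exc}")
            continue
        nu_records.append(est)
        nu_rows.append((vpid, rep, cond, est.nu, est.n_points))
    pd.DataFrame(nu_rows, columns=["viewpoint", "replicate", "condition",
                                   "nu", "n_points"]) \
      .to_csv(out / "nu.tsv", sep="\t", index=False)

    result = PipelineResult(config, factors_all, asym_before, asym_after,
                            profiles, drcp_tracks, dir_calls, nu_records, out)
    report = make_report(result)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    (out / "run.log").write_text("\n".join(log) + "\n")
    return result


def make_report(result: PipelineResult) -> dict:
    """Summary statistics: DIR counts and size quantiles, nu table,
    asymmetry medians before/after correction."""
    all_calls = [c for calls in result.dir_calls.values() for c in calls]
    sizes = np.array([c.span for c in all_calls], dtype=float)
    dir_stats = {"n_dirs": int(len(all_calls))}
    if sizes.size:
        dir_stats.update(min_bp=float(sizes.min()),
                         median_bp=float(np.median(sizes)),
                         max_bp=float(sizes.max()),
                         total_bp=float(sizes.sum()))
    nu_table = [
        {"viewpoint": e.viewpoint_id, "replicate": e.replicate, "nu": e.nu}
        for e in result.nu
    ]
    asym = {
        f"{cond}/{rep}": {"before": result.asymmetry_before[(cond, rep)],
                          "after": result.asymmetry_after[(cond, rep)]}
        for (cond, rep) in result.asymmetry_before
    }
    return {"dirs": dir_stats, "nu": nu_table, "median_asymmetry": asym}
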