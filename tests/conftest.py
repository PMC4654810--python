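import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import fourcpoly as fp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def uniform_frags():
    return fp.FragmentMap.uniform("chrT", 50, 5000)


@pytest.fixture
def small_chain():
    """200-bead ideal Gaussian chain, 10 kb segments (2 Mb)."""
    return fp.GaussianChainModel.uniform(200, 10_000, nu=-1.5)


@pytest.fixture
def biased_experiment():
    """A 6-viewpoint biased capture experiment on a 15 Mb ideal chain,
    with the ground-truth bias factors attached."""
    rng = np.random.default_rng(7)
    model = fp.GaussianChainModel.uniform(3000, 5000, nu=-1.5)
    n = 6
    beads = np.linspace(300, 2700, n).astype(int).tolist()
    C = np.exp(rng.uniform(np.log(0.5), np.log(2), n))
    K = np.exp(rng.uniform(np.log(0.5), np.log(2), n))
    cfg = fp.SyntheticExperimentConfig(viewpoint_beads=beads, C=C, K=K,
                                       depth=1e6, n_replicates=1)
    table, vps = fp.generate_capture_counts(model, cfg, seed=11)
    return {"model": model, "table": table, "viewpoints": vps,
            "C": C, "K": K, "config": cfg}


def spline_route_pair_matrix(experiment, replicate="rep1", condition="WT"):
    """Phase-1 front end: BCP -> decay fits -> inter-viewpoint matrix."""
    from fourcpoly import bias
    model = experiment["model"]
    fits = {}
    for vp in experiment["viewpoints"]:
        counts = experiment["table"].counts(vp.id, replicate, condition)
        prof = bias.compute_bcp(counts, vp, model.frags, replicate, condition)
        fits[vp.id] = bias.fit_loglog_decay(prof)
    return bias.interviewpoint_bcp(fits, experiment["viewpoints"])


def model_pair_matrix(C, K, positions, ids=None, nu=-1.5, scale=1.0):
    """Noiseless F_IJ = C_I C_J K_I P(s_IJ) with a power-law P."""
    from fourcpoly.bias import ViewpointPairMatrix
    n = len(positions)
    pos = np.asarray(positions, dtype=float)
    ids = ids or [f"v{i}" for i in range(n)]
    s = np.abs(pos[:, None] - pos[None, :])
    with np.errstate(divide="ignore"):
        P = np.where(s > 0, scale * s ** nu, np.nan)
    F = np.asarray(C)[:, None] * np.asarray(C)[None, :] \
        * np.asarray(K)[:, None] * P
    np.fill_diagonal(F, np.nan)
    return ViewpointPairMatrix(ids, pos, F, s,
                               np.zeros((n, n), dtype=bool))


def simulated_condition_profiles(model, bead, spike=None, seed=0, depth=1e6,
                                 condition="WT", n_replicates=2):
    """Phase-2 profiles (thresholded, pseudo-counted, smoothed) for one
    synthetic single-viewpoint condition; biases are unity so DIR behaviour
    can be studied in isolation."""
    from fourcpoly import bias, cpp
    spikes = [] if spike is None else [spike]
    cfg = fp.SyntheticExperimentConfig(
        viewpoint_beads=[bead], depth=depth, n_replicates=n_replicates,
        spikes=spikes, condition=condition)
    table, vps = fp.generate_capture_counts(model, cfg, seed=seed)
    unity = fp.BiasFactors([vps[0].id], np.ones(1), np.ones(1), 0.0)
    grid = cpp.make_grid(model.frags)
    out = {}
    for r in range(n_replicates):
        rep = f"rep{r + 1}"
        counts = cpp.threshold_and_pseudocount(
            table.counts(vps[0].id, rep, condition))
        prof_b = bias.compute_bcp(counts, vps[0], model.frags, rep, condition)
        prof = cpp.compute_cpp(prof_b, unity, model.frags)
        cpp.smooth_cpp(prof, grid=grid)
        out[rep] = prof
    return out
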