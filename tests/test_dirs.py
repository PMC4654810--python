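import numpy as np
import pytest

import fourcpoly as fp
from fourcpoly import dirs

from conftest import simulated_condition_profiles


def track(values, step=20_000.0):
    values = np.asarray(values, dtype=float)
    grid = step / 2 + step * np.arange(values.size)
    return fp.SmoothedTrack(grid, values, 20_000, 80_000)


class TestDRCP:
    def test_identical_profiles_zero(self):
        a = track([0.01, 0.02, 0.03, 0.04])
        out = dirs.compute_drcp(a, track([0.01, 0.02, 0.03, 0.04]),
                                normalize=False)
        assert np.allclose(out.values, 0.0)

    def test_direct_arithmetic(self):
        out = dirs.compute_drcp(track([0.02]), track([0.01]),
                                normalize=False)
        assert out.values[0] == pytest.approx(np.log(2) / abs(np.log(0.01)),
                                              rel=1e-9)
        assert out.values[0] == pytest.approx(0.1505, abs=1e-3)

    def test_positive_means_enrichment_in_test(self):
        out = dirs.compute_drcp(track([0.04]), track([0.01]),
                                normalize=False)
        assert out.values[0] > 0

    def test_missing_and_floor_masked(self):
        a = track([0.02, np.nan, 0.02])
        b = track([0.01, 0.01, 0.005])
        out = dirs.compute_drcp(a, b, ref_floor=0.005, normalize=False)
        assert np.isfinite(out.values[0])
        assert np.isnan(out.values[1])    # missing test value
        assert np.isnan(out.values[2])    # reference at the floor

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dirs.compute_drcp(track([1, 2]), track([1, 2], step=10_000),
                              normalize=False)


class TestWindowTest:
    def test_identical_values_p_one(self):
        assert dirs.test_window([2.0] * 5, [2.0] * 5) == 1.0

    def test_fully_separated_exact_p(self):
        p = dirs.test_window([10, 20, 30, 40, 50], [1, 2, 3, 4, 5])
        assert p == pytest.approx(2 / 252, rel=1e-9)  # 0.0079...

    def test_small_windows_untestable(self):
        assert dirs.test_window([1.0, 2.0], [1.0, 2.0, 3.0]) is None
        assert dirs.test_window([], []) is None


@pytest.fixture(scope="module")
def chain():
    return fp.GaussianChainModel.uniform(2000, 5000, nu=-1.5)


class TestCallDIRs:

    def test_spike_recovered_with_direction(self, chain):
        spike = (0, 1150, 1210, 2.0)  # 300 kb, 2-fold, ~0.75 Mb from vp
        test = simulated_condition_profiles(chain, 1000, spike=spike, seed=3)
        ref = simulated_condition_profiles(chain, 1000, seed=4)
        d1 = dirs.compute_drcp(test["rep1"].smoothed, ref["rep1"].smoothed)
        d2 = dirs.compute_drcp(test["rep2"].smoothed, ref["rep2"].smoothed)
        calls = dirs.call_dirs(d1, d2, test["rep1"], ref["rep1"],
                               test["rep2"], ref["rep2"])
        lo, hi = 1150 * 5000, 1210 * 5000
        hits = [c for c in calls if c.direction == "increase"
                and c.end > lo and c.start < hi]
        assert hits, "injected spike not recovered"
        assert all(c.span >= 80_000 for c in calls)

    def test_swapping_conditions_flips_directions(self, chain):
        spike = (0, 1150, 1210, 2.0)
        test = simulated_condition_profiles(chain, 1000, spike=spike, seed=3)
        ref = simulated_condition_profiles(chain, 1000, seed=4)
        d_fwd = [dirs.compute_drcp(test[r].smoothed, ref[r].smoothed)
                 for r in ("rep1", "rep2")]
        d_rev = [dirs.compute_drcp(ref[r].smoothed, test[r].smoothed)
                 for r in ("rep1", "rep2")]
        fwd = dirs.call_dirs(d_fwd[0], d_fwd[1], test["rep1"], ref["rep1"],
                             test["rep2"], ref["rep2"])
        rev = dirs.call_dirs(d_rev[0], d_rev[1], ref["rep1"], test["rep1"],
                             ref["rep2"], test["rep2"])
        flip = {"increase": "decrease", "decrease": "increase"}
        assert [(c.start, c.end, flip[c.direction]) for c in fwd] == \
               [(c.start, c.end, c.direction) for c in rev]

    def test_null_calls_rare(self, chain):
        test = simulated_condition_profiles(chain, 1000, seed=11)
        ref = simulated_condition_profiles(chain, 1000, seed=12)
        d1 = dirs.compute_drcp(test["rep1"].smoothed, ref["rep1"].smoothed)
        d2 = dirs.compute_drcp(test["rep2"].smoothed, ref["rep2"].smoothed)
        calls = dirs.call_dirs(d1, d2, test["rep1"], ref["rep1"],
                               test["rep2"], ref["rep2"])
        assert len(calls) <= 1  # typically zero at this scale

    def test_deletion_interval_masked(self, chain):
        spike = (0, 1150, 1210, 2.0)
        test = simulated_condition_profiles(chain, 1000, spike=spike, seed=3)
        ref = simulated_condition_profiles(chain, 1000, seed=4)
        d1 = dirs.compute_drcp(test["rep1"].smoothed, ref["rep1"].smoothed)
        d2 = dirs.compute_drcp(test["rep2"].smoothed, ref["rep2"].smoothed)
        calls = dirs.call_dirs(d1, d2, test["rep1"], ref["rep1"],
                               test["rep2"], ref["rep2"],
                               deletion=(1150 * 5000.0, 1210 * 5000.0))
        inside = [c for c in calls
                  if 1150 * 5000 < (c.start + c.end) / 2 < 1210 * 5000]
        assert not inside


class TestDIRSerialization:
    def test_empty_call_list_header_only(self, tmp_path):
        path = tmp_path / "dirs.bed"
        dirs.write_dirs([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#chrom")

    def test_sorted_and_round_trip(self, tmp_path):
        calls = [
            fp.DIRCall("chr4", 500_000, 700_000, "decrease", 0.08,
                       0.01, 0.02, 2),
            fp.DIRCall("chr4", 100_000, 260_000, "increase", 0.12,
                       0.001, 0.004, 3),
        ]
        path = tmp_path / "dirs.bed"
        dirs.write_dirs(calls, path)
        back = dirs.read_dirs(path)
        assert [c.start for c in back] == [100_000, 260_000][:1] + [500_000]
        assert back[0].direction == "increase"
        assert back[0].max_drcp == pytest.approx(0.12)
        assert back[1].p_rep2 == pytest.approx(0.02)

    def test_overlapping_same_direction_asserted(self, tmp_path):
        calls = [
            fp.DIRCall("chr4", 0, 200_000, "increase", 0.1, 0.01, 0.01),
            fp.DIRCall("chr4", 100_000, 300_000, "increase", 0.1, 0.01, 0.01),
        ]
        with pytest.raises(AssertionError):
            dirs.write_dirs(calls, tmp_path / "bad.bed")
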