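import numpy as np
import pytest

import fourcpoly as fp
from fourcpoly import synthetic


class TestChainSampling:
    def test_zero_configs(self, small_chain):
        out = fp.sample_chain(small_chain, 0, seed=1)
        assert out.shape == (0, 200, 3)

    def test_two_bead_second_moment(self):
        # k = 4 => <r^2> = 3/k = 0.75
        model = fp.GaussianChainModel.uniform(2, 10_000)
        # k = (s / s_ref)^(2 nu / 3) = s_ref / s for nu = -3/2
        model = fp.GaussianChainModel(model.frags, model.nu,
                                      s_ref=4 * 10_000,
                                      reference_midpoints=model.positions)
        assert model.spring_constants[0] == pytest.approx(4.0)
        configs = fp.sample_chain(model, 100_000, seed=1)
        r2 = np.sum((configs[:, 1] - configs[:, 0]) ** 2, axis=1).mean()
        assert r2 == pytest.approx(3.0 / 4.0, rel=0.02)

    def test_same_seed_bit_identical(self, small_chain):
        a = fp.sample_chain(small_chain, 10, seed=99)
        b = fp.sample_chain(small_chain, 10, seed=99)
        assert np.array_equal(a, b)

    def test_end_to_end_variance_linear_in_beads(self):
        """Gaussian chain law: Var(end-to-end) grows linearly with length."""
        rng = np.random.default_rng(0)
        var = {}
        for n in (50, 100, 200):
            model = fp.GaussianChainModel.uniform(n, 10_000)
            configs = fp.sample_chain(model, 20_000, rng)
            r2 = np.sum((configs[:, -1] - configs[:, 0]) ** 2, axis=1)
            var[n] = r2.mean()
        assert var[100] / var[50] == pytest.approx(99 / 49, rel=0.1)
        assert var[200] / var[100] == pytest.approx(199 / 99, rel=0.1)


class TestContactProbabilities:
    def test_huge_radius_all_ones(self, small_chain):
        configs = fp.sample_chain(small_chain, 50, seed=2)
        P = fp.contact_probabilities(configs, radius=1e9)
        assert np.allclose(P, 1.0)

    def test_symmetric_and_decaying(self, small_chain):
        configs = fp.sample_chain(small_chain, 2000, seed=3)
        radius = fp.default_capture_radius(small_chain)
        P = fp.contact_probabilities(configs, radius)
        assert np.allclose(P, P.T)
        near = np.mean([P[i, i + 1] for i in range(0, 190, 10)])
        far = np.mean([P[i, i + 10] for i in range(0, 190, 10)])
        assert near > far

    def test_profile_matches_matrix_row(self, small_chain):
        configs = fp.sample_chain(small_chain, 500, seed=4)
        radius = fp.default_capture_radius(small_chain)
        P = fp.contact_probabilities(configs, radius)
        row = fp.contact_profile(configs, 17, radius)
        assert np.allclose(P[17], row)

    def test_monte_carlo_agrees_with_theory(self, small_chain):
        radius = fp.default_capture_radius(small_chain)
        sim = fp.simulate_contact_profile(small_chain, [100], 20_000,
                                          radius=radius, seed=5)[0]
        theory = fp.theoretical_contact_profile(small_chain, 100, radius)
        sel = np.abs(np.arange(200) - 100) <= 30
        sel[100] = False
        assert np.allclose(sim[sel], theory[sel], atol=0.02)


class TestDeletion:
    def test_empty_range_identity(self, small_chain):
        out = fp.apply_deletion(small_chain, (50, 50))
        assert out is small_chain

    def test_bookkeeping(self, small_chain):
        out = fp.apply_deletion(small_chain, (60, 140))
        assert out.n_beads == 120
        assert out.frags.span[1] == small_chain.frags.span[1] - 80 * 10_000
        # reference coordinates of surviving beads unchanged
        assert out.reference_midpoints[59] == small_chain.positions[59]
        assert out.reference_midpoints[60] == small_chain.positions[140]

    def test_range_touching_ends_rejected(self, small_chain):
        with pytest.raises(ValueError):
            fp.apply_deletion(small_chain, (0, 10))
        with pytest.raises(ValueError):
            fp.apply_deletion(small_chain, (190, 200))

    def test_flanking_contact_increases(self, small_chain):
        """Entropic null: joining the flanks raises their contact
        probability relative to the intact chain (paired seeds)."""
        deleted = fp.apply_deletion(small_chain, (60, 140))
        radius = fp.default_capture_radius(small_chain)
        pre = fp.simulate_contact_profile(small_chain, [59], 20_000,
                                          radius=radius, seed=5)[0][140]
        post = fp.simulate_contact_profile(deleted, [59], 20_000,
                                           radius=radius, seed=5)[0][60]
        assert post > pre

    def test_deleted_coordinate_compression(self):
        pos = np.array([1e6, 2e6, 5e6, 9e6])
        out = fp.compress_coordinates(pos, (2.5e6, 6.5e6))
        assert np.allclose(out, [1e6, 2e6, 2.5e6, 5e6])


class TestCaptureGeneration:
    def test_zero_depth_zero_counts(self, small_chain):
        cfg = fp.SyntheticExperimentConfig(viewpoint_beads=[100], depth=0.0)
        table, vps = fp.generate_capture_counts(small_chain, cfg, seed=1)
        assert table.counts("vp1", "rep1", "WT").sum() == 0

    def test_poisson_mean_matches_expectation(self):
        model = fp.GaussianChainModel.uniform(120, 10_000)
        cfg = fp.SyntheticExperimentConfig(viewpoint_beads=[60], depth=5e4,
                                           n_replicates=1)
        mu, vps = synthetic.expected_counts(model, cfg)
        rng = np.random.default_rng(8)
        acc = np.zeros(model.n_beads)
        n_rep = 500
        for _ in range(n_rep):
            t, _ = fp.generate_capture_counts(model, cfg, seed=rng)
            acc += t.counts("vp1", "rep1", "WT")
        mean = acc / n_rep
        se = np.sqrt(np.maximum(mu[0], 1e-12) / n_rep)
        assert np.all(np.abs(mean - mu[0]) <= 3 * se + 1e-9)

    def test_doubling_K_doubles_expectation(self, small_chain):
        base = fp.SyntheticExperimentConfig(viewpoint_beads=[100, 50],
                                            K=np.array([1.0, 1.0]))
        doubled = fp.SyntheticExperimentConfig(viewpoint_beads=[100, 50],
                                               K=np.array([2.0, 1.0]))
        mu1, _ = synthetic.expected_counts(small_chain, base)
        mu2, _ = synthetic.expected_counts(small_chain, doubled)
        assert np.allclose(mu2[0], 2 * mu1[0])
        assert np.allclose(mu2[1], mu1[1])

    def test_spike_multiplies_expectation(self, small_chain):
        plain = fp.SyntheticExperimentConfig(viewpoint_beads=[100])
        spiked = fp.SyntheticExperimentConfig(
            viewpoint_beads=[100], spikes=[(0, 120, 130, 2.0)])
        mu1, _ = synthetic.expected_counts(small_chain, plain)
        mu2, _ = synthetic.expected_counts(small_chain, spiked)
        ratio = mu2[0][120:130] / mu1[0][120:130]
        assert np.allclose(ratio, ratio[0])
        # the depth renormalization slightly dilutes the nominal 2-fold
        assert 1.5 < ratio[0] <= 2.0

    def test_negative_fold_rejected(self):
        with pytest.raises(ValueError):
            fp.SyntheticExperimentConfig(viewpoint_beads=[10],
                                         spikes=[(0, 1, 2, -1.0)])

    def test_replicates_differ_only_by_noise(self, small_chain):
        cfg = fp.SyntheticExperimentConfig(viewpoint_beads=[100], depth=1e5,
                                           n_replicates=2)
        t, _ = fp.generate_capture_counts(small_chain, cfg, seed=3)
        a = t.counts("vp1", "rep1", "WT")
        b = t.counts("vp1", "rep2", "WT")
        assert not np.array_equal(a, b)
        assert abs(a.sum() - b.sum()) / a.sum() < 0.05


class TestFishSampling:
    def test_second_moment(self):
        sample = fp.sample_fish_distances(2.0, 100_000, seed=1)
        assert np.mean(sample.distances ** 2) == pytest.approx(3 / 2.0,
                                                               rel=0.02)

    def test_large_k_concentrates_near_zero(self):
        tight = fp.sample_fish_distances(100.0, 1000, seed=2)
        loose = fp.sample_fish_distances(0.1, 1000, seed=2)
        assert np.median(tight.distances) < np.median(loose.distances)

    def test_determinism(self):
        a = fp.sample_fish_distances(2.0, 50, seed=3)
        b = fp.sample_fish_distances(2.0, 50, seed=3)
        assert np.array_equal(a.distances, b.distances)
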