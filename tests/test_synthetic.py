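"""Generator contracts: spectra, event morphology, Poisson counts, trees."""

import numpy as np
import pytest

import tectapipe as tp
from tectapipe.errors import ConfigError, SamplingError
from tectapipe.synthetic import _segment_circle_crossings


def spectral_slope(trace, fs, fmin=1.0, fmax=500.0):
    """Independent least-squares log-log slope of the periodogram."""
    freqs = np.fft.rfftfreq(trace.size, d=1.0 / fs)
    power = np.abs(np.fft.rfft(trace)) ** 2
    sel = (freqs >= fmin) & (freqs <= fmax)
    # bin into log-spaced bands to stabilize the periodogram scatter
    edges = np.geomspace(fmin, fmax, 40)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = sel & (freqs >= lo) & (freqs < hi)
        if m.sum():
            centers.append(np.sqrt(lo * hi))
            means.append(power[m].mean())
    coeffs = np.polyfit(np.log(centers), np.log(means), 1)
    return coeffs[0]


def energy_fraction_above(wave, fs, floor_hz=100.0):
    """FFT oracle: fraction of waveform energy above floor_hz."""
    freqs = np.fft.rfftfreq(wave.size, d=1.0 / fs)
    e = np.abs(np.fft.rfft(wave)) ** 2
    return e[freqs > floor_hz].sum() / e.sum()


class TestBaseline:
    def test_rms_and_length(self):
        cfg = tp.LFPSimConfig(duration_s=20.0, baseline_rms=10.0)
        rec = tp.generate_baseline(cfg, seed=1)
        assert rec.samples.size == int(cfg.fs * cfg.duration_s)
        rms = np.sqrt(np.mean(rec.samples**2))
        assert 9.5 <= rms <= 10.5

    def test_default_duration_sample_count(self):
        cfg = tp.LFPSimConfig()
        assert cfg.n_samples == 2_400_000

    def test_spectral_slope_tracks_noise_exponent(self):
        fs = 2000.0
        cfg1 = tp.LFPSimConfig(fs=fs, duration_s=60.0, noise_exponent=1.0)
        cfg0 = tp.LFPSimConfig(fs=fs, duration_s=60.0, noise_exponent=0.0)
        s1 = spectral_slope(tp.generate_baseline(cfg1, 3).samples, fs)
        s0 = spectral_slope(tp.generate_baseline(cfg0, 3).samples, fs)
        assert s0 - s1 == pytest.approx(1.0, abs=0.2)

    def test_deterministic(self):
        cfg = tp.LFPSimConfig(duration_s=5.0)
        a = tp.generate_baseline(cfg, 7).samples
        b = tp.generate_baseline(cfg, 7).samples
        np.testing.assert_array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            tp.LFPSimConfig(duration_s=-1)
        with pytest.raises(ConfigError):
            tp.LFPSimConfig(fs=500)
        with pytest.raises(ConfigError):
            tp.LFPSimConfig(amp_factor_range=(0.5, 8))


class TestEventWaveform:
    def test_hfo_energy_above_100hz(self):
        w = tp.make_event_waveform(0.5, 5.0, spike_rate_hz=150, fs=2000)
        assert energy_fraction_above(w, 2000) > 0.5

    def test_artifact_energy_below_100hz(self):
        w = tp.make_event_waveform(2.0, 5.0, spike_rate_hz=10, fs=2000)
        assert energy_fraction_above(w, 2000) < 0.1

    def test_peak_amplitude(self):
        w = tp.make_event_waveform(0.5, 3.0, 150, 2000)
        assert np.max(np.abs(w)) == pytest.approx(3.0, rel=0.05)

    def test_zero_amplitude(self):
        w = tp.make_event_waveform(0.5, 0.0, 150, 2000)
        assert not w.any()

    def test_undersampled_rate_rejected(self):
        with pytest.raises(SamplingError):
            tp.make_event_waveform(0.5, 1.0, spike_rate_hz=300, fs=1000)


class TestSimulateRecording:
    def test_no_events_when_rates_zero(self, short_lfp_cfg):
        _, truth = tp.simulate_recording(short_lfp_cfg, 0)
        assert truth.events == []
        assert truth.n_true_ictal == 0

    def test_deterministic(self):
        cfg = tp.LFPSimConfig(duration_s=20.0, event_rate=2.0)
        r1, t1 = tp.simulate_recording(cfg, 5)
        r2, t2 = tp.simulate_recording(cfg, 5)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert t1.events == t2.events

    def test_poisson_event_count_conservation(self):
        # mean true count over R recordings within 3*sqrt(lambda/R) of lambda
        lam, R = 2.0, 500
        cfg = tp.LFPSimConfig(duration_s=20.0, event_rate=lam,
                              event_duration_range_s=(0.2, 0.5))
        counts = [
            tp.simulate_recording(cfg, s)[1].n_true_ictal for s in range(R)
        ]
        assert abs(np.mean(counts) - lam) <= 3 * np.sqrt(lam / R)

    def test_events_non_overlapping_and_in_bounds(self):
        cfg = tp.LFPSimConfig(duration_s=30.0, event_rate=5.0)
        _, truth = tp.simulate_recording(cfg, 11)
        evs = truth.events
        for e in evs:
            assert 0 <= e.onset_s and e.offset_s <= cfg.duration_s
        for a, b in zip(evs, evs[1:]):
            assert b.onset_s >= a.offset_s

    def test_artifacts_flagged_non_hfo(self):
        cfg = tp.LFPSimConfig(duration_s=30.0, event_rate=0.0,
                              artifact_rate=3.0)
        _, truth = tp.simulate_recording(cfg, 3)
        assert truth.events  # Poisson(3) draw at this seed is non-zero
        assert truth.n_true_ictal == 0
        assert all(not e.has_hfo for e in truth.events)

    def test_overload_raises_placement_error(self):
        cfg = tp.LFPSimConfig(duration_s=5.0, event_rate=40.0,
                              event_duration_range_s=(1.0, 1.5))
        with pytest.raises(tp.PlacementError):
            tp.simulate_recording(cfg, 1)


class TestSimulateCohort:
    def test_group_sizes_and_labels(self, short_lfp_cfg):
        specs = [("wt", 2, short_lfp_cfg), ("kd", 3, short_lfp_cfg)]
        cohort = tp.simulate_cohort(specs, 0)
        assert [lab for lab, _, _ in cohort] == ["wt", "wt", "kd", "kd", "kd"]

    def test_deterministic(self, short_lfp_cfg):
        specs = [("g", 2, short_lfp_cfg)]
        c1 = tp.simulate_cohort(specs, 9)
        c2 = tp.simulate_cohort(specs, 9)
        for (_, r1, _), (_, r2, _) in zip(c1, c2):
            np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_duplicate_labels_rejected(self, short_lfp_cfg):
        with pytest.raises(ConfigError):
            tp.simulate_cohort(
                [("g", 1, short_lfp_cfg), ("g", 1, short_lfp_cfg)], 0
            )


class TestGrowArbor:
    def test_unbranched_path(self):
        cfg = tp.ArborSimConfig(branch_prob=0.0, n_steps=10,
                                segment_len_um=4.0,
                                field_um=(150.0, 150.0, 11.0))
        tree = tp.grow_arbor(cfg, 1)
        assert len(tree.segments) == 10
        assert len(tree.tips()) == 1

    def test_full_binary_branching(self):
        cfg = tp.ArborSimConfig(branch_prob=1.0, n_steps=3,
                                segment_len_um=5.0)
        tree = tp.grow_arbor(cfg, 2)
        assert len(tree.tips()) == 8
        assert len(tree.segments) == 2 + 4 + 8

    def test_tree_is_connected(self, small_arbor_cfg):
        tree = tp.grow_arbor(small_arbor_cfg, 5)
        known = {tuple(np.round(tree.soma, 9))}
        for p, q in tree.segments:  # segments are emitted parent-first
            assert tuple(np.round(p, 9)) in known
            known.add(tuple(np.round(q, 9)))

    def test_mean_tip_count_matches_branching_oracle(self):
        # independent Monte-Carlo of the pure branching process
        p, steps, n_mc = 0.5, 4, 4000
        rng = np.random.default_rng(0)

        def mc_tips():
            tips = 1
            for _ in range(steps):
                tips += rng.binomial(tips, p)
            return tips

        oracle = np.mean([mc_tips() for _ in range(n_mc)])
        cfg = tp.ArborSimConfig(branch_prob=p, n_steps=steps,
                                segment_len_um=4.0,
                                field_um=(120.0, 120.0, 11.0))
        sim = np.mean([len(tp.grow_arbor(cfg, s).tips()) for s in range(500)])
        assert sim == pytest.approx(oracle, rel=0.05)


class TestTrueSholl:
    def _ray_tree(self, length=30.0, n_rays=1):
        soma = np.array([50.0, 50.0, 5.0])
        segs = []
        for k in range(n_rays):
            a = 2 * np.pi * k / n_rays
            d = np.array([np.cos(a), np.sin(a), 0.0])
            segs.append((soma, soma + d * length))
        return tp.ArborTree(soma=soma, segments=segs)

    def test_single_ray(self):
        tree = self._ray_tree()
        res = tp.true_sholl(tree, tree.soma, [5, 10, 15, 20, 25])
        assert res.counts.tolist() == [1, 1, 1, 1, 1]

    def test_eight_ray_star(self):
        tree = self._ray_tree(n_rays=8)
        res = tp.true_sholl(tree, tree.soma, [5, 15, 25])
        assert res.counts.tolist() == [8, 8, 8]

    def test_empty_radii_rejected(self):
        tree = self._ray_tree()
        with pytest.raises(ConfigError):
            tp.true_sholl(tree, tree.soma, [])

    def test_matches_brute_force_arc_sampling(self, small_arbor_cfg):
        # brute-force oracle: walk each segment at 0.01 um steps and count
        # sign changes of (distance - r)
        def brute(tree, center, radii):
            counts = np.zeros(len(radii), dtype=int)
            for p, q in tree.segments:
                p2, q2 = p[:2], q[:2]
                n = max(int(np.linalg.norm(q2 - p2) / 0.01), 2)
                ts = np.linspace(0, 1, n)
                pts = p2[None] + ts[:, None] * (q2 - p2)[None]
                dist = np.linalg.norm(pts - center[:2], axis=1)
                for i, r in enumerate(radii):
                    sign = np.sign(dist - r)
                    counts[i] += int(np.sum(np.abs(np.diff(sign)) > 1))
            return counts

        radii = np.arange(2.0, 40.0, 2.0)
        for seed in range(100):
            tree = tp.grow_arbor(small_arbor_cfg, seed)
            got = tp.true_sholl(tree, tree.soma, radii).counts
            want = brute(tree, tree.soma, radii)
            np.testing.assert_array_equal(got, want)

    def test_crossing_counter_tangent_and_secant(self):
        c = np.array([0.0, 0.0])
        # secant through the circle: two crossings
        assert _segment_circle_crossings(
            np.array([-2.0, 0.0]), np.array([2.0, 0.0]), c, 1.0) == 2
        # fully inside: none
        assert _segment_circle_crossings(
            np.array([-0.3, 0.0]), np.array([0.3, 0.0]), c, 1.0) == 0


class TestRenderStack:
    def test_slice_count_from_z_extent(self):
        cfg = tp.ArborSimConfig(field_um=(20.0, 20.0, 22.0), z_step_um=0.44,
                                pixel_um=1.0)
        soma = np.array([10.0, 10.0, 11.0])
        tree = tp.ArborTree(soma=soma,
                            segments=[(soma, soma + np.array([5.0, 0, 0]))])
        stack, _ = tp.render_stack([tree], cfg, 0)
        assert stack.shape[0] == 50

    def test_noiseless_ray_voxels_on_path(self):
        cfg = tp.ArborSimConfig(field_um=(40.0, 40.0, 4.4), pixel_um=1.0,
                                noise_sd=0.0)
        soma = np.array([20.0, 20.0, 2.2])
        end = soma + np.array([15.0, 0.0, 0.0])
        tree = tp.ArborTree(soma=soma, segments=[(soma, end)])
        stack, _ = tp.render_stack([tree], cfg, 0)
        zz, yy, xx = np.nonzero(stack.voxels)
        # all foreground voxels lie within the 1-voxel dilation of the path
        assert np.all(np.abs(yy - 20) <= 1)
        assert np.all((xx >= 19) & (xx <= 36))

    def test_truth_recorded_before_rasterization(self, small_arbor_cfg):
        tree = tp.grow_arbor(small_arbor_cfg, 4)
        _, truth = tp.render_stack([tree], small_arbor_cfg, 4)
        direct = tp.true_sholl(tree, tree.soma, truth.radii)
        np.testing.assert_array_equal(truth.counts, direct.counts)

    def test_out_of_field_tree_rejected(self):
        cfg = tp.ArborSimConfig(field_um=(10.0, 10.0, 4.4))
        soma = np.array([5.0, 5.0, 2.0])
        tree = tp.ArborTree(
            soma=soma, segments=[(soma, soma + np.array([20.0, 0, 0]))]
        )
        with pytest.raises(ConfigError):
            tp.render_stack([tree], cfg, 0)
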