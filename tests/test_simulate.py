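"""Drift profiles, waveform bank processing, spike trains, rendering."""

import numpy as np
import pytest

from spikegraph import simulate
from spikegraph.drift_profiles import generate_drift
from spikegraph.io import RecordingHandle
from spikegraph.simulate import (GroundTruth, depth_variation,
                                 generate_spike_trains,
                                 generate_waveform_bank, kriging_upsample,
                                 render_recording)


class TestDriftProfiles:
    def test_none_profile_is_zero(self):
        p = generate_drift("none", 600.0, seed=1)
        assert np.all(p.trace == 0)

    def test_medium_extremes_exact(self):
        p = generate_drift("medium", 600.0, seed=3)
        assert p.trace.min() == pytest.approx(-7.0)
        assert p.trace.max() == pytest.approx(7.0)

    def test_high_extremes_exact(self):
        p = generate_drift("high", 600.0, seed=3)
        assert p.trace.min() == pytest.approx(-18.5)
        assert p.trace.max() == pytest.approx(18.5)

    def test_step_offset_everywhere(self):
        p = generate_drift("step", 600.0, seed=2)
        n = p.n_bins
        jump = p.trace[n // 2:].mean(axis=0) - p.trace[:n // 2].mean(axis=0)
        assert np.all(jump > 20.0)          # 30-um offset dominates

    def test_fast_profile_bins_and_events(self):
        p = generate_drift("fast", 120.0, seed=4)
        assert p.bin_size == pytest.approx(0.2)
        # transient events push beyond the +-7 um slow envelope
        assert p.trace.max() > 7.5

    def test_deterministic_under_seed(self):
        a = generate_drift("medium", 300.0, seed=11)
        b = generate_drift("medium", 300.0, seed=11)
        assert np.array_equal(a.trace, b.trace)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_drift("sideways", 60.0)


class TestWaveformBank:
    def test_translation_only_unit_scores_near_zero(self, probe8_line):
        """A unit that purely translates across depth passes the
        variation filter with a score near zero."""
        bank = generate_waveform_bank(3, probe8_line, seed=0,
                                      morph_sd=0.0, sigma_range=(15, 20))
        assert np.all(bank.variation < 0.1)

    def test_morphing_unit_scores_above_threshold(self, probe8_line):
        """A unit whose temporal width morphs strongly across depth has
        a depth-variation score well above the 0.25 retention cut."""
        t = np.arange(61) - 30
        y = probe8_line.y
        depths = np.linspace(-20, 20, 21)
        waves = np.empty((21, 8, 61))
        for di, d in enumerate(depths):
            wd = 3.0 * (1.0 + 0.4 * d / 20.0)      # 40% width morph
            shape = -np.exp(-0.5 * (t / wd) ** 2)
            amp = np.exp(-0.5 * ((y - (60.0 + d)) / 18.0) ** 2)
            waves[di] = amp[:, None] * shape[None, :]
        waves /= np.linalg.norm(waves.reshape(21, -1), axis=1).mean()
        assert depth_variation(waves, probe8_line) > 0.25

    def test_kriging_consistent_at_bank_depths(self, rng):
        """Upsampling evaluated at an original depth reproduces the
        original waveform within a couple of percent (small lambda)."""
        depths = np.linspace(-20, 20, 21)
        waves = np.stack([np.sin(np.linspace(0, 6, 40) + 0.05 * d)
                          for d in depths])
        fine = np.array([depths[7]])
        up = kriging_upsample(waves, depths, fine)
        rel = np.linalg.norm(up[0] - waves[7]) / np.linalg.norm(waves[7])
        assert rel < 0.02

    def test_average_norm_one(self, probe16):
        bank = generate_waveform_bank(2, probe16, seed=1,
                                      sigma_range=(10, 20))
        for u in range(bank.n_units):
            norms = np.linalg.norm(
                bank.fine[u].reshape(len(bank.fine[u]), -1), axis=1)
            assert norms.mean() == pytest.approx(1.0, abs=1e-3)


class TestSpikeTrains:
    @pytest.fixture(scope="class")
    def bank(self, probe16):
        return generate_waveform_bank(4, probe16, seed=2, n_multi=4,
                                      sigma_range=(10, 20))

    def test_multi_unit_norms_in_range(self, bank):
        truth = generate_spike_trains(bank, 60.0, seed=3)
        multi = [n for n, c in zip(truth.norms, truth.unit_class)
                 if c == "multi"]
        assert all(4.0 <= n <= 10.0 for n in multi)

    def test_single_unit_norm_mean(self, probe16):
        """Norms are 10 + Exp(mean 7): the empirical mean over many
        draws sits near 17."""
        bank = generate_waveform_bank(1, probe16, seed=5,
                                      sigma_range=(10, 20))
        rng = np.random.default_rng(0)
        draws = [generate_spike_trains(bank, 1.0, seed=rng).norms[0]
                 for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(17.0, abs=0.4)

    def test_shuffled_isis_preserve_multiset(self, bank):
        """A single unit's ISI multiset is a permutation of (a prefix
        of) its reference set: shuffling preserves the sorted values."""
        t1 = generate_spike_trains(bank, 120.0, seed=7)
        t2 = generate_spike_trains(bank, 120.0, seed=7)
        for a, b in zip(t1.spike_samples, t2.spike_samples):
            assert np.array_equal(a, b)      # deterministic
        isis = np.diff(t1.spike_samples[0]) / 30000.0
        assert isis.min() >= 0.002           # refractory floor survives

    def test_min_norm_conditioning(self, bank):
        truth = generate_spike_trains(bank, 30.0, seed=9,
                                      min_single_norm=12.0)
        singles = [n for n, c in zip(truth.norms, truth.unit_class)
                   if c == "single"]
        assert all(n >= 12.0 for n in singles)


class TestRenderer:
    def test_zero_units_zero_noise_all_zero(self, tmp_path, probe16):
        bank = generate_waveform_bank(1, probe16, seed=1,
                                      sigma_range=(10, 20))
        truth = GroundTruth([np.empty(0, np.int64)], np.array([15.0]),
                            ["single"], bank.base_y[:1], bank.base_x[:1],
                            30000.0)
        prof = generate_drift("none", 2.0, seed=0,
                              probe_span=probe16.y.max())
        rec = render_recording(bank, truth, prof, probe16,
                               tmp_path / "z.bin", seed=0, noise_sd=0.0,
                               unwhiten=False)
        assert np.all(np.asarray(rec.memmap()) == 0)

    def test_single_spike_round_trip(self, tmp_path, probe16):
        """No noise, no unwhitening: the patch around a spike equals the
        inserted waveform after undoing the int16 gain."""
        bank = generate_waveform_bank(1, probe16, seed=1,
                                      sigma_range=(10, 20))
        truth = GroundTruth([np.array([30000])], np.array([15.0]),
                            ["single"], bank.base_y[:1], bank.base_x[:1],
                            30000.0)
        prof = generate_drift("none", 2.0, seed=0,
                              probe_span=probe16.y.max())
        rec = render_recording(bank, truth, prof, probe16,
                               tmp_path / "s.bin", seed=0, noise_sd=0.0,
                               unwhiten=False)
        mm = np.asarray(rec.memmap(), float)
        patch = mm[30000 - 30:30000 + 31].T / 200.0
        w = bank.waveform_at(0, 0.0) * 15.0
        assert np.abs(patch - w).max() < 0.02      # int16 quantization

    def test_colliding_spikes_superpose_linearly(self, tmp_path, probe16):
        bank = generate_waveform_bank(2, probe16, seed=2,
                                      sigma_range=(10, 20))
        truth = GroundTruth([np.array([30000]), np.array([30010])],
                            np.array([15.0, 12.0]), ["single"] * 2,
                            bank.base_y[:2], bank.base_x[:2], 30000.0)
        prof = generate_drift("none", 2.0, seed=0,
                              probe_span=probe16.y.max())
        rec = render_recording(bank, truth, prof, probe16,
                               tmp_path / "c.bin", seed=0, noise_sd=0.0,
                               unwhiten=False)
        mm = np.asarray(rec.memmap(), float)
        patch = mm[30000 - 40:30000 + 60].T / 200.0
        expect = np.zeros_like(patch)
        expect[:, 10:71] += bank.waveform_at(0, 0.0) * 15.0
        expect[:, 20:81] += bank.waveform_at(1, 0.0) * 12.0
        assert np.abs(patch - expect).max() < 0.04

    def test_deterministic_bits(self, tmp_path, probe16):
        bank = generate_waveform_bank(2, probe16, seed=3,
                                      sigma_range=(10, 20))
        truth = generate_spike_trains(bank, 3.0, seed=4)
        prof = generate_drift("medium", 3.0, seed=5,
                              probe_span=probe16.y.max())
        a = render_recording(bank, truth, prof, probe16,
                             tmp_path / "a.bin", seed=6)
        b = render_recording(bank, truth, prof, probe16,
                             tmp_path / "b.bin", seed=6)
        assert open(tmp_path / "a.bin", "rb").read() == \
            open(tmp_path / "b.bin", "rb").read()

    def test_truth_sidecar_round_trip(self, micro_recording):
        path = micro_recording["path"].with_suffix(".truth.json")
        loaded = GroundTruth.from_json(path)
        orig = micro_recording["truth"]
        assert loaded.n_units == orig.n_units
        for a, b in zip(loaded.spike_samples, orig.spike_samples):
            assert np.array_equal(a, b)


class TestHybridInsert:
    def test_inserted_trains_respect_refractory_floor(self, tmp_path,
                                                      probe16, rng):
        base = rng.normal(0, 30, (60 * 30000, 16)).astype(np.int16)
        base_path = tmp_path / "base.bin"
        base.tofile(base_path)
        rec = RecordingHandle(base_path, "int16", 16, 30000.0)
        w = rng.standard_normal((16, 61)).astype(np.float32) * 50
        # dense source train -> smooth near-unity rate modulation
        units = [{"times": np.sort(rng.integers(0, rec.n_samples, 20000)),
                  "waveform": w, "best_channel": 5, "contamination": 0.05}]
        out, truth = simulate.hybrid_insert(rec, probe16, units,
                                            tmp_path / "hyb.bin", seed=1,
                                            n_insert=1)
        isis = np.diff(truth.spike_samples[0]) / 30000.0
        assert isis.min() >= 0.0019       # 2-ms floor up to sample rounding
        # near-unity modulation: exponential ISIs with ~500 ms mean
        assert 0.35 < isis.mean() < 0.75

    def test_inserted_waveform_recovered_at_offset(self, tmp_path,
                                                   probe16, rng):
        base = np.zeros((30 * 30000, 16), np.int16)
        base_path = tmp_path / "b0.bin"
        base.tofile(base_path)
        rec = RecordingHandle(base_path, "int16", 16, 30000.0)
        w = np.zeros((16, 61), np.float32)
        w[5] = -200 * np.exp(-0.5 * ((np.arange(61) - 30) / 3.0) ** 2)
        units = [{"times": np.array([1000, 40000]), "waveform": w,
                  "best_channel": 5, "contamination": 0.05}]
        out, truth = simulate.hybrid_insert(rec, probe16, units,
                                            tmp_path / "h0.bin", seed=2,
                                            n_insert=1)
        mm = np.asarray(out.memmap(), float)
        s = truth.spike_samples[0][0]
        patch = mm[s - 30:s + 31].T
        src = int(np.argmax(np.abs(patch).max(axis=1)))
        # eight sites up, or clipped at the probe edge going down
        assert src in (13, 0)
        assert np.abs(patch[src] - w[5]).max() < 1.0
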