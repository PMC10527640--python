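"""Wave detection: candidates, classification, splitting, frequency."""

import numpy as np
import pytest

from calscan import (
    LineScanImage,
    NoiseModel,
    TransientKinetics,
    ValidationError,
    WaveDetectionConfig,
    WaveModel,
    classify_events,
    detect_candidate_events,
    detect_waves,
    estimate_f0,
    normalize,
    simulate_paced_scan,
    wave_frequency,
)
from calscan.simulate import WaveTruth, _render_waves
from calscan.waves import WaveEvent


def _norm(image):
    return normalize(image, estimate_f0(image))


def _inject_wave(image, origin_um, origin_ms, amplitude=0.6, extent_um=150.0,
                 duration_ms=60.0, velocity_mm_s=2.0, f0=500.0):
    """Add one wave band directly into an image's pixels (noiseless)."""
    truth = WaveTruth(origin_um, origin_ms, extent_um, duration_ms, velocity_mm_s, amplitude)

    class _Geo:
        pixel_pitch_um = image.pixel_pitch_um
        line_period_ms = image.line_period_ms

        @staticmethod
        def positions_um():
            return image.positions_um()

    dff = np.zeros(image.pixels.shape)
    _render_waves(dff, [truth], _Geo)
    image.pixels = image.pixels + f0 * dff
    return truth


def _match(truth_xy, det_xy, xtol=60.0, ttol=40.0):
    used, tp = set(), 0
    for xu, tu in truth_xy:
        best, bd = None, np.inf
        for i, (xd, td) in enumerate(det_xy):
            if i in used:
                continue
            d = abs(xu - xd) / xtol + abs(tu - td) / ttol
            if d < bd:
                bd, best = d, i
        if best is not None and bd < 2:
            used.add(best)
            tp += 1
    return tp, len(truth_xy) - tp, len(det_xy) - tp  # tp, fn, fp


class TestCandidates:
    def test_all_zero_scan_has_no_candidates(self):
        img = LineScanImage(np.full((64, 500), 100.0), 2.0, 2.0)
        assert detect_candidate_events(_norm(img)) == []

    def test_single_noiseless_wave_is_one_candidate(self, kinetics, small_geometry):
        img, _ = simulate_paced_scan(
            kinetics, None, NoiseModel.none(), 0.0, 4.0, small_geometry, seed=0, sinus_hz=1.0
        )
        truth = _inject_wave(img, origin_um=250.0, origin_ms=2500.0)
        cands = detect_candidate_events(_norm(img))
        # one candidate per beat (4) plus exactly one for the wave
        wave_cands = [c for c in cands if c.width_fraction < 0.5]
        assert len(wave_cands) == 1
        cand = wave_cands[0]
        assert cand.extent_um == pytest.approx(truth.extent_um, abs=2 * img.pixel_pitch_um)
        assert cand.onset_ms == pytest.approx(truth.origin_ms, abs=3 * img.line_period_ms)

    def test_paced_transients_are_full_width_candidates(self, kinetics, small_geometry):
        img, _ = simulate_paced_scan(
            kinetics, WaveModel(rate_per_mm_s=0.0), NoiseModel.none(), 8.0, 2.0, small_geometry, seed=0
        )
        cands = detect_candidate_events(_norm(img))
        assert len(cands) == 16  # one per beat
        assert all(c.width_fraction > 0.95 for c in cands)


class TestClassification:
    def test_noiseless_wave_classified_with_true_kinematics(self, kinetics, small_geometry):
        img, _ = simulate_paced_scan(
            kinetics, None, NoiseModel.none(), 0.0, 4.0, small_geometry, seed=0, sinus_hz=1.0
        )
        _inject_wave(img, 250.0, 2500.0, velocity_mm_s=2.0)
        waves, paced = detect_waves(_norm(img))
        assert len(waves) == 1
        assert len(paced) == 4
        ev = waves[0]
        assert ev.origin_um == pytest.approx(250.0, abs=10.0)
        assert ev.origin_ms == pytest.approx(2500.0, abs=8.0)
        assert ev.velocity_mm_s == pytest.approx(2.0, rel=0.15)
        assert 0 < ev.velocity_mm_s < 5.0

    def test_wave_just_after_stimulus_caught_by_velocity_criterion(
        self, kinetics, small_geometry
    ):
        """A slow wave 5 ms after a beat is still a wave (criterion b)."""
        img, _ = simulate_paced_scan(
            kinetics, None, NoiseModel.none(), 8.0, 2.0, small_geometry, seed=0
        )
        stim = img.stimulus_times_ms
        _inject_wave(img, 250.0, float(stim[8]) + 5.0, velocity_mm_s=2.0)
        waves, _ = detect_waves(_norm(img))
        assert len(waves) == 1
        assert waves[0].synchrony_offset_ms <= 30.0  # synchronous, yet a wave
        assert waves[0].velocity_mm_s < 5.0

    def test_no_stimulus_list_warns_and_uses_velocity_only(self, kinetics, small_geometry):
        img, _ = simulate_paced_scan(
            kinetics, None, NoiseModel.none(), 8.0, 2.0, small_geometry, seed=0
        )
        _inject_wave(img, 250.0, 1062.0)
        img.stimulus_times_ms = np.empty(0)  # metadata lost
        norm = _norm(img)
        cands = detect_candidate_events(norm)
        with pytest.warns(UserWarning):
            waves, _ = classify_events(cands, None)
        assert len(waves) == 1


class TestTruthLogEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_noiseless_precision_recall_one(self, kinetics, wave_model, small_geometry, seed):
        img, log = simulate_paced_scan(
            kinetics, wave_model, NoiseModel.none(), 8.0, 6.0, small_geometry, seed=seed
        )
        waves, _ = detect_waves(_norm(img))
        tp, fn, fp = _match(
            [(w.origin_um, w.origin_ms) for w in log.waves],
            [(w.origin_um, w.origin_ms) for w in waves],
        )
        assert fn == 0 and fp == 0

    def test_specificity_under_noise(self, kinetics, shot_noise, small_geometry):
        """Zero injected waves with shot noise on: FP rate < 0.5/(mm s)."""
        freqs = []
        for seed in range(1, 13):
            img, _ = simulate_paced_scan(
                kinetics, WaveModel(rate_per_mm_s=0.0), shot_noise, 8.0, 5.0, small_geometry, seed=seed
            )
            waves, _ = detect_waves(_norm(img))
            freqs.append(wave_frequency(waves, img).frequency)
        assert np.mean(freqs) < 0.5

    def test_frequency_linearity_in_rate(self, kinetics, shot_noise, small_geometry):
        """Doubling the injected rate doubles the detected frequency."""
        means = []
        for rate in (4.0, 8.0):
            freqs = []
            for seed in range(1, 25):
                img, _ = simulate_paced_scan(
                    kinetics,
                    WaveModel(rate_per_mm_s=rate),
                    shot_noise,
                    8.0,
                    5.0,
                    small_geometry,
                    seed=seed,
                )
                waves, _ = detect_waves(_norm(img))
                freqs.append(wave_frequency(waves, img).frequency)
            means.append((np.mean(freqs), np.std(freqs) / np.sqrt(len(freqs))))
        (m1, s1), (m2, s2) = means
        assert m2 == pytest.approx(2 * m1, abs=2 * np.hypot(2 * s1, s2))


class TestInvariances:
    def test_monotone_threshold(self, kinetics, small_geometry):
        """Raising the detection threshold never increases the wave count."""
        img, _ = simulate_paced_scan(
            kinetics, WaveModel(rate_per_mm_s=8.0), NoiseModel.none(), 8.0, 6.0, small_geometry, seed=5
        )
        norm = _norm(img)
        counts = []
        for k in (2.0, 3.5, 5.0, 8.0):
            waves, _ = detect_waves(norm, WaveDetectionConfig(k_sd=k))
            counts.append(len(waves))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_intensity_scale_invariance(self, kinetics, wave_model, shot_noise, small_geometry):
        img, _ = simulate_paced_scan(
            kinetics, wave_model, shot_noise, 8.0, 5.0, small_geometry, seed=2
        )
        waves_a, _ = detect_waves(_norm(img))
        waves_b, _ = detect_waves(_norm(img.scaled(3.0)))
        assert len(waves_a) == len(waves_b)
        for a, b in zip(waves_a, waves_b):
            assert a.origin_ms == pytest.approx(b.origin_ms, abs=2.0)

    def test_pitch_invariance_at_fixed_physical_length(self, kinetics):
        """Same physical waves, coarser pixels: the count is unchanged."""
        from calscan.simulate import ScanGeometry

        fine = ScanGeometry(n_space=500, pixel_pitch_um=2.0, line_period_ms=2.0)
        coarse = ScanGeometry(n_space=250, pixel_pitch_um=4.0, line_period_ms=2.0)
        truths = [
            WaveTruth(200.0, 1300.0, 150.0, 60.0, 2.0, 0.6),
            WaveTruth(700.0, 2400.0, 150.0, 60.0, 2.0, 0.6),
            WaveTruth(450.0, 3600.0, 150.0, 60.0, 2.0, 0.6),
        ]
        counts = []
        for geo in (fine, coarse):
            img, _ = simulate_paced_scan(
                kinetics, None, NoiseModel.none(), 8.0, 5.0, geo, seed=0
            )
            for w in truths:
                _inject_wave(
                    img, w.origin_um, w.origin_ms, extent_um=w.extent_um,
                    duration_ms=w.duration_ms, velocity_mm_s=w.velocity_mm_s,
                )
            waves, _ = detect_waves(_norm(img))
            counts.append(len(waves))
            assert img.scan_length_mm == pytest.approx(1.0)
        assert counts[0] == counts[1] == 3


class TestSplitting:
    def test_two_colliding_waves_counted_separately(self, kinetics, small_geometry):
        img, _ = simulate_paced_scan(
            kinetics, None, NoiseModel.none(), 0.0, 4.0, small_geometry, seed=0, sinus_hz=1.0
        )
        # same onset time, 100 um apart: fronts collide and merge
        _inject_wave(img, 180.0, 2000.0)
        _inject_wave(img, 300.0, 2000.0)
        waves, _ = detect_waves(_norm(img))
        assert len(waves) == 2

    def test_occluded_origin_recovered(self, kinetics, small_geometry):
        """A wave firing on the front of an earlier wave is still counted."""
        img, _ = simulate_paced_scan(
            kinetics, None, NoiseModel.none(), 0.0, 4.0, small_geometry, seed=0, sinus_hz=1.0
        )
        _inject_wave(img, 200.0, 2000.0)
        # origin lies on the first wave's right-going front (100 um / 2 mm/s later)
        _inject_wave(img, 300.0, 2050.0)
        waves, _ = detect_waves(_norm(img))
        assert len(waves) == 2


class TestFrequency:
    def _scan(self):
        return LineScanImage(np.full((500, 1000), 100.0), 2.0, 2.0)

    def _event(self, t_ms):
        return WaveEvent(100.0, t_ms, 150.0, 60.0, 2.0, 0.6, np.inf)

    def test_three_waves_one_mm_two_seconds(self):
        scan = self._scan()  # 1 mm x 2 s
        waves = [self._event(t) for t in (100.0, 900.0, 1500.0)]
        res = wave_frequency(waves, scan, (0.0, 2000.0))
        assert res.frequency == pytest.approx(1.5)
        assert res.n_waves == 3

    def test_zero_waves_zero_frequency(self):
        res = wave_frequency([], self._scan(), (0.0, 2000.0))
        assert res.frequency == 0.0

    def test_half_open_window_counts_onsets_only(self):
        waves = [self._event(0.0), self._event(1999.9), self._event(2000.0)]
        res = wave_frequency(waves, self._scan(), (0.0, 2000.0))
        assert res.n_waves == 2

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValidationError):
            wave_frequency([], self._scan(), (500.0, 500.0))
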