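import numpy as np
import pytest

from nddsleep.edf_io import Recording
from nddsleep.preprocess import ArtifactMask
from nddsleep.spindle import SpindleEvent, ValidEpochSet, \
    build_valid_epochs, detect_spindles, sigma_relative_power, \
    spindle_density
from nddsleep.synthetic import Hypnogram, generate_recording, nt_profile

from oracles import brute_force_spindles, recall_precision

FS = 200.0


@pytest.fixture()
def loose_params(params):
    # whole short test signals count as one valid run
    return params.replace(min_valid_epoch_s=60.0)


def _two_channel(x, make_background, n=None, seed=1):
    n = n if n is not None else x.size
    other = make_background(n, seed=seed)
    return Recording(np.vstack([x, other]), ["C3", "C4"], FS)


class TestSigmaRelativePower:
    def test_pure_sigma_tone_saturates(self, params):
        t = np.arange(int(30 * FS)) / FS
        _, rp = sigma_relative_power(np.sin(2 * np.pi * 13 * t), FS, params)
        assert np.all(rp >= 0.95)

    def test_theta_tone_excluded(self, params):
        t = np.arange(int(30 * FS)) / FS
        _, rp = sigma_relative_power(np.sin(2 * np.pi * 5 * t), FS, params)
        assert np.all(rp <= 0.05)

    def test_white_noise_matches_flat_spectrum_fraction(self, params, rng):
        x = rng.standard_normal(int(120 * FS))
        _, rp = sigma_relative_power(x, FS, params)
        assert abs(rp.mean() - (16 - 11) / (30 - 1)) < 0.05

    def test_window_grid(self, params):
        starts, rp = sigma_relative_power(np.zeros(int(10 * FS)), FS, params)
        assert starts[0] == 0.0
        assert np.allclose(np.diff(starts), params.spindle_win_shift_s)

    def test_short_signal_and_low_fs_rejected(self, params):
        with pytest.raises(ValueError, match="short"):
            sigma_relative_power(np.zeros(100), FS, params)
        with pytest.raises(ValueError, match="fs"):
            sigma_relative_power(np.zeros(1000), 50.0, params)


class TestDetection:
    def test_single_burst_detected_once_with_overlap(self, loose_params,
                                                     make_background,
                                                     make_burst):
        x = make_background(int(60 * FS), seed=0)
        w = make_burst(FS, 1.0, amp=45.0)
        x[int(30 * FS):int(30 * FS) + w.size] += w
        rec = _two_channel(x, make_background)
        ev = detect_spindles(rec, None, ValidEpochSet([(0.0, 60.0)]),
                             loose_params)
        assert len(ev) == 1
        lo = max(ev[0].start_s, 30.0)
        hi = min(ev[0].end_s, 31.0)
        assert hi - lo >= 0.5  # >= 50% of the 1-s truth covered

    def test_three_second_burst_eliminated(self, loose_params,
                                           make_background):
        # continuous (unmodulated) 3-s sigma oscillation: too long
        x = make_background(int(60 * FS), seed=0)
        t = np.arange(int(3.0 * FS)) / FS
        x[int(30 * FS):int(33 * FS)] += 45.0 * np.sin(2 * np.pi * 13 * t)
        rec = _two_channel(x, make_background)
        ev = detect_spindles(rec, None, ValidEpochSet([(0.0, 60.0)]),
                             loose_params)
        assert ev == []

    def test_close_bursts_become_one_event(self, loose_params,
                                           make_background, make_burst):
        # two 0.6-s bursts 0.45 s apart: closer than the 0.5-s merge gap,
        # detected as a single event within the duration limits
        x = make_background(int(60 * FS), seed=0)
        for t0 in (30.0, 31.05):
            w = make_burst(FS, 0.6, amp=30.0)
            x[int(t0 * FS):int(t0 * FS) + w.size] += w
        rec = _two_channel(x, make_background)
        ev = detect_spindles(rec, None, ValidEpochSet([(0.0, 60.0)]),
                             loose_params)
        assert len(ev) == 1
        assert ev[0].start_s <= 30.2 and ev[0].end_s >= 31.4
        assert 0.5 <= ev[0].duration_s <= 2.0

    def test_distant_bursts_stay_separate(self, loose_params,
                                          make_background, make_burst):
        x = make_background(int(60 * FS), seed=0)
        for t0 in (20.0, 40.0):
            w = make_burst(FS, 1.0, amp=45.0)
            x[int(t0 * FS):int(t0 * FS) + w.size] += w
        rec = _two_channel(x, make_background)
        ev = detect_spindles(rec, None, ValidEpochSet([(0.0, 60.0)]),
                             loose_params)
        assert len(ev) == 2

    def test_cross_channel_consolidation(self, loose_params,
                                         make_background, make_burst):
        x1 = make_background(int(60 * FS), seed=0)
        x2 = make_background(int(60 * FS), seed=1)
        w = make_burst(FS, 1.0, amp=45.0)
        x1[int(30.0 * FS):int(30.0 * FS) + w.size] += w
        x2[int(30.1 * FS):int(30.1 * FS) + w.size] += w
        rec = Recording(np.vstack([x1, x2]), ["C3", "C4"], FS)
        ev = detect_spindles(rec, None, ValidEpochSet([(0.0, 60.0)]),
                             loose_params)
        assert len(ev) == 1

    def test_event_outside_valid_epochs_dropped(self, loose_params,
                                                make_background,
                                                make_burst):
        x = make_background(int(180 * FS), seed=0)
        w = make_burst(FS, 1.0, amp=45.0)
        x[int(30 * FS):int(30 * FS) + w.size] += w      # inside valid
        x[int(150 * FS):int(150 * FS) + w.size] += w    # outside valid
        rec = _two_channel(x, make_background, n=int(180 * FS))
        ev = detect_spindles(rec, None, ValidEpochSet([(0.0, 120.0)]),
                             loose_params)
        assert len(ev) == 1 and ev[0].start_s < 120.0

    def test_masked_event_dropped(self, loose_params, make_background,
                                  make_burst):
        x = make_background(int(60 * FS), seed=0)
        w = make_burst(FS, 1.0, amp=45.0)
        x[int(30 * FS):int(30 * FS) + w.size] += w
        rec = _two_channel(x, make_background)
        m = ArtifactMask(np.zeros(rec.n_samples, dtype=bool),
                         [(29.0, 32.0)], FS)
        m.sample_mask[int(29 * FS):int(32 * FS)] = True
        ev = detect_spindles(rec, m, ValidEpochSet([(0.0, 60.0)]),
                             loose_params)
        assert ev == []

    def test_empty_valid_set_warns_and_returns_empty(self, loose_params,
                                                     make_background):
        rec = _two_channel(make_background(int(60 * FS)), make_background)
        with pytest.warns(UserWarning, match="valid"):
            assert detect_spindles(rec, None, ValidEpochSet([]),
                                   loose_params) == []


class TestOracleEquivalence:
    def _random_signal(self, seed, make_background, make_burst):
        g = np.random.default_rng(seed)
        x = make_background(int(60 * FS), seed=seed + 1000)
        for _ in range(g.integers(0, 6)):
            dur = g.uniform(0.3, 2.5)
            amp = g.uniform(15.0, 60.0)
            t0 = g.uniform(1.0, 58.0 - dur)
            w = make_burst(FS, dur, freq=g.uniform(11, 16), amp=amp,
                           phase=g.uniform(0, 2 * np.pi))
            x[int(t0 * FS):int(t0 * FS) + w.size] += w
        return x

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_signals(self, seed, loose_params,
                                                   make_background,
                                                   make_burst):
        x = self._random_signal(seed, make_background, make_burst)
        y = self._random_signal(seed + 500, make_background, make_burst)
        sig = np.vstack([x, y])
        rec = Recording(sig, ["C3", "C4"], FS)
        valid = ValidEpochSet([(0.0, 60.0)])
        got = detect_spindles(rec, None, valid, loose_params)
        want = brute_force_spindles(sig, ["C3", "C4"], FS, valid.intervals,
                                    loose_params)
        assert len(got) == len(want)
        for ev, (lab, s, e, p) in zip(got, want):
            assert ev.channel == lab
            assert abs(ev.start_s - s) < 1e-9
            assert abs(ev.end_s - e) < 1e-9
            assert abs(ev.peak_relpow - p) < 1e-9


@pytest.fixture(scope="module")
def n2_recording():
    prof = nt_profile(spindle_density_per_min=3.0, artifact_rates={},
                      sws_fraction=0.0, line_amp_uv=0.0)
    hyp = Hypnogram(["N2"] * 40)  # 20 min
    labels = ["F3", "F4", "Fz", "C3", "C4", "Cz", "O1", "O2"]
    rec, truth = generate_recording(hyp, labels, prof, FS, 7)
    return rec, truth, hyp


class TestRecoveryAndDensity:

    def test_recall_and_precision(self, params, n2_recording):
        rec, truth, hyp = n2_recording
        assert len(truth.spindles) >= 30
        mask = ArtifactMask.empty(rec.n_samples, rec.fs)
        valid = build_valid_epochs(mask, hyp, params)
        ev = detect_spindles(rec, mask, valid, params)
        rec_, prec = recall_precision(
            [(s, e) for _, s, e in truth.spindles],
            [(e.start_s, e.end_s) for e in ev])
        assert rec_ >= 0.8
        assert prec >= 0.8

    def test_recall_non_decreasing_in_amplitude(self, params):
        hyp = Hypnogram(["N2"] * 20)
        labels = ["F3", "F4", "C3", "C4", "Cz"]
        recalls = []
        for amp in (30.0, 45.0, 60.0):
            prof = nt_profile(spindle_density_per_min=3.0,
                              artifact_rates={}, sws_fraction=0.0,
                              line_amp_uv=0.0, spindle_amp_uv=amp)
            rec, truth = generate_recording(hyp, labels, prof, FS, 13)
            mask = ArtifactMask.empty(rec.n_samples, rec.fs)
            valid = build_valid_epochs(mask, hyp, params)
            ev = detect_spindles(rec, mask, valid, params)
            r, _ = recall_precision([(s, e) for _, s, e in truth.spindles],
                                    [(e.start_s, e.end_s) for e in ev])
            recalls.append(r)
        assert recalls == sorted(recalls)

    def test_detected_density_monotone_in_generated_density(self, params):
        hyp = Hypnogram(["N2"] * 24)  # 12 min
        labels = ["F3", "F4", "C3", "C4", "Cz"]
        densities = []
        for rate in (0.0, 2.0, 5.0):
            prof = nt_profile(spindle_density_per_min=rate,
                              artifact_rates={}, sws_fraction=0.0,
                              line_amp_uv=0.0)
            rec, _ = generate_recording(hyp, labels, prof, FS, 29)
            mask = ArtifactMask.empty(rec.n_samples, rec.fs)
            valid = build_valid_epochs(mask, hyp, params)
            d, _ = spindle_density(detect_spindles(rec, mask, valid,
                                                   params), valid)
            densities.append(d)
        assert densities[0] < densities[1] < densities[2]

    def test_detector_output_invariants(self, params, n2_recording):
        rec, _, hyp = n2_recording
        mask = ArtifactMask.empty(rec.n_samples, rec.fs)
        valid = build_valid_epochs(mask, hyp, params)
        ev = detect_spindles(rec, mask, valid, params)
        for e in ev:
            assert params.spindle_min_dur_s <= e.duration_s \
                <= params.spindle_max_dur_s
            assert e.peak_relpow >= params.spindle_relpow_thresh
        starts = [e.start_s for e in ev]
        assert all(b - a >= params.spindle_consolidate_s
                   for a, b in zip(starts[:-1], starts[1:]))


class TestDensityArithmetic:
    def _events(self, times):
        return [SpindleEvent("C3", t, t + 1.0, 0.5) for t in times]

    def test_twelve_events_in_six_minutes(self):
        valid = ValidEpochSet([(0.0, 360.0)])
        d, rows = spindle_density(self._events(np.linspace(1, 350, 12)),
                                  valid)
        assert d == pytest.approx(2.0)
        assert rows[0]["n_spindles"] == 12

    def test_unweighted_mean_over_runs_not_pooled(self):
        valid = ValidEpochSet([(0.0, 120.0), (200.0, 440.0)])
        events = self._events([10.0]) + \
            self._events(np.linspace(201, 430, 8))
        d, _ = spindle_density(events, valid)
        assert d == pytest.approx((0.5 + 2.0) / 2)  # 1.25, not 9/6

    def test_zero_events_zero_density(self):
        d, _ = spindle_density([], ValidEpochSet([(0.0, 300.0)]))
        assert d == 0.0

    def test_empty_valid_set_is_missing(self):
        with pytest.warns(UserWarning):
            d, rows = spindle_density(self._events([1.0]), ValidEpochSet([]))
        assert d is None and rows == []


class TestValidEpochs:
    def test_runs_split_at_mask_and_wake(self, params):
        fs = 200.0
        n = int(600 * fs)
        mask = ArtifactMask(np.zeros(n, dtype=bool), [], fs)
        mask.sample_mask[int(300 * fs):int(302 * fs)] = True
        hyp = Hypnogram(["W"] * 2 + ["N2"] * 18)  # sleep from 60 s on
        valid = build_valid_epochs(mask, hyp, params)
        assert valid.intervals == [(60.0, 300.0), (302.0, 600.0)]

    def test_short_runs_dropped(self, params):
        fs = 200.0
        n = int(300 * fs)
        mask = ArtifactMask(np.zeros(n, dtype=bool), [], fs)
        mask.sample_mask[int(100 * fs):int(200 * fs)] = True
        valid = build_valid_epochs(mask, None, params)
        # 0-100 s run is below the 2-min floor; 200-300 s run is too
        assert valid.intervals == []

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ValidEpochSet([(0.0, 130.0), (120.0, 260.0)])


def test_event_export_roundtrip(tmp_path):
    from nddsleep.spindle import write_events_json, write_events_tsv
    import json

    events = [SpindleEvent("C3", 1.25, 2.0, 0.41),
              SpindleEvent("Cz", 5.0, 6.2, 0.33)]
    write_events_tsv(events, tmp_path / "ev.tsv")
    lines = (tmp_path / "ev.tsv").read_text().splitlines()
    assert lines[0].split("\t") == ["channel", "start_s", "end_s",
                                    "peak_relpow"]
    assert lines[1].startswith("C3\t1.250\t2.000")
    write_events_json(events, tmp_path / "ev.json")
    back = json.loads((tmp_path / "ev.json").read_text())
    assert back[1]["channel"] == "Cz" and back[1]["end_s"] == 6.2
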