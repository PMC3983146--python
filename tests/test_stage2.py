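"""Stage-2 spectral parameterization, validation criteria, classification."""

import numpy as np
import pytest
from scipy.signal.windows import tukey

from conftest import FS, background, plant_burst, stage1_features
from hfodetect.stage1 import EoI, detect_eois
from hfodetect.stage2 import (
    HfoClass,
    HfoEvent,
    RejectReason,
    SpectralTriplet,
    Stage2Params,
    classify_event,
    detect_hfos,
    parameterize_psd,
    validate_eoi,
)
from hfodetect.stockwell import stockwell_transform
from hfodetect.synth import SynthSpec, EventRates, ies_transient, synthesize_recording


def gaussian_bump(f, center, width, height):
    return height * np.exp(-0.5 * ((f - center) / width) ** 2)


class TestParameterizePsd:
    def test_published_example_triplet(self):
        # spectrum built with local maxima at 47 and 116 Hz and an
        # intervening minimum at 73 Hz, the worked example morphology
        f = np.arange(1001, dtype=float)
        psd = (
            gaussian_bump(f, 47, 12.0, 1.0)
            + gaussian_bump(f, 116, 18.0, 1.2)
            + 1e-4
        )
        tr, status = parameterize_psd(psd)
        assert status is RejectReason.NONE
        # the summed bumps shift the extrema by at most a bin or two
        assert abs(tr.hifp_hz - 116) <= 2
        assert abs(tr.trough_hz - 73) <= 4
        assert abs(tr.lofp_hz - 47) <= 2

    def test_exact_constructed_extrema(self):
        # piecewise-linear spectrum with exact extrema at 47 / 73 / 116 Hz
        f = np.arange(1001, dtype=float)
        psd = np.interp(
            f, [0, 47, 73, 116, 1000], [0.5, 1.0, 0.2, 1.3, 1e-3]
        )
        tr, status = parameterize_psd(psd)
        assert status is RejectReason.NONE
        assert (tr.hifp_hz, tr.trough_hz, tr.lofp_hz) == (116.0, 73.0, 47.0)

    def test_monotone_spectrum_has_no_trough(self):
        f = np.arange(1001, dtype=float)
        psd = 1.0 / (1.0 + f)
        tr, status = parameterize_psd(psd)
        assert status is RejectReason.NO_TROUGH
        assert tr.hifp_hz == 60.0
        assert tr.trough_hz == tr.hifp_hz

    def test_two_tone_window(self):
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 30 * t) + np.sin(2 * np.pi * 82 * t)
        tf = stockwell_transform(x, FS)
        tr, status = parameterize_psd(tf.power[:, int(FS) // 2])
        assert status is RejectReason.NONE
        assert abs(tr.hifp_hz - 82) <= 1
        assert 40 <= tr.trough_hz <= 62
        assert abs(tr.lofp_hz - 30) <= 1

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            parameterize_psd(np.zeros(1001))

    def test_no_lofp_when_rising_into_trough(self):
        # monotone increase below the trough: no local maximum exists
        f = np.arange(1001, dtype=float)
        psd = np.interp(f, [0, 73, 116, 1000], [2.0, 0.2, 1.3, 1e-3])
        tr, status = parameterize_psd(psd)
        assert status is RejectReason.NO_LOFP


def _accepted_event(hifp):
    tr = SpectralTriplet(hifp, 1.0, hifp - 40, 0.3, hifp - 60, 0.5)
    eoi = EoI(0, 100, 200, 150, 30.0, 50.0)
    return HfoEvent(eoi, True, RejectReason.NONE, tr, None, 50.0, 30.0)


class TestClassify:
    @pytest.mark.parametrize(
        "hifp,expected",
        [
            (116.0, HfoClass.RIPPLE),
            (292.0, HfoClass.FAST_RIPPLE),
            (200.0, HfoClass.FAST_RIPPLE),  # bin-edge convention
            (65.0, HfoClass.RIPPLE),  # sub-80 events stay in the ripple bin
        ],
    )
    def test_split_at_200(self, hifp, expected):
        assert classify_event(_accepted_event(hifp)) is expected

    def test_unaccepted_event_errors(self):
        ev = _accepted_event(150.0)
        ev.accepted = False
        with pytest.raises(ValueError, match="accepted"):
            classify_event(ev)


class TestValidateEoi:
    def test_planted_burst_accepted_with_correct_peak(self, sos, rng):
        x = background(20.0, rng)
        plant_burst(x, sos, 120.0, 10, 8.0, center=int(10 * FS))
        xf, env, thr = stage1_features(x, sos)
        eois = detect_eois(xf, env, FS)
        near = [e for e in eois if abs(e.peak_sample - int(10 * FS)) < 200]
        assert len(near) == 1
        ev = validate_eoi(x, env, near[0], thr, FS)
        assert ev.accepted
        assert abs(ev.characteristic.hifp_hz - 120) <= 5
        assert ev.hfo_class is HfoClass.RIPPLE

    def test_spike_rejected_for_missing_trough(self, sos, rng):
        # the "false ripple": a sharp spike passing Stage 1 shows a smooth
        # transition between low and high frequencies, with no trough
        found = False
        for attempt in range(20):
            x = background(10.0, rng)
            spike = ies_transient(40.0, FS) * 12 * 20.0
            c = int(5 * FS)
            x[c : c + len(spike)] += spike
            xf, env, thr = stage1_features(x, sos)
            eois = [e for e in detect_eois(xf, env, FS)
                    if abs(e.peak_sample - c) < 300]
            if not eois:
                continue
            found = True
            ev = validate_eoi(x, env, eois[0], thr, FS)
            assert not ev.accepted
            assert ev.reject_reason is RejectReason.NO_TROUGH
            break
        assert found, "no spike passed Stage 1 in 20 attempts"

    def test_impulse_rejected_above_500(self, sos, rng):
        found = False
        for attempt in range(20):
            x = background(10.0, rng)
            c = int(5 * FS)
            x[c : c + 3] += 60 * 20.0  # 3-sample pop, far above background
            xf, env, thr = stage1_features(x, sos)
            eois = [e for e in detect_eois(xf, env, FS)
                    if abs(e.peak_sample - c) < 300]
            if not eois:
                continue
            found = True
            ev = validate_eoi(x, env, eois[0], thr, FS)
            assert not ev.accepted
            assert ev.reject_reason is RejectReason.PEAK_ABOVE_500
            break
        assert found, "no impulse passed Stage 1 in 20 attempts"

    def test_sub80_harmonic_event_accepted_as_ripple(self, sos, rng):
        # an oscillation peaking below 80 Hz whose harmonics carry it
        # through the Stage-1 band-pass is accepted with its true peak
        x = background(20.0, rng)
        from hfodetect.stage1 import zero_phase_filter

        band_rms = zero_phase_filter(x, sos).std()
        f0 = 70.0
        n = int(8 / f0 * FS)
        t = np.arange(n) / FS
        osc = (
            np.sin(2 * np.pi * f0 * t)
            + 0.45 * np.sin(2 * np.pi * 2 * f0 * t)
            + 0.2 * np.sin(2 * np.pi * 3 * f0 * t)
        ) * tukey(n, 0.25)
        c = int(10 * FS)
        x[c - n // 2 : c - n // 2 + n] += osc * 10 * band_rms
        xf, env, thr = stage1_features(x, sos)
        eois = [e for e in detect_eois(xf, env, FS)
                if abs(e.peak_sample - c) < 300]
        assert eois, "harmonic-rich sub-80 Hz event must pass Stage 1"
        ev = validate_eoi(x, env, eois[0], thr, FS)
        assert ev.accepted
        assert 60 <= ev.characteristic.hifp_hz < 85
        assert ev.hfo_class is HfoClass.RIPPLE

    def test_window_at_epoch_edge_is_padded_and_flagged(self, sos, rng):
        x = background(20.0, rng)
        plant_burst(x, sos, 150.0, 10, 8.0, center=600)  # 0.3 s from edge
        xf, env, thr = stage1_features(x, sos)
        eois = [e for e in detect_eois(xf, env, FS) if e.peak_sample < 1200]
        assert eois
        ev = validate_eoi(x, env, eois[0], thr, FS)
        assert ev.window_padded


class TestDetectHfos:
    def test_all_zero_recording_yields_no_events(self):
        from hfodetect.io import Montage, Recording

        rec = Recording(np.zeros((3, int(60 * FS))), FS, ["A", "B", "C"],
                        Montage.BIPOLAR)
        res = detect_hfos(rec)
        assert all(v == [] for v in res.values())

    def test_too_short_recording_refused(self):
        from hfodetect.io import Montage, Recording

        rec = Recording(np.zeros((1, int(10 * FS))), FS, ["A"],
                        Montage.BIPOLAR)
        with pytest.raises(ValueError, match="too short"):
            detect_hfos(rec)

    def test_deterministic(self):
        spec = SynthSpec(duration_s=60, n_channels=2,
                         rates=EventRates(hfo=6), seed=5)
        rec, _ = synthesize_recording(spec)
        r1 = detect_hfos(rec)
        r2 = detect_hfos(rec)
        for ch in rec.labels:
            a = [(e.eoi.start_sample, e.accepted, e.reject_reason) for e in r1[ch]]
            b = [(e.eoi.start_sample, e.accepted, e.reject_reason) for e in r2[ch]]
            assert a == b

    def test_acceptance_invariant_to_amplitude_scaling(self):
        from hfodetect.io import Recording

        spec = SynthSpec(duration_s=60, n_channels=1,
                         rates=EventRates(hfo=6), seed=8)
        rec, _ = synthesize_recording(spec)
        res1 = detect_hfos(rec)
        scaled = Recording(rec.samples * 37.0, rec.fs, rec.labels, rec.montage)
        res2 = detect_hfos(scaled)
        for ch in rec.labels:
            a = [(e.eoi.start_sample, e.accepted) for e in res1[ch]]
            b = [(e.eoi.start_sample, e.accepted) for e in res2[ch]]
            assert a == b

    def test_accepted_triplets_satisfy_ratio_criteria(self):
        p = Stage2Params()
        spec = SynthSpec(duration_s=120, n_channels=2,
                         rates=EventRates(hfo=8), seed=9)
        rec, _ = synthesize_recording(spec)
        res = detect_hfos(rec)
        n_acc = 0
        for ch in rec.labels:
            for e in res[ch]:
                if e.accepted:
                    n_acc += 1
                    tr = e.characteristic
                    assert tr.trough_power / tr.hifp_power < p.trough_ratio_max
                    assert tr.hifp_power / tr.lofp_power > p.r_thr
        assert n_acc > 0

    def test_planted_count_recovery(self):
        spec = SynthSpec(duration_s=120, n_channels=2,
                         rates=EventRates(hfo=8),
                         seed=10)
        rec, truth = synthesize_recording(spec)
        res = detect_hfos(rec)
        for ch in rec.labels:
            planted = (truth.channel == ch).sum()
            detected = sum(1 for e in res[ch] if e.accepted)
            assert detected >= 0.6 * planted
            assert detected <= 1.3 * planted + 1
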