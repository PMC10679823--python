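"""Preprocessing contracts: bipolar derivation, trial selection rules, line
removal, detrending, normalization, epoch windows."""

import numpy as np
import pandas as pd
import pytest

from phasebehav.synthgen import SessionRecording, SimConfig, simulate_session
from phasebehav.preprocess import (EmptySelectionError, bipolar_derive,
                                   clean_and_select_trials, condition_signal,
                                   extract_epochs)


def _manual_session(signal, lanes=None, **kw):
    n_ch, _, n_tr = signal.shape
    meta = pd.DataFrame({
        "area": ["A"] * n_ch, "cluster": ["none"] * n_ch,
        "lane": lanes if lanes is not None else [0] * n_ch,
        "electrode": kw.pop("electrode", list(range(n_ch))),
    })
    defaults = dict(
        sample_rate=1000.0, rt=np.full(n_tr, 300.0),
        condition=np.array(["IN"] * n_tr),
        cue_time=np.full(n_tr, 100.0), change_time=np.full(n_tr, 1000.0),
        target_first=np.ones(n_tr, bool), correct=np.ones(n_tr, bool),
        channel_meta=meta, derivation="unipolar",
    )
    defaults.update(kw)
    return SessionRecording(signal=signal, **defaults)


class TestBipolarDerive:
    def test_common_signal_cancels_exactly(self, rng):
        t = np.arange(1200)
        c = rng.standard_normal(1200)              # shared reference
        x = np.sin(2 * np.pi * 0.01 * t)
        y = np.cos(2 * np.pi * 0.013 * t)
        sig = np.stack([x + c, y + c])[:, :, None]
        out = bipolar_derive(_manual_session(sig))
        np.testing.assert_allclose(out.signal[0, :, 0], y - x, atol=1e-12)
        assert out.derivation == "bipolar"

    def test_lane_of_three_gives_two_sites(self, rng):
        sig = rng.standard_normal((3, 500, 2))
        out = bipolar_derive(_manual_session(sig))
        assert out.n_channels == 2
        np.testing.assert_allclose(out.signal[0], sig[1] - sig[0])
        np.testing.assert_allclose(out.signal[1], sig[2] - sig[1])

    def test_short_lanes_contribute_no_sites(self, rng):
        sig = rng.standard_normal((3, 100, 2))
        out = bipolar_derive(_manual_session(sig, lanes=[0, 0, 1],
                                             electrode=[0, 1, 0]))
        assert out.n_channels == 1               # singleton lane dropped

    def test_all_singleton_lanes_error(self, rng):
        sig = rng.standard_normal((2, 100, 2))
        with pytest.raises(ValueError, match="bipolar"):
            bipolar_derive(_manual_session(sig, lanes=[0, 1],
                                           electrode=[0, 0]))

    def test_derivation_is_linear(self, rng):
        a = rng.standard_normal((3, 200, 2))
        b = rng.standard_normal((3, 200, 2))
        out_sum = bipolar_derive(_manual_session(a + b)).signal
        parts = bipolar_derive(_manual_session(a)).signal + \
            bipolar_derive(_manual_session(b)).signal
        np.testing.assert_allclose(out_sum, parts, atol=1e-12)


class TestTrialSelection:
    def _session_with_defects(self, rng):
        n_tr = 20
        sig = rng.standard_normal((2, 1000, n_tr))
        sig[:, :, 3] *= np.sqrt(10.0)            # variance ~8x the mean
        rec = _manual_session(sig)
        rec.change_time = np.full(n_tr, 1000.0)
        rec.change_time[5] = 800.0               # 700 ms after the 100 ms cue
        rec.target_first[7] = False
        rec.correct[9] = False
        return rec

    def test_each_rule_rejects_with_its_reason(self, rng):
        mask = clean_and_select_trials(self._session_with_defects(rng))
        assert not mask.keep[3] and mask.reason[3] == "artifact-variance"
        assert not mask.keep[5] and mask.reason[5] == "change-before-800ms"
        assert not mask.keep[7] and mask.reason[7] == "distractor-first"
        assert not mask.keep[9] and mask.reason[9] == "error-trial"
        assert mask.n_kept == 16

    def test_mask_is_conjunction_of_rules(self, rng):
        """Order independence: the kept set equals the intersection of the
        four individual rule masks."""
        rec = self._session_with_defects(rng)
        mask = clean_and_select_trials(rec)
        var = rec.signal.var(axis=1)
        ok_var = ~(var > 5.0 * var.mean(axis=1, keepdims=True)).any(axis=0)
        expected = (ok_var & rec.target_first & rec.correct
                    & ((rec.change_time - rec.cue_time) >= 800.0))
        np.testing.assert_array_equal(mask.keep, expected)

    def test_boundary_change_at_exactly_800ms_kept(self, rng):
        rec = _manual_session(rng.standard_normal((2, 1000, 4)))
        rec.change_time[:] = 900.0               # exactly 800 ms post cue
        assert clean_and_select_trials(rec).n_kept == 4

    def test_empty_selection_raises(self, rng):
        rec = _manual_session(rng.standard_normal((2, 1000, 4)))
        rec.correct[:] = False
        with pytest.raises(EmptySelectionError):
            clean_and_select_trials(rec)

    def test_injected_artifacts_rejected_in_synthetic_session(self):
        rec, gt = simulate_session(SimConfig(n_trials_per_condition=40, seed=2))
        mask = clean_and_select_trials(bipolar_derive(rec))
        assert not mask.keep[gt.artifact].any()


class TestConditionSignal:
    def test_pure_line_noise_removed_to_numerical_zero(self):
        t = np.arange(1000) / 1000.0
        sig = np.cos(2 * np.pi * 50.0 * t + 0.7)[None, :, None] * 3.0
        out = condition_signal(_manual_session(sig), steps=("line",))
        spec_in = np.abs(np.fft.rfft(sig[0, :, 0]))[50] ** 2
        spec_out = np.abs(np.fft.rfft(out.signal[0, :, 0]))[50] ** 2
        assert spec_out < 1e-6 * spec_in

    def test_other_frequencies_untouched(self, rng):
        t = np.arange(1000) / 1000.0
        sig = (np.sin(2 * np.pi * 30.0 * t)
               + 0.5 * np.cos(2 * np.pi * 50.0 * t))[None, :, None]
        out = condition_signal(_manual_session(sig), steps=("line",))
        c_in = np.fft.rfft(sig[0, :, 0])[30]
        c_out = np.fft.rfft(out.signal[0, :, 0])[30]
        # integer cycle counts make the regressors exactly orthogonal
        np.testing.assert_allclose(c_out, c_in, atol=1e-9)

    def test_linear_ramp_detrended(self):
        sig = np.linspace(0.0, 5.0, 800)[None, :, None] + 2.0
        out = condition_signal(_manual_session(sig), steps=("detrend",))
        slope = np.polyfit(np.arange(800), out.signal[0, :, 0], 1)[0]
        assert abs(slope) < 1e-12
        assert abs(out.signal[0, :, 0].mean()) < 1e-12

    def test_normalization_uses_retained_trials_only(self, rng):
        sig = rng.standard_normal((2, 500, 10))
        sig[:, :, 0] += 100.0                    # rejected outlier trial
        keep = np.ones(10, bool)
        keep[0] = False
        out = condition_signal(_manual_session(sig), keep=keep,
                               steps=("normalize",))
        used = out.signal[:, :, keep]
        np.testing.assert_allclose(used.mean(axis=(1, 2)), 0.0, atol=1e-12)
        np.testing.assert_allclose(used.std(axis=(1, 2)), 1.0, atol=1e-12)

    def test_zero_variance_site_error_names_site(self):
        sig = np.zeros((2, 300, 3))
        sig[0] = np.random.default_rng(0).standard_normal((300, 3))
        with pytest.raises(ValueError, match="site.*1"):
            condition_signal(_manual_session(sig), steps=("normalize",))


class TestExtractEpochs:
    def test_window_lengths(self, rng):
        rec = _manual_session(rng.standard_normal((2, 1200, 3)))
        assert extract_epochs(rec, "power-ppc-gpr").signal.shape[1] == 200
        assert extract_epochs(rec, "gc").signal.shape[1] == 400

    def test_window_ends_at_change_onset(self):
        n_tr = 2
        sig = np.zeros((1, 1200, n_tr))
        sig[0, 999, :] = 1.0                      # last pre-change sample
        sig[0, 1000, :] = 7.0                     # first post-change sample
        rec = _manual_session(sig)
        ep = extract_epochs(rec, "power-ppc-gpr")
        assert ep.signal[0, -1, 0] == 1.0
        assert 7.0 not in ep.signal

    def test_short_trial_raises(self, rng):
        rec = _manual_session(rng.standard_normal((1, 600, 2)))
        rec.change_time[:] = 300.0
        with pytest.raises(ValueError, match="too short"):
            extract_epochs(rec, "gc")

    def test_unknown_purpose_rejected(self, rng):
        rec = _manual_session(rng.standard_normal((1, 1200, 2)))
        with pytest.raises(ValueError):
            extract_epochs(rec, "other")
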