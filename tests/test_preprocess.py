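"""Preprocessing stages: rates, epochs, filters, ICA, full pipeline."""

import numpy as np
import pytest
from scipy import signal, stats

from eegmrcnn.data import BANDS, BandSpec, Recording
from eegmrcnn.preprocess import (
    PipelineConfig,
    bandpass,
    baseline_correct,
    design_bandpass,
    downsample,
    remove_artifacts_ica,
    run_pipeline,
    segment,
    select_channels,
)

FRONTAL = ("Fp1", "Fp2", "F3", "F4", "F7", "F8")


def _sine_recording(freq, rate=125.0, dur=20.0, channels=1):
    t = np.arange(0, dur, 1 / rate)
    x = np.tile(np.sin(2 * np.pi * freq * t), (channels, 1))
    return Recording(x, rate, FRONTAL[:channels])


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestDownsample:
    def test_halving_250_to_125(self, rng):
        rec = Recording(rng.standard_normal((6, 150000)), 250.0, FRONTAL)
        out = downsample(rec, 125.0)
        assert out.rate_hz == 125.0
        assert out.samples.shape == (6, 75000)
        assert abs(out.duration_s - rec.duration_s) < 1 / 125.0

    def test_identity_when_target_equals_rate(self, rng):
        rec = Recording(rng.standard_normal((2, 1000)), 250.0, FRONTAL[:2])
        out = downsample(rec, 250.0)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_spectral_peak_preserved(self):
        rec = _sine_recording(10.0, rate=250.0, dur=60.0)
        out = downsample(rec, 125.0)
        for r in (rec, out):
            f, p = signal.periodogram(r.samples[0], r.rate_hz)
            assert abs(f[p.argmax()] - 10.0) <= f[1] - f[0]

    def test_upsampling_rejected(self, rng):
        rec = Recording(rng.standard_normal((1, 100)), 125.0, ("Fp1",))
        with pytest.raises(ValueError, match="target_hz"):
            downsample(rec, 250.0)

    def test_non_integer_ratio_resamples(self, rng):
        rec = Recording(rng.standard_normal((1, 25000)), 250.0, ("Fp1",))
        out = downsample(rec, 100.0)
        assert out.samples.shape[1] == 10000


class TestBaseline:
    def test_constant_channel_becomes_zero(self):
        rec = Recording(np.full((2, 100), 5.0), 100.0, ("Fp1", "Fp2"))
        out = baseline_correct(rec)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_offset_sine_recovered(self):
        rec = _sine_recording(5.0)
        shifted = rec.with_samples(rec.samples + 3.2)
        out = baseline_correct(shifted)
        np.testing.assert_allclose(out.samples, rec.samples - rec.samples.mean(),
                                   atol=1e-9)
        sd = out.samples.std(axis=1)
        assert np.all(np.abs(out.samples.mean(axis=1)) < 1e-9 * sd)


class TestSegment:
    def test_600s_at_125hz_gives_150_epochs(self, rng):
        rec = Recording(rng.standard_normal((6, 75000)), 125.0, FRONTAL, "s1", "DD")
        ep = segment(rec, 4.0)
        assert ep.data.shape == (150, 6, 500)
        assert list(np.unique(ep.labels)) == ["DD"]
        assert list(np.unique(ep.subject_ids)) == ["s1"]

    def test_trailing_remainder_dropped(self, rng):
        n = int(601.5 * 125)
        rec = Recording(rng.standard_normal((2, n)), 125.0, FRONTAL[:2])
        ep = segment(rec, 4.0)
        assert ep.n_epochs == 150

    def test_concatenation_reconstructs_prefix(self, rng):
        rec = Recording(rng.standard_normal((3, 75000)), 125.0, FRONTAL[:3])
        ep = segment(rec, 4.0)
        recon = np.concatenate(list(ep.data), axis=1)
        np.testing.assert_array_equal(recon, rec.samples[:, : recon.shape[1]])

    def test_bad_epoch_length_rejected(self, rng):
        rec = Recording(rng.standard_normal((1, 1000)), 125.0, ("Fp1",))
        with pytest.raises(ValueError, match="epoch_len_s"):
            segment(rec, -1.0)
        with pytest.raises(ValueError, match="shorter"):
            segment(rec, 100.0)


class TestBandpass:
    def test_passband_center_rms_preserved(self):
        rec = _sine_recording(20.0)
        core = slice(625, 1875)  # central 10 s, away from edges
        for zp in (True, False):
            out = bandpass(rec, BANDS["beta"], zero_phase=zp)
            ratio = _rms(out.samples[0, core]) / _rms(rec.samples[0, core])
            assert abs(ratio - 1.0) < 0.05

    def test_stopband_attenuated_beyond_20db(self):
        rec = _sine_recording(2.0)
        core = slice(625, 1875)
        out = bandpass(rec, BANDS["beta"], zero_phase=False)
        ratio = _rms(out.samples[0, core]) / _rms(rec.samples[0, core])
        assert 20 * np.log10(ratio) < -20

    @pytest.mark.parametrize("freq", [13.0, 30.0])
    def test_cutoff_minus_3db_single_pass(self, freq):
        rec = _sine_recording(freq)
        core = slice(625, 1875)
        out = bandpass(rec, BANDS["beta"], zero_phase=False)
        db = 20 * np.log10(_rms(out.samples[0, core]) / _rms(rec.samples[0, core]))
        assert abs(db + 3.0) < 0.5
        # zero-phase squares the response: -6 dB at cutoff
        out2 = bandpass(rec, BANDS["beta"], zero_phase=True)
        db2 = 20 * np.log10(_rms(out2.samples[0, core]) / _rms(rec.samples[0, core]))
        assert abs(db2 + 6.0) < 1.0

    def test_epochset_path_sets_band_metadata(self, rng):
        rec = Recording(rng.standard_normal((6, 6000)), 125.0, FRONTAL, "s", "HC")
        ep = segment(rec, 4.0)
        out = bandpass(ep, BANDS["beta"])
        assert out.band == BANDS["beta"]
        assert out.data.shape == ep.data.shape
        assert out.meta["bandpass"]["mode"] == "zero_phase"

    def test_banded_power_no_more_than_broadband(self, rng):
        rec = Recording(rng.standard_normal((6, 12000)), 125.0, FRONTAL)
        out = bandpass(rec, BANDS["beta"])
        assert np.sum(out.samples**2) <= np.sum(rec.samples**2) * (1 + 1e-9)

    def test_band_above_nyquist_rejected(self, rng):
        rec = Recording(rng.standard_normal((1, 1000)), 125.0, ("Fp1",))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, BandSpec(30.0, 70.0))

    @pytest.mark.parametrize("name", sorted(BANDS))
    def test_designed_filters_are_stable(self, name):
        """Impulse response decays: 10 s zero-input tail stays near zero."""
        sos = design_bandpass(BANDS[name], 125.0)
        impulse = np.zeros(60 * 125)
        impulse[0] = 1.0
        y = signal.sosfilt(sos, impulse)
        assert np.abs(y[-1250:]).max() < 1e-6 * np.abs(y).max()


class TestSelectChannels:
    def test_subset_and_reorder(self, rng):
        from eegmrcnn.synth import MONTAGE_16

        rec = Recording(rng.standard_normal((16, 1000)), 250.0, MONTAGE_16)
        out = select_channels(rec, FRONTAL)
        assert out.channel_labels == FRONTAL
        assert out.samples.shape == (6, 1000)
        np.testing.assert_array_equal(out.samples[2], rec.samples[2])  # F3

    def test_case_insensitive_and_alias(self, rng):
        rec = Recording(rng.standard_normal((2, 100)), 100.0, ("T7", "Fp1"))
        out = select_channels(rec, ["fp1", "T3"])  # T3 aliases T7
        assert out.samples.shape == (2, 100)
        np.testing.assert_array_equal(out.samples[0], rec.samples[1])

    def test_identity_order(self, rng):
        rec = Recording(rng.standard_normal((3, 100)), 100.0, FRONTAL[:3])
        out = select_channels(rec, list(FRONTAL[:3]))
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_unknown_label_error_names_it(self, rng):
        rec = Recording(rng.standard_normal((2, 100)), 100.0, FRONTAL[:2])
        with pytest.raises(KeyError, match="XX"):
            select_channels(rec, ["Fp1", "XX"])


class TestICA:
    def test_artifact_component_rejected_and_kurtosis_drops(self, artifact_recording):
        clean, report = remove_artifacts_ica(artifact_recording, seed=0)
        assert len(report.rejected) >= 1
        k_before = stats.kurtosis(artifact_recording.samples[:2], axis=1).mean()
        k_after = stats.kurtosis(clean.samples[:2], axis=1).mean()
        assert k_after < k_before

    def test_clean_recording_mostly_untouched(self, clean_recording):
        clean, report = remove_artifacts_ica(clean_recording, seed=0)
        assert len(report.rejected) <= 1
        retained = clean.samples.var(axis=1).sum() / clean_recording.samples.var(axis=1).sum()
        assert retained >= 0.90

    def test_keep_all_is_identity(self, artifact_recording):
        out, report = remove_artifacts_ica(artifact_recording,
                                           reject_policy="keep-all", seed=0)
        dev = np.abs(out.samples - artifact_recording.samples).max()
        assert dev < 1e-6 * artifact_recording.samples.std()
        assert report.rejected == []

    def test_rank_deficient_input_rejected(self, rng):
        x = rng.standard_normal((1, 2000))
        rec = Recording(np.vstack([x, x, x]), 250.0, ("Fp1", "Fp2", "F3"))
        with pytest.raises(ValueError, match="rank"):
            remove_artifacts_ica(rec)

    def test_too_short_recording_rejected(self, rng):
        rec = Recording(rng.standard_normal((6, 30)), 250.0, FRONTAL)
        with pytest.raises(ValueError, match="short"):
            remove_artifacts_ica(rec)

    def test_unknown_policy_rejected(self, clean_recording):
        with pytest.raises(ValueError, match="policy"):
            remove_artifacts_ica(clean_recording, reject_policy="bogus")


class TestPipeline:
    def test_default_shapes_and_metadata(self, small_cohort):
        cfg = PipelineConfig(band=BANDS["beta"], use_ica=False)
        ep = run_pipeline(small_cohort[0], cfg)
        assert ep.data.shape == (6, 6, 500)  # 24 s -> 6 four-second epochs
        assert ep.band == BANDS["beta"]
        stages = [m["stage"] for m in ep.meta["manifest"]]
        assert stages == ["downsample", "baseline_correct", "segment", "bandpass"]

    def test_equals_manual_composition_without_ica(self, small_cohort):
        rec = small_cohort[0]
        cfg = PipelineConfig(band=BANDS["beta"], use_ica=False)
        ep = run_pipeline(rec, cfg)
        manual = bandpass(segment(baseline_correct(downsample(rec, 125.0)), 4.0),
                          BANDS["beta"])
        np.testing.assert_allclose(ep.data, manual.data, rtol=0, atol=1e-12)

    def test_deterministic_with_ica(self, small_cohort):
        cfg = PipelineConfig(band=BANDS["beta"], use_ica=True, ica_seed=0)
        a = run_pipeline(small_cohort[0], cfg)
        b = run_pipeline(small_cohort[0], cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_band_before_segment_flag(self, small_cohort):
        rec = small_cohort[0]
        cfg = PipelineConfig(band=BANDS["beta"], use_ica=False,
                             band_before_segment=True)
        ep = run_pipeline(rec, cfg)
        assert ep.band == BANDS["beta"]
        assert ep.data.shape == (6, 6, 500)

    def test_epoch_accounting_across_cohort(self, small_cohort):
        from eegmrcnn.preprocess import preprocess_cohort

        cfg = PipelineConfig(band=None, use_ica=False)
        pooled = preprocess_cohort(small_cohort, cfg)
        per_subject = int(24.0 // 4)
        assert pooled.n_epochs == per_subject * len(small_cohort)
        for sid in np.unique(pooled.subject_ids):
            labels = pooled.labels[pooled.subject_ids == sid]
            assert len(set(labels)) == 1  # no epoch spans two subjects
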