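"""Synthetic PPG generator: determinism, periodicity, event semantics."""

import numpy as np
import pytest

import ppgsas as P
from ppgsas.synth import ApneaEventSpec, EventModel, SynthConfig


def clean_config(**kw):
    """All stochastic terms disabled unless overridden."""
    base = dict(duration_s=10.0, mean_heart_rate_bpm=60.0, hrv_sd_bpm=0.0,
                respiratory_modulation_depth=0.0, baseline_wander_amplitude=0.0,
                sensor_noise_sd=0.0, beat_amplitude_jitter_sd=0.0)
    base.update(kw)
    return SynthConfig(**base)


class TestBaselineGeneration:
    def test_deterministic_clean_signal_is_exactly_periodic(self):
        # 60 bpm at 100 Hz with every stochastic term off -> period 100 samples
        rec = P.generate_baseline_ppg(clean_config())
        x = rec.samples
        assert len(x) == 1000
        core = x[100:800]
        assert np.array_equal(core, x[200:900])

    def test_peak_count_matches_heart_rate(self):
        # peak-detection oracle: maxima above half range, >= 0.5 s apart
        from scipy.signal import find_peaks
        rec = P.generate_baseline_ppg(clean_config())
        x = rec.samples
        height = x.min() + 0.5 * (x.max() - x.min())
        peaks, _ = find_peaks(x, height=height, distance=50)
        assert abs(len(peaks) - 10) <= 1

    def test_identical_seed_gives_bit_identical_output(self):
        cfg = SynthConfig(duration_s=30.0, seed=42)
        a = P.generate_baseline_ppg(cfg)
        b = P.generate_baseline_ppg(cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_record_length_and_label(self):
        cfg = SynthConfig(duration_s=17.3, sampling_rate_hz=100.0)
        rec = P.generate_baseline_ppg(cfg)
        assert len(rec.samples) == round(17.3 * 100)
        assert rec.label == "healthy" and rec.events == []

    @pytest.mark.parametrize("field,value", [
        ("sampling_rate_hz", 0.0), ("duration_s", -1.0), ("hrv_sd_bpm", -0.1),
        ("respiratory_modulation_depth", 1.0), ("sensor_noise_sd", -1.0),
        ("beat_morphology", ((1.0, 0.3, 0.0),)),
    ])
    def test_invalid_config_rejected_naming_field(self, field, value):
        cfg = SynthConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()


class TestApneaInjection:
    def test_empty_event_list_relabels_without_touching_samples(self):
        rec = P.generate_baseline_ppg(clean_config(duration_s=30))
        out = P.inject_apnea_events(rec, [])
        assert out.label == "sas"
        assert np.array_equal(out.samples, rec.samples)

    def test_full_attenuation_suppresses_oscillation_in_event_core(self):
        rec = P.generate_baseline_ppg(clean_config(duration_s=60))
        ev = ApneaEventSpec(onset_s=20, duration_s=15, amplitude_attenuation=1.0,
                            hr_dip_bpm=0, hr_rebound_bpm=0, rebound_duration_s=0)
        out = P.inject_apnea_events(rec, [ev])
        core = out.samples[2200:3300]       # inside event, clear of ramps
        ref = out.samples[500:1600]         # unaffected region
        assert np.ptp(core) < 0.05 * np.ptp(ref)

    def test_locality_outside_event_and_ramp(self):
        rec = P.generate_baseline_ppg(clean_config(duration_s=60))
        ev = ApneaEventSpec(onset_s=10.0, duration_s=10.0, amplitude_attenuation=0.9,
                            hr_dip_bpm=5, hr_rebound_bpm=8, rebound_duration_s=8)
        out = P.inject_apnea_events(rec, [ev], ramp_s=1.0)
        # event core [1000, 2000), ramps within 1 s, rebound ends at 28 s
        assert np.array_equal(out.samples[:900], rec.samples[:900])
        assert np.array_equal(out.samples[3000:], rec.samples[3000:])

    def test_overlapping_events_rejected(self):
        rec = P.generate_baseline_ppg(clean_config(duration_s=60))
        evs = [ApneaEventSpec(onset_s=10, duration_s=10),
               ApneaEventSpec(onset_s=19, duration_s=10)]
        with pytest.raises(ValueError, match="overlap"):
            P.inject_apnea_events(rec, evs)

    def test_event_past_record_end_rejected(self):
        rec = P.generate_baseline_ppg(clean_config(duration_s=20))
        with pytest.raises(ValueError, match="exceeds"):
            P.inject_apnea_events(rec, [ApneaEventSpec(onset_s=15, duration_s=10)])


class TestCohort:
    def test_default_cohort_counts(self):
        recs = P.generate_cohort(20, 39, SynthConfig(duration_s=60.0), seed=0)
        assert len(recs) == 59
        assert sum(r.label == "healthy" for r in recs) == 20
        assert sum(r.label == "sas" for r in recs) == 39

    def test_single_healthy_record(self):
        recs = P.generate_cohort(1, 0, SynthConfig(duration_s=60.0), seed=0)
        assert len(recs) == 1 and recs[0].label == "healthy" and recs[0].events == []

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            P.generate_cohort(0, 0, SynthConfig(duration_s=60.0))

    def test_every_sas_record_has_events_and_rate_is_calibrated(self):
        # Monte-Carlo check of the event model against rate x duration
        model = EventModel(rate_per_hour=30.0)
        rng = np.random.default_rng(5)
        counts = [len(model.sample_events(600.0, rng)) for _ in range(300)]
        assert min(counts) >= 1
        expected = 30.0 * 600.0 / 3600.0
        assert abs(np.mean(counts) - expected) <= 0.2 * expected
        # integration: generated sas records carry non-overlapping events
        recs = P.generate_cohort(0, 5, SynthConfig(duration_s=600.0),
                                 EventModel(rate_per_hour=30.0), seed=2)
        for r in recs:
            assert len(r.events) >= 1
            evs = sorted(r.events, key=lambda e: e.onset_s)
            for a, b in zip(evs, evs[1:]):
                assert a.end_s <= b.onset_s

    def test_cohort_determinism_and_finiteness(self, small_cohort):
        again = P.generate_cohort(6, 6, SynthConfig(duration_s=600), seed=11)
        for a, b in zip(small_cohort, again):
            assert np.array_equal(a.samples, b.samples)
            assert np.isfinite(a.samples).all()

    def test_roundtrip_serialization(self, tmp_path, small_cohort):
        P.save_cohort(small_cohort, tmp_path)
        back = P.load_cohort(tmp_path)
        assert [r.subject_id for r in back] == [r.subject_id for r in small_cohort]
        for a, b in zip(small_cohort, back):
            assert np.array_equal(a.samples, b.samples)
            assert len(a.events) == len(b.events)


def test_class_signal_two_feature_oracle(small_cohort):
    """Amplitude variance + peak-rate variance must linearly separate healthy
    segments from SAS segments that overlap an apnea event (AUC > 0.9)."""
    from scipy.signal import find_peaks
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.preprocessing import StandardScaler
    import ppgsas as P_

    subj = P_.segment_cohort(small_cohort, labeling="subject")
    event = P_.segment_cohort(small_cohort, labeling="event")
    mask = (subj.labels == 0) | (event.labels == 1)
    x = P_.standardize(subj.samples[mask])
    y = event.labels[mask]

    feats = []
    for seg in x:
        h = seg.min() + 0.55 * (seg.max() - seg.min())
        pk, props = find_peaks(seg, height=h, distance=40)
        amp_var = props["peak_heights"].var() if len(pk) > 1 else 0.0
        rates = [len(find_peaks(seg[i * 300:(i + 1) * 300], height=h,
                                distance=40)[0]) for i in range(5)]
        feats.append([amp_var, np.var(rates)])
    feats = StandardScaler().fit_transform(feats)
    score = LogisticRegression().fit(feats, y).decision_function(feats)
    assert roc_auc_score(y, score) > 0.9
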