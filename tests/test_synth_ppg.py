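"""Generator: modulation waveform, integrate-and-fire beats, PPG rendering,
profile and cohort draws, ground-truth attachment."""

import numpy as np
import pytest
from scipy import integrate

from rsasync import (AGE_GROUPS, GeneratorConfig, NoiseConfig,
                     ParticipantProfile, draw_profile, generate_beats,
                     instantaneous_hr, render_ppg, simulate_cohort)
from rsasync.protocol import DEFAULT_PROTOCOL as P
from rsasync.synth_ppg import (allocate_groups, ground_truth_for,
                               modulation_waveform)


class TestModulationWaveform:
    def test_unit_peaks_at_window_centres(self):
        assert modulation_waveform(3.0) == pytest.approx(1.0)
        assert modulation_waveform(8.0) == pytest.approx(-1.0)
        u = np.linspace(0, 10, 5001)
        g = modulation_waveform(u)
        assert g.max() <= 1.0 + 1e-12 and g.min() >= -1.0 - 1e-12

    def test_zero_mean_over_cycle(self):
        u = np.linspace(0, 10, 400001)[:-1]
        assert abs(modulation_waveform(u).mean()) < 1e-6

    def test_periodic(self):
        assert modulation_waveform(12.5) == pytest.approx(
            float(modulation_waveform(2.5)))


class TestInstantaneousHR:
    def test_end_of_inhale_peak(self):
        prof = ParticipantProfile(id="a", age_years=8, baseline_hr=84.0,
                                  rsa_amp=11.0, resp_mode="paced")
        assert instantaneous_hr(prof, P, 3.0)[0] == pytest.approx(95.0)

    def test_zero_modulation_is_constant(self):
        prof = ParticipantProfile(id="a", age_years=8, baseline_hr=77.0,
                                  rsa_amp=0.0, resp_mode="paced")
        t = np.linspace(0, 60, 1000)
        assert np.allclose(instantaneous_hr(prof, P, t), 77.0)

    def test_cycle_mean_equals_baseline(self):
        prof = ParticipantProfile(id="a", age_years=8, baseline_hr=90.0,
                                  rsa_amp=15.0, resp_mode="paced")
        t = np.linspace(0, 10, 200001)[:-1]
        assert instantaneous_hr(prof, P, t).mean() == pytest.approx(
            90.0, abs=1e-6)

    def test_spontaneous_deterministic_per_seed(self):
        kw = dict(id="a", age_years=8, baseline_hr=90.0, rsa_amp=6.0,
                  resp_mode="spontaneous", resp_period=3.7,
                  phase_offset=1.2, seed=5)
        t = np.linspace(0, 60, 600)
        a = instantaneous_hr(ParticipantProfile(**kw), P, t)
        b = instantaneous_hr(ParticipantProfile(**kw), P, t)
        assert np.array_equal(a, b)


class TestProfileInvariants:
    @pytest.mark.parametrize("kw", [
        dict(baseline_hr=40.0, rsa_amp=0.0),          # HR below range
        dict(baseline_hr=150.0, rsa_amp=0.0),         # HR above range
        dict(baseline_hr=60.0, rsa_amp=-1.0),         # negative amplitude
        dict(baseline_hr=55.0, rsa_amp=30.0),         # HR - amp <= 30
    ])
    def test_invalid_profiles_rejected(self, kw):
        with pytest.raises(ValueError):
            ParticipantProfile(id="x", age_years=10, resp_mode="paced", **kw)

    def test_spontaneous_period_bounds(self):
        with pytest.raises(ValueError):
            ParticipantProfile(id="x", age_years=10, baseline_hr=80.0,
                               rsa_amp=5.0, resp_mode="spontaneous",
                               resp_period=8.0)


class TestGenerateBeats:
    def test_constant_60_bpm(self):
        prof = ParticipantProfile(id="c", age_years=8, baseline_hr=60.0,
                                  rsa_amp=0.0, resp_mode="paced")
        beats = generate_beats(prof, P, 10.0)
        assert np.allclose(beats, np.arange(1.0, 11.0), atol=1e-9)

    def test_constant_120_bpm(self):
        prof = ParticipantProfile(id="c", age_years=8, baseline_hr=120.0,
                                  rsa_amp=0.0, resp_mode="paced")
        beats = generate_beats(prof, P, 5.0)
        assert beats.size == 10
        assert np.allclose(np.diff(beats), 0.5, atol=1e-9)

    def test_count_matches_quadrature_oracle(self):
        prof = ParticipantProfile(id="c", age_years=12, baseline_hr=95.0,
                                  rsa_amp=18.0, resp_mode="paced")
        beats = generate_beats(prof, P, 90.0)
        # independent quadrature oracle: one cycle at a time (periodic rate)
        total = sum(integrate.quad(
            lambda t: instantaneous_hr(prof, P, t)[0] / 60.0,
            10.0 * k, 10.0 * (k + 1))[0] for k in range(9))
        assert abs(beats.size - np.floor(total)) <= 1

    def test_strictly_increasing_with_min_gap(self):
        prof = ParticipantProfile(id="c", age_years=6, baseline_hr=110.0,
                                  rsa_amp=20.0, resp_mode="paced")
        beats = generate_beats(prof, P, 120.0)
        gaps = np.diff(beats)
        assert np.all(gaps > 0)
        assert gaps.min() > 60.0 / (110.0 + 20.0) - 1e-3

    def test_invalid_duration(self):
        prof = ParticipantProfile(id="c", age_years=8, baseline_hr=60.0,
                                  rsa_amp=0.0, resp_mode="paced")
        with pytest.raises(ValueError):
            generate_beats(prof, P, -1.0)


class TestRenderPPG:
    def test_no_sources_gives_zeros(self):
        rec = render_ppg(np.empty(0), 100.0, NoiseConfig.zero(), 10.0)
        assert rec.samples.shape == (1000,)
        assert np.all(rec.samples == 0.0)

    def test_single_beat_peak_location(self):
        rec = render_ppg(np.array([5.0]), 200.0, NoiseConfig.zero(), 10.0)
        t_peak = np.argmax(rec.samples) / 200.0
        # documented pulse offset is zero: peak at the beat time
        assert t_peak == pytest.approx(5.0, abs=0.01)

    def test_sample_count_contract(self):
        rec = render_ppg(np.empty(0), 100.0, NoiseConfig.zero(), 60.0)
        assert rec.samples.size == 6000

    def test_fs_floor(self):
        with pytest.raises(ValueError):
            render_ppg(np.empty(0), 10.0, NoiseConfig.zero(), 10.0)

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError):
            render_ppg(np.empty(0), 100.0, NoiseConfig(white_sigma=0.1), 5.0)


class TestDrawProfile:
    def test_degenerate_ratio_gives_zero_amplitude(self):
        cfg = GeneratorConfig(ratio_support=(1.0, 1.0 + 1e-12),
                              noise=NoiseConfig.zero())
        prof = draw_profile(np.random.default_rng(0), "8-10", "paced", cfg)
        assert prof.rsa_amp == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_identical(self):
        cfg = GeneratorConfig()
        a = draw_profile(np.random.default_rng(3), "5-7", "spontaneous", cfg)
        b = draw_profile(np.random.default_rng(3), "5-7", "spontaneous", cfg)
        assert a == b

    def test_baseline_centred_per_group(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(1)
        hrs = [draw_profile(rng, "5-7", "spontaneous", cfg).baseline_hr
               for _ in range(300)]
        # centred between the group's spontaneous window medians (~81.6)
        assert np.mean(hrs) == pytest.approx(81.6, abs=2.0)

    def test_paced_ratio_distribution_shape(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(2)
        ratios = []
        for _ in range(400):
            p = draw_profile(rng, "11-13", "paced", cfg)
            ratios.append((p.baseline_hr + p.rsa_amp)
                          / (p.baseline_hr - p.rsa_amp))
        assert 1.01 <= min(ratios) and max(ratios) <= 1.60
        assert np.median(ratios) == pytest.approx(1.26, abs=0.03)

    def test_unknown_age_group(self):
        with pytest.raises(ValueError, match="age_group"):
            draw_profile(np.random.default_rng(0), "18-20", "paced",
                         GeneratorConfig())

    def test_spontaneous_attenuation_and_period(self):
        cfg = GeneratorConfig()
        rng_p = np.random.default_rng(9)
        rng_s = np.random.default_rng(9)
        paced = draw_profile(rng_p, "8-10", "paced", cfg)
        spont = draw_profile(rng_s, "8-10", "spontaneous", cfg)
        assert spont.rsa_amp == pytest.approx(
            cfg.spont_attenuation * paced.rsa_amp)
        assert 2.5 <= spont.resp_period <= 5.0


class TestCohort:
    def test_default_allocation_matches_study(self):
        counts = allocate_groups(80, {"5-7": 18, "8-10": 20,
                                      "11-13": 21, "14-17": 21})
        assert counts == {"5-7": 18, "8-10": 20, "11-13": 21, "14-17": 21}

    def test_empty_cohort(self):
        assert simulate_cohort(0, "paced", 1) == []

    def test_negative_n(self):
        with pytest.raises(ValueError):
            simulate_cohort(-1, "paced", 1)

    def test_determinism_bit_identical(self, quiet_cfg):
        a = simulate_cohort(3, "paced", 5, quiet_cfg)
        b = simulate_cohort(3, "paced", 5, quiet_cfg)
        for (ra, ta), (rb, tb) in zip(a, b):
            assert np.array_equal(ra.samples, rb.samples)
            assert np.array_equal(ta.beat_times, tb.beat_times)
            assert ta.true_participant_ratio == tb.true_participant_ratio

    def test_durations_by_mode(self, quiet_cfg):
        (rec_s, _), = simulate_cohort(1, "spontaneous", 2, quiet_cfg)
        (rec_p, _), = simulate_cohort(1, "paced", 2, quiet_cfg)
        assert rec_s.duration == pytest.approx(60.0)
        assert rec_p.duration == pytest.approx(120.0)

    def test_ages_fall_in_assigned_groups(self, quiet_cfg):
        cohort = simulate_cohort(8, "paced", 3, quiet_cfg)
        for rec, _ in cohort:
            assert 5 <= rec.meta["age_years"] <= 17


class TestGroundTruth:
    def test_zero_modulation_ratio_is_one(self, protocol):
        prof = ParticipantProfile(id="z", age_years=8, baseline_hr=75.0,
                                  rsa_amp=0.0, resp_mode="paced")
        beats = generate_beats(prof, protocol, 120.0)
        truth = ground_truth_for(prof, protocol, beats, 120.0)
        assert truth.true_participant_ratio == pytest.approx(1.0, abs=1e-9)

    def test_cycle_count(self, paced_profile, protocol):
        beats = generate_beats(paced_profile, protocol, 120.0)
        truth = ground_truth_for(paced_profile, protocol, beats, 120.0)
        assert len(truth.true_cycle_metrics) == 12
        assert all(i > e for i, e in truth.true_cycle_metrics)
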