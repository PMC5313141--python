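"""Forward models and phantom generation: causality, closure, determinism."""

import numpy as np
import pytest

import strokebbb as sb
from strokebbb.errors import GeometryError, ParameterError


class TestVif:
    def test_zero_before_arrival(self, vif_params, acq):
        vif = sb.generate_vif(vif_params, acq)
        assert np.all(vif.cp[vif.times < vif_params.arrival_time] == 0)
        assert np.all(vif.cp >= 0)
        assert np.all(np.isfinite(vif.cp))

    def test_peak_at_gamma_variate_mode(self, acq):
        # alpha * tau = 18 s after a 45 s arrival -> frame 7 (t = 63 s)
        p = sb.VifParams(arrival_time=45.0, shape_alpha=2.0,
                         timescale_tau=9.0, recirculation_fraction=0.0)
        vif = sb.generate_vif(p, acq)
        assert vif.times[np.argmax(vif.cp)] == 63.0

    def test_matches_closed_form_pointwise(self, vif_params, acq):
        vif = sb.generate_vif(vif_params, acq)
        a, tau = vif_params.shape_alpha, vif_params.timescale_tau
        t0, amp = vif_params.arrival_time, vif_params.amplitude
        f, w = vif_params.recirculation_fraction, vif_params.washout_timescale
        expected = []
        for t in acq.frame_times:
            ts = t - t0
            if ts <= 0:
                expected.append(0.0)
                continue
            gv = amp * (ts / (a * tau)) ** a * np.exp(a - ts / tau)
            rc = f * amp * (1 - np.exp(-ts / (a * tau))) * np.exp(-ts / w)
            expected.append(gv + rc)
        np.testing.assert_allclose(vif.cp, expected, rtol=1e-12, atol=1e-15)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            sb.VifParams(timescale_tau=-1.0)
        with pytest.raises(ParameterError):
            sb.VifParams(shape_alpha=0.0)


class TestTissueCurve:
    def test_ki_zero_is_pure_intravascular(self, vif):
        ct = sb.simulate_tissue_curve(vif, ki=0.0, vp=0.05)
        np.testing.assert_allclose(ct, 0.05 * vif.cp, rtol=1e-14)

    def test_constant_input_integrates_linearly(self):
        t = np.arange(31) * 9.0
        vif = sb.InputFunction(times=t, cp=np.ones_like(t))
        ct = sb.simulate_tissue_curve(vif, ki=0.01, vp=0.03)
        np.testing.assert_allclose(ct, 0.01 * t / 60.0 + 0.03, rtol=1e-12)

    @pytest.mark.parametrize("ki,vp", [(0.004, 0.02), (0.012, 0.07),
                                       (0.02, 0.1)])
    def test_patlak_round_trip(self, vif, ki, vp):
        ct = sb.simulate_tissue_curve(vif, ki=ki, vp=vp)
        fit = sb.patlak_fit(ct, vif)
        assert abs(fit.ki - ki) / ki < 1e-6
        assert abs(fit.vp - vp) / vp < 1e-6

    def test_invalid_parameters_rejected(self, vif):
        with pytest.raises(ParameterError):
            sb.simulate_tissue_curve(vif, ki=-0.01, vp=0.03)
        with pytest.raises(ParameterError):
            sb.simulate_tissue_curve(vif, ki=0.01, vp=1.0)


class TestSignalModel:
    def test_zero_concentration_gives_flat_baseline(self, acq):
        conc = np.zeros(acq.n_frames)
        sig = sb.concentration_to_signal(conc, 1000.0, 4.3, acq, s0=500.0)
        from strokebbb.spgr import baseline_factor
        expected = 500.0 * baseline_factor(1000.0, acq.repetition_time,
                                           acq.flip_angle)
        np.testing.assert_allclose(sig, expected, rtol=1e-12)

    def test_signal_linear_in_s0(self, vif, acq):
        ct = sb.simulate_tissue_curve(vif, 0.01, 0.03)
        s1 = sb.concentration_to_signal(ct, 1000.0, 4.3, acq, s0=1000.0)
        s2 = sb.concentration_to_signal(ct, 1000.0, 4.3, acq, s0=2000.0)
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-14)

    def test_inverse_round_trip(self, vif, acq, conv):
        ct = sb.simulate_tissue_curve(vif, 0.015, 0.08)
        sig = sb.concentration_to_signal(ct, conv.t1_tissue,
                                         conv.relaxivity_r1, acq)
        back = sb.signal_to_concentration(sig, conv, acq)
        pos = ct > 0
        assert np.max(np.abs(back[pos] - ct[pos]) / ct[pos]) < 1e-8


class TestPhantom:
    def test_same_seed_is_bit_identical(self):
        sigma = sb.snr_to_sigma(20.0)
        a = sb.generate_phantom(sb.default_phantom_truth(noise_sigma=sigma,
                                                         seed=11))
        b = sb.generate_phantom(sb.default_phantom_truth(noise_sigma=sigma,
                                                         seed=11))
        assert np.array_equal(a.dce.signal, b.dce.signal)
        assert np.array_equal(a.dwi.sb_volume, b.dwi.sb_volume)

    def test_dwi_decay_bounded(self, phantom_nf):
        brain = phantom_nf.truth.brain_mask
        s0 = phantom_nf.dwi.s0_volume[brain]
        sbv = phantom_nf.dwi.sb_volume[brain]
        assert np.all(sbv > 0)
        assert np.all(sbv <= s0)

    def test_null_permeability_maps_to_zero(self, conv):
        truth = sb.default_phantom_truth(lesion_kps=0.0, background_kps=0.0,
                                         vp=0.0, noise_sigma=0.0, seed=3)
        ph = sb.generate_phantom(truth)
        vif = sb.extract_vif(ph.dce, truth.sinus_mask, conv)
        kmap = sb.compute_kps_map(ph.dce, vif, truth.brain_mask, conv)
        tissue = truth.brain_mask & ~truth.sinus_mask
        assert np.nanmax(np.abs(kmap.values[tissue])) < 1e-9

    def test_overlapping_sinus_and_lesion_rejected(self):
        truth = sb.default_phantom_truth(seed=0)
        with pytest.raises(GeometryError):
            sb.PhantomTruth(
                kps_true=truth.kps_true, vp_true=truth.vp_true,
                adc_true=truth.adc_true, lesion_mask=truth.lesion_mask,
                sinus_mask=truth.lesion_mask,  # deliberately overlapping
                brain_mask=truth.brain_mask, affine=truth.affine)

    def test_forward_inverse_consistency_of_lesion_kps(self, phantom_nf,
                                                       kps_map_nf):
        lesion = phantom_nf.truth.lesion_mask
        assert abs(np.nanmean(kps_map_nf.values[lesion]) - 1.0) < 1e-6


class TestCohortGeneration:
    def test_phase_counts(self):
        df = sb.generate_cohort(sb.default_cohort_spec(seed=5))
        assert len(df) == 42
        counts = df["phase"].value_counts()
        assert (counts["hyperacute"], counts["acute"], counts["subacute"]) \
            == (20, 11, 11)

    def test_ht_subgroup_appended(self):
        df = sb.generate_cohort(sb.default_cohort_spec(seed=5,
                                                       include_ht=True))
        assert len(df) == 49
        assert int(df["ht_flag"].sum()) == 7

    def test_zero_sd_degenerates_to_phase_means(self):
        spec = sb.default_cohort_spec(seed=2)
        phases = {
            name: sb.PhaseSpec(
                n=ph.n, onset_range=ph.onset_range,
                kps_i=(ph.kps_i[0], 0.0), kps_c=(ph.kps_c[0], 0.0),
                adc_i=(ph.adc_i[0], 0.0), adc_c=(ph.adc_c[0], 0.0),
                volume=(ph.volume[0], 0.0))
            for name, ph in spec.phases.items()
        }
        df = sb.generate_cohort(sb.CohortSpec(phases=phases, seed=2))
        for name, ph in phases.items():
            sub = df[df["phase"] == name]
            assert np.allclose(sub["kps_i"], ph.kps_i[0])
            assert np.allclose(sub["kps_c"], ph.kps_c[0])

    def test_moment_matching_is_unbiased(self):
        # truncation at zero must not shift the requested moments
        from strokebbb.cohort import _matched_truncnorm
        dist = _matched_truncnorm(0.72, 0.37)
        m, v = dist.stats(moments="mv")
        assert abs(m - 0.72) < 1e-8
        assert abs(np.sqrt(v) - 0.37) < 1e-8
        assert dist.ppf(0.0001) >= 0

    def test_lognormal_volume_moments(self):
        from strokebbb.cohort import _draw_lognormal
        rng = np.random.default_rng(0)
        x = _draw_lognormal(rng, 200_000, (5.31, 8.38))
        assert np.all(x > 0)
        assert abs(x.mean() - 5.31) < 0.1
        assert abs(x.std(ddof=1) - 8.38) < 0.25

    def test_deterministic_given_seed(self):
        a = sb.generate_cohort(sb.default_cohort_spec(seed=9))
        b = sb.generate_cohort(sb.default_cohort_spec(seed=9))
        assert a.equals(b)

    def test_onset_times_respect_phase_windows(self):
        df = sb.generate_cohort(sb.default_cohort_spec(seed=4))
        t = df["onset_to_scan_hr"]
        assert t.min() >= 1.3 and t.max() <= 90.7
        assert np.all(df.loc[df.phase == "hyperacute", "onset_to_scan_hr"] < 6)
        assert np.all(df.loc[df.phase == "subacute", "onset_to_scan_hr"] > 48)
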