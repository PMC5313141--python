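"""Signal conversion, VIF extraction, Patlak fitting and ROI summaries."""

import numpy as np
import pytest

import strokebbb as sb
from strokebbb.core import AdcMap, InputFunction, KpsMap, RoiPair
from strokebbb.errors import FitError, ParameterError


class TestSignalToConcentration:
    def test_flat_baseline_maps_to_zero(self, conv, acq):
        sig = np.full(acq.n_frames, 123.4)
        conc = sb.signal_to_concentration(sig, conv, acq)
        np.testing.assert_allclose(conc, 0.0, atol=1e-12)

    def test_concentration_inverse_to_relaxivity(self, vif, acq):
        ct = sb.simulate_tissue_curve(vif, 0.01, 0.05)
        sig = sb.concentration_to_signal(ct, 1000.0, 4.3, acq)
        c1 = sb.signal_to_concentration(
            sig, sb.ConversionParams(relaxivity_r1=4.3), acq)
        c2 = sb.signal_to_concentration(
            sig, sb.ConversionParams(relaxivity_r1=8.6), acq)
        pos = c1 > 1e-12
        np.testing.assert_allclose(c2[pos], 0.5 * c1[pos], rtol=1e-10)

    def test_linear_mode_tracks_spgr_at_low_dose(self, vif, acq):
        ct = sb.simulate_tissue_curve(vif, 0.002, 0.01)
        sig = sb.concentration_to_signal(ct, 1000.0, 4.3, acq)
        spgr = sb.signal_to_concentration(
            sig, sb.ConversionParams(signal_model="spgr"), acq)
        lin = sb.signal_to_concentration(
            sig, sb.ConversionParams(signal_model="linear"), acq)
        pos = spgr > 0.001
        assert np.all(np.abs(lin[pos] - spgr[pos]) / spgr[pos] < 0.25)


class TestExtractVif:
    def test_phantom_ground_truth_recovered(self, phantom_nf, vif_nf):
        truth_cp = phantom_nf.vif_true.cp
        pos = truth_cp > 0
        rel = np.abs(vif_nf.cp[pos] - truth_cp[pos]) / truth_cp[pos]
        assert rel.max() < 1e-6
        np.testing.assert_allclose(vif_nf.cp[~pos], 0.0, atol=1e-9)

    def test_zero_hematocrit_disables_plasma_correction(self, phantom_nf):
        conv45 = sb.ConversionParams(hematocrit=0.45)
        conv0 = sb.ConversionParams(hematocrit=0.0)
        sinus = phantom_nf.truth.sinus_mask
        cp45 = sb.extract_vif(phantom_nf.dce, sinus, conv45).cp
        cp0 = sb.extract_vif(phantom_nf.dce, sinus, conv0).cp
        np.testing.assert_allclose(cp0, cp45 * 0.55, rtol=1e-10)

    def test_disjoint_submasks_of_homogeneous_sinus_agree(self, phantom_nf,
                                                          conv):
        sinus = phantom_nf.truth.sinus_mask
        idx = np.argwhere(sinus)
        half_a = np.zeros_like(sinus)
        half_b = np.zeros_like(sinus)
        half_a[tuple(idx[: len(idx) // 2].T)] = True
        half_b[tuple(idx[len(idx) // 2:].T)] = True
        cp_a = sb.extract_vif(phantom_nf.dce, half_a, conv).cp
        cp_b = sb.extract_vif(phantom_nf.dce, half_b, conv).cp
        np.testing.assert_allclose(cp_a, cp_b, rtol=1e-9, atol=1e-12)

    def test_flat_curve_warns_no_bolus(self, acq, conv):
        signal = np.full((4, 4, 2, acq.n_frames), 100.0)
        dce = sb.DceSeries(signal=signal, acq=acq, affine=np.eye(4))
        with pytest.warns(RuntimeWarning, match="no bolus"):
            vif = sb.extract_vif(dce, np.ones((4, 4, 2), bool), conv)
        assert vif.status == "no-bolus-detected"

    def test_empty_mask_rejected(self, phantom_nf, conv):
        with pytest.raises(ParameterError):
            sb.extract_vif(phantom_nf.dce,
                           np.zeros(phantom_nf.dce.shape3d, bool), conv)


class TestPatlakFit:
    def test_null_tissue_gives_null_fit(self, vif):
        fit = sb.patlak_fit(np.zeros_like(vif.cp), vif)
        assert fit.ki == 0 and fit.vp == 0
        assert fit.flag == "zero-variance-y"
        assert np.isnan(fit.r_squared)

    def test_pure_intravascular_voxel(self, vif):
        fit = sb.patlak_fit(0.05 * vif.cp, vif)
        assert abs(fit.ki) < 1e-12
        assert abs(fit.vp - 0.05) < 1e-12
        assert fit.flag == "zero-variance-y"

    def test_too_few_usable_frames_rejected(self):
        t = np.arange(5, dtype=float)
        vif = InputFunction(times=t, cp=np.array([0, 0, 0, 1.0, 1.0]))
        with pytest.raises(FitError):
            sb.patlak_fit(np.zeros(5), vif, fit_start=3)

    def test_degenerate_constant_abscissa_rejected(self):
        # crafted so the Patlak abscissa is identical on every usable frame
        t = np.arange(4, dtype=float)
        vif = InputFunction(times=t, cp=np.array([2.0, 2.0, 6.0, 18.0]))
        with pytest.raises(FitError, match="zero-variance"):
            sb.patlak_fit(np.ones(4), vif, fit_start=1, cp_floor=0.0)

    def test_estimate_monotone_in_true_ki(self, vif):
        estimates = []
        for ki in (0.002, 0.005, 0.01, 0.015, 0.02):
            ct = sb.simulate_tissue_curve(vif, ki, 0.03)
            estimates.append(sb.patlak_fit(ct, vif).ki)
        assert np.all(np.diff(estimates) > 0)


class TestComputeKpsMap:
    def test_phantom_roi_means_exact(self, phantom_nf, kps_map_nf):
        truth = phantom_nf.truth
        lesion = truth.lesion_mask
        bg = truth.brain_mask & ~lesion & ~truth.sinus_mask
        assert abs(np.nanmean(kps_map_nf.values[lesion]) - 1.0) < 1e-6
        assert abs(np.nanmean(kps_map_nf.values[bg]) - 0.5) < 1e-6

    def test_vp_map_recovered(self, phantom_nf, kps_map_nf):
        truth = phantom_nf.truth
        tissue = truth.brain_mask & ~truth.sinus_mask
        assert abs(np.nanmean(kps_map_nf.vp[tissue]) - 0.03) < 1e-6

    def test_unit_conversion_scale(self, vif, acq, conv):
        # ki = 0.0072 min^-1 with unit density -> 0.72 mL/100 g/min
        ct = sb.simulate_tissue_curve(vif, 0.0072, 0.03)
        fit = sb.patlak_fit(ct, vif)
        kps = fit.ki * 100.0 / conv.tissue_density
        assert abs(kps - 0.72) < 1e-6


class TestSummarizePatient:
    def _maps(self, values, shape=(10, 10, 4)):
        arr = np.full(shape, float(values))
        return KpsMap(values=arr, vp=np.zeros(shape),
                      r_squared=np.zeros(shape), affine=np.eye(4))

    def test_identical_rois_give_unit_ratio(self):
        shape = (10, 10, 4)
        lesion = np.zeros(shape, bool)
        contra = np.zeros(shape, bool)
        lesion[1:3, 2:4, 1] = True
        contra[7:9, 2:4, 1] = True
        adc = AdcMap(values=np.full(shape, 8e-4), affine=np.eye(4))
        rois = RoiPair(lesion_mask=lesion, contralateral_mask=contra,
                       voxel_volume=20.0)
        rec = sb.summarize_patient(self._maps(0.6), adc, rois)
        assert rec["kps_ratio"] == 1.0

    def test_lesion_volume_arithmetic(self):
        shape = (10, 10, 10)
        lesion = np.zeros(shape, bool)
        lesion.flat[:100] = True
        contra = np.zeros(shape, bool)
        contra.flat[-100:] = True
        rois = RoiPair(lesion_mask=lesion, contralateral_mask=contra,
                       voxel_volume=2 * 2 * 5.0)
        rec = sb.summarize_patient(
            self._maps(1.0, shape),
            AdcMap(values=np.ones(shape), affine=np.eye(4)), rois)
        assert rec["lesion_volume_cm3"] == 2.0

    def test_phantom_truth_ratio(self, phantom_nf, kps_map_nf, adc_map_nf):
        pair = sb.mirror_contralateral(phantom_nf.truth.lesion_mask)
        rec = sb.summarize_patient(kps_map_nf, adc_map_nf, pair)
        assert abs(rec["kps_ratio"] - 2.0) < 1e-6
        assert abs(rec["adc_i"] - 6.0e-4) < 1e-12
        assert abs(rec["adc_c"] - 8.5e-4) < 1e-12

    def test_nonpositive_contralateral_flagged(self):
        shape = (10, 10, 4)
        lesion = np.zeros(shape, bool)
        contra = np.zeros(shape, bool)
        lesion[1:3, 1:3, 1] = True
        contra[7:9, 1:3, 1] = True
        kps = self._maps(0.5)
        kps.values[contra] = 0.0
        rois = RoiPair(lesion_mask=lesion, contralateral_mask=contra,
                       voxel_volume=10.0)
        rec = sb.summarize_patient(
            kps, AdcMap(values=np.ones(shape), affine=np.eye(4)), rois)
        assert np.isnan(rec["kps_ratio"])
        assert "nonpositive-contralateral-kps" in rec["flags"]
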