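"""Patlak permeability estimation from dynamic contrast-enhanced MRI.

The unidirectional two-compartment model linearizes as

    C_t(t) / C_p(t) = Ki * [int_0^t C_p dtau] / C_p(t) + v_p

so an ordinary least-squares line through (x, y) with
x = cumulative integral of the input function over its instantaneous
value and y = tissue-to-plasma concentration ratio yields the influx
constant Ki (slope) and the plasma volume fraction v_p (intercept).
Ki is reported as the permeability-surface-area product
KPS = Ki[min^-1] * 100 / density in mL/100 g/min.

Signal is converted to concentration by inverting the SPGR equation at
an assumed fixed T1 (blood 800 ms; tissue configurable), with the
unenhanced baseline estimated from the pre-bolus frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import AdcMap, DceSeries, InputFunction, KpsMap, PatlakFit, RoiPair
from .errors import FitError, GeometryError, ParameterError
from .params import AcquisitionParams, ConversionParams
from .spgr import baseline_factor, spgr_invert


# --------------------------------------------------------------------------
# signal <-> concentration
# --------------------------------------------------------------------------

def signal_to_concentration(signal, conv: ConversionParams,
                            acq: AcquisitionParams,
                            t1_ms: float | None = None) -> np.ndarray:
    """Convert SPGR signal time courses to concentration (mM).

    Works on any array whose last axis is time.  The pre-contrast
    baseline is the mean of the first ``conv.baseline_frames`` frames;
    the effective proton-density scale follows from the baseline and the
    assumed T1.  Inversion negatives (noise) are clamped to 0; signals
    outside the invertible SPGR range are clamped to the range edge.
    ``conv.signal_model='linear'`` uses the relative-enhancement
    shortcut dR1 = R10 * (S - S0)/S0 instead of the full inversion.
    """
    signal = np.asarray(signal, dtype=float)
    t1 = conv.t1_tissue if t1_ms is None else t1_ms
    if signal.shape[-1] < conv.baseline_frames:
        raise ParameterError("fewer frames than baseline_frames")
    baseline = signal[..., : conv.baseline_frames].mean(axis=-1, keepdims=True)
    r10 = 1000.0 / t1

    if conv.signal_model == "linear":
        with np.errstate(divide="ignore", invalid="ignore"):
            d_r1 = r10 * (signal - baseline) / baseline
        conc = d_r1 / conv.relaxivity_r1
        return np.maximum(np.nan_to_num(conc), 0.0)

    s0_eff = baseline / baseline_factor(t1, acq.repetition_time,
                                        acq.flip_angle)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1, _clamped = spgr_invert(signal, s0_eff, acq.repetition_time,
                                   acq.flip_angle)
    conc = (r1 - r10) / conv.relaxivity_r1
    return np.maximum(np.nan_to_num(conc), 0.0)


def extract_vif(dce: DceSeries, sinus_mask: np.ndarray,
                conv: ConversionParams) -> InputFunction:
    """Venous input function from the sagittal-sinus ROI.

    Mean sinus signal per frame -> SPGR inversion at the fixed blood T1
    (800 ms by default) -> whole-blood concentration -> plasma
    concentration via division by (1 - hematocrit).  A flat curve (peak
    enhancement below 3 baseline SDs) is returned with a warning status
    rather than an error.
    """
    sinus_mask = np.asarray(sinus_mask, dtype=bool)
    if sinus_mask.shape != dce.shape3d:
        raise GeometryError("sinus mask does not match the DCE grid")
    if not sinus_mask.any():
        raise ParameterError("sinus mask is empty")
    ts = dce.signal[sinus_mask].mean(axis=0)
    cb = signal_to_concentration(ts, conv, dce.acq, t1_ms=conv.t1_blood)
    cp = cb / (1.0 - conv.hematocrit)

    base = ts[: conv.baseline_frames]
    status = "ok"
    peak_rise = ts.max() - base.mean()
    if peak_rise < 3.0 * max(base.std(), np.finfo(float).tiny):
        status = "no-bolus-detected"
        warnings.warn("sinus curve shows no bolus (peak < 3 baseline SD)",
                      RuntimeWarning)
    return InputFunction(times=dce.frame_times, cp=cp, status=status)


# --------------------------------------------------------------------------
# Patlak regression
# --------------------------------------------------------------------------

def detect_fit_start(vif: InputFunction, baseline_frames: int = 5) -> int:
    """First frame where the input function exceeds baseline + 3 SD.

    Ties (several equal threshold crossings) resolve to the later frame
    by construction of the scan; falls back to the frame after the
    baseline block if nothing crosses.
    """
    base = vif.cp[:baseline_frames]
    thr = base.mean() + 3.0 * base.std()
    above = np.nonzero(vif.cp > max(thr, 0.0))[0]
    above = above[above >= 1]
    if above.size == 0:
        return int(baseline_frames)
    return int(above[0])


def _patlak_design(vif: InputFunction, fit_start: int, cp_floor: float):
    cp = vif.cp
    integral = cumulative_trapezoid(cp, vif.times, initial=0.0)
    usable = (np.arange(cp.size) >= fit_start) & (cp > cp_floor)
    return integral, usable


def patlak_fit(ct: np.ndarray, vif: InputFunction,
               fit_start: int | None = None,
               cp_floor: float | None = None) -> PatlakFit:
    """Fit the Patlak line to one tissue concentration curve.

    Frames before ``fit_start`` (bolus arrival, auto-detected when None)
    or with input concentration at/below ``cp_floor`` (default 0.1% of
    the peak) are excluded.  Requires >= 3 usable frames and a
    non-degenerate abscissa.
    """
    ct = np.asarray(ct, dtype=float)
    if ct.shape != vif.cp.shape:
        raise GeometryError("tissue curve and input function grids differ")
    if fit_start is None:
        fit_start = detect_fit_start(vif)
    if cp_floor is None:
        cp_floor = 1e-3 * float(vif.cp.max())
    integral, usable = _patlak_design(vif, fit_start, cp_floor)
    n = int(usable.sum())
    if n < 3:
        raise FitError(f"only {n} usable frames (>= 3 required)")
    x = integral[usable] / vif.cp[usable]
    y = ct[usable] / vif.cp[usable]
    xm = x.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx <= 0:
        raise FitError("zero-variance Patlak abscissa")
    slope = float(np.sum((x - xm) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xm)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # rounding noise on an exactly-constant response is ~eps relative
    y_scale = max(1.0, float(np.abs(y).max()))
    tol = n * (10 * np.finfo(float).eps * y_scale) ** 2
    if ss_tot <= tol:
        r2, flag = float("nan"), "zero-variance-y"
    else:
        r2, flag = 1.0 - float(np.sum(resid ** 2)) / ss_tot, ""
    return PatlakFit(ki=slope * 60.0, vp=intercept, r_squared=r2,
                     n_points=n, flag=flag)


def compute_kps_map(dce: DceSeries, vif: InputFunction,
                    brain_mask: np.ndarray,
                    conv: ConversionParams | None = None,
                    fit_start: int | None = None) -> KpsMap:
    """Pixel-by-pixel Patlak mapping over the brain mask.

    Each masked voxel's signal is converted to concentration at the
    tissue T1 and regressed against the shared input function (one
    design matrix, solved for all voxels at once).  Failed voxels (non
    finite response) become NaN and are counted; negative slopes are
    retained, not clamped, and counted separately.
    """
    conv = conv or ConversionParams()
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != dce.shape3d:
        raise GeometryError("brain mask does not match the DCE grid")
    if not brain_mask.any():
        raise ParameterError("brain mask is empty")
    if fit_start is None:
        fit_start = detect_fit_start(vif, conv.baseline_frames)
    cp_floor = 1e-3 * float(vif.cp.max())
    integral, usable = _patlak_design(vif, fit_start, cp_floor)
    if int(usable.sum()) < 3:
        raise FitError("fewer than 3 usable frames in the input function")

    conc = signal_to_concentration(dce.signal[brain_mask], conv, dce.acq)
    cp_u = vif.cp[usable]
    x = integral[usable] / cp_u
    design = np.column_stack([x, np.ones_like(x)])  # (n_used, 2)
    y = conc[:, usable] / cp_u[None, :]             # (nvox, n_used)

    bad = ~np.all(np.isfinite(y), axis=1)
    y_fit = np.where(np.isfinite(y), y, 0.0)
    beta, *_ = np.linalg.lstsq(design, y_fit.T, rcond=None)
    slope, intercept = beta[0], beta[1]
    resid = y_fit - (design @ beta).T
    ss_res = np.sum(resid ** 2, axis=1)
    ss_tot = np.sum((y_fit - y_fit.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)

    kps_vox = slope * 60.0 * 100.0 / conv.tissue_density
    kps_vox[bad] = np.nan
    intercept = np.where(bad, np.nan, intercept)

    shape = dce.shape3d
    kps = np.full(shape, np.nan)
    vp = np.full(shape, np.nan)
    r2_map = np.full(shape, np.nan)
    kps[brain_mask] = kps_vox
    vp[brain_mask] = intercept
    r2_map[brain_mask] = r2
    return KpsMap(values=kps, vp=vp, r_squared=r2_map, affine=dce.affine,
                  n_failed=int(bad.sum()),
                  n_negative=int(np.sum(kps_vox[~bad] < 0)))


# --------------------------------------------------------------------------
# per-patient summary
# --------------------------------------------------------------------------

def summarize_patient(kps: KpsMap, adc: AdcMap, rois: RoiPair) -> dict:
    """ROI means feeding the cohort table.

    Returns infarct and contralateral KPS means, their ratio KPS_i/c,
    the corresponding ADC means (excluding QC-invalid voxels) and the
    lesion volume in cm^3.  A non-positive contralateral KPS leaves the
    ratio NaN with a flag; a majority of failed voxels in either ROI is
    an error.
    """
    out = {}
    flags = []
    for name, mask in (("i", rois.lesion_mask), ("c", rois.contralateral_mask)):
        vals = kps.values[mask]
        n_bad = int(np.sum(~np.isfinite(vals)))
        if n_bad * 2 > vals.size:
            raise FitError(f"majority of failed KPS voxels in ROI '{name}'")
        out[f"kps_{name}"] = float(np.nanmean(vals))
        adc_vals = adc.values[mask & ~adc.invalid_mask]
        out[f"adc_{name}"] = float(adc_vals.mean()) if adc_vals.size else float("nan")
    if out["kps_c"] > 0:
        out["kps_ratio"] = out["kps_i"] / out["kps_c"]
    else:
        out["kps_ratio"] = float("nan")
        flags.append("nonpositive-contralateral-kps")
    out["lesion_volume_cm3"] = float(
        rois.lesion_mask.sum() * rois.voxel_volume / 1000.0)
    out["flags"] = flags
    return out
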