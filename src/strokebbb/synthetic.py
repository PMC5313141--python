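"""Digital DCE/DWI stroke phantom with known pharmacokinetic ground truth.

The phantom is the test substrate for the whole pipeline: an ellipsoidal
"brain" on a 64x64x16 grid containing a spherical ischemic lesion (low
ADC, elevated permeability), a small sagittal-sinus slab near the
posterior midline that carries the blood signal, and surrounding
background.  Tissue curves follow the unidirectional two-compartment
model

    C_t(t) = Ki * int_0^t C_p(tau) dtau + v_p * C_p(t)

driven by a gamma-variate plasma input function, and are converted to
dynamic SPGR signal at the acquisition parameters.  The DWI pair obeys
S_b = S0 * exp(-b * ADC).  All randomness is drawn from a generator
seeded in :class:`PhantomTruth`, so phantoms are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import DceSeries, DwiPair, InputFunction
from .errors import GeometryError, ParameterError
from .params import AcquisitionParams, ConversionParams, VifParams
from .spgr import spgr_signal


# --------------------------------------------------------------------------
# forward curve models
# --------------------------------------------------------------------------

def generate_vif(params: VifParams, acq: AcquisitionParams) -> InputFunction:
    """Evaluate the bolus model on the DCE frame grid.

    The first pass is a mode-normalised gamma-variate peaking at
    ``arrival_time + shape_alpha * timescale_tau`` with peak value
    ``amplitude``; recirculation adds a plateau rising on the bolus
    timescale and decaying with ``washout_timescale``.  Concentration is
    identically zero before arrival.
    """
    t = acq.frame_times
    tp = params.shape_alpha * params.timescale_tau  # time-to-peak after arrival
    ts = t - params.arrival_time
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(ts > 0, ts / tp, 0.0)
        first_pass = np.where(
            ts > 0,
            params.amplitude * rel ** params.shape_alpha
            * np.exp(params.shape_alpha * (1.0 - rel)),
            0.0,
        )
        recirc = np.where(
            ts > 0,
            params.recirculation_fraction * params.amplitude
            * (1.0 - np.exp(-np.maximum(ts, 0.0) / tp))
            * np.exp(-np.maximum(ts, 0.0) / params.washout_timescale),
            0.0,
        )
    cp = first_pass + recirc
    return InputFunction(times=t, cp=cp)


def simulate_tissue_curve(vif: InputFunction, ki: float, vp: float) -> np.ndarray:
    """Tissue concentration (mM) for influx ``ki`` (min^-1) and plasma
    fraction ``vp`` under the unidirectional two-compartment model.

    The running integral of the input function uses the trapezoid rule on
    the frame grid, matching the discretisation of the Patlak estimator,
    so noise-free round trips are exact.
    """
    if ki < 0:
        raise ParameterError("ki must be >= 0")
    if not 0 <= vp < 1:
        raise ParameterError("vp must lie in [0, 1)")
    ki_per_s = ki / 60.0
    integral = cumulative_trapezoid(vif.cp, vif.times, initial=0.0)
    return ki_per_s * integral + vp * vif.cp


def concentration_to_signal(conc, t10_ms: float, r1: float,
                            acq: AcquisitionParams, s0: float = 1000.0):
    """Forward SPGR signal for a concentration time course.

    R1(t) = 1/T10 + r1 * C(t); linear relaxivity, fast-exchange regime.
    """
    if t10_ms <= 0 or r1 <= 0:
        raise ParameterError("t10 and r1 must be > 0")
    r1_t = 1000.0 / t10_ms + r1 * np.asarray(conc, dtype=float)
    return spgr_signal(r1_t, s0, acq.repetition_time, acq.flip_angle)


# --------------------------------------------------------------------------
# phantom geometry and ground truth
# --------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground-truth parameter maps and geometry of a digital phantom."""

    kps_true: np.ndarray      # mL/100 g/min
    vp_true: np.ndarray       # plasma volume fraction
    adc_true: np.ndarray      # mm^2/s
    lesion_mask: np.ndarray
    sinus_mask: np.ndarray
    brain_mask: np.ndarray
    affine: np.ndarray
    noise_sigma: float = 0.0
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        for name in ("lesion_mask", "sinus_mask", "brain_mask"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shapes = {self.kps_true.shape, self.vp_true.shape, self.adc_true.shape,
                  self.lesion_mask.shape, self.sinus_mask.shape,
                  self.brain_mask.shape}
        if len(shapes) != 1:
            raise GeometryError("truth maps and masks disagree in shape")
        if np.any(self.kps_true < 0):
            raise ParameterError("kps_true must be >= 0")
        if np.any((self.vp_true < 0) | (self.vp_true >= 1)):
            raise ParameterError("vp_true must lie in [0, 1)")
        if np.any(self.adc_true[self.brain_mask] <= 0):
            raise ParameterError("adc_true must be > 0 within the brain")
        if np.any(self.lesion_mask & ~self.brain_mask):
            raise GeometryError("lesion_mask must lie inside brain_mask")
        if np.any(self.sinus_mask & self.lesion_mask):
            raise GeometryError("sinus and lesion masks overlap")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    @property
    def shape(self):
        return self.kps_true.shape


def default_affine(shape, voxel_size) -> np.ndarray:
    """Axis-aligned RAS affine with the world origin at the grid centre."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    centre = (np.asarray(shape) - 1) / 2.0
    aff[:3, 3] = -centre * np.asarray(voxel_size, dtype=float)
    return aff


def default_phantom_truth(
    shape=(64, 64, 16),
    voxel_size=(3.75, 3.75, 5.0),
    lesion_kps: float = 1.0,
    background_kps: float = 0.5,
    lesion_adc: float = 6.0e-4,
    background_adc: float = 8.5e-4,
    blood_adc: float = 3.0e-3,
    vp: float = 0.03,
    blood_vp: float = 0.95,
    lesion_radius_vox: float = 5.0,
    lesion_offset_vox: float = 10.0,
    noise_sigma: float = 0.0,
    s0: float = 1000.0,
    seed: int = 0,
) -> PhantomTruth:
    """Single spherical lesion plus sinus slab in an ellipsoidal brain.

    The lesion is centred ``lesion_offset_vox`` voxels off the midline
    along the left-right axis (axis 0), so mirroring across the
    midsagittal plane lands in normal tissue.  Defaults give ADC and KPS
    contrasts at the magnitudes seen in acute ischemic stroke (lesion
    ADC ~6e-4 vs contralateral ~8.5e-4 mm^2/s; lesion permeability about
    twice the contralateral value).
    """
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")

    brain = (((ix - cx) / (0.42 * nx)) ** 2
             + ((iy - cy) / (0.45 * ny)) ** 2
             + ((iz - cz) / (0.45 * nz)) ** 2) <= 1.0

    lesion = (((ix - (cx + lesion_offset_vox)) ** 2
               + (iy - cy) ** 2 + (iz - cz) ** 2)
              <= lesion_radius_vox ** 2) & brain

    sinus = ((np.abs(ix - cx) <= 1.0)
             & (iy - cy >= 0.30 * ny) & (iy - cy <= 0.30 * ny + 3)
             & (np.abs(iz - cz) <= 2.0)) & brain
    if not sinus.any():
        raise GeometryError("sinus slab fell outside the brain ellipsoid")

    kps = np.zeros(shape)
    kps[brain] = background_kps
    kps[lesion] = lesion_kps
    kps[sinus] = 0.0

    vp_map = np.zeros(shape)
    vp_map[brain] = vp
    vp_map[sinus] = blood_vp  # informational; sinus voxels carry blood signal

    adc = np.full(shape, background_adc)
    adc[lesion] = lesion_adc
    adc[sinus] = blood_adc

    return PhantomTruth(
        kps_true=kps, vp_true=vp_map, adc_true=adc,
        lesion_mask=lesion, sinus_mask=sinus, brain_mask=brain,
        affine=default_affine(shape, voxel_size),
        noise_sigma=noise_sigma, s0=s0, seed=seed,
    )


@dataclass
class Phantom:
    """A generated phantom: dynamic series, DWI pair, truth and VIF."""

    dce: DceSeries
    dwi: DwiPair
    truth: PhantomTruth
    vif_true: InputFunction
    b_value: float = 1000.0


def generate_phantom(
    truth: PhantomTruth,
    vif_params: VifParams | None = None,
    acq: AcquisitionParams | None = None,
    conv: ConversionParams | None = None,
    b_value: float = 1000.0,
    out_dir=None,
) -> Phantom:
    """Render a phantom's ground truth into DCE signal and a DWI pair.

    Sinus voxels carry whole-blood signal at T1 = 800 ms (blood
    concentration = (1 - Hct) * C_p); tissue voxels carry the forward
    two-compartment signal at the tissue T1 from ``conv``.  Additive
    Gaussian noise with ``truth.noise_sigma`` is applied to every volume;
    all draws come from ``default_rng(truth.seed)`` so identical truth
    yields bit-identical output.
    """
    vif_params = vif_params or VifParams()
    acq = acq or AcquisitionParams()
    conv = conv or ConversionParams()
    rng = np.random.default_rng(truth.seed)

    vif = generate_vif(vif_params, acq)
    cp = vif.cp
    integral = cumulative_trapezoid(cp, vif.times, initial=0.0)

    tissue = truth.brain_mask & ~truth.sinus_mask
    ki_per_s = truth.kps_true * conv.tissue_density / 100.0 / 60.0

    shape4 = truth.shape + (acq.n_frames,)
    conc = np.zeros(shape4)
    conc[tissue] = (ki_per_s[tissue, None] * integral[None, :]
                    + truth.vp_true[tissue, None] * cp[None, :])
    conc[truth.sinus_mask] = (1.0 - conv.hematocrit) * cp[None, :]

    # smooth proton-density texture: parenchyma is not uniform, and the
    # MI registration metric needs intensity structure away from edges.
    # The per-voxel scale cancels exactly in the ADC log-ratio and in the
    # baseline-normalised signal-to-concentration inversion, so it does
    # not perturb parameter recovery.
    from scipy.ndimage import gaussian_filter

    texture = gaussian_filter(rng.normal(0.0, 1.0, truth.shape), sigma=2.5)
    texture = 1.0 + 0.15 * texture / max(np.abs(texture).max(), 1e-12)

    signal = np.zeros(shape4)
    signal[tissue] = concentration_to_signal(
        conc[tissue], conv.t1_tissue, conv.relaxivity_r1, acq, truth.s0)
    signal[truth.sinus_mask] = concentration_to_signal(
        conc[truth.sinus_mask], conv.t1_blood, conv.relaxivity_r1, acq, truth.s0)
    signal *= texture[..., None]

    s0_dwi = np.where(truth.brain_mask, truth.s0 * texture, 0.0)
    sb_dwi = s0_dwi * np.exp(-b_value * truth.adc_true)

    if truth.noise_sigma > 0:
        signal = signal + rng.normal(0.0, truth.noise_sigma, shape4)
        s0_dwi = s0_dwi + rng.normal(0.0, truth.noise_sigma, truth.shape)
        sb_dwi = sb_dwi + rng.normal(0.0, truth.noise_sigma, truth.shape)

    phantom = Phantom(
        dce=DceSeries(signal=signal, acq=acq, affine=truth.affine),
        dwi=DwiPair(s0_volume=s0_dwi, sb_volume=sb_dwi,
                    affine=truth.affine, b_values=(0.0, b_value)),
        truth=truth,
        vif_true=vif,
        b_value=b_value,
    )
    if out_dir is not None:
        write_phantom(phantom, vif_params, acq, conv, out_dir)
    return phantom


def write_phantom(phantom: Phantom, vif_params, acq, conv, out_dir) -> Path:
    """Serialize a phantom: NIfTI volumes plus a JSON sidecar of scalars."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = phantom.truth
    aff = t.affine
    _io.save_nifti(phantom.dce.signal, aff, out / "dce.nii")
    _io.save_nifti(phantom.dwi.s0_volume, aff, out / "dwi_b0.nii")
    _io.save_nifti(phantom.dwi.sb_volume, aff, out / "dwi_b1000.nii")
    for name in ("lesion_mask", "sinus_mask", "brain_mask"):
        _io.save_nifti(getattr(t, name).astype(np.uint8), aff, out / f"{name}.nii")
    _io.save_nifti(t.kps_true, aff, out / "kps_true.nii")
    _io.save_nifti(t.vp_true, aff, out / "vp_true.nii")
    _io.save_nifti(t.adc_true, aff, out / "adc_true.nii")
    sidecar = {
        "seed": t.seed,
        "noise_sigma": t.noise_sigma,
        "s0": t.s0,
        "b_value": phantom.b_value,
        "acquisition": {
            "repetition_time": acq.repetition_time,
            "echo_time": acq.echo_time,
            "flip_angle": acq.flip_angle,
            "frame_interval": acq.frame_interval,
            "n_frames": acq.n_frames,
            "voxel_size": list(acq.voxel_size),
        },
        "vif": {
            "arrival_time": vif_params.arrival_time,
            "amplitude": vif_params.amplitude,
            "shape_alpha": vif_params.shape_alpha,
            "timescale_tau": vif_params.timescale_tau,
            "recirculation_fraction": vif_params.recirculation_fraction,
            "washout_timescale": vif_params.washout_timescale,
        },
        "conversion": {
            "t1_blood": conv.t1_blood,
            "t1_tissue": conv.t1_tissue,
            "relaxivity_r1": conv.relaxivity_r1,
            "baseline_frames": conv.baseline_frames,
            "hematocrit": conv.hematocrit,
            "tissue_density": conv.tissue_density,
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def snr_to_sigma(snr: float, conv: ConversionParams | None = None,
                 acq: AcquisitionParams | None = None,
                 s0: float = 1000.0) -> float:
    """Noise SD giving the requested SNR on the baseline tissue signal."""
    from .spgr import baseline_factor

    conv = conv or ConversionParams()
    acq = acq or AcquisitionParams()
    if snr <= 0:
        raise ParameterError("snr must be > 0")
    return s0 * baseline_factor(conv.t1_tissue, acq.repetition_time,
                                acq.flip_angle) / snr
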