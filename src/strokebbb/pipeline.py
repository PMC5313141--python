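"""End-to-end orchestration: phantom -> ADC -> registration -> KPS -> stats.

A run is described by a single YAML config (CLI flags override).  Every
output directory receives a provenance JSON — config, seeds, package
version and per-stage QC counters — sufficient to reproduce the run
exactly; no timestamps are recorded so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as _io
from .adc import compute_adc, mirror_contralateral, segment_lesion
from .cohort import CohortSpec, default_cohort_spec, generate_cohort
from .cohort_stats import assign_phase, run_primary_and_secondary_analysis, split_ht
from .core import DceSeries, DwiPair
from .errors import StageError, StrokeBbbError
from .params import (AcquisitionParams, ConversionParams, RegistrationConfig,
                     SegmentationParams, VifParams)
from .patlak import compute_kps_map, extract_vif, summarize_patient
from .registration import register_affine, resample
from .synthetic import default_phantom_truth, generate_phantom


@dataclass
class RunConfig:
    """Run description; every field has a working default."""

    seed: int = 0
    out_dir: str = "out"
    acquisition: dict = field(default_factory=dict)
    vif: dict = field(default_factory=dict)
    conversion: dict = field(default_factory=dict)
    registration: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # paths for real-data runs
    do_registration: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise StrokeBbbError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    # typed views -----------------------------------------------------------
    def acq(self) -> AcquisitionParams:
        kw = dict(self.acquisition)
        if "voxel_size" in kw:
            kw["voxel_size"] = tuple(kw["voxel_size"])
        return AcquisitionParams(**kw)

    def vif_params(self) -> VifParams:
        return VifParams(**self.vif)

    def conv(self) -> ConversionParams:
        return ConversionParams(**self.conversion)

    def reg_config(self) -> RegistrationConfig:
        return RegistrationConfig(**self.registration)

    def seg_params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_json(obj, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def _load_inputs(config: RunConfig):
    """Phantom simulation or file loading, per config."""
    acq = config.acq()
    conv = config.conv()
    if config.inputs:
        paths = config.inputs
        for key in ("dce", "dwi_b0", "dwi_b1000", "brain_mask"):
            if key not in paths:
                raise StrokeBbbError(f"inputs section lacks '{key}'")
        dce_data, dce_aff = _io.load_nifti(paths["dce"])
        b0, dwi_aff = _io.load_nifti(paths["dwi_b0"])
        b1000, _ = _io.load_nifti(paths["dwi_b1000"])
        brain, _ = _io.load_mask(paths["brain_mask"])
        sinus = None
        if paths.get("sinus_mask"):
            sinus, _ = _io.load_mask(paths["sinus_mask"])
        dce = DceSeries(signal=dce_data, acq=acq, affine=dce_aff)
        dwi = DwiPair(s0_volume=b0, sb_volume=b1000, affine=dwi_aff,
                      b_values=(0.0, float(paths.get("b_value", 1000.0))))
        return dce, dwi, brain, sinus, None

    kw = dict(config.phantom)
    kw.setdefault("seed", config.seed)
    truth = default_phantom_truth(**kw)
    phantom = generate_phantom(truth, config.vif_params(), acq, conv)
    return (phantom.dce, phantom.dwi, truth.brain_mask, truth.sinus_mask,
            phantom)


def run_patient_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Single-subject run: DWI/DCE to a per-patient summary record.

    Executes ADC mapping, lesion segmentation and mirroring, DWI->DCE
    MI registration, ROI transfer, VIF extraction, pixel-wise Patlak
    mapping and ROI summarisation.  Artifacts (maps, masks, summary and
    provenance JSON) are written under ``out_dir``; any stage failure
    raises :class:`StageError` naming the stage.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    conv = config.conv()
    qc = {}

    with _stage("load-inputs"):
        dce, dwi, brain_mask, sinus_mask, phantom = _load_inputs(config)

    with _stage("adc-mapping"):
        adc = compute_adc(dwi, brain_mask)
        qc["adc_excluded_voxels"] = adc.n_excluded

    with _stage("lesion-segmentation"):
        seg = segment_lesion(adc, brain_mask, params=config.seg_params())
        qc["lesion_voxels"] = int(seg.mask.sum())
        qc["lesion_empty"] = bool(seg.empty)

    with _stage("contralateral-mirroring"):
        voxel = config.acq().voxel_size
        rois = mirror_contralateral(seg.mask, voxel_size=voxel)

    with _stage("registration"):
        if config.do_registration:
            frame0 = dce.signal[..., 0]
            reg = register_affine(dwi.s0_volume, dwi.affine, frame0,
                                  dce.affine, config.reg_config())
            transform = reg.transform
            qc["registration_mi_bits"] = reg.mi_bits
            qc["registration_converged"] = bool(reg.converged)
        else:
            from .core import AffineTransform
            transform = AffineTransform.identity()

    with _stage("roi-transfer"):
        # ROIs live in DWI space; the registration transform maps DCE
        # coordinates into DWI space, so pulling the masks through it
        # lands them on the DCE grid.
        lesion_dce = resample(rois.lesion_mask, dwi.affine, transform,
                              dce.shape3d, dce.affine, is_mask=True)
        contra_dce = resample(rois.contralateral_mask, dwi.affine, transform,
                              dce.shape3d, dce.affine, is_mask=True)
        from .core import RoiPair
        rois_dce = RoiPair(lesion_mask=lesion_dce,
                           contralateral_mask=contra_dce,
                           voxel_volume=rois.voxel_volume)

    with _stage("input-function"):
        if sinus_mask is None:
            raise StrokeBbbError("no sinus mask available for VIF extraction")
        vif = extract_vif(dce, sinus_mask, conv)
        qc["vif_status"] = vif.status

    with _stage("kps-mapping"):
        kps = compute_kps_map(dce, vif, brain_mask, conv)
        qc["kps_failed_voxels"] = kps.n_failed
        qc["kps_negative_voxels"] = kps.n_negative

    with _stage("summary"):
        record = summarize_patient(kps, adc, rois_dce)

    out.mkdir(parents=True, exist_ok=True)
    _io.save_nifti(adc.values, adc.affine, out / "adc.nii")
    _io.save_nifti(rois.lesion_mask.astype(np.uint8), adc.affine,
                   out / "lesion_mask.nii")
    _io.save_nifti(rois.contralateral_mask.astype(np.uint8), adc.affine,
                   out / "contralateral_mask.nii")
    _io.save_nifti(kps.values, kps.affine, out / "kps.nii")
    _io.save_nifti(kps.vp, kps.affine, out / "vp.nii")
    _io.save_nifti(kps.r_squared, kps.affine, out / "r_squared.nii")
    transform.to_json(out / "transform.json")
    _write_json(record, out / "summary.json")
    _write_json({
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "qc": qc,
    }, out / "provenance.json")
    return record


def cohort_spec_from_config(config: RunConfig) -> CohortSpec:
    kw = dict(config.cohort)
    kw.setdefault("seed", config.seed)
    include_ht = bool(kw.pop("include_ht", False))
    overrides = {k: kw.pop(k) for k in ("pair_correlation",) if k in kw}
    if kw.keys() - {"seed"}:
        raise StrokeBbbError(
            f"unsupported cohort config keys: {sorted(kw.keys() - {'seed'})}")
    spec = default_cohort_spec(seed=kw["seed"], include_ht=include_ht)
    if overrides:
        from dataclasses import replace
        spec = replace(spec, **overrides)
    return spec


def run_cohort_pipeline(config: RunConfig, table_path=None,
                        column_map=None, out_dir=None) -> dict:
    """Cohort-level run: table -> phase assignment -> HT split -> stats.

    Reads a cohort table when ``table_path`` is given, otherwise
    generates one from the config's cohort spec.  Writes summary CSVs,
    the full statistics JSON and a provenance record; returns the
    statistics dictionary.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)

    with _stage("cohort-table"):
        if table_path is not None:
            df = _io.read_cohort_table(table_path, column_map)
        else:
            df = generate_cohort(cohort_spec_from_config(config))
        if len(df) == 0:
            raise StrokeBbbError("cohort table is empty")
        df = df.assign(phase=assign_phase(df["onset_to_scan_hr"].to_numpy()))

    with _stage("ht-split"):
        ht_df, non_ht = split_ht(df)

    with _stage("statistics"):
        result = run_primary_and_secondary_analysis(non_ht, drop_ht=False)

    stats_dict = result.to_dict()
    stats_dict["ht_subgroup"] = {
        "n": int(len(ht_df)),
        "kps_i_mean": float(ht_df["kps_i"].mean()) if len(ht_df) else None,
        "kps_ratio_mean": float(ht_df["kps_ratio"].mean())
        if len(ht_df) else None,
    }

    out.mkdir(parents=True, exist_ok=True)
    _io.write_cohort_table(df, out / "cohort.csv")
    for name, tbl in result.tables.items():
        tbl.to_csv(out / f"table_{name}.csv", index=False)
    _write_json(stats_dict, out / "statistics.json")
    _write_json({
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "n_patients": int(len(df)),
    }, out / "provenance.json")
    return stats_dict
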