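"""NIfTI and cohort-table input/output.

Volumes travel as NIfTI-1 (4D for the dynamic series, uint8 for masks).
Cohort tables are CSV canonically, with XLSX read/write mirroring the
role of a supplementary per-patient measurement workbook; an optional
column map (YAML/dict) renames externally named columns onto the
canonical schema before validation.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .errors import SchemaError

#: columns that must be present for the statistical analysis
REQUIRED_COLUMNS = ["patient_id", "onset_to_scan_hr", "ht_flag",
                    "kps_i", "kps_c"]


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def load_nifti(path):
    """Return (data, affine) as float64/float64 arrays."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine, dtype=float)


def load_mask(path):
    data, affine = load_nifti(path)
    return data > 0.5, affine


def write_cohort_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


def read_cohort_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a cohort table (CSV or XLSX) onto the canonical schema.

    ``column_map`` maps source column names to canonical ones
    (``{"KPS infarct": "kps_i", ...}``).  Missing required columns raise
    :class:`SchemaError` listing every unmatched name.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    if "ht_flag" in df.columns:
        df["ht_flag"] = df["ht_flag"].astype(bool)
    if "kps_ratio" not in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = df["kps_i"] / df["kps_c"]
        df["kps_ratio"] = ratio.where(df["kps_c"] > 0)
    ordered = [c for c in COHORT_COLUMNS if c in df.columns]
    extras = [c for c in df.columns if c not in ordered]
    return df[ordered + extras]
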