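"""Domain containers: image series, maps, ROIs, fits and transforms."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .params import AcquisitionParams


def _check_same_grid(*arrays):
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise GeometryError(f"volumes disagree in shape: {sorted(shapes)}")


@dataclass
class DceSeries:
    """4D dynamic contrast-enhanced series: space x frames plus acquisition."""

    signal: np.ndarray  # (nx, ny, nz, n_frames)
    acq: AcquisitionParams
    affine: np.ndarray  # 4x4 voxel -> world (mm, RAS)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise GeometryError("DCE signal must be 4D (x, y, z, t)")
        if self.signal.shape[-1] != self.acq.n_frames:
            raise GeometryError(
                f"series has {self.signal.shape[-1]} frames, "
                f"acquisition declares {self.acq.n_frames}"
            )
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def frame_times(self) -> np.ndarray:
        return self.acq.frame_times

    @property
    def shape3d(self):
        return self.signal.shape[:3]


@dataclass
class DwiPair:
    """b = 0 / b = 1000 s/mm^2 diffusion-weighted volume pair."""

    s0_volume: np.ndarray
    sb_volume: np.ndarray
    affine: np.ndarray
    b_values: tuple[float, float] = (0.0, 1000.0)

    def __post_init__(self):
        self.s0_volume = np.asarray(self.s0_volume, dtype=float)
        self.sb_volume = np.asarray(self.sb_volume, dtype=float)
        _check_same_grid(self.s0_volume, self.sb_volume)
        if not (self.b_values[0] == 0 and self.b_values[1] > 0):
            raise ParameterError("b_values must be (0, b) with b > 0")
        self.affine = np.asarray(self.affine, dtype=float)


@dataclass
class InputFunction:
    """Plasma contrast concentration sampled on the DCE frame grid."""

    times: np.ndarray  # s
    cp: np.ndarray  # mM
    status: str = "ok"  # "ok" or "no-bolus-detected"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape or self.times.ndim != 1:
            raise GeometryError("times and cp must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.cp)):
            raise ParameterError("cp must be finite")


@dataclass
class AdcMap:
    """Apparent-diffusion-coefficient map in mm^2/s.

    ``invalid_mask`` marks voxels where the log-decay was non-physical
    (S_b <= 0 or S_b > S0); their ADC is set to 0 and they are excluded
    from ROI statistics.
    """

    values: np.ndarray
    affine: np.ndarray
    invalid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.invalid_mask is None:
            self.invalid_mask = np.zeros(self.values.shape, dtype=bool)
        self.invalid_mask = np.asarray(self.invalid_mask, dtype=bool)
        _check_same_grid(self.values, self.invalid_mask)

    @property
    def n_excluded(self) -> int:
        return int(self.invalid_mask.sum())


@dataclass
class RoiPair:
    """Diffusion-lesion mask and its mirror-image contralateral homologue."""

    lesion_mask: np.ndarray
    contralateral_mask: np.ndarray
    voxel_volume: float  # mm^3

    def __post_init__(self):
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        self.contralateral_mask = np.asarray(self.contralateral_mask, dtype=bool)
        _check_same_grid(self.lesion_mask, self.contralateral_mask)
        if np.any(self.lesion_mask & self.contralateral_mask):
            raise GeometryError("lesion and contralateral masks overlap")
        if self.lesion_mask.sum() != self.contralateral_mask.sum():
            raise GeometryError("mirrored ROI lost/gained voxels")
        if self.voxel_volume <= 0:
            raise ParameterError("voxel_volume must be > 0")


@dataclass(frozen=True)
class PatlakFit:
    """Result of a single-curve Patlak regression.

    ``ki`` is the unidirectional influx constant (slope) in min^-1 and
    ``vp`` the plasma-volume fraction (intercept).  ``r_squared`` is NaN,
    with ``flag='zero-variance-y'``, when the response has no variance
    around the fitted line (e.g. a purely intravascular voxel).
    """

    ki: float
    vp: float
    r_squared: float
    n_points: int
    flag: str = ""


@dataclass
class KpsMap:
    """Voxel-wise permeability-surface-area product map (mL/100 g/min)."""

    values: np.ndarray
    vp: np.ndarray
    r_squared: np.ndarray
    affine: np.ndarray
    n_failed: int = 0
    n_negative: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.vp = np.asarray(self.vp, dtype=float)
        self.r_squared = np.asarray(self.r_squared, dtype=float)
        _check_same_grid(self.values, self.vp, self.r_squared)


@dataclass(frozen=True)
class AffineTransform:
    """World-coordinate affine (row 4 = [0,0,0,1]); mm, RAS convention.

    Maps fixed-image world coordinates to moving-image world coordinates
    (a "pull" transform used directly for resampling onto the fixed grid).
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ParameterError("transform matrix must be 4x4")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ParameterError("transform linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self @ other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "convention": "world RAS mm; maps fixed coordinates to moving",
                "matrix": self.matrix.tolist(),
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "AffineTransform":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(np.asarray(data["matrix"], dtype=float))
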