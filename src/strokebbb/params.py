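"""Parameter containers for acquisition, bolus, conversion and registration.

Unit conventions, used consistently across the package:

* relaxation times (T1, TR, TE) in **milliseconds**,
* frame timing and bolus time constants in **seconds**,
* contrast concentration in **mM**, relaxivity in s^-1 mM^-1,
* flip angle in **degrees**, voxel size in **mm**,
* permeability (KPS) in **mL/100 g/min**, ADC in **mm^2/s**.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class AcquisitionParams:
    """Dynamic spoiled-gradient-echo acquisition settings.

    Defaults reproduce a 1.5 T stroke DCE protocol: TR 5.9 ms, TE 1.5 ms,
    flip angle 20 deg, one volume every 9 s, 31 volumes, 240 mm FOV on a
    64-voxel in-plane phantom grid (3.75 mm) with 5 mm slices.
    """

    repetition_time: float = 5.9
    echo_time: float = 1.5
    flip_angle: float = 20.0
    frame_interval: float = 9.0
    n_frames: int = 31
    voxel_size: tuple[float, float, float] = (3.75, 3.75, 5.0)

    def __post_init__(self):
        if min(self.repetition_time, self.echo_time, self.frame_interval) <= 0:
            raise ParameterError("timing parameters must be strictly positive")
        if not 0 < self.flip_angle <= 90:
            raise ParameterError("flip_angle must lie in (0, 90] degrees")
        if self.n_frames < 4:
            raise ParameterError("n_frames must be >= 4")
        if min(self.voxel_size) <= 0:
            raise ParameterError("voxel dimensions must be strictly positive")

    @property
    def frame_times(self) -> np.ndarray:
        """Frame mid-times in seconds, first frame at t = 0."""
        return np.arange(self.n_frames) * float(self.frame_interval)


@dataclass(frozen=True)
class VifParams:
    """Gamma-variate bolus with a recirculation plateau.

    ``amplitude`` is the first-pass peak plasma concentration in mM (the
    gamma-variate is normalised to its mode at
    ``arrival_time + shape_alpha * timescale_tau``).  The recirculation
    term rises on the bolus timescale to ``recirculation_fraction`` of the
    peak and decays with ``washout_timescale``.
    """

    arrival_time: float = 45.0
    amplitude: float = 5.0
    shape_alpha: float = 2.5
    timescale_tau: float = 6.0
    recirculation_fraction: float = 0.15
    washout_timescale: float = 80.0

    def __post_init__(self):
        if self.arrival_time < 0:
            raise ParameterError("arrival_time must be >= 0")
        if self.shape_alpha <= 0 or self.timescale_tau <= 0:
            raise ParameterError("shape_alpha and timescale_tau must be > 0")
        if self.washout_timescale <= 0:
            raise ParameterError("washout_timescale must be > 0")
        if not 0 <= self.recirculation_fraction < 1:
            raise ParameterError("recirculation_fraction must lie in [0, 1)")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")


@dataclass(frozen=True)
class ConversionParams:
    """Signal-to-concentration conversion assumptions.

    The blood T1 is fixed at 800 ms for all subjects (no T1 mapping is
    acquired in the acute setting); tissue T1 and the gadodiamide
    relaxivity at 1.5 T are configurable assumptions.  ``hematocrit``
    converts whole-blood to plasma concentration; 0 disables the
    correction.  ``tissue_density`` (g/mL) fixes the Ki -> mL/100 g/min
    conversion: KPS = Ki[min^-1] * 100 / density.
    """

    t1_blood: float = 800.0
    t1_tissue: float = 1000.0
    relaxivity_r1: float = 4.3
    baseline_frames: int = 5
    hematocrit: float = 0.45
    tissue_density: float = 1.0
    signal_model: str = "spgr"  # "spgr" (full inversion) or "linear"

    def __post_init__(self):
        if self.t1_blood <= 0 or self.t1_tissue <= 0:
            raise ParameterError("T1 values must be > 0")
        if self.relaxivity_r1 <= 0:
            raise ParameterError("relaxivity_r1 must be > 0")
        if self.baseline_frames < 1:
            raise ParameterError("baseline_frames must be >= 1")
        if not 0 <= self.hematocrit < 1:
            raise ParameterError("hematocrit must lie in [0, 1)")
        if self.tissue_density <= 0:
            raise ParameterError("tissue_density must be > 0")
        if self.signal_model not in ("spgr", "linear"):
            raise ParameterError("signal_model must be 'spgr' or 'linear'")


@dataclass(frozen=True)
class RegistrationConfig:
    """Settings for mutual-information affine registration.

    ``dof`` selects the transform model: 6 (rigid), 9 (+scale) or 12
    (full affine).  The optimizer is a derivative-free simplex run over a
    coarse-to-fine image pyramid.
    """

    histogram_bins: int = 32
    pyramid_levels: int = 3
    dof: int = 12
    max_iter: int = 400
    xatol: float = 2.0e-4
    fatol: float = 1.0e-9
    interp_order: int = 1

    def __post_init__(self):
        if self.histogram_bins < 8:
            raise ParameterError("histogram_bins must be >= 8")
        if self.pyramid_levels < 1:
            raise ParameterError("pyramid_levels must be >= 1")
        if self.dof not in (6, 9, 12):
            raise ParameterError("dof must be one of 6, 9, 12")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.interp_order not in (0, 1, 3):
            raise ParameterError("interp_order must be 0, 1 or 3")


@dataclass(frozen=True)
class SegmentationParams:
    """Relative ADC threshold used to delineate the diffusion lesion."""

    threshold_fraction: float = 0.85
    connectivity: int = 26

    def __post_init__(self):
        if self.threshold_fraction < 0:
            raise ParameterError("threshold_fraction must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ParameterError("connectivity must be 6, 18 or 26")
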