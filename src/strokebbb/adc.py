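"""ADC mapping, diffusion-lesion segmentation and contralateral mirroring.

The ADC of each voxel follows from the two-point log-linear decay
``ADC = ln(S0 / Sb) / b`` at b = 1000 s/mm^2.  The ischemic lesion is the
largest connected component of voxels whose ADC falls below a fraction
of the normal-tissue reference mean, and its homologue is the voxelwise
reflection across the midsagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AdcMap, DwiPair, RoiPair
from .errors import GeometryError, ParameterError
from .params import SegmentationParams

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def compute_adc(dwi: DwiPair, brain_mask: np.ndarray) -> AdcMap:
    """Voxelwise ADC map (mm^2/s) from a b=0 / b=1000 pair.

    Voxels where noise makes the decay non-physical (S_b <= 0 or
    S_b > S0, which would give a negative or infinite ADC) are set to 0
    and recorded in the map's ``invalid_mask`` so downstream ROI
    statistics can exclude them.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != dwi.s0_volume.shape:
        raise GeometryError("brain mask does not match the DWI grid")
    s0 = dwi.s0_volume
    sb = dwi.sb_volume
    b = dwi.b_values[1]
    valid = brain_mask & (s0 > 0) & (sb > 0) & (sb <= s0)
    values = np.zeros(s0.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[valid] = np.log(s0[valid] / sb[valid]) / b
    invalid = brain_mask & ~valid
    return AdcMap(values=values, affine=dwi.affine, invalid_mask=invalid)


@dataclass
class SegmentationResult:
    mask: np.ndarray
    reference_mean: float
    threshold: float
    n_components: int
    empty: bool


def segment_lesion(adc: AdcMap, brain_mask: np.ndarray,
                   reference_mean: float | None = None,
                   params: SegmentationParams | None = None) -> SegmentationResult:
    """Threshold-and-component lesion segmentation on an ADC map.

    A voxel joins the candidate set when its ADC is below
    ``threshold_fraction`` times the normal-tissue reference mean
    (computed over valid brain voxels when not supplied); the largest
    connected component is kept.  An empty result is legal and flagged.
    """
    params = params or SegmentationParams()
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != adc.values.shape:
        raise GeometryError("brain mask does not match the ADC grid")
    valid = brain_mask & ~adc.invalid_mask
    if reference_mean is None:
        if not valid.any():
            raise ParameterError("no valid voxels to derive a reference mean")
        reference_mean = float(adc.values[valid].mean())
    if reference_mean <= 0:
        raise ParameterError("reference ADC mean must be > 0")

    threshold = params.threshold_fraction * reference_mean
    candidates = valid & (adc.values < threshold)
    labels, n_comp = ndimage.label(candidates,
                                   structure=_STRUCTURES[params.connectivity])
    if n_comp == 0:
        mask = np.zeros(adc.values.shape, dtype=bool)
        return SegmentationResult(mask, reference_mean, threshold, 0, True)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_comp + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return SegmentationResult(mask, reference_mean, threshold, int(n_comp), False)


def mirror_contralateral(lesion_mask: np.ndarray,
                         voxel_size=(3.75, 3.75, 5.0),
                         axis: int = 0,
                         plane_offset_vox: float = 0.0) -> RoiPair:
    """Reflect the lesion across the midsagittal plane.

    The midline is the centre of the left-right voxel axis (``axis``),
    optionally shifted by ``plane_offset_vox`` voxels for brains not
    centred on the grid.  The lesion must lie entirely within one
    hemisphere; reflection is an exact involution on the voxel lattice
    when ``2 * plane_offset_vox`` is an integer.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    n = lesion_mask.shape[axis]
    centre = (n - 1) / 2.0 + plane_offset_vox
    coords = np.nonzero(lesion_mask)
    pos = coords[axis]
    if pos.size == 0:
        raise ParameterError("lesion mask is empty")
    left = int(np.sum(pos < centre))
    right = int(np.sum(pos > centre))
    on_plane = int(np.sum(pos == centre))
    straddle = min(left, right) + on_plane
    if straddle > 0 and left and right:
        raise GeometryError(
            f"lesion straddles the midsagittal plane: {min(left, right)} "
            f"voxel(s) on the minority side, {on_plane} on the plane")
    if on_plane > 0:
        raise GeometryError(
            f"lesion touches the midsagittal plane at {on_plane} voxel(s)")

    reflected = np.rint(2.0 * centre - pos).astype(int)
    if reflected.min() < 0 or reflected.max() >= n:
        raise GeometryError("reflected lesion falls outside the grid")
    mirror = np.zeros_like(lesion_mask)
    idx = list(coords)
    idx[axis] = reflected
    mirror[tuple(idx)] = True

    return RoiPair(lesion_mask=lesion_mask, contralateral_mask=mirror,
                   voxel_volume=float(np.prod(voxel_size)))
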