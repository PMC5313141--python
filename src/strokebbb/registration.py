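"""Mutual-information affine registration and resampling.

Alignment of the diffusion (ADC/ROI) space to the dynamic series is a
single global affine maximizing the mutual information of the joint
intensity histogram, optimized with a derivative-free simplex over a
coarse-to-fine image pyramid.  Transforms live in world coordinates
(mm, RAS) and map fixed-image coordinates to moving-image coordinates,
so they can be applied directly when resampling the moving volume onto
the fixed grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import AffineTransform
from .errors import GeometryError, ParameterError
from .params import RegistrationConfig


# --------------------------------------------------------------------------
# information metric
# --------------------------------------------------------------------------

def joint_histogram(a: np.ndarray, b: np.ndarray, bins: int = 32,
                    mask: np.ndarray | None = None,
                    a_range=None, b_range=None) -> np.ndarray:
    """2D count table of paired intensities.

    Bin edges are equal-width over each volume's 1st-99th percentile
    range (or an explicit ``(lo, hi)``); values outside are clipped to
    the edge bins so counts always sum to the number of masked voxels.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError("volumes disagree in shape")
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise GeometryError("mask does not match the volumes")
        if not mask.any():
            raise ParameterError("mask is empty")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()

    def _edges(x, rng):
        lo, hi = np.percentile(x, [1, 99]) if rng is None else rng
        if hi <= lo:  # constant image: a single degenerate bin suffices
            hi = lo + 1.0
        return np.linspace(lo, hi, bins + 1)

    ea, eb = _edges(a, a_range), _edges(b, b_range)
    a = np.clip(a, ea[0], ea[-1])
    b = np.clip(b, eb[0], eb[-1])
    hist, _, _ = np.histogram2d(a, b, bins=[ea, eb])
    return hist


def mutual_information(hist: np.ndarray) -> float:
    """Mutual information of a joint count table, in bits.

    MI = sum_ij p_ij log2(p_ij / (p_i p_j)); empty cells contribute 0.
    Always >= 0 and bounded by min(H(a), H(b)).
    """
    hist = np.asarray(hist, dtype=float)
    if np.any(hist < 0):
        raise ParameterError("histogram counts must be >= 0")
    total = hist.sum()
    if total <= 0:
        raise ParameterError("histogram is empty")
    p = hist / total
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p[nz] * np.log2(p[nz] / (pa @ pb)[nz])
    return float(max(terms.sum(), 0.0))


# --------------------------------------------------------------------------
# transforms and resampling
# --------------------------------------------------------------------------

def params_to_transform(p, centre, dof: int) -> AffineTransform:
    """Build a world affine from an optimizer parameter vector.

    Layout: [tx ty tz, rx ry rz (deg), sx sy sz (% deviation),
    kxy kxz kyz (% shear)], truncated to ``dof``.  Rotation/scale/shear
    act about the world-space ``centre``; translation is in mm.
    """
    p = np.asarray(p, dtype=float)
    t = p[0:3]
    angles = np.deg2rad(p[3:6]) if dof >= 6 else np.zeros(3)

    def rot(axis, theta):
        c, s = np.cos(theta), np.sin(theta)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -s if axis != 1 else s
        m[j, i] = s if axis != 1 else -s
        return m

    lin = rot(0, angles[0]) @ rot(1, angles[1]) @ rot(2, angles[2])
    if dof >= 9:
        lin = lin @ np.diag(1.0 + p[6:9] / 100.0)
    if dof >= 12:
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = p[9:12] / 100.0
        lin = lin @ shear

    centre = np.asarray(centre, dtype=float)
    mat = np.eye(4)
    mat[:3, :3] = lin
    mat[:3, 3] = centre - lin @ centre + t
    return AffineTransform(mat)


def resample(volume: np.ndarray, moving_affine: np.ndarray,
             transform: AffineTransform, target_shape,
             target_affine: np.ndarray, is_mask: bool = False,
             order: int = 1) -> np.ndarray:
    """Pull ``volume`` onto the target grid through a world transform.

    Intensity volumes use trilinear interpolation; masks use
    nearest-neighbour so the output stays binary.
    """
    volume = np.asarray(volume)
    if is_mask:
        order = 0
        data = volume.astype(np.uint8)
    else:
        data = volume.astype(float)
    # voxel mapping: target voxel -> world -> moving world -> moving voxel
    m = np.linalg.inv(moving_affine) @ transform.matrix @ target_affine
    out = ndimage.affine_transform(
        data, m[:3, :3], offset=m[:3, 3], output_shape=tuple(target_shape),
        order=order, mode="constant", cval=0.0, prefilter=order > 1)
    if is_mask:
        return out.astype(bool)
    return out


# --------------------------------------------------------------------------
# registration driver
# --------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    transform: AffineTransform
    mi_bits: float
    converged: bool
    n_eval: int
    params: np.ndarray


def _pyramid(data, sigma):
    """Smoothing-only pyramid level (no decimation).

    Decimated levels starve the joint histogram of samples and let the
    interpolation-blur penalty on the moving image outweigh the
    alignment signal, biasing rotations toward zero; smoothing alone
    widens the capture range while keeping the metric honest.
    """
    if sigma <= 0:
        return np.asarray(data, dtype=float)
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=sigma)


def register_affine(moving: np.ndarray, moving_affine: np.ndarray,
                    fixed: np.ndarray, fixed_affine: np.ndarray,
                    config: RegistrationConfig | None = None) -> RegistrationResult:
    """Estimate the affine maximizing MI between ``moving`` and ``fixed``.

    Initialized at identity; each pyramid level warm-starts from the
    previous solution with a fresh simplex whose steps shrink with the
    level's voxel spacing.  Non-convergence at the final level emits a
    warning and returns the best transform found.
    """
    config = config or RegistrationConfig()
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    centre_vox = (np.asarray(fixed.shape) - 1) / 2.0
    centre = (fixed_affine @ np.append(centre_vox, 1.0))[:3]

    x = np.zeros(0)
    total_eval = 0
    converged = False
    mi_final = np.nan

    # schedule: rigid alignment over the smoothing pyramid, then (for
    # dof > 6) scale/shear released at full resolution with shrinking
    # simplex steps; a full-affine simplex started cold reliably stalls
    # off-optimum, and every stage ends with a small-step polish pass
    sigmas = [float(2 ** k) for k in range(config.pyramid_levels - 1, 0, -1)]
    sigmas.append(0.0)
    schedule = [(6, sigma, 1.0) for sigma in sigmas]
    if config.dof == 6:
        schedule.append((6, 0.0, 0.05))
    else:
        schedule += [(config.dof, 0.0, 0.3), (config.dof, 0.0, 0.05)]

    for n_par, sigma, scale in schedule:
        x = np.concatenate([x, np.zeros(n_par - x.size)])
        fx = _pyramid(fixed, sigma)
        mv = _pyramid(moving, sigma)
        a_rng = tuple(np.percentile(fx, [1, 99]))
        b_rng = tuple(np.percentile(mv, [1, 99]))

        def neg_mi(p, _fx=fx, _mv=mv, _ar=a_rng, _br=b_rng, _dof=n_par):
            tr = params_to_transform(p, centre, _dof)
            res = resample(_mv, moving_affine, tr, _fx.shape, fixed_affine,
                           order=config.interp_order)
            hist = joint_histogram(_fx, res, bins=config.histogram_bins,
                                   a_range=_ar, b_range=_br)
            return -mutual_information(hist)

        steps = scale * np.concatenate([
            np.full(3, 2.0 * (sigma + 1.0)),    # translation, mm
            np.full(3, 2.0),                    # rotation, deg
            np.full(max(n_par - 6, 0), 1.0),    # scale/shear, %
        ])[:n_par]
        simplex = np.vstack([x] + [x + steps[i] * np.eye(n_par)[i]
                                   for i in range(n_par)])
        res = optimize.minimize(
            neg_mi, x, method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxiter": config.max_iter,
                "xatol": config.xatol if scale <= 0.05 else config.xatol * 10,
                "fatol": config.fatol,
            },
        )
        x = res.x
        total_eval += res.nfev
        converged = bool(res.success)
        mi_final = -res.fun

    if not converged:
        warnings.warn("registration did not converge within max_iter; "
                      "returning best transform found", RuntimeWarning)
    return RegistrationResult(
        transform=params_to_transform(x, centre, config.dof),
        mi_bits=float(mi_final), converged=converged,
        n_eval=total_eval, params=np.asarray(x),
    )
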