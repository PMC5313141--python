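"""Spoiled-gradient-echo steady-state signal model and its inverse.

S = s0 * sin(a) * (1 - E1) / (1 - cos(a) * E1),   E1 = exp(-TR * R1)

with R1 in s^-1 and TR converted from ms.  The model is monotonically
increasing in R1 (hence in concentration) for flip angles in (0, 90],
so the inversion is single-valued on S in (0, s0*sin(a)).
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

_EPS = 1e-12


def _angles(fa_deg: float):
    a = np.deg2rad(fa_deg)
    return np.sin(a), np.cos(a)


def spgr_signal(r1_per_s, s0, tr_ms, fa_deg):
    """SPGR signal for longitudinal rate ``r1_per_s`` (vectorised)."""
    if tr_ms <= 0:
        raise ParameterError("TR must be > 0")
    sa, ca = _angles(fa_deg)
    e1 = np.exp(-(tr_ms / 1000.0) * np.asarray(r1_per_s, dtype=float))
    return s0 * sa * (1.0 - e1) / (1.0 - ca * e1)


def spgr_invert(signal, s0, tr_ms, fa_deg):
    """Invert the SPGR equation to R1 (s^-1).

    Signals outside the invertible range (0, s0*sin(a)) are clamped to
    the range edge; the returned boolean array flags those samples.
    """
    sa, ca = _angles(fa_deg)
    y = np.asarray(signal, dtype=float) / (s0 * sa)
    y_cl = np.clip(y, _EPS, 1.0 - 1e-9)
    clamped = y_cl != y
    e1 = (1.0 - y_cl) / (1.0 - ca * y_cl)
    r1 = -np.log(e1) / (tr_ms / 1000.0)
    return r1, clamped


def baseline_factor(t1_ms, tr_ms, fa_deg):
    """Unit-s0 SPGR signal of tissue at rest (R1 = 1/T1)."""
    return spgr_signal(1000.0 / t1_ms, 1.0, tr_ms, fa_deg)
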