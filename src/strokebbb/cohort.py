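"""Synthetic stroke-cohort generation with per-phase distributions.

Each patient carries infarct and contralateral KPS and ADC, a lesion
volume, an onset-to-scan time and basic clinical covariates.  Per-phase
continuous measures are drawn from truncated-at-zero normal
distributions whose *post-truncation* mean and SD equal the requested
values (moment matching), so phase summaries are unbiased relative to
the targets.  Lesion volume, whose requested CV can exceed 1, uses a
moment-matched lognormal instead.

Infarct/contralateral pairs within a patient are coupled through a
Gaussian copula (default rank correlation 0.9): the two hemispheres
share patient-level physiology, and the coupling is what gives paired
infarct-vs-contralateral tests their power in real stroke cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_stats import assign_phase
from .errors import CohortSpecError

PHASES = ("hyperacute", "acute", "subacute")

#: canonical cohort-table column names (the PatientRecord schema)
COHORT_COLUMNS = [
    "patient_id", "onset_to_scan_hr", "phase", "ht_flag",
    "kps_i", "kps_c", "kps_ratio", "adc_i", "adc_c",
    "lesion_volume_cm3", "nihss", "age_yr", "sex", "tpa_flag",
    "stroke_subtype",
]

_SUBTYPES = (
    ("cortical infarct", 23),
    ("lacunar infarct", 5),
    ("lenticulostriate artery GM infarct", 3),
    ("lenticulostriate artery WM infarct", 4),
    ("lenticulostriate artery GM + WM infarct", 1),
    ("cortical + lenticulostriate artery WM infarct", 2),
    ("cortical + watershed infarct", 2),
    ("WM perforating artery infarct", 1),
    ("brainstem", 1),
)


@dataclass(frozen=True)
class PhaseSpec:
    """Patient count and measure distributions (mean, SD) for one phase."""

    n: int
    onset_range: tuple[float, float]  # hours
    kps_i: tuple[float, float]
    kps_c: tuple[float, float]
    adc_i: tuple[float, float]       # mm^2/s
    adc_c: tuple[float, float]
    volume: tuple[float, float]      # cm^3

    def __post_init__(self):
        if self.n < 0:
            raise CohortSpecError("phase count must be >= 0")
        lo, hi = self.onset_range
        if not 0 < lo < hi:
            raise CohortSpecError("onset_range must satisfy 0 < lo < hi")
        for name in ("kps_i", "kps_c", "adc_i", "adc_c", "volume"):
            m, s = getattr(self, name)
            if s < 0:
                raise CohortSpecError(f"{name} SD must be >= 0")
            if self.n == 0 and (m or s):
                raise CohortSpecError(
                    f"phase with n=0 requests nonzero statistics for {name}")


@dataclass(frozen=True)
class HtSpec:
    """Hemorrhagic-transformation subgroup (scanned in the hyperacute
    window only; roughly doubled permeability)."""

    n: int = 7
    onset_range: tuple[float, float] = (1.3, 6.0)
    kps_i: tuple[float, float] = (1.44, 0.76)
    kps_ratio: tuple[float, float] = (2.77, 1.29)


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort recipe: per-phase specs, pairing, covariates, seed."""

    phases: dict
    ht: HtSpec | None = None
    pair_correlation: float = 0.9
    nihss: tuple[float, float] = (5.2, 3.0)
    age: tuple[float, float] = (59.4, 17.0)
    male_fraction: float = 0.571
    tpa_fraction: float = 0.19
    seed: int = 0

    def __post_init__(self):
        if not -1 < self.pair_correlation < 1:
            raise CohortSpecError("pair_correlation must lie in (-1, 1)")
        for name, ph in self.phases.items():
            if name not in PHASES:
                raise CohortSpecError(f"unknown phase '{name}'")


def default_cohort_spec(seed: int = 0, include_ht: bool = False) -> CohortSpec:
    """Cohort at the study's phase sizes and per-phase moments.

    Group sizes 20/11/11 (hyperacute/acute/subacute); KPS in
    mL/100 g/min, ADC in mm^2/s, volume in cm^3; onset-to-scan times
    span 1.3-90.7 h across phases.  ``include_ht=True`` appends the
    7-patient hemorrhagic-transformation subgroup.
    """
    phases = {
        "hyperacute": PhaseSpec(
            n=20, onset_range=(1.3, 6.0),
            kps_i=(0.72, 0.37), kps_c=(0.56, 0.26),
            adc_i=(5.93e-4, 1.49e-4), adc_c=(8.52e-4, 1.48e-4),
            volume=(2.89, 2.82)),
        "acute": PhaseSpec(
            n=11, onset_range=(6.0, 48.0),
            kps_i=(0.94, 0.69), kps_c=(0.51, 0.14),
            adc_i=(6.42e-4, 1.27e-4), adc_c=(8.50e-4, 1.07e-4),
            volume=(2.27, 2.39)),
        "subacute": PhaseSpec(
            n=11, onset_range=(48.0, 90.7),
            kps_i=(0.70, 0.35), kps_c=(0.48, 0.20),
            adc_i=(6.21e-4, 1.76e-4), adc_c=(8.70e-4, 1.47e-4),
            volume=(5.31, 8.38)),
    }
    return CohortSpec(phases=phases, ht=HtSpec() if include_ht else None,
                      seed=seed)


# --------------------------------------------------------------------------
# moment-matched samplers
# --------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _matched_truncnorm(mean: float, sd: float):
    """Frozen truncnorm on [0, inf) whose truncated moments equal (mean, sd).

    Requires mean > 0 and CV < 1; a lower-truncated normal cannot exceed
    CV = 1 (the exponential limit).
    """
    if mean <= 0:
        raise CohortSpecError("truncated-normal target mean must be > 0")
    if sd / mean >= 0.995:
        raise CohortSpecError(
            f"target CV {sd / mean:.2f} infeasible for a truncated normal; "
            "use a lognormal measure instead")

    def residual(p):
        mu, log_sig = p
        sig = np.exp(log_sig)
        m, v = stats.truncnorm.stats(-mu / sig, np.inf, loc=mu, scale=sig,
                                     moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or max(abs(np.asarray(residual(sol.x)))) > 1e-8 * mean:
        raise CohortSpecError(
            f"moment matching failed for mean={mean}, sd={sd}")
    mu, sig = sol.x[0], np.exp(sol.x[1])
    return stats.truncnorm(-mu / sig, np.inf, loc=mu, scale=sig)


def _draw(rng, n, mean_sd):
    mean, sd = mean_sd
    if sd == 0:
        return np.full(n, float(mean))
    return _matched_truncnorm(mean, sd).ppf(rng.uniform(size=n))


def _draw_pair(rng, n, spec_a, spec_b, rho):
    """Copula-coupled pair with moment-matched truncnorm marginals."""
    if spec_a[1] == 0 or spec_b[1] == 0 or rho == 0:
        return _draw(rng, n, spec_a), _draw(rng, n, spec_b)
    cov = [[1.0, rho], [rho, 1.0]]
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = stats.norm.cdf(z)
    a = _matched_truncnorm(*spec_a).ppf(u[:, 0])
    b = _matched_truncnorm(*spec_b).ppf(u[:, 1])
    return a, b


def _draw_lognormal(rng, n, mean_sd):
    mean, sd = mean_sd
    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _covariates(rng, spec, n):
    nihss = np.clip(np.rint(_draw(rng, n, spec.nihss)), 0, 42).astype(int)
    age = np.clip(np.rint(_draw(rng, n, spec.age)), 18, 100).astype(int)
    sex = np.where(rng.uniform(size=n) < spec.male_fraction, "M", "F")
    tpa = rng.uniform(size=n) < spec.tpa_fraction
    labels = [s for s, _ in _SUBTYPES]
    probs = np.array([c for _, c in _SUBTYPES], dtype=float)
    subtype = rng.choice(labels, size=n, p=probs / probs.sum())
    return nihss, age, sex, tpa, subtype


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with the :data:`COHORT_COLUMNS` schema.

    Deterministic for a given ``spec.seed``.  Onset-to-scan times are
    uniform within each phase's range; phases in the table are the
    labels the onset times imply.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    pid = 0
    for phase in PHASES:
        if phase not in spec.phases:
            continue
        ph = spec.phases[phase]
        if ph.n == 0:
            continue
        kps_i, kps_c = _draw_pair(rng, ph.n, ph.kps_i, ph.kps_c,
                                  spec.pair_correlation)
        adc_i, adc_c = _draw_pair(rng, ph.n, ph.adc_i, ph.adc_c,
                                  spec.pair_correlation)
        volume = _draw_lognormal(rng, ph.n, ph.volume)
        onset = rng.uniform(*ph.onset_range, size=ph.n)
        nihss, age, sex, tpa, subtype = _covariates(rng, spec, ph.n)
        for j in range(ph.n):
            pid += 1
            rows.append({
                "patient_id": f"P{pid:03d}",
                "onset_to_scan_hr": onset[j],
                "phase": assign_phase(onset[j]),
                "ht_flag": False,
                "kps_i": kps_i[j],
                "kps_c": kps_c[j],
                "kps_ratio": kps_i[j] / kps_c[j],
                "adc_i": adc_i[j],
                "adc_c": adc_c[j],
                "lesion_volume_cm3": volume[j],
                "nihss": nihss[j],
                "age_yr": age[j],
                "sex": sex[j],
                "tpa_flag": bool(tpa[j]),
                "stroke_subtype": subtype[j],
            })

    if spec.ht is not None and spec.ht.n > 0:
        ht = spec.ht
        kps_i, ratio = _draw_pair(rng, ht.n, ht.kps_i, ht.kps_ratio,
                                  spec.pair_correlation)
        hyper = spec.phases.get("hyperacute")
        if hyper is None:
            raise CohortSpecError(
                "HT subgroup requires a hyperacute phase spec for ADC/volume")
        adc_i, adc_c = _draw_pair(rng, ht.n, hyper.adc_i, hyper.adc_c,
                                  spec.pair_correlation)
        volume = _draw_lognormal(rng, ht.n, hyper.volume)
        onset = rng.uniform(*ht.onset_range, size=ht.n)
        nihss, age, sex, tpa, subtype = _covariates(rng, spec, ht.n)
        for j in range(ht.n):
            pid += 1
            rows.append({
                "patient_id": f"P{pid:03d}",
                "onset_to_scan_hr": onset[j],
                "phase": assign_phase(onset[j]),
                "ht_flag": True,
                "kps_i": kps_i[j],
                "kps_c": kps_i[j] / ratio[j],
                "kps_ratio": ratio[j],
                "adc_i": adc_i[j],
                "adc_c": adc_c[j],
                "lesion_volume_cm3": volume[j],
                "nihss": nihss[j],
                "age_yr": age[j],
                "sex": sex[j],
                "tpa_flag": bool(tpa[j]),
                "stroke_subtype": subtype[j],
            })

    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
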