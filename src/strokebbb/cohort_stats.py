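"""Phase-stratified cohort statistics.

Patients are binned by onset-to-scan time into hyperacute (<6 h), acute
(6-48 h, inclusive at both ends) and subacute (>48 h) phases; patients
who later proceed to hemorrhagic transformation (HT) are analysed
separately.  The primary analysis runs a classical one-way ANOVA with a
Tukey-Kramer HSD follow-up on infarct KPS across phases, plus paired
two-tailed t-tests of infarct vs contralateral KPS within each phase;
the secondary analysis repeats ANOVA + Tukey on the per-patient ratio
KPS_i/c.  A Levene diagnostic surfaces variance heterogeneity without
switching tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

PHASES = ("hyperacute", "acute", "subacute")

#: Table-2 style summary measures and their display scaling
SUMMARY_MEASURES = {
    "kps_i": ("infarct KPS (mL/100g/min)", 1.0),
    "kps_c": ("contralateral KPS (mL/100g/min)", 1.0),
    "adc_i": ("infarct ADC (x10^-4 mm^2/s)", 1e4),
    "adc_c": ("contralateral ADC (x10^-4 mm^2/s)", 1e4),
    "lesion_volume_cm3": ("infarct volume (cm^3)", 1.0),
}


def assign_phase(onset_to_scan_hr):
    """Phase label for an onset-to-scan time in hours.

    <6 h -> hyperacute; 6-48 h inclusive -> acute; >48 h -> subacute.
    Vectorised over arrays; non-positive times are an error.
    """
    arr = np.asarray(onset_to_scan_hr, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ParameterError("onset_to_scan must be positive and finite")
    out = np.where(arr < 6.0, "hyperacute",
                   np.where(arr <= 48.0, "acute", "subacute"))
    if np.isscalar(onset_to_scan_hr) or arr.ndim == 0:
        return str(out)
    return out


def split_ht(cohort: pd.DataFrame):
    """Partition a cohort table into (HT, non-HT) sub-tables."""
    if "ht_flag" not in cohort.columns:
        raise ParameterError("cohort table lacks an 'ht_flag' column")
    flags = cohort["ht_flag"].astype(bool)
    return cohort[flags].copy(), cohort[~flags].copy()


def group_summary(cohort: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per-phase n, sample mean and sample SD (n-1) for one measure.

    Phases absent from the table are omitted with a warning; a
    single-record phase reports SD = NaN.  Missing values are excluded
    per-measure with a logged count.
    """
    if measure not in cohort.columns:
        raise ParameterError(f"unknown measure '{measure}'")
    rows = []
    for phase in PHASES:
        vals = cohort.loc[cohort["phase"] == phase, measure]
        n_missing = int(vals.isna().sum())
        vals = vals.dropna().to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"phase '{phase}' has no records for '{measure}'",
                          RuntimeWarning)
            continue
        rows.append({
            "phase": phase,
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            "n_missing": n_missing,
        })
    return pd.DataFrame(rows).set_index("phase")


# --------------------------------------------------------------------------
# hypothesis tests (scipy-backed; R serves as the independent oracle in
# the test suite)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    flag: str = ""

    def to_dict(self):
        return {"F": self.f, "df_between": self.df_between,
                "df_within": self.df_within, "p": self.p, "flag": self.flag}


@dataclass(frozen=True)
class TukeyResult:
    labels: tuple
    p_values: dict          # frozenset({a, b}) -> adjusted p
    statistics: dict        # frozenset({a, b}) -> mean difference
    flag: str = ""

    def p(self, a, b) -> float:
        return self.p_values[frozenset((a, b))]

    def to_dict(self):
        return {
            "pairs": {
                " vs ".join(sorted(k)): {"p": v,
                                         "diff": self.statistics[k]}
                for k, v in self.p_values.items()
            },
            "flag": self.flag,
        }


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    flag: str = ""

    def to_dict(self):
        return {"t": self.t, "df": self.df, "p": self.p, "flag": self.flag}


def _as_groups(groups):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ParameterError("at least 2 groups required")
    if any(a.size < 2 for a in arrs):
        raise ParameterError("each group needs >= 2 values")
    return arrs


def one_way_anova(groups) -> AnovaResult:
    """Classical (equal-variance) one-way ANOVA over the given groups."""
    arrs = _as_groups(groups)
    df_b = len(arrs) - 1
    df_w = sum(a.size for a in arrs) - len(arrs)
    allv = np.concatenate(arrs)
    if np.ptp(allv) == 0:
        return AnovaResult(float("nan"), df_b, df_w, float("nan"),
                           flag="zero-total-variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrs)
    if not np.isfinite(f):
        return AnovaResult(float(f), df_b, df_w, float(p),
                           flag="zero-within-variance")
    return AnovaResult(float(f), df_b, df_w, float(p))


def tukey_hsd(groups, labels=None) -> TukeyResult:
    """Tukey-Kramer HSD adjusted p-values for all group pairs."""
    arrs = _as_groups(groups)
    if labels is None:
        labels = tuple(range(len(arrs)))
    labels = tuple(labels)
    if len(labels) != len(arrs):
        raise ParameterError("labels/groups length mismatch")
    allv = np.concatenate(arrs)
    if np.ptp(allv) == 0:
        pv = {frozenset((a, b)): 1.0
              for i, a in enumerate(labels) for b in labels[i + 1:]}
        st = {k: 0.0 for k in pv}
        return TukeyResult(labels, pv, st, flag="zero-total-variance")
    res = stats.tukey_hsd(*arrs)
    pv, st = {}, {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            key = frozenset((a, labels[j]))
            pv[key] = float(res.pvalue[i, j])
            st[key] = float(arrs[i].mean() - arrs[j].mean())
    return TukeyResult(labels, pv, st)


def paired_ttest(x, y) -> PairedTestResult:
    """Two-tailed paired Student's t-test.

    Zero-variance differences are flagged explicitly rather than being
    reported as p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("paired samples must be 1D of equal length")
    if x.size < 2:
        raise ParameterError("need >= 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        return PairedTestResult(float("nan"), x.size - 1, float("nan"),
                                flag="zero-variance-differences")
    t, p = stats.ttest_rel(x, y)
    return PairedTestResult(float(t), x.size - 1, float(p))


def levene_test(groups):
    """Levene variance-homogeneity diagnostic (W statistic, p)."""
    arrs = _as_groups(groups)
    w, p = stats.levene(*arrs)
    return float(w), float(p)


# --------------------------------------------------------------------------
# the full primary + secondary analysis
# --------------------------------------------------------------------------

@dataclass
class GroupStatsResult:
    """Everything the phase-stratified analysis produces."""

    group_sizes: dict
    summaries: dict                     # measure -> per-phase DataFrame
    anova: dict                         # measure -> AnovaResult
    tukey: dict                         # measure -> TukeyResult
    paired: dict                        # phase -> PairedTestResult
    levene_kps_i: tuple
    tables: dict = field(default_factory=dict)  # rendered summary frames

    def to_dict(self) -> dict:
        return {
            "group_sizes": dict(self.group_sizes),
            "summaries": {
                m: df.reset_index().to_dict(orient="records")
                for m, df in self.summaries.items()
            },
            "anova": {m: r.to_dict() for m, r in self.anova.items()},
            "tukey": {m: r.to_dict() for m, r in self.tukey.items()},
            "paired_infarct_vs_contralateral": {
                ph: r.to_dict() for ph, r in self.paired.items()
            },
            "levene_kps_i": {"W": self.levene_kps_i[0],
                             "p": self.levene_kps_i[1]},
        }


def _phase_groups(df, measure):
    out, labels = [], []
    for phase in PHASES:
        vals = df.loc[df["phase"] == phase, measure].dropna().to_numpy(float)
        if vals.size >= 2:
            out.append(vals)
            labels.append(phase)
    return out, labels


def run_primary_and_secondary_analysis(cohort: pd.DataFrame,
                                       drop_ht: bool = True) -> GroupStatsResult:
    """Run the phase-stratified analysis on a cohort table.

    Primary: one-way ANOVA + Tukey HSD on infarct KPS across phases,
    the same ANOVA on NIHSS and lesion volume, and paired t-tests of
    infarct vs contralateral KPS within each phase.  Secondary: ANOVA +
    Tukey on KPS_i/c.  Rendered summary tables mirror the demographic
    table, the per-phase measure table and the two bar-chart summaries.
    """
    df = cohort
    if drop_ht and "ht_flag" in df.columns:
        _, df = split_ht(df)
    if len(df) == 0:
        raise ParameterError("cohort table is empty")
    if "phase" not in df.columns:
        df = df.assign(phase=assign_phase(df["onset_to_scan_hr"].to_numpy()))

    group_sizes = {ph: int((df["phase"] == ph).sum()) for ph in PHASES}

    summaries = {m: group_summary(df, m) for m in SUMMARY_MEASURES
                 if m in df.columns}

    anova, tukey = {}, {}
    for measure in ("kps_i", "kps_ratio", "nihss", "lesion_volume_cm3"):
        if measure not in df.columns:
            continue
        groups, labels = _phase_groups(df, measure)
        if len(groups) >= 2:
            anova[measure] = one_way_anova(groups)
            if measure in ("kps_i", "kps_ratio"):
                tukey[measure] = tukey_hsd(groups, labels)

    paired = {}
    for phase in PHASES:
        sub = df[df["phase"] == phase].dropna(subset=["kps_i", "kps_c"])
        if len(sub) >= 2:
            paired[phase] = paired_ttest(sub["kps_i"].to_numpy(float),
                                         sub["kps_c"].to_numpy(float))

    kps_groups, _ = _phase_groups(df, "kps_i")
    levene = levene_test(kps_groups) if len(kps_groups) >= 2 else (
        float("nan"), float("nan"))

    result = GroupStatsResult(
        group_sizes=group_sizes, summaries=summaries,
        anova=anova, tukey=tukey, paired=paired, levene_kps_i=levene,
    )
    result.tables = render_tables(df, result)
    return result


def render_tables(df: pd.DataFrame, result: GroupStatsResult) -> dict:
    """Demographics, per-phase measures and bar-chart summary frames."""
    tables = {}

    demo_rows = [("n", float(len(df)))]
    if "sex" in df.columns:
        demo_rows.append(("male_pct", 100.0 * (df["sex"] == "M").mean()))
    for col, label in (("age_yr", "age_mean_yr"), ("nihss", "nihss_mean"),
                       ("onset_to_scan_hr", "onset_to_scan_mean_hr")):
        if col in df.columns:
            demo_rows.append((label, float(df[col].mean())))
            demo_rows.append((label.replace("mean", "min"),
                              float(df[col].min())))
            demo_rows.append((label.replace("mean", "max"),
                              float(df[col].max())))
    if "tpa_flag" in df.columns:
        demo_rows.append(("tpa_pct", 100.0 * df["tpa_flag"].mean()))
    tables["demographics"] = pd.DataFrame(demo_rows,
                                          columns=["variable", "value"])

    rows = []
    for measure, (label, scale) in SUMMARY_MEASURES.items():
        if measure not in result.summaries:
            continue
        summ = result.summaries[measure]
        row = {"measure": label}
        for phase in PHASES:
            if phase in summ.index:
                row[f"{phase}_mean"] = summ.loc[phase, "mean"] * scale
                row[f"{phase}_sd"] = summ.loc[phase, "sd"] * scale
        rows.append(row)
    tables["phase_measures"] = pd.DataFrame(rows)

    bar_rows = []
    for phase in PHASES:
        for region, col in (("infarct", "kps_i"), ("contralateral", "kps_c")):
            vals = df.loc[df["phase"] == phase, col].dropna()
            if len(vals):
                bar_rows.append({
                    "phase": phase, "region": region,
                    "mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else float("nan"),
                })
    tables["kps_by_region"] = pd.DataFrame(bar_rows)

    ratio_rows = []
    for phase in PHASES:
        vals = df.loc[df["phase"] == phase, "kps_ratio"].dropna()
        if len(vals):
            ratio_rows.append({
                "phase": phase, "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1 else float("nan"),
            })
    tables["kps_ratio"] = pd.DataFrame(ratio_rows)
    return tables
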