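"""Biomarker calls from fitted PLS models.

Combines three views of the time course:

* PLSr VIP + coefficient sign classifies a bin as *consumed* (negative
  regression on the growth response) or *produced* (positive);
* PLS-DA per-class VIP picks up *transient* bins — expressed in one
  incubation window only, hence invisible to the linear regression;
* the induced-metabolite rule flags bins elevated by the treatment:
  VIP > 1 (PLSr or any PLS-DA class) AND Welch t-test p < 0.005 between
  treatment and control peak areas AND a treatment/control mean-area fold
  of at least 3.

Peak areas enter the rule at the total-area-normalized stage (pre-g-log),
since the criterion speaks of areas, not transformed values. The Welch
test, however, is computed on log areas restricted to the bin's occurrence
window (days whose treatment mean exceeds 5% of the bin's maximum day
mean): a bin expressed on a single day would otherwise never reach
significance, because pooling all days puts the between-day variance in
the denominator of the statistic. Fold change stays on the raw normalized
means over all samples. No multiple-testing correction is applied by
default (a Benjamini-Hochberg option exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureMatrix
from .pls import ClassEncoding

TREND_CLASSES = ("consumed", "produced", "transient_early", "transient_late", "unchanged")


def select_vip(vip: np.ndarray, bin_ids: Sequence[int], threshold: float = 1.0) -> list[int]:
    """Bins with VIP strictly above the threshold."""
    vip = np.asarray(vip, dtype=float)
    return [bid for bid, v in zip(bin_ids, vip) if v > threshold]


@dataclass
class VIPReports:
    """VIP vectors feeding the biomarker logic (aligned to bin_ids)."""

    bin_ids: list[int]
    plsr_treatment: np.ndarray
    plsr_control: np.ndarray | None = None
    plsda_per_class: np.ndarray | None = None  # bins x classes
    plsda_classes: list[str] | None = None
    plsr_coef_treatment: np.ndarray | None = None

    def any_above(self, threshold: float = 1.0) -> np.ndarray:
        """Per-bin flag: VIP > threshold in PLSr (treatment) or any PLS-DA class."""
        flag = self.plsr_treatment > threshold
        if self.plsda_per_class is not None:
            flag = flag | (self.plsda_per_class > threshold).any(axis=1)
        return flag


def classify_trend(
    vip: VIPReports,
    class_means: np.ndarray | None = None,
    early_class: str = "4",
    late_class: str = "8/12",
    threshold: float = 1.0,
) -> tuple[pd.Series, list[int]]:
    """Trend class per bin from the PLSr and PLS-DA relevance pattern.

    PLSr relevance wins over pulse-class relevance (conflicts are returned
    for logging): a linearly consumed/produced bin often also loads on the
    terminal day-classes of the discriminant model. Per-class VIPs of the
    two transient classes are strongly coupled (the latent components are
    shared), so when ``class_means`` (bins x classes mean intensities,
    aligned to ``plsda_classes``) is given, a transient bin is attributed
    to the class where its expression actually peaks.
    """
    if vip.plsr_coef_treatment is None:
        raise ValueError("classify_trend needs PLSr regression coefficients")
    n = len(vip.bin_ids)
    plsr_rel = vip.plsr_treatment > threshold
    trends = []
    conflicts: list[int] = []
    for j in range(n):
        early_vip = late_vip = 0.0
        if vip.plsda_per_class is not None and vip.plsda_classes is not None:
            if early_class in vip.plsda_classes:
                early_vip = vip.plsda_per_class[j, vip.plsda_classes.index(early_class)]
            if late_class in vip.plsda_classes:
                late_vip = vip.plsda_per_class[j, vip.plsda_classes.index(late_class)]
        pulse_hit = max(early_vip, late_vip) > threshold
        if plsr_rel[j]:
            if pulse_hit:
                conflicts.append(vip.bin_ids[j])
            trends.append("consumed" if vip.plsr_coef_treatment[j] < 0 else "produced")
        elif pulse_hit:
            if class_means is not None and vip.plsda_classes is not None:
                ei = vip.plsda_classes.index(early_class)
                li = vip.plsda_classes.index(late_class)
                early_wins = class_means[j, ei] >= class_means[j, li]
            else:
                early_wins = early_vip >= late_vip
            trends.append("transient_early" if early_wins else "transient_late")
        else:
            trends.append("unchanged")
    return pd.Series(trends, index=vip.bin_ids, name="trend"), conflicts


def _group_day_means(fm: FeatureMatrix) -> tuple[np.ndarray, list[int], np.ndarray]:
    days = sorted({s.day for s in fm.samples if s.day is not None})
    means = np.vstack([
        fm.values[[i for i, s in enumerate(fm.samples) if s.day == d]].mean(axis=0)
        for d in days
    ])
    return means, days, np.array(days)


def induced_criterion(
    fm_treatment: FeatureMatrix,
    fm_control: FeatureMatrix,
    vip: VIPReports,
    p_max: float = 0.005,
    fold_min: float = 3.0,
    vip_threshold: float = 1.0,
    occurrence_frac: float = 0.05,
) -> pd.DataFrame:
    """Flag treatment-induced bins by the VIP / t-test / fold triple rule.

    Both matrices must hold the same bins at the normalized (pre-g-log)
    stage, study samples only. Returns one row per bin with the fold
    change, Welch p-value, the three sub-criteria and the final flag.
    """
    if fm_treatment.bin_ids != fm_control.bin_ids:
        raise ValueError("treatment and control matrices must share the same bins")
    if fm_treatment.bin_ids != vip.bin_ids:
        raise ValueError("VIP report bins do not match the matrices")
    t_rows = [i for i, s in enumerate(fm_treatment.samples) if s.group in ("B", "F")]
    c_rows = [i for i, s in enumerate(fm_control.samples) if s.group in ("B", "F")]
    if len(t_rows) < 2 or len(c_rows) < 2:
        raise ValueError("need at least 2 study samples per group")
    tv = fm_treatment.values[t_rows]
    cv = fm_control.values[c_rows]
    t_days = np.array([fm_treatment.samples[i].day for i in t_rows])
    c_days = np.array([fm_control.samples[i].day for i in c_rows])

    day_means, days, _ = _group_day_means(fm_treatment)
    eps = 1e-12  # floor on a unit-total-area scale
    vip_flag = vip.any_above(vip_threshold)

    rows = []
    for j, bid in enumerate(fm_treatment.bin_ids):
        mean_t = tv[:, j].mean()
        mean_c = cv[:, j].mean()
        fold = mean_t / max(mean_c, eps)

        # occurrence window: days where the treatment day-mean is material
        dm = day_means[:, j]
        window = [d for d, m in zip(days, dm) if m > occurrence_frac * dm.max()]
        t_sel = np.log(tv[np.isin(t_days, window), j] + eps)
        c_sel = np.log(cv[np.isin(c_days, window), j] + eps)
        if len(t_sel) >= 2 and len(c_sel) >= 2 and (t_sel.var() + c_sel.var()) > 0:
            p = float(stats.ttest_ind(t_sel, c_sel, equal_var=False).pvalue)
        else:
            p = 1.0

        rows.append({
            "bin_id": bid,
            "vip_pass": bool(vip_flag[j]),
            "p_value": p,
            "p_pass": p < p_max,
            "fold_change": float(fold),
            "fold_pass": fold >= fold_min,
            "induced": bool(vip_flag[j]) and (p < p_max) and (fold >= fold_min),
        })
    return pd.DataFrame(rows)


def spearman_bin_correlation(fm: FeatureMatrix) -> tuple[pd.DataFrame, list[int]]:
    """Bin x bin Spearman rank correlation (average tie handling).

    Constant bins have undefined correlations, reported as 0 and returned
    in the flag list.
    """
    if fm.n_samples < 3:
        raise ValueError("need at least 3 samples")
    x = fm.values
    const = [fm.bin_ids[j] for j in range(fm.n_bins) if np.ptp(x[:, j]) == 0]
    import warnings as _warnings

    with _warnings.catch_warnings():
        # constant bins are handled below (reported as 0 and flagged)
        _warnings.simplefilter("ignore", stats.ConstantInputWarning)
        if fm.n_bins == 1:
            corr = np.ones((1, 1))
        elif fm.n_bins == 2:
            r, _ = stats.spearmanr(x[:, 0], x[:, 1])
            corr = np.array([[1.0, r], [r, 1.0]])
        else:
            corr, _ = stats.spearmanr(x)
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=fm.bin_ids, columns=fm.bin_ids), const


def biomarker_report(
    trends: pd.Series,
    induced: pd.DataFrame,
    vip: VIPReports,
) -> pd.DataFrame:
    """Merge VIPs, trend classes and induced flags into one table."""
    df = induced.set_index("bin_id")
    df.insert(0, "vip_plsr_treatment", vip.plsr_treatment)
    if vip.plsr_control is not None:
        df.insert(1, "vip_plsr_control", vip.plsr_control)
    if vip.plsda_per_class is not None and vip.plsda_classes is not None:
        for k, cname in enumerate(vip.plsda_classes):
            df[f"vip_plsda_{cname}"] = vip.plsda_per_class[:, k]
    if vip.plsr_coef_treatment is not None:
        df["coef_sign"] = np.sign(vip.plsr_coef_treatment)
    df["trend"] = trends
    return df.reset_index()


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional guard against multiplicity)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
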