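"""Preprocessing chain and QC filters for binned LC-MS intensity tables.

The chain mirrors standard chemometric practice for TIC-binned data:
retention-time edge trimming, asymmetric-least-squares (Whittaker) baseline
correction for point traces, total-area normalization, generalized-log
transformation and autoscaling, together with pooled-QC relative standard
deviation, signal-to-noise, replicate-occurrence and blank/medium filters.

Notes on two scale-sensitive choices:

* the g-log is ``g(x) = ln(x + sqrt(x^2 + lambda))``; the variant with a
  division by 2 inside the logarithm differs only by a constant ``ln 2``
  which autoscaling removes, so the two are downstream-equivalent;
* ``glog_lambda`` (default 0.1) applies to total-area-normalized rows
  (unit sum), i.e. after :func:`normalize_total_area` — the transform is
  scale-dependent, so the order matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .core import FeatureMatrix, subset


@dataclass
class PreprocessConfig:
    rt_lo: float = 11.5
    rt_hi: float = 31.0
    whittaker_lambda: float = 100.0
    whittaker_p: float = 0.001
    whittaker_max_iter: int = 10
    glog_lambda: float = 0.1
    rsd_max_pct: float = 25.0
    snr_min: float = 5.0
    occurrence_min_frac: float = 0.75

    def __post_init__(self) -> None:
        if not self.rt_lo < self.rt_hi:
            raise ValueError("rt_lo must be below rt_hi")
        if not (0 < self.whittaker_p < 1):
            raise ValueError("whittaker_p must be in (0, 1)")
        for name in ("whittaker_lambda", "glog_lambda", "rsd_max_pct", "snr_min",
                     "occurrence_min_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def trim_rt(fm: FeatureMatrix, cfg: PreprocessConfig) -> FeatureMatrix:
    """Keep bins inside the closed RT window [rt_lo, rt_hi]."""
    try:
        out = subset(fm, bin_filter=lambda b: cfg.rt_lo <= b.rt_min <= cfg.rt_hi)
    except ValueError:
        raise ValueError(
            f"no bins inside RT window [{cfg.rt_lo}, {cfg.rt_hi}]"
        ) from None
    out.stage = "trimmed"
    return out


def whittaker_system(
    y: np.ndarray, w: np.ndarray, lam: float
) -> tuple[sp.csc_matrix, np.ndarray]:
    """Left-hand matrix and right-hand side of (W + lam D'D) z = W y."""
    m = len(y)
    d = sp.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(m - 2, m))
    a = sp.diags_array(w) + lam * (d.T @ d)
    return sp.csc_matrix(a), w * y


def baseline_whittaker(
    trace: np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric-least-squares baseline of a single trace.

    The baseline z minimizes ``sum_i w_i (y_i - z_i)^2 + lam sum (d2 z)^2``
    with weights ``w_i = p`` where ``y_i > z_i`` and ``1 - p`` elsewhere,
    iterated until the weights stop changing (at most
    ``whittaker_max_iter`` sweeps, with a warning when not converged).
    Returns ``(baseline, corrected)`` where corrected = max(y - z, 0).
    """
    cfg = cfg or PreprocessConfig()
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise ValueError("trace must be 1-D with length >= 4")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in trace")
    p, lam = cfg.whittaker_p, cfg.whittaker_lambda
    w = np.full(len(y), 1.0 - p)
    # tolerance keeps exact fits (flat/linear traces) from oscillating on
    # floating-point residuals
    resid_tol = 1e-9 * (float(np.max(np.abs(y))) + 1.0)
    for _ in range(cfg.whittaker_max_iter):
        a, rhs = whittaker_system(y, w, lam)
        z = spsolve(a, rhs)
        w_new = np.where(y - z > resid_tol, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    else:
        warnings.warn("Whittaker weights did not converge; returning last iterate",
                      stacklevel=2)
    return z, np.clip(y - z, 0.0, None)


def normalize_total_area(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each sample row by its total area so rows sum to one."""
    sums = fm.values.sum(axis=1)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ValueError(f"zero total area for sample {fm.samples[zero[0]].sample_id!r}")
    return fm.with_values(fm.values / sums[:, None], stage="normalized")


def glog(fm: FeatureMatrix, cfg: PreprocessConfig | None = None) -> FeatureMatrix:
    """Generalized log transform g(x) = ln(x + sqrt(x^2 + lambda))."""
    cfg = cfg or PreprocessConfig()
    if np.any(fm.values < 0):
        raise ValueError("g-log requires non-negative intensities")
    x = fm.values
    out = fm.with_values(np.log(x + np.sqrt(x * x + cfg.glog_lambda)), stage="glogged")
    out.stage = "glogged"
    return out


def autoscale(fm: FeatureMatrix) -> FeatureMatrix:
    """Mean-centre and scale each bin to unit (n-1) standard deviation."""
    mu = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0, ddof=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance bin {fm.bins[dead[0]].bin_id}")
    return fm.with_values((fm.values - mu) / sd, stage="autoscaled")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _drop_bins(fm: FeatureMatrix, drop: set[int]) -> FeatureMatrix:
    if not drop:
        return fm.copy()
    return subset(fm, bin_filter=lambda b: b.bin_id not in drop)


def rsd_filter(
    fm: FeatureMatrix, cfg: PreprocessConfig | None = None
) -> tuple[FeatureMatrix, list[dict]]:
    """Drop bins with pooled-QC relative standard deviation above the cap.

    RSD = 100 * sd / mean over the QC rows, on raw (pre-transform)
    intensities with an (n-1) standard deviation. Bins whose QC mean is
    zero have undefined RSD and are dropped with their own reason code.
    """
    cfg = cfg or PreprocessConfig()
    qc_rows = [i for i, s in enumerate(fm.samples) if s.group == "QC"]
    if len(qc_rows) < 2:
        raise ValueError("rsd_filter needs at least 2 QC samples")
    qc = fm.values[qc_rows]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    removed = []
    for j, b in enumerate(fm.bins):
        if mean[j] == 0:
            removed.append({"stage": "rsd_filter", "bin_id": b.bin_id,
                            "reason": "undefined RSD (QC mean 0)"})
        elif 100.0 * sd[j] / mean[j] > cfg.rsd_max_pct:
            removed.append({"stage": "rsd_filter", "bin_id": b.bin_id,
                            "reason": f"QC RSD {100.0 * sd[j] / mean[j]:.2f}% > {cfg.rsd_max_pct}%"})
    return _drop_bins(fm, {r["bin_id"] for r in removed}), removed


def _cell_means(fm: FeatureMatrix) -> np.ndarray:
    """Per-(group, day) replicate-mean intensities, cells x bins."""
    cells: dict[tuple, list[int]] = {}
    for i, s in enumerate(fm.samples):
        if s.group in ("B", "F"):
            cells.setdefault((s.group, s.day), []).append(i)
    if not cells:
        raise ValueError("no study (B/F) samples present")
    return np.vstack([fm.values[idx].mean(axis=0) for idx in cells.values()])


def snr_filter(
    fm: FeatureMatrix, noise_level: float, cfg: PreprocessConfig | None = None
) -> tuple[FeatureMatrix, list[dict]]:
    """Drop bins whose best (group, day) mean is below snr_min x noise."""
    cfg = cfg or PreprocessConfig()
    if not noise_level > 0:
        raise ValueError("noise_level must be positive")
    peak = _cell_means(fm).max(axis=0)
    removed = [
        {"stage": "snr_filter", "bin_id": b.bin_id,
         "reason": f"SNR {peak[j] / noise_level:.2f} < {cfg.snr_min}"}
        for j, b in enumerate(fm.bins)
        if peak[j] / noise_level < cfg.snr_min
    ]
    return _drop_bins(fm, {r["bin_id"] for r in removed}), removed


def occurrence_filter(
    fm: FeatureMatrix, detection_floor: float, cfg: PreprocessConfig | None = None
) -> tuple[FeatureMatrix, list[dict]]:
    """Keep bins detected in >= occurrence_min_frac of replicates somewhere.

    A bin survives when at least one (group, day) cell has a fraction of
    replicates with intensity above ``detection_floor`` at or above the
    configured minimum.
    """
    cfg = cfg or PreprocessConfig()
    cells: dict[tuple, list[int]] = {}
    for i, s in enumerate(fm.samples):
        if s.group in ("B", "F"):
            cells.setdefault((s.group, s.day), []).append(i)
    if not cells:
        raise ValueError("occurrence_filter needs replicate structure (B/F samples)")
    best = np.zeros(fm.n_bins)
    for idx in cells.values():
        frac = (fm.values[idx] > detection_floor).mean(axis=0)
        best = np.maximum(best, frac)
    removed = [
        {"stage": "occurrence_filter", "bin_id": b.bin_id,
         "reason": f"max replicate occurrence {best[j]:.2f} < {cfg.occurrence_min_frac}"}
        for j, b in enumerate(fm.bins)
        if best[j] < cfg.occurrence_min_frac
    ]
    return _drop_bins(fm, {r["bin_id"] for r in removed}), removed


def blank_subtraction(
    fm: FeatureMatrix,
    os_bins: Sequence[int] = (),
    cm_bins: Sequence[int] = (),
) -> tuple[FeatureMatrix, list[dict]]:
    """Remove organic-solvent contaminant bins; flag culture-medium bins.

    CM bins stay in the matrix (they carry the negatively-correlated
    medium-consumption signal) but get a ``culture_medium`` label.
    """
    known = set(fm.bin_ids)
    for bid in list(os_bins) + list(cm_bins):
        if bid not in known:
            raise ValueError(f"unknown bin_id {bid} in reference list")
    log = [
        {"stage": "blank_subtraction", "bin_id": bid, "reason": "organic-solvent contaminant"}
        for bid in os_bins
    ]
    out = _drop_bins(fm, set(os_bins))
    if cm_bins:
        cm = set(cm_bins)
        new_bins = []
        for b in out.bins:
            if b.bin_id in cm:
                label = f"{b.label}; culture_medium" if b.label else "culture_medium"
                new_bins.append(
                    type(b)(bin_id=b.bin_id, rt_min=b.rt_min, mz=b.mz, label=label)
                )
                log.append({"stage": "blank_subtraction", "bin_id": b.bin_id,
                            "reason": "flagged culture_medium"})
            else:
                new_bins.append(b)
        out = FeatureMatrix(out.values, out.samples, new_bins, out.stage)
    return out, log


def run_preprocess(
    fm_raw: FeatureMatrix,
    cfg: PreprocessConfig | None = None,
    noise_level: float | None = None,
    detection_floor: float | None = None,
    os_bins: Sequence[int] = (),
    cm_bins: Sequence[int] = (),
) -> tuple[FeatureMatrix, list[dict]]:
    """Full chain: trim -> SNR -> occurrence -> RSD -> blanks -> normalize
    -> g-log -> autoscale. Returns the autoscaled matrix and a provenance
    log recording every bin removal with a reason code.

    ``noise_level`` defaults to the MAD-based estimate from OS blank rows
    when present (1.4826 x median absolute deviation); without OS rows and
    without an explicit value the SNR filter is skipped (logged).
    ``detection_floor`` defaults to the noise level (or 0 when unknown).
    """
    cfg = cfg or PreprocessConfig()
    log: list[dict] = []
    fm = trim_rt(fm_raw, cfg)
    kept = {b.bin_id for b in fm.bins}
    log += [
        {"stage": "trim_rt", "bin_id": b.bin_id, "reason": "outside RT window"}
        for b in fm_raw.bins
        if b.bin_id not in kept
    ]

    if noise_level is None:
        os_rows = [i for i, s in enumerate(fm.samples) if s.group == "OS"]
        if os_rows:
            blank = fm.values[os_rows]
            noise_level = float(1.4826 * np.median(np.abs(blank - np.median(blank))))
    if noise_level and noise_level > 0:
        fm, rm = snr_filter(fm, noise_level, cfg)
        log += rm
    else:
        log.append({"stage": "snr_filter", "bin_id": None,
                    "reason": "skipped: no noise estimate available"})

    floor = detection_floor if detection_floor is not None else (noise_level or 0.0)
    fm, rm = occurrence_filter(fm, floor, cfg)
    log += rm

    if any(s.group == "QC" for s in fm.samples):
        fm, rm = rsd_filter(fm, cfg)
        log += rm
    else:
        log.append({"stage": "rsd_filter", "bin_id": None,
                    "reason": "skipped: no QC samples"})

    fm, rm = blank_subtraction(fm, os_bins, cm_bins)
    log += rm

    fm = normalize_total_area(fm)
    fm = glog(fm, cfg)
    fm = autoscale(fm)
    return fm, log
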