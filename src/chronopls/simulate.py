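"""Synthetic generator for the two-group fungal time-course study design.

Real raw data for this kind of study (a *Fusarium* culture fed piperidine
alkaloids, harvested on incubation days 1/4/8/12/16 in triplicate, profiled
by LC-MS and reduced to 25 retention-time bins) are rarely shareable, so
this module emulates the design with planted ground truth. Each bin follows
one archetypal trajectory tied to the colony-growth signal
``g(day) = ln(diameter_cm)``:

``media_decay``
    culture-medium component consumed as the colony grows,
    mean ∝ 1 − g/g_max in both groups;
``growth_linked``
    constitutive fungal metabolite, mean ∝ g/g_max in both groups;
``alkaloid``
    fed compound, exponential decay in the feeding group (below 1% of its
    initial level by day 12), absent in the control;
``early_pulse`` / ``late_pulse``
    stress responses expressed only in the feeding group and only on day 4
    (early) or days 8+12 (late);
``stress_upregulated``
    constitutive growth-linked metabolite whose production is amplified
    several-fold under feeding (a beauvericin-like mycotoxin);
``inert``
    flat background bin.

Replicate scatter is multiplicative lognormal at a configured CV plus a
small additive floor (0.1% of the median base intensity) so raw intensities
stay strictly positive. Pooled-QC rows are the mean over all study samples
re-drawn with the same noise model.

The module also renders point-by-point chromatograms (Gaussian peaks on an
optional smooth baseline drift) and re-integrates them, so the baseline
corrector and the binning step can be exercised against known peak areas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BinMeta, FeatureMatrix, GrowthRecord, SampleMeta

ARCHETYPES = (
    "media_decay",
    "growth_linked",
    "alkaloid",
    "early_pulse",
    "late_pulse",
    "stress_upregulated",
    "inert",
)
FEEDING_ONLY = {"alkaloid", "early_pulse", "late_pulse"}
LINEAR_KINDS = {"media_decay", "growth_linked", "alkaloid", "stress_upregulated"}

DEFAULT_ARCHETYPE_COUNTS = {
    "media_decay": 5,
    "growth_linked": 8,
    "alkaloid": 2,
    "early_pulse": 3,
    "late_pulse": 2,
    "stress_upregulated": 1,
    "inert": 4,
}

#: colony diameters (cm) on days 1/4/8/12/16 in a 9 cm Petri dish
DIAMETERS_FEEDING = (1.0, 3.19, 7.54, 8.41, 9.0)
DIAMETERS_CONTROL = (1.0, 4.9, 8.0, 8.5, 9.0)


@dataclass(frozen=True)
class BinArchetype:
    """Planted behaviour of one bin."""

    kind: str
    base_intensity: float
    group_restriction: str = "both"  # both | feeding_only
    pulse_days: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPES:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        if self.kind in FEEDING_ONLY and self.group_restriction != "feeding_only":
            raise ValueError(f"{self.kind} bins must be feeding_only")
        if self.kind.endswith("_pulse") and not self.pulse_days:
            raise ValueError("pulse kinds need non-empty pulse_days")


@dataclass
class SimConfig:
    """Study-design parameters for :func:`simulate_dataset`."""

    n_replicates: int = 3
    days: tuple[int, ...] = (1, 4, 8, 12, 16)
    archetype_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_COUNTS)
    )
    replicate_cv: float = 0.10
    qc_count: int = 3
    seed: int = 0
    diameters_feeding: tuple[float, ...] = DIAMETERS_FEEDING
    diameters_control: tuple[float, ...] = DIAMETERS_CONTROL
    stress_fold: float = 5.0
    alkaloid_decay_rate: float = 0.45  # per day; <1% of initial by day 12
    rt_lo: float = 11.5
    rt_hi: float = 31.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if sum(self.archetype_counts.values()) < 1:
            raise ValueError("archetype counts sum to 0")
        for k in self.archetype_counts:
            if k not in ARCHETYPES:
                raise ValueError(f"unknown archetype kind {k!r}")
        if len(self.diameters_feeding) != len(self.days) or len(
            self.diameters_control
        ) != len(self.days):
            raise ValueError("diameter lists must align with days")
        if not (0 <= self.replicate_cv < 1):
            raise ValueError("replicate_cv must be in [0, 1)")

    @property
    def n_bins(self) -> int:
        return sum(self.archetype_counts.values())


@dataclass
class GroundTruth:
    """Planted per-bin truth for recovery testing."""

    table: pd.DataFrame  # bin_id, kind, plsr_relevant, plsda_class, induced

    def kinds(self) -> pd.Series:
        return self.table.set_index("bin_id")["kind"]

    def induced_bins(self) -> list[int]:
        return self.table.loc[self.table["induced"], "bin_id"].tolist()


def growth_signal(diameters: Sequence[float]) -> np.ndarray:
    """Normalized log-diameter growth signal g(day)/g(max)."""
    g = np.log(np.asarray(diameters, dtype=float))
    return g / g[-1]


def _archetype_layout(cfg: SimConfig, rng: np.random.Generator) -> list[BinArchetype]:
    kinds: list[str] = []
    for kind in ARCHETYPES:  # fixed order, then shuffled deterministically
        kinds += [kind] * cfg.archetype_counts.get(kind, 0)
    rng.shuffle(kinds)
    arts = []
    for kind in kinds:
        base = float(10 ** rng.uniform(4.7, 5.7))
        if kind == "early_pulse":
            arts.append(BinArchetype(kind, base, "feeding_only", (4,)))
        elif kind == "late_pulse":
            arts.append(BinArchetype(kind, base, "feeding_only", (8, 12)))
        elif kind == "alkaloid":
            arts.append(BinArchetype(kind, base, "feeding_only"))
        else:
            arts.append(BinArchetype(kind, base))
    return arts


def _mean_trajectory(
    art: BinArchetype, cfg: SimConfig, group: str, gn: np.ndarray
) -> np.ndarray:
    """Noise-free mean intensity per day for one bin in one group."""
    days = np.asarray(cfg.days)
    base = art.base_intensity
    if art.kind == "media_decay":
        return base * (1.0 - gn)
    if art.kind == "growth_linked":
        return base * gn
    if art.kind == "inert":
        return np.full(days.shape, base)
    if art.kind == "stress_upregulated":
        fold = cfg.stress_fold if group == "B" else 1.0
        return fold * base * gn
    # feeding-only kinds: flat zero in the control
    if group != "B":
        return np.zeros(days.shape)
    if art.kind == "alkaloid":
        return base * np.exp(-cfg.alkaloid_decay_rate * (days - days[0]))
    if art.kind.endswith("_pulse"):
        return np.where(np.isin(days, art.pulse_days), base, 0.0)
    raise AssertionError(art.kind)


def _noisy(mean: np.ndarray, floor: float, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal noise at given CV plus a small additive floor."""
    if cv == 0:
        return mean + floor
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = -0.5 * sigma * sigma  # unit-mean lognormal
    f1 = rng.lognormal(mu, sigma, size=mean.shape)
    f2 = rng.lognormal(mu, sigma, size=mean.shape)
    return mean * f1 + floor * f2


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[FeatureMatrix, FeatureMatrix, dict[str, list[GrowthRecord]], GroundTruth]:
    """Generate feeding (B) and control (F) matrices plus growth and truth.

    Deterministic given ``cfg.seed``. Each matrix holds
    ``len(days) * n_replicates`` study rows followed by ``qc_count``
    pooled-QC rows (QC pooled over both groups).
    """
    rng = np.random.default_rng(cfg.seed)
    arts = _archetype_layout(cfg, rng)
    n_bins = len(arts)

    # retention times spread over the analysis window; fed alkaloids pinned
    # at their characteristic RTs when present
    rts = np.linspace(cfg.rt_lo + 0.6, cfg.rt_hi - 0.6, n_bins)
    bins: list[BinMeta] = []
    alk_rts = iter((13.3, 15.4))
    alk_labels = iter(("A1 cassine", "A2 spectaline"))
    for j, art in enumerate(arts):
        label = None
        if art.kind == "alkaloid":
            label = next(alk_labels, None)
        bins.append(BinMeta(bin_id=j + 1, rt_min=float(rts[j]), label=label))

    floor = 0.001 * float(np.median([a.base_intensity for a in arts]))
    gn = {"B": growth_signal(cfg.diameters_feeding), "F": growth_signal(cfg.diameters_control)}

    matrices: dict[str, np.ndarray] = {}
    samples: dict[str, list[SampleMeta]] = {}
    for group in ("B", "F"):
        means = np.column_stack(
            [_mean_trajectory(a, cfg, group, gn[group]) for a in arts]
        )  # days x bins
        rows, meta = [], []
        for di, day in enumerate(cfg.days):
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(_noisy(means[di], floor, cfg.replicate_cv, rng))
                meta.append(SampleMeta(f"{group}{day}_r{rep}", group, int(day), rep))
        matrices[group] = np.vstack(rows)
        samples[group] = meta

    pooled = np.vstack([matrices["B"], matrices["F"]]).mean(axis=0)
    for group in ("B", "F"):
        qc_rows, qc_meta = [], []
        for k in range(1, cfg.qc_count + 1):
            qc_rows.append(_noisy(pooled, floor, cfg.replicate_cv, rng))
            qc_meta.append(SampleMeta(f"QC{group}_{k}", "QC", None, k))
        if qc_rows:
            matrices[group] = np.vstack([matrices[group], qc_rows])
            samples[group] = samples[group] + qc_meta

    fm_b = FeatureMatrix(matrices["B"], samples["B"], list(bins), stage="raw")
    fm_f = FeatureMatrix(matrices["F"], samples["F"], list(bins), stage="raw")

    growth = {
        "B": [GrowthRecord(int(d), float(x)) for d, x in zip(cfg.days, cfg.diameters_feeding)],
        "F": [GrowthRecord(int(d), float(x)) for d, x in zip(cfg.days, cfg.diameters_control)],
    }

    truth_rows = []
    for b, art in zip(bins, arts):
        if art.kind == "early_pulse":
            plsda_class = "4"
        elif art.kind == "late_pulse":
            plsda_class = "8/12"
        elif art.kind in ("media_decay", "alkaloid"):
            plsda_class = "1"
        elif art.kind in ("growth_linked", "stress_upregulated"):
            plsda_class = "16"
        else:
            plsda_class = ""
        induced = (
            art.kind in ("early_pulse", "late_pulse", "alkaloid")
            or (art.kind == "stress_upregulated" and cfg.stress_fold >= 3.0)
        )
        truth_rows.append(
            {
                "bin_id": b.bin_id,
                "kind": art.kind,
                "plsr_relevant": art.kind in LINEAR_KINDS,
                "plsda_class": plsda_class,
                "induced": induced,
            }
        )
    truth = GroundTruth(pd.DataFrame(truth_rows))
    return fm_b, fm_f, growth, truth


# ---------------------------------------------------------------------------
# chromatogram rendering and re-binning
# ---------------------------------------------------------------------------

def render_chromatograms(
    fm: FeatureMatrix,
    rt_grid_step: float = 0.01,
    peak_width_sd: float = 0.08,
    baseline_drift_amplitude: float = 0.0,
    rt_pad: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render each sample row as a point-by-point chromatogram.

    Every bin becomes a Gaussian peak centred at its ``rt_min`` whose area
    equals the bin intensity; an optional smooth low-frequency baseline of
    the stated amplitude is added. Returns ``(rt_grid, traces)`` with traces
    of shape (n_samples, n_points).
    """
    if rt_grid_step <= 0:
        raise ValueError("rt_grid_step must be positive")
    centers = np.array([b.rt_min for b in fm.bins])
    order = np.argsort(centers)
    gaps = np.diff(centers[order])
    if np.any(gaps < 2 * peak_width_sd):
        warnings.warn("bins closer than 2x peak width: peaks will convolve", stacklevel=2)

    lo = centers.min() - rt_pad
    hi = centers.max() + rt_pad
    rt = np.arange(lo, hi + rt_grid_step / 2, rt_grid_step)
    # Gaussian basis: area-normalized peaks
    basis = np.exp(-0.5 * ((rt[None, :] - centers[:, None]) / peak_width_sd) ** 2)
    basis /= peak_width_sd * math.sqrt(2 * math.pi)
    traces = fm.values @ basis
    if baseline_drift_amplitude:
        span = hi - lo
        drift = baseline_drift_amplitude * (
            0.5 + 0.3 * (rt - lo) / span + 0.2 * np.sin(2 * math.pi * (rt - lo) / span)
        )
        traces = traces + drift[None, :]
    return rt, traces


def bin_chromatograms(
    rt: np.ndarray,
    traces: np.ndarray,
    bins: Sequence[BinMeta],
    window_half_width: float = 0.35,
    samples: Sequence[SampleMeta] | None = None,
    stage: str = "raw",
) -> FeatureMatrix:
    """Integrate traces over +-window around each bin centre (trapezoid)."""
    centers = np.array([b.rt_min for b in bins])
    order = np.argsort(centers)
    for a, b in zip(order, order[1:]):
        if centers[b] - centers[a] < 2 * window_half_width:
            raise ValueError(
                f"windows of bins {bins[a].bin_id} and {bins[b].bin_id} overlap"
            )
    values = np.zeros((traces.shape[0], len(bins)))
    for j, c in enumerate(centers):
        if c - window_half_width < rt[0] or c + window_half_width > rt[-1]:
            raise ValueError(f"window of bin {bins[j].bin_id} outside trace RT span")
        mask = (rt >= c - window_half_width) & (rt <= c + window_half_width)
        if mask.sum() >= 2:
            values[:, j] = np.trapezoid(traces[:, mask], rt[mask], axis=1)
    if samples is None:
        samples = [SampleMeta(f"S{i + 1}", "QC", None, i + 1) for i in range(traces.shape[0])]
    return FeatureMatrix(np.clip(values, 0, None), list(samples), list(bins), stage=stage)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, index=False)
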