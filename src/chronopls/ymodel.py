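"""Growth-informed response vectors for supervised modelling.

A time-course PLS regression needs a quantitative response per sample. Two
microbial-specific candidates are supported — the incubation day itself and
the measured colony diameter on that day — each either raw or after a
natural-log transform. The log of the colony diameter jointly encodes
growth rate and remaining medium availability, which is why it tends to
out-predict calendar time: replicate cultures do not develop at the same
pace, but their chemistry tracks how far the colony has actually grown.

Candidate models are compared by leave-one-out Q^2 (cross-validated R^2)
with permutation-test guards: the winner is the candidate with the highest
Q^2 among those whose Wilcoxon, sign-test and t-test permutation p-values
are all below 0.05; ties break toward fewer latent components, then listed
order.

``format_table_value`` reproduces the truncation-toward-zero convention of
two-decimal printed tables (ln 8 = 2.0794 prints as 2.07, not 2.08).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GrowthRecord, SampleMeta
from .validation import loo_cv, permutation_test


@dataclass
class YModel:
    """Response vector aligned to a sample list."""

    values: np.ndarray
    source: str      # "days" | "diameter"
    treatment: str   # "raw" | "log"
    design: dict[int, float]  # day -> y

    @property
    def name(self) -> str:
        return f"{self.source}_{self.treatment}"


@dataclass
class CandidateResult:
    name: str
    r2cv: float
    chosen_a: int
    p_wilcoxon: float
    p_sign: float
    p_ttest: float
    valid: bool
    failure: str | None = None


@dataclass
class ModelComparison:
    candidates: list[CandidateResult]
    winner: str | None


def truncate_decimals(x: float, decimals: int = 2) -> float:
    """Truncate toward zero at the given number of decimals."""
    f = 10.0 ** decimals
    return math.trunc(x * f) / f


def format_table_value(x: float, decimals: int = 2) -> str:
    """Printed-table formatting: truncation toward zero, trailing zeros kept."""
    return f"{truncate_decimals(x, decimals):.{decimals}f}"


def build_y(
    samples: Sequence[SampleMeta],
    growth: Sequence[GrowthRecord] | None,
    source: str,
    treatment: str,
) -> YModel:
    """Per-sample response from incubation day or colony diameter.

    Replicates of the same (group, day) share one design value; the log
    treatment is the natural logarithm and requires positive sources.
    """
    if source not in ("days", "diameter"):
        raise ValueError(f"unknown source {source!r}")
    if treatment not in ("raw", "log"):
        raise ValueError(f"unknown treatment {treatment!r}")

    days = []
    for s in samples:
        if s.day is None:
            raise ValueError(f"sample {s.sample_id!r} carries no incubation day")
        days.append(s.day)

    if source == "days":
        base = {d: float(d) for d in sorted(set(days))}
    else:
        if growth is None:
            raise ValueError("diameter source needs growth records")
        by_day = {r.day: r.diameter_cm for r in growth}
        missing = sorted(set(days) - set(by_day))
        if missing:
            raise ValueError(f"growth records missing day(s) {missing}")
        base = {d: float(by_day[d]) for d in sorted(set(days))}

    if treatment == "log":
        for d, v in base.items():
            if v <= 0:
                raise ValueError(f"log treatment undefined for day {d} value {v}")
        design = {d: math.log(v) for d, v in base.items()}
    else:
        design = base
    return YModel(
        values=np.array([design[d] for d in days]),
        source=source, treatment=treatment, design=design,
    )


def default_candidates(
    samples: Sequence[SampleMeta], growth: Sequence[GrowthRecord]
) -> list[YModel]:
    """The four-candidate grid: {days, diameter} x {raw, log}."""
    return [
        build_y(samples, growth, src, tr)
        for src in ("days", "diameter")
        for tr in ("raw", "log")
    ]


def compare_y_models(
    X: np.ndarray,
    candidates: Sequence[YModel],
    a_max: int = 5,
    n_perm: int = 199,
    seed: int = 0,
    alpha: float = 0.05,
    scale: bool = True,
) -> ModelComparison:
    """Fit a PLSr per candidate and pick the best-validated response model.

    Winner rule: among candidates whose three permutation p-values are all
    below ``alpha``, take the highest cross-validated R^2 (Q^2); ties break
    toward fewer latent components, then listed order.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    X = np.asarray(X, dtype=float)
    results: list[CandidateResult] = []
    for cand in candidates:
        try:
            cv = loo_cv(X, cand.values, a_max=a_max, scale=scale)
            perm = permutation_test(
                X, cand.values, cv.chosen_a, n_perm=n_perm, seed=seed, scale=scale
            )
        except ValueError as exc:
            results.append(CandidateResult(cand.name, float("nan"), 0,
                                           1.0, 1.0, 1.0, False, failure=str(exc)))
            continue
        ps = (perm.p_wilcoxon, perm.p_sign, perm.p_ttest)
        results.append(CandidateResult(
            name=cand.name, r2cv=cv.q2, chosen_a=cv.chosen_a,
            p_wilcoxon=ps[0], p_sign=ps[1], p_ttest=ps[2],
            valid=all(p < alpha for p in ps),
        ))

    eligible = [
        (i, r) for i, r in enumerate(results) if r.valid and np.isfinite(r.r2cv)
    ]
    winner = None
    if eligible:
        # max Q2, ties -> fewer components -> listed order
        best = max(eligible, key=lambda ir: (ir[1].r2cv, -ir[1].chosen_a, -ir[0]))
        winner = best[1].name
    return ModelComparison(candidates=results, winner=winner)


def comparison_table(cmp: ModelComparison, candidates: Sequence[YModel]) -> pd.DataFrame:
    """Tabular view of a model comparison (one row per candidate)."""
    by_name = {c.name: c for c in candidates}
    rows = []
    for r in cmp.candidates:
        cand = by_name.get(r.name)
        row = {"candidate": r.name, "r2cv": r.r2cv, "n_components": r.chosen_a,
               "p_wilcoxon": r.p_wilcoxon, "p_sign": r.p_sign, "p_ttest": r.p_ttest,
               "winner": r.name == cmp.winner}
        if cand is not None:
            for k, (day, y) in enumerate(sorted(cand.design.items()), start=1):
                row[f"class{k}_day{day}"] = truncate_decimals(y)
        rows.append(row)
    return pd.DataFrame(rows)
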