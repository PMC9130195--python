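"""Shared data model for binned LC-MS feature tables.

The analysis operates on a dense samples x bins intensity matrix carrying
typed metadata on both axes: each sample is one LC-MS run of a fungal
culture (treatment group, incubation day, replicate) or a technical
reference (pooled QC, organic-solvent blank, culture-medium reference);
each bin is one integrated retention-time window of the total ion
chromatogram. Everything downstream (preprocessing, PLS modelling,
biomarker calls) transforms :class:`FeatureMatrix` objects.

On disk a matrix is a three-file comma-separated dialect:

* ``features.csv`` — header ``sample_id,<bin_id>,...``; one row per sample;
* ``samples.csv``  — ``sample_id,group,day,replicate`` (day empty for
  QC/OS/CM rows);
* ``bins.csv``     — ``bin_id,rt_min,mz,label`` (mz and label optional).

Colony growth records use a fourth file, ``growth.csv`` with header
``day,diameter_cm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

VALID_GROUPS = ("B", "F", "QC", "OS", "CM")
#: groups that denote biological study samples (carry an incubation day)
STUDY_GROUPS = ("B", "F")
STAGES = ("raw", "trimmed", "baselined", "normalized", "glogged", "autoscaled")
PLATE_DIAMETER_CM = 9.0


class ParseError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass(frozen=True)
class SampleMeta:
    """One LC-MS run: treatment group, incubation day and replicate index.

    ``group`` is ``B`` (alkaloidal feeding), ``F`` (control), ``QC``
    (pooled quality control), ``OS`` (organic-solvent blank) or ``CM``
    (culture-medium reference). Only B/F samples carry a day.
    """

    sample_id: str
    group: str
    day: int | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r} for sample {self.sample_id!r}")
        if self.group in STUDY_GROUPS:
            if self.day is None:
                raise ValueError(f"sample {self.sample_id!r} in group {self.group} needs a day")
        elif self.day is not None:
            raise ValueError(f"{self.group} sample {self.sample_id!r} must not carry a day")
        if self.replicate < 1:
            raise ValueError(f"replicate must be positive for sample {self.sample_id!r}")


@dataclass(frozen=True)
class BinMeta:
    """One retention-time bin (variable) of the chromatogram."""

    bin_id: int
    rt_min: float
    mz: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.bin_id < 1:
            raise ValueError("bin_id must be a positive integer")
        if not (self.rt_min > 0):
            raise ValueError(f"bin {self.bin_id}: rt_min must be strictly positive")


@dataclass(frozen=True)
class GrowthRecord:
    """Colony diameter (cm) measured on one incubation day."""

    day: int
    diameter_cm: float

    def __post_init__(self) -> None:
        if not (0 < self.diameter_cm <= PLATE_DIAMETER_CM):
            raise ValueError(
                f"day {self.day}: diameter {self.diameter_cm} cm outside (0, {PLATE_DIAMETER_CM}]"
            )


def validate_growth(records: Sequence[GrowthRecord]) -> None:
    """Check diameters are non-decreasing with day."""
    ordered = sorted(records, key=lambda r: r.day)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.diameter_cm < prev.diameter_cm:
            raise ValueError(
                f"diameter decreases from day {prev.day} ({prev.diameter_cm}) "
                f"to day {cur.day} ({cur.diameter_cm})"
            )


@dataclass
class FeatureMatrix:
    """Dense samples x bins intensity table with aligned metadata.

    ``stage`` tags how far through the preprocessing chain the values are;
    raw through normalized stages must hold finite non-negative values,
    the autoscaled stage holds centred values of either sign.
    """

    values: np.ndarray
    samples: list[SampleMeta]
    bins: list[BinMeta]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.samples):
            raise ValueError(f"{n} rows but {len(self.samples)} sample records")
        if p != len(self.bins):
            raise ValueError(f"{p} columns but {len(self.bins)} bin records")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dup}")
        bids = [b.bin_id for b in self.bins]
        if len(set(bids)) != len(bids):
            dup = sorted({i for i in bids if bids.count(i) > 1})
            raise ValueError(f"duplicate bin_id(s): {dup}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite intensity values")
        # g-log of sub-unit intensities and autoscaled values may be negative
        if self.stage not in ("glogged", "autoscaled") and np.any(self.values < 0):
            raise ValueError(f"negative intensities at stage {self.stage!r}")

    # -- conveniences -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def bin_ids(self) -> list[int]:
        return [b.bin_id for b in self.bins]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.bin_ids)

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "FeatureMatrix":
        return FeatureMatrix(
            values=np.asarray(values, dtype=float),
            samples=list(self.samples),
            bins=list(self.bins),
            stage=stage or self.stage,
        )

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), list(self.samples), list(self.bins), self.stage)


def subset(
    fm: FeatureMatrix,
    sample_filter: Callable[[SampleMeta], bool] | None = None,
    bin_filter: Callable[[BinMeta], bool] | None = None,
) -> FeatureMatrix:
    """Restrict a matrix to samples/bins passing the predicates.

    Raises ``ValueError("empty selection")`` when nothing survives.
    """
    rows = [i for i, s in enumerate(fm.samples) if sample_filter is None or sample_filter(s)]
    cols = [j for j, b in enumerate(fm.bins) if bin_filter is None or bin_filter(b)]
    if not rows or not cols:
        raise ValueError("empty selection")
    return FeatureMatrix(
        fm.values[np.ix_(rows, cols)],
        [fm.samples[i] for i in rows],
        [fm.bins[j] for j in cols],
        fm.stage,
    )


# ---------------------------------------------------------------------------
# file dialect
# ---------------------------------------------------------------------------

def _sample_sort_key(s: SampleMeta):
    return (s.group, s.day if s.day is not None else -1, s.replicate)


def write_feature_matrix(fm: FeatureMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Emit the three-file dialect; values serialized at full precision.

    Samples are written sorted by (group, day, replicate); readers must not
    rely on order. Returns the paths written.
    """
    if fm.n_samples == 0:
        raise ValueError("empty matrix")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    order = sorted(range(fm.n_samples), key=lambda i: _sample_sort_key(fm.samples[i]))
    samples = [fm.samples[i] for i in order]
    values = fm.values[order]

    feats = pd.DataFrame(values, columns=[str(b.bin_id) for b in fm.bins])
    feats.insert(0, "sample_id", [s.sample_id for s in samples])
    f_path = out / "features.csv"
    # repr is the shortest exact decimal representation: bit-for-bit round-trip
    feats.to_csv(f_path, index=False, float_format=lambda v: repr(float(v)))

    smeta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "day": [("" if s.day is None else s.day) for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    s_path = out / "samples.csv"
    smeta.to_csv(s_path, index=False)

    bmeta = pd.DataFrame(
        {
            "bin_id": [b.bin_id for b in fm.bins],
            "rt_min": [b.rt_min for b in fm.bins],
            "mz": [("" if b.mz is None else b.mz) for b in fm.bins],
            "label": [("" if b.label is None else b.label) for b in fm.bins],
        }
    )
    b_path = out / "bins.csv"
    bmeta.to_csv(b_path, index=False)

    (out / "stage.txt").write_text(fm.stage + "\n", encoding="utf-8")
    return {"features": f_path, "samples": s_path, "bins": b_path, "stage": out / "stage.txt"}


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return int(v)


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_feature_matrix(
    matrix_path: str | Path,
    sample_meta_path: str | Path,
    bin_meta_path: str | Path,
    stage: str | None = None,
) -> FeatureMatrix:
    """Read the three-file dialect back into a :class:`FeatureMatrix`.

    Ordering is preserved from the files; metadata are joined by
    sample_id / bin_id with structured errors naming offending rows.
    """
    feats = pd.read_csv(matrix_path, dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in feats.columns:
        raise ParseError(f"{matrix_path}: missing 'sample_id' header")
    smeta = pd.read_csv(sample_meta_path, dtype={"sample_id": str})
    bmeta = pd.read_csv(bin_meta_path)

    if smeta["sample_id"].duplicated().any():
        dup = smeta.loc[smeta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{sample_meta_path}: duplicated sample_id {dup!r}")
    if bmeta["bin_id"].duplicated().any():
        dup = int(bmeta.loc[bmeta["bin_id"].duplicated(), "bin_id"].iloc[0])
        raise ParseError(f"{bin_meta_path}: duplicated bin_id {dup}")

    meta_by_id = {}
    for _, row in smeta.iterrows():
        meta_by_id[row["sample_id"]] = SampleMeta(
            sample_id=row["sample_id"],
            group=str(row["group"]),
            day=_opt_int(row.get("day")),
            replicate=int(row.get("replicate", 1)),
        )
    bin_by_id = {}
    for _, row in bmeta.iterrows():
        bin_by_id[int(row["bin_id"])] = BinMeta(
            bin_id=int(row["bin_id"]),
            rt_min=float(row["rt_min"]),
            mz=_opt_float(row.get("mz")),
            label=(None if pd.isna(row.get("label")) or row.get("label") == "" else str(row["label"])),
        )

    samples: list[SampleMeta] = []
    for sid in feats["sample_id"]:
        if sid not in meta_by_id:
            raise ParseError(f"{matrix_path}: sample_id {sid!r} absent from sample metadata")
        samples.append(meta_by_id[sid])

    bins: list[BinMeta] = []
    for col in feats.columns[1:]:
        try:
            bid = int(col)
        except ValueError as exc:
            raise ParseError(f"{matrix_path}: bin column {col!r} is not an integer id") from exc
        if bid not in bin_by_id:
            raise ParseError(f"{matrix_path}: bin_id {bid} absent from bin metadata")
        bins.append(bin_by_id[bid])

    raw = feats.iloc[:, 1:]
    try:
        values = raw.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                try:
                    float(raw.iat[i, j])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{matrix_path}: non-numeric intensity at row {i + 2}, "
                        f"column {raw.columns[j]!r}: {raw.iat[i, j]!r}"
                    ) from None
        raise

    if stage is None:
        stage_file = Path(matrix_path).parent / "stage.txt"
        stage = stage_file.read_text(encoding="utf-8").strip() if stage_file.exists() else "raw"
    return FeatureMatrix(values, samples, bins, stage=stage)


def write_growth(records: Sequence[GrowthRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"day": [r.day for r in records], "diameter_cm": [r.diameter_cm for r in records]}
    ).to_csv(path, index=False)
    return path


def read_growth(path: str | Path) -> list[GrowthRecord]:
    df = pd.read_csv(path)
    records = [GrowthRecord(int(r["day"]), float(r["diameter_cm"])) for _, r in df.iterrows()]
    validate_growth(records)
    return records
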