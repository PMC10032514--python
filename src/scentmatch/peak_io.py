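"""Peak-table and sample-manifest I/O.

A *peak table* is one sample's list of detected GCxGC peaks: an opaque peak
id, first- and second-dimension retention times in seconds, and a peak area
in arbitrary detector units.  The on-disk dialect is a plain UTF-8 CSV with
header ``peak_id,rt1_s,rt2_s,area,label`` ("." decimal separator); vendor
exports are expected to be converted to this layout by the user.

Sample-level metadata (subject, carrier material, exclusion flags) lives in a
separate *manifest* CSV with header
``sample_id,subject_id,carrier,exclude,exclude_reason`` so that sample
exclusions — e.g. dropping a contaminated sample — are recorded as data
rather than hard-coded.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import FormatError, RowError, ValidationError

__all__ = [
    "Carrier",
    "Peak",
    "PeakTable",
    "SampleMeta",
    "SampleSet",
    "read_peak_table",
    "write_peak_table",
    "read_manifest",
    "write_manifest",
    "read_sample_set",
    "write_sample_set",
    "write_matrix",
    "read_matrix",
]

PEAK_COLUMNS = ("peak_id", "rt1_s", "rt2_s", "area", "label")
MANIFEST_COLUMNS = ("sample_id", "subject_id", "carrier", "exclude", "exclude_reason")


class Carrier(str, Enum):
    """Material the scent sample was collected on."""

    glass_beads = "glass_beads"
    projectile = "projectile"
    fired_cartridge = "fired_cartridge"
    blank = "blank"


@dataclass(frozen=True)
class Peak:
    """One detected peak: retention coordinates (seconds) plus area."""

    peak_id: str
    rt1: float
    rt2: float
    area: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("rt1", "rt2", "area"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not self.rt1 > 0:
            raise ValidationError(f"peak {self.peak_id!r}: rt1 must be > 0, got {self.rt1}")
        if self.rt2 < 0:
            raise ValidationError(f"peak {self.peak_id!r}: rt2 must be >= 0, got {self.rt2}")
        if self.area < 0 or not math.isfinite(self.area):
            raise ValidationError(
                f"peak {self.peak_id!r}: area must be finite and >= 0, got {self.area}"
            )


@dataclass
class PeakTable:
    """All peaks of one sample, with sample-level identity."""

    sample_id: str
    peaks: list[Peak]
    subject_id: Optional[str] = None
    carrier: Carrier = Carrier.glass_beads

    def __post_init__(self) -> None:
        self.carrier = Carrier(self.carrier)
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"sample {self.sample_id!r}: duplicate peak ids")
        if self.carrier is Carrier.blank and self.subject_id is not None:
            raise ValidationError(f"blank sample {self.sample_id!r} must not carry a subject_id")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class SampleMeta:
    """Provenance row for one sample in the manifest."""

    sample_id: str
    subject_id: Optional[str]
    carrier: Carrier
    exclude: bool = False
    exclude_reason: str = ""

    def __post_init__(self) -> None:
        if self.exclude and not self.exclude_reason:
            raise ValidationError(
                f"sample {self.sample_id!r} is excluded but no reason is given"
            )


@dataclass
class SampleSet:
    """A cohort of peak tables plus their manifest metadata."""

    tables: list[PeakTable]
    metadata: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.sample_id for t in self.tables]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sample_ids in SampleSet")
        for meta in self.metadata.values():
            if meta.exclude and not meta.exclude_reason:
                raise ValidationError(
                    f"excluded sample {meta.sample_id!r} carries no reason"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [t.sample_id for t in self.tables]

    def table(self, sample_id: str) -> PeakTable:
        for t in self.tables:
            if t.sample_id == sample_id:
                return t
        raise KeyError(sample_id)

    def active_tables(self) -> list[PeakTable]:
        """Tables not flagged as excluded in the manifest."""
        return [
            t
            for t in self.tables
            if not (t.sample_id in self.metadata and self.metadata[t.sample_id].exclude)
        ]


def _parse_float(value: str, column: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(line, f"column {column!r}: cannot parse {value!r} as a number")


def read_peak_table(
    path: str | Path,
    dialect: str = "csv",
    *,
    sample_id: Optional[str] = None,
    subject_id: Optional[str] = None,
    carrier: Carrier | str = Carrier.glass_beads,
) -> PeakTable:
    """Read one sample's peak table from a CSV/TSV file.

    Raises :class:`FormatError` when a required column is missing and
    :class:`RowError` (citing the 1-based line number) when a row holds an
    unparsable number or a negative area.  No row is ever silently dropped.
    """
    path = Path(path)
    delim = {"csv": ",", "tsv": "\t"}.get(dialect)
    if delim is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in ("peak_id", "rt1_s", "rt2_s", "area"):
            if col not in header:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        peaks: list[Peak] = []
        for row in reader:
            line = reader.line_num
            area = _parse_float(row["area"], "area", line)
            if area < 0:
                raise RowError(line, f"negative area {area}")
            try:
                peaks.append(
                    Peak(
                        peak_id=row["peak_id"],
                        rt1=_parse_float(row["rt1_s"], "rt1_s", line),
                        rt2=_parse_float(row["rt2_s"], "rt2_s", line),
                        area=area,
                        label=(row.get("label") or None),
                    )
                )
            except ValidationError as exc:
                raise RowError(line, str(exc)) from exc
    return PeakTable(
        sample_id=sample_id or path.stem,
        peaks=peaks,
        subject_id=subject_id,
        carrier=Carrier(carrier),
    )


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PEAK_COLUMNS)
        for p in table.peaks:
            writer.writerow([p.peak_id, repr(p.rt1), repr(p.rt2), repr(p.area), p.label or ""])


def read_manifest(path: str | Path) -> dict[str, SampleMeta]:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("sample_id", "carrier"):
            if col not in header:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        out: dict[str, SampleMeta] = {}
        for row in reader:
            line = reader.line_num
            try:
                carrier = Carrier(row["carrier"])
            except ValueError:
                raise RowError(line, f"unknown carrier {row['carrier']!r}")
            meta = SampleMeta(
                sample_id=row["sample_id"],
                subject_id=row.get("subject_id") or None,
                carrier=carrier,
                exclude=(row.get("exclude", "") or "").strip().lower() in {"1", "true", "yes"},
                exclude_reason=row.get("exclude_reason", "") or "",
            )
            if meta.sample_id in out:
                raise RowError(line, f"duplicate sample_id {meta.sample_id!r}")
            out[meta.sample_id] = meta
    return out


def write_manifest(metadata: Mapping[str, SampleMeta], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for meta in metadata.values():
            writer.writerow(
                [
                    meta.sample_id,
                    meta.subject_id or "",
                    meta.carrier.value,
                    "true" if meta.exclude else "false",
                    meta.exclude_reason,
                ]
            )


def read_sample_set(directory: str | Path, manifest: str = "manifest.csv") -> SampleSet:
    """Load a directory of ``<sample_id>.csv`` peak tables plus a manifest."""
    directory = Path(directory)
    metadata = read_manifest(directory / manifest)
    tables = []
    for sample_id, meta in metadata.items():
        tables.append(
            read_peak_table(
                directory / f"{sample_id}.csv",
                sample_id=sample_id,
                subject_id=meta.subject_id,
                carrier=meta.carrier,
            )
        )
    return SampleSet(tables=tables, metadata=dict(metadata))


def write_sample_set(sample_set: SampleSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_manifest(sample_set.metadata, directory / "manifest.csv")
    for table in sample_set.tables:
        write_peak_table(table, directory / f"{table.sample_id}.csv")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x features matrix; round-trips bit-exactly via repr."""
    if matrix.empty:
        raise ValidationError("refusing to write an empty matrix")
    matrix.to_csv(path, index_label="sample_id", float_format=None)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")
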