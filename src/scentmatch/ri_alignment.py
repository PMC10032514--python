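"""Retention-index computation and cross-sample peak alignment.

First-dimension retention times of GCxGC runs drift between injections.  A
ladder of marker compounds (here siloxane contaminants, which are present in
every sample including blanks) maps each retention time to a dimensionless
retention index (RI) by piecewise-linear interpolation between the bracketing
markers.  Because the same distortion acts on markers and analytes alike, RIs
are invariant under any strictly increasing affine drift of the time axis,
which is what makes them usable as an alignment coordinate.

Peaks from all samples are then pooled, sorted by RI, and clustered with a
greedy single-linkage rule (a new compound starts wherever the gap between
consecutive RIs exceeds ``ri_tol``).  The result is a samples x compounds
area matrix; a compound that is undetected in a sample gets area zero, and
co-eluting duplicates within one sample are summed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .errors import AlignmentError, ValidationError
from .peak_io import PeakTable, SampleSet

__all__ = [
    "MarkerLadder",
    "CompoundMatrix",
    "compute_ri",
    "resolve_ladder",
    "align",
    "subtract_blanks",
    "read_ladder",
    "write_ladder",
]


@dataclass(frozen=True)
class MarkerLadder:
    """Ordered (index_value, rt1 seconds) marker pairs, optionally labelled.

    Both coordinates must be strictly increasing; at least two markers are
    required so that a linear segment exists.
    """

    markers: tuple[tuple[float, float], ...]
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValidationError("a marker ladder needs at least 2 markers")
        idx = [m[0] for m in self.markers]
        rts = [m[1] for m in self.markers]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValidationError("ladder rt1 values must be strictly increasing")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("ladder index values must be strictly increasing")
        if self.labels is not None and len(self.labels) != len(self.markers):
            raise ValidationError("one label per marker required")

    @property
    def index_values(self) -> np.ndarray:
        return np.array([m[0] for m in self.markers], dtype=float)

    @property
    def rt1_values(self) -> np.ndarray:
        return np.array([m[1] for m in self.markers], dtype=float)


def read_ladder(path) -> MarkerLadder:
    """Read a ladder CSV with columns ``index_value,rt1_s`` (optional ``label``)."""
    df = pd.read_csv(path)
    for col in ("index_value", "rt1_s"):
        if col not in df.columns:
            raise ValidationError(f"ladder file missing column {col!r}")
    markers = tuple(zip(df["index_value"].astype(float), df["rt1_s"].astype(float)))
    labels = tuple(df["label"].astype(str)) if "label" in df.columns else None
    return MarkerLadder(markers=markers, labels=labels)


def write_ladder(ladder: MarkerLadder, path) -> None:
    data = {
        "index_value": [m[0] for m in ladder.markers],
        "rt1_s": [m[1] for m in ladder.markers],
    }
    if ladder.labels:
        data["label"] = list(ladder.labels)
    pd.DataFrame(data).to_csv(path, index=False)


def compute_ri(rt1, ladder: MarkerLadder):
    """Retention index of ``rt1`` (scalar or array) on ``ladder``.

    Piecewise-linear between bracketing markers; outside the ladder the
    nearest segment is extended linearly.
    """
    t = ladder.rt1_values
    i = ladder.index_values
    rt1_arr = np.asarray(rt1, dtype=float)
    k = np.clip(np.searchsorted(t, rt1_arr, side="right") - 1, 0, len(t) - 2)
    ri = i[k] + (i[k + 1] - i[k]) * (rt1_arr - t[k]) / (t[k + 1] - t[k])
    return float(ri) if np.isscalar(rt1) or rt1_arr.ndim == 0 else ri


def resolve_ladder(
    table: PeakTable,
    reference: MarkerLadder,
    *,
    rt_window: float = 60.0,
) -> MarkerLadder:
    """Locate the reference markers inside one sample and return its ladder.

    Each marker is found by label match when the reference carries labels,
    falling back to the nearest peak within ``rt_window`` seconds of the
    declared marker time.  Raises :class:`AlignmentError` when half or more
    of the markers cannot be located.
    """
    by_label = {p.label: p for p in table.peaks if p.label}
    found: list[tuple[float, float]] = []
    for pos, (index_value, ref_rt) in enumerate(reference.markers):
        label = reference.labels[pos] if reference.labels else None
        if label is not None and label in by_label:
            found.append((index_value, by_label[label].rt1))
            continue
        candidates = [p for p in table.peaks if abs(p.rt1 - ref_rt) <= rt_window]
        if candidates:
            nearest = min(candidates, key=lambda p: abs(p.rt1 - ref_rt))
            found.append((index_value, nearest.rt1))
    if len(found) < max(2, (len(reference.markers) + 1) // 2):
        raise AlignmentError(
            f"sample {table.sample_id!r}: only {len(found)} of "
            f"{len(reference.markers)} ladder markers found"
        )
    found.sort(key=lambda m: m[0])
    return MarkerLadder(markers=tuple(found))


@dataclass
class CompoundMatrix:
    """Samples x compounds area matrix with per-compound consensus RI.

    ``areas`` is a DataFrame (rows = sample ids, columns = compound ids,
    zero = not detected); ``compound_ri`` and ``compound_label`` are indexed
    by compound id.  Compounds absent from every sample are dropped.
    """

    areas: pd.DataFrame
    compound_ri: pd.Series
    compound_label: pd.Series

    def __post_init__(self) -> None:
        if (self.areas.to_numpy() < 0).any():
            raise ValidationError("compound areas must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.areas.columns)

    def compounds_labeled(self, prefix: str) -> list[str]:
        """Compound ids whose consensus label starts with ``prefix``."""
        mask = self.compound_label.fillna("").str.startswith(prefix)
        return list(self.compound_label.index[mask])

    def drop_absent(self) -> "CompoundMatrix":
        keep = self.areas.columns[(self.areas != 0).any(axis=0)]
        return CompoundMatrix(
            areas=self.areas[keep],
            compound_ri=self.compound_ri[keep],
            compound_label=self.compound_label[keep],
        )


def align(
    samples: SampleSet | Sequence[PeakTable],
    ladders: MarkerLadder | Mapping[str, MarkerLadder],
    ri_tol: float = 5.0,
) -> CompoundMatrix:
    """Cluster all samples' peaks by RI into a samples x compounds matrix.

    ``ladders`` is either one ladder shared by every sample or a mapping
    sample_id -> per-sample ladder (typically from :func:`resolve_ladder`).
    Peaks whose sorted RIs are separated by gaps of at most ``ri_tol`` form
    one compound column; within a sample, multiple peaks mapping to the same
    compound have their areas summed.
    """
    tables = samples.active_tables() if isinstance(samples, SampleSet) else list(samples)
    if not tables:
        raise ValidationError("no samples to align")

    rows = []
    for table in tables:
        ladder = ladders if isinstance(ladders, MarkerLadder) else ladders[table.sample_id]
        for p in table.peaks:
            rows.append((compute_ri(p.rt1, ladder), table.sample_id, p.area, p.label))
    rows.sort(key=lambda r: r[0])

    # greedy single-linkage: break a cluster when the adjacent RI gap > ri_tol
    clusters: list[list[tuple[float, str, float, Optional[str]]]] = []
    for row in rows:
        if clusters and row[0] - clusters[-1][-1][0] <= ri_tol:
            clusters[-1].append(row)
        else:
            clusters.append([row])

    sample_ids = [t.sample_id for t in tables]
    n_digits = max(3, len(str(len(clusters))))
    compound_ids = [f"C{i:0{n_digits}d}" for i in range(len(clusters))]
    areas = pd.DataFrame(0.0, index=sample_ids, columns=compound_ids)
    ri_vals, labels = [], []
    for cid, cluster in zip(compound_ids, clusters):
        ri_vals.append(float(np.mean([r[0] for r in cluster])))
        cluster_labels = [r[3] for r in cluster if r[3]]
        labels.append(max(set(cluster_labels), key=cluster_labels.count) if cluster_labels else None)
        for _, sid, area, _ in cluster:
            areas.loc[sid, cid] += area
    matrix = CompoundMatrix(
        areas=areas,
        compound_ri=pd.Series(ri_vals, index=compound_ids, name="ri"),
        compound_label=pd.Series(labels, index=compound_ids, name="label", dtype=object),
    )
    return matrix.drop_absent()


def subtract_blanks(
    matrix: CompoundMatrix,
    blank_ids: Sequence[str],
    mode: str = "drop_compound",
    keep: Sequence[str] = (),
) -> CompoundMatrix:
    """Remove compounds detected in any blank sample.

    In ``drop_compound`` mode, every compound with a nonzero area in at least
    one blank is removed from all samples — except ids listed in ``keep``
    (the RI ladder markers, which are contaminants by design and must stay
    available for alignment).  ``keep`` ids are typically obtained via
    ``matrix.compounds_labeled("siloxane")``.  Mode ``keep`` returns the
    matrix unchanged.
    """
    unknown = set(blank_ids) - set(matrix.sample_ids)
    if unknown:
        raise ValidationError(f"blank ids not in matrix: {sorted(unknown)}")
    if mode == "keep":
        return matrix
    if mode != "drop_compound":
        raise ValueError(f"unknown mode {mode!r}")
    blanks = matrix.areas.loc[list(blank_ids)]
    contaminated = set(blanks.columns[(blanks != 0).any(axis=0)]) - set(keep)
    cols = [c for c in matrix.areas.columns if c not in contaminated]
    return CompoundMatrix(
        areas=matrix.areas[cols],
        compound_ri=matrix.compound_ri[cols],
        compound_label=matrix.compound_label[cols],
    )
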