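"""Pairwise peak-area-ratio features.

Each sample's compound-area vector is rewritten as the flattened off-diagonal
of its P x P area-ratio matrix: value(i, j) = area_i / area_j.  Ratios whose
divisor is zero are set to zero, and any non-finite result is likewise set to
zero, so zero uniformly encodes "undefined or absent".  Both orientations
(i, j) and (j, i) are kept; the diagonal self-ratios (identically one) are
excluded.  The transform is invariant to a global rescaling of a sample's
areas, which removes run-to-run instrument response differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ri_alignment import CompoundMatrix

__all__ = ["RatioVector", "ratio_ids", "ratio_vector", "stack", "ratio_matrix"]

SEP = "|"


def ratio_ids(compounds) -> list[str]:
    """Canonical ``"numerator|denominator"`` id order: row-major, i != j."""
    compounds = list(compounds)
    return [f"{a}{SEP}{b}" for a in compounds for b in compounds if a != b]


@dataclass(frozen=True)
class RatioVector:
    """One sample's flattened off-diagonal area-ratio representation."""

    sample_id: str
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.values):
            raise ValidationError("ids and values length mismatch")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValidationError("ratio values must be finite and >= 0")


def ratio_vector(areas: pd.Series, sample_id: str | None = None) -> RatioVector:
    """Transform one sample's compound areas into its RatioVector.

    ``areas`` is indexed by compound id.  Requires at least two compounds.
    """
    if len(areas) < 2:
        raise ValidationError("ratio transform needs at least 2 compounds")
    a = areas.to_numpy(dtype=float)
    if (a < 0).any():
        raise ValidationError("areas must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = a[:, np.newaxis] / a[np.newaxis, :]  # mat[i, j] = a[i] / a[j]
    mat = np.where((a > 0)[np.newaxis, :], mat, 0.0)
    mat[~np.isfinite(mat)] = 0.0
    off = ~np.eye(len(a), dtype=bool)
    return RatioVector(
        sample_id=sample_id or str(getattr(areas, "name", "") or "sample"),
        ids=tuple(ratio_ids(areas.index)),
        values=mat[off],
    )


def stack(vectors) -> pd.DataFrame:
    """Stack RatioVectors sharing one id order into a samples x ratios frame."""
    vectors = list(vectors)
    if not vectors:
        raise ValidationError("no vectors to stack")
    ids = vectors[0].ids
    for v in vectors[1:]:
        if v.ids != ids:
            raise ValidationError(f"sample {v.sample_id!r}: ratio id order mismatch")
    return pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        index=[v.sample_id for v in vectors],
        columns=list(ids),
    )


def ratio_matrix(
    compound_areas: CompoundMatrix | pd.DataFrame, drop_absent: bool = True
) -> pd.DataFrame:
    """Ratio-transform every sample of a compound-area matrix.

    With ``drop_absent`` (default), compounds absent from every sample are
    removed before forming ratios, reducing the dimensionality.
    """
    areas = compound_areas.areas if isinstance(compound_areas, CompoundMatrix) else compound_areas
    if drop_absent:
        areas = areas.loc[:, (areas != 0).any(axis=0)]
    return stack(ratio_vector(row, sample_id=str(sid)) for sid, row in areas.iterrows())
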