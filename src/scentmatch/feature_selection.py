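"""Two-threshold least-SD selection of "significant" peak-area ratios.

The selection algorithm builds a named ``Model_<N>_<T2>``:

1. per subject, keep only ratios whose *incidence rate* — the fraction of
   that subject's samples in which the ratio is nonzero — is at least T1
   (default 75%);
2. per subject, keep the N surviving ratios with the smallest intra-subject
   sample standard deviation (ascending; ties broken by lexicographically
   smaller ratio id);
3. merge the per-subject sets (set union by default; intersection available)
   and apply a second incidence threshold T2, computed over *all* pooled
   samples.

Low intra-subject SD marks ratios that are stable components of one person's
scent signature; T2 then trades subject-specificity (low T2) against
commonality across the cohort (high T2).  The PCA-guided ``optimize`` ranks
every (N, T2) grid point by the cumulative variance explained by the first
seven principal components of the selected-ratio matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyModelError, ValidationError
from .multivariate_stats import pca

logger = logging.getLogger(__name__)

__all__ = [
    "RatioModel",
    "SelectionGrid",
    "incidence_filter",
    "least_sd_select",
    "build_model",
    "optimize",
    "project",
]


@dataclass(frozen=True)
class RatioModel:
    """A selected-ratio set named after the parameters that produced it."""

    n_param: int
    t2: float
    t1: float
    selected_ratio_ids: tuple[str, ...]
    per_subject_selected: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    merge: str = "union"

    @property
    def name(self) -> str:
        return f"Model_{self.n_param}_{self.t2:g}"

    def __post_init__(self) -> None:
        if self.per_subject_selected:
            pool = set().union(*map(set, self.per_subject_selected.values()))
            if not set(self.selected_ratio_ids) <= pool:
                raise ValidationError("selected ratios must come from per-subject sets")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "n_param": self.n_param,
            "t1": self.t1,
            "t2": self.t2,
            "merge": self.merge,
            "selected_ratio_ids": list(self.selected_ratio_ids),
            "per_subject_selected": {k: list(v) for k, v in self.per_subject_selected.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RatioModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            n_param=payload["n_param"],
            t2=payload["t2"],
            t1=payload["t1"],
            selected_ratio_ids=tuple(payload["selected_ratio_ids"]),
            per_subject_selected={
                k: tuple(v) for k, v in payload.get("per_subject_selected", {}).items()
            },
            merge=payload.get("merge", "union"),
        )


@dataclass(frozen=True)
class SelectionGrid:
    """Default parameter grids for model optimisation."""

    n_values: tuple[int, ...] = tuple(range(25, 501, 25))
    t2_values: tuple[float, ...] = (25.0, 50.0, 75.0)
    t1: float = 75.0

    def __post_init__(self) -> None:
        if not self.n_values or not self.t2_values:
            raise ValidationError("grids must be nonempty")
        if min(self.n_values) < 1:
            raise ValidationError("N must be >= 1")
        if not (0 < self.t1 <= 100) or any(not 0 < t <= 100 for t in self.t2_values):
            raise ValidationError("thresholds are percentages in (0, 100]")


def incidence_filter(
    matrix: pd.DataFrame,
    threshold: float,
    candidates: Optional[Sequence[str]] = None,
) -> list[str]:
    """Ratio ids whose nonzero fraction across samples is >= ``threshold`` %."""
    if matrix.empty:
        raise ValidationError("incidence filter needs a nonempty matrix")
    if not 0 < threshold <= 100:
        raise ValidationError("threshold must be a percentage in (0, 100]")
    sub = matrix if candidates is None else matrix[list(candidates)]
    incidence = (sub != 0).mean(axis=0) * 100.0
    return list(sub.columns[incidence.to_numpy() >= threshold])


def least_sd_select(
    matrix: pd.DataFrame, candidates: Sequence[str], n: int
) -> list[str]:
    """The ``n`` candidate ratios with smallest sample SD, ascending.

    Sample (n-1 denominator) standard deviation; ties at the cutoff are
    broken by the lexicographically smaller ratio id.  Returns all candidates
    when fewer than ``n`` exist.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    candidates = list(candidates)
    if not candidates:
        return []
    sds = matrix[candidates].std(axis=0, ddof=1)
    order = sorted(candidates, key=lambda rid: (sds[rid], rid))
    return order[: min(n, len(order))]


def build_model(
    per_subject_matrices: Mapping[str, pd.DataFrame],
    n: int,
    t2: float,
    t1: float = 75.0,
    merge: str = "union",
    pooled: Optional[pd.DataFrame] = None,
) -> RatioModel:
    """Run the full two-threshold selection and return the named model.

    ``per_subject_matrices`` maps subject id -> that subject's samples x
    ratios matrix (all sharing one column set).  ``pooled`` is the matrix of
    all samples the T2 incidence is computed over; by default the
    concatenation of the per-subject matrices, but callers may pass a wider
    pool (e.g. standards plus fired-cartridge samples).
    """
    if len(per_subject_matrices) < 2:
        raise ValidationError("model building needs at least 2 subjects")
    if merge not in {"union", "intersection"}:
        raise ValueError(f"unknown merge mode {merge!r}")
    per_subject: dict[str, tuple[str, ...]] = {}
    for subject in sorted(per_subject_matrices):
        mat = per_subject_matrices[subject]
        kept = incidence_filter(mat, t1)
        per_subject[subject] = tuple(least_sd_select(mat, kept, n))
    sets = [set(v) for v in per_subject.values()]
    merged = set.union(*sets) if merge == "union" else set.intersection(*sets)
    if pooled is None:
        pooled = pd.concat(list(per_subject_matrices.values()), axis=0)
    final = incidence_filter(pooled, t2, candidates=sorted(merged)) if merged else []
    if not final:
        raise EmptyModelError(
            f"Model_{n}_{t2:g}: no ratio passed the T2={t2:g}% incidence filter; "
            "lower t2 (or use merge='union')"
        )
    return RatioModel(
        n_param=n,
        t2=float(t2),
        t1=float(t1),
        selected_ratio_ids=tuple(final),
        per_subject_selected=per_subject,
        merge=merge,
    )


def project(matrix: pd.DataFrame, model: RatioModel) -> pd.DataFrame:
    """Restrict a samples x ratios matrix to a model's selected ratios."""
    missing = [r for r in model.selected_ratio_ids if r not in matrix.columns]
    if missing:
        raise ValidationError(
            f"{model.name}: {len(missing)} selected ratios absent from the data, "
            f"e.g. {missing[:5]}"
        )
    return matrix[list(model.selected_ratio_ids)]


def optimize(
    per_subject_matrices: Mapping[str, pd.DataFrame],
    grid: SelectionGrid | None = None,
    pooled: Optional[pd.DataFrame] = None,
    n_components: int = 7,
    merge: str = "union",
) -> list[tuple[RatioModel, float]]:
    """Rank every (N, T2) grid point by 7-PC cumulative explained variance.

    For each grid point the model is built, all pooled samples are projected
    onto its ratios, and a PCA is fitted; models are ranked by the cumulative
    percentage of variance explained by the first ``min(n_components, rank)``
    components, descending, with ties broken by smaller N then smaller T2.
    Grid points whose model comes out empty are skipped (logged).
    """
    grid = grid or SelectionGrid()
    if pooled is None:
        pooled = pd.concat(list(per_subject_matrices.values()), axis=0)
    results: list[tuple[RatioModel, float]] = []
    for n in grid.n_values:
        for t2 in grid.t2_values:
            try:
                model = build_model(
                    per_subject_matrices, n, t2, t1=grid.t1, merge=merge, pooled=pooled
                )
            except EmptyModelError as exc:
                logger.info("skipping grid point (N=%d, T2=%g): %s", n, t2, exc)
                continue
            x = project(pooled, model).to_numpy(dtype=float)
            k = min(n_components, x.shape[0] - 1, x.shape[1])
            var7 = float(np.sum(pca(x, k).explained_pct[:k]))
            results.append((model, var7))
    results.sort(key=lambda mv: (-mv[1], mv[0].n_param, mv[0].t2))
    return results
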