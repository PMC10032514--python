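"""Similarity-based scent identification.

A query sample (typically scent recovered from a fired cartridge case) is
scored against a panel of reference "standard" samples with one of four
measures — cosine similarity, Pearson, Spearman or Kendall tau-b correlation
— forming a *comparison row*.  The identification is the subject of the
best-scoring reference, mimicking a scent line-up performed by a trained
dog.  Spearman and Kendall use average ranks / tie correction, which matters
because zero-valued ratios create massive ties.

Whether the winner beats the runner-up by more than chance is assessed with
a Fisher z-transform test on the top two correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedSimilarityError, ValidationError
from .feature_selection import RatioModel, project

__all__ = [
    "METHODS",
    "SimilarityScore",
    "ComparisonRow",
    "TopTwoTest",
    "similarity",
    "comparison_row",
    "comparison_rows",
    "top_two_test",
    "identification_report",
]

METHODS = ("cosine", "pearson", "spearman", "kendall")


@dataclass(frozen=True)
class SimilarityScore:
    method: str
    value: float
    query_id: str
    reference_id: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.value <= 1.0 + 1e-12:
            raise ValidationError(f"similarity {self.value} out of [-1, 1]")


def _as_array(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 3:
        raise ValidationError(f"{name}: need length >= 3")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite values")
    return arr


def similarity(u, v, method: str) -> float:
    """Similarity of two equal-length feature vectors under ``method``.

    Correlation methods on a constant vector (or cosine on a zero vector)
    raise :class:`UndefinedSimilarityError` rather than returning 0.
    """
    u = _as_array(u, "u")
    v = _as_array(v, "v")
    if u.size != v.size:
        raise ValidationError("vectors must have equal length")
    if method == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise UndefinedSimilarityError("cosine undefined for a zero vector")
        return float(np.dot(u, v) / (nu * nv))
    if method in {"pearson", "spearman", "kendall"}:
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            raise UndefinedSimilarityError(f"{method} undefined for a constant vector")
        if method == "pearson":
            return float(stats.pearsonr(u, v).statistic)
        if method == "spearman":
            return float(stats.spearmanr(u, v).statistic)
        return float(stats.kendalltau(u, v).statistic)  # tau-b, tie-corrected
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


@dataclass(frozen=True)
class ComparisonRow:
    """One query scored against every panel member under one method."""

    query_id: str
    method: str
    scores: Mapping[str, float]  # reference_id -> value, sorted descending
    predicted_subject: Optional[str]
    tied_subjects: tuple[str, ...]  # all subjects sharing the top score
    correct: Optional[bool]  # None when ground truth unknown

    @property
    def tied(self) -> bool:
        return len(self.tied_subjects) > 1

    def top_two(self) -> tuple[float, float]:
        values = list(self.scores.values())
        if len(values) < 2:
            raise ValidationError("comparison row has fewer than 2 scores")
        return values[0], values[1]


def comparison_row(
    query_id: str,
    matrix: pd.DataFrame,
    panel_ids: Sequence[str],
    subjects: Mapping[str, Optional[str]],
    method: str,
    model: Optional[RatioModel] = None,
) -> ComparisonRow:
    """Score ``query_id`` against ``panel_ids`` on a samples x ratios matrix.

    ``subjects`` maps sample ids to subject ids (ground truth for the query
    if known).  With a ``model`` the matrix is first restricted to its
    selected ratios; otherwise all columns are used.  Exact top-score ties
    are reported, never silently broken: the row counts as correct only when
    the winning subject is unique and matches the truth.  A query whose true
    subject has no panel member is still scored (open-set case) and can
    never be correct.
    """
    if not len(panel_ids):
        raise ValidationError("panel must be nonempty")
    data = project(matrix, model) if model is not None else matrix
    q = data.loc[query_id]
    raw = {ref: similarity(q, data.loc[ref], method) for ref in panel_ids}
    ordered = dict(sorted(raw.items(), key=lambda kv: (-kv[1], kv[0])))
    top = next(iter(ordered.values()))
    tied_refs = [r for r, s in ordered.items() if s == top]
    tied_subjects = tuple(dict.fromkeys(str(subjects.get(r)) for r in tied_refs))
    predicted = tied_subjects[0] if len(tied_subjects) == 1 else None
    truth = subjects.get(query_id)
    correct = None if truth is None else (predicted is not None and predicted == truth)
    return ComparisonRow(
        query_id=query_id,
        method=method,
        scores=ordered,
        predicted_subject=predicted,
        tied_subjects=tied_subjects,
        correct=correct,
    )


def comparison_rows(
    matrix: pd.DataFrame,
    query_ids: Sequence[str],
    panel_ids: Sequence[str],
    subjects: Mapping[str, Optional[str]],
    method: str,
    model: Optional[RatioModel] = None,
) -> list[ComparisonRow]:
    """One :func:`comparison_row` per query, in query order."""
    return [
        comparison_row(q, matrix, panel_ids, subjects, method, model) for q in query_ids
    ]


@dataclass(frozen=True)
class TopTwoTest:
    r1: float
    r2: float
    n: int
    z1: float
    z2: float
    z_stat: float
    p_value: float
    alpha: float
    significant: bool

    def __post_init__(self) -> None:
        if self.r1 < self.r2:
            raise ValidationError("r1 must be the larger score")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value out of range")


def top_two_test(
    row_or_scores,
    n: int,
    alpha: float = 0.05,
    method: str = "independent",
    r12: Optional[float] = None,
) -> TopTwoTest:
    """Fisher z test of whether the top two correlations differ.

    ``row_or_scores`` is a :class:`ComparisonRow` or an ``(r1, r2)`` pair;
    ``n`` is the length of the vectors the correlations were computed over.
    ``method="independent"`` uses z = (z1-z2)/sqrt(2/(n-3)); ``"steiger"``
    applies Steiger's correction for two correlations sharing the query
    variable and needs ``r12``, the correlation between the two reference
    vectors.  Two-sided p from the standard normal.
    """
    if isinstance(row_or_scores, ComparisonRow):
        r1, r2 = row_or_scores.top_two()
    else:
        r1, r2 = row_or_scores
    if r1 < r2:
        r1, r2 = r2, r1
    if n <= 3:
        raise ValidationError("top-two test needs n > 3")
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValidationError("|r| = 1 has an infinite Fisher transform")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    if method == "independent":
        se = math.sqrt(2.0 / (n - 3))
    elif method == "steiger":
        if r12 is None or not -1.0 < r12 < 1.0:
            raise ValidationError("steiger variant needs r12 in (-1, 1)")
        rm2 = (r1**2 + r2**2) / 2.0
        f = min((1.0 - r12) / (2.0 * (1.0 - rm2)), 1.0)
        h = (1.0 - f * rm2) / (1.0 - rm2)
        se = math.sqrt(2.0 * (1.0 - r12) * h / (n - 3))
    else:
        raise ValueError(f"unknown test variant {method!r}")
    z_stat = (z1 - z2) / se
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return TopTwoTest(
        r1=r1, r2=r2, n=n, z1=z1, z2=z2, z_stat=float(z_stat),
        p_value=p, alpha=alpha, significant=bool(p < alpha),
    )


def identification_report(
    rows: Sequence[ComparisonRow],
    subjects: Optional[Mapping[str, Optional[str]]] = None,
) -> dict:
    """Summarise comparison rows: success counts plus per-query detail.

    Every row must carry ground truth (``correct`` not None).  When
    ``subjects`` is provided, each query also reports the percentage of its
    own subject's standards that outscore every foreign standard — values
    below 100% flag foreign standards intruding above the originator's own.
    """
    if any(r.correct is None for r in rows):
        raise ValidationError("identification report needs ground truth on every row")
    per_method: dict[str, dict] = {}
    for row in rows:
        m = per_method.setdefault(row.method, {"n_correct": 0, "n_total": 0, "rows": []})
        m["n_total"] += 1
        m["n_correct"] += int(bool(row.correct))
        detail = {
            "query_id": row.query_id,
            "predicted_subject": row.predicted_subject,
            "correct": bool(row.correct),
            "tied": row.tied,
            "top_score": next(iter(row.scores.values())),
        }
        if subjects is not None:
            truth = subjects.get(row.query_id)
            own = [s for ref, s in row.scores.items() if subjects.get(ref) == truth]
            foreign = [s for ref, s in row.scores.items() if subjects.get(ref) != truth]
            if own and foreign:
                best_foreign = max(foreign)
                detail["own_top_pct"] = 100.0 * sum(s > best_foreign for s in own) / len(own)
        m["rows"].append(detail)
    for m in per_method.values():
        m["success_pct"] = 100.0 * m["n_correct"] / m["n_total"]
    return per_method
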