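import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import rankdata

from scentmatch.errors import UndefinedSimilarityError, ValidationError
from scentmatch.similarity_id import (
    METHODS,
    comparison_row,
    comparison_rows,
    identification_report,
    similarity,
    top_two_test,
)


def pearson_oracle(u, v):
    uc, vc = u - u.mean(), v - v.mean()
    return float(uc @ vc / np.sqrt((uc @ uc) * (vc @ vc)))


def spearman_oracle(u, v):
    """Average-rank then Pearson — the definition, not scipy's shortcut."""
    return pearson_oracle(rankdata(u), rankdata(v))


def kendall_oracle(u, v):
    """O(n^2) pair enumeration, tau-b tie correction."""
    n = len(u)
    conc = disc = tie_u = tie_v = 0
    for i, j in itertools.combinations(range(n), 2):
        du, dv = u[i] - u[j], v[i] - v[j]
        if du == 0 and dv == 0:
            tie_u += 1
            tie_v += 1
        elif du == 0:
            tie_u += 1
        elif dv == 0:
            tie_v += 1
        elif du * dv > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) // 2
    return (conc - disc) / math.sqrt((n0 - tie_u) * (n0 - tie_v))


@pytest.mark.parametrize("method", METHODS)
def test_self_similarity_is_one(method, rng):
    u = rng.lognormal(size=10)
    assert similarity(u, u, method) == pytest.approx(1.0)


def test_spearman_kendall_worked_examples():
    u, v = [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]
    # d = (rank_u - rank_v) = (-2, 1, 1): 1 - 6*6/(3*8) = -0.5
    assert similarity(u, v, "spearman") == pytest.approx(-0.5)
    # pairs: 1 concordant, 2 discordant of 3
    assert similarity(u, v, "kendall") == pytest.approx(-1.0 / 3.0)


@settings(deadline=None, derandomize=True, max_examples=150)
@given(
    data=st.integers(3, 50).flatmap(
        lambda n: st.tuples(
            hnp.arrays(float, n, elements=st.sampled_from([0.0, 1.0, 2.5, 7.0, 7.0, 11.0])),
            hnp.arrays(float, n, elements=st.sampled_from([0.0, 0.0, 3.0, 4.5, 9.0])),
        )
    )
)
def test_rank_methods_match_brute_force_oracles(data):
    u, v = data
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        return
    assert similarity(u, v, "spearman") == pytest.approx(spearman_oracle(u, v), abs=1e-12)
    assert similarity(u, v, "kendall") == pytest.approx(kendall_oracle(u, v), abs=1e-12)
    assert similarity(u, v, "pearson") == pytest.approx(pearson_oracle(u, v), abs=1e-12)


def test_rank_methods_invariant_under_monotone_transform(rng):
    u, v = rng.lognormal(size=20), rng.lognormal(size=20)
    for method in ("spearman", "kendall"):
        base = similarity(u, v, method)
        assert similarity(np.exp(u), v, method) == pytest.approx(base)
        assert similarity(u, v**3, method) == pytest.approx(base)
    assert similarity(2.5 * u + 1, v, "pearson") == pytest.approx(similarity(u, v, "pearson"))


def test_constant_vector_is_explicit_error():
    with pytest.raises(UndefinedSimilarityError):
        similarity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "pearson")
    with pytest.raises(UndefinedSimilarityError):
        similarity([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], "cosine")


def _panel_matrix(rng):
    refs = {f"ref{k}": rng.lognormal(size=8) for k in range(4)}
    refs["query"] = refs["ref2"].copy()  # exact copy of one panel member
    return pd.DataFrame(refs).T


def test_comparison_row_exact_copy_wins(rng):
    m = _panel_matrix(rng)
    subjects = {"query": "S2", "ref0": "S0", "ref1": "S1", "ref2": "S2", "ref3": "S3"}
    row = comparison_row("query", m, [f"ref{k}" for k in range(4)], subjects, "spearman")
    assert row.predicted_subject == "S2"
    assert next(iter(row.scores.values())) == pytest.approx(1.0)
    assert row.correct is True


def test_comparison_row_open_set_never_correct(rng):
    m = _panel_matrix(rng)
    subjects = {"query": "S9", "ref0": "S0", "ref1": "S1", "ref2": "S2", "ref3": "S3"}
    row = comparison_row("query", m, [f"ref{k}" for k in range(4)], subjects, "cosine")
    assert row.correct is False


def test_comparison_row_reports_ties(rng):
    base = rng.lognormal(size=6)
    # identical reference vectors from different subjects -> exact score tie
    m = pd.DataFrame({"query": base, "a": base * 2, "b": base * 2}).T
    subjects = {"query": "SA", "a": "SA", "b": "SB"}
    row = comparison_row("query", m, ["a", "b"], subjects, "cosine")
    assert row.tied
    assert row.predicted_subject is None
    assert row.correct is False


def test_top_two_null_case():
    t = top_two_test((0.6, 0.6), n=65)
    assert t.z_stat == 0.0
    assert t.p_value == pytest.approx(1.0)
    assert not t.significant


def test_fisher_transform_closed_form():
    t = top_two_test((0.5, 0.1), n=40)
    assert t.z1 == pytest.approx(0.5 * math.log(1.5 / 0.5))
    assert t.z1 == pytest.approx(0.5493, abs=1e-4)


def test_top_two_swap_symmetric_and_bounds():
    a = top_two_test((0.7, 0.3), n=50)
    b = top_two_test((0.3, 0.7), n=50)
    assert a.p_value == b.p_value
    with pytest.raises(ValidationError):
        top_two_test((1.0, 0.5), n=50)
    with pytest.raises(ValidationError):
        top_two_test((0.5, 0.2), n=3)


def test_top_two_p_monotone_in_gap_and_n():
    gaps = [top_two_test((0.5 + g, 0.5 - g), n=60).p_value for g in (0.05, 0.15, 0.3)]
    assert gaps == sorted(gaps, reverse=True)
    ns = [top_two_test((0.7, 0.4), n=n).p_value for n in (10, 40, 160)]
    assert ns == sorted(ns, reverse=True)


def test_top_two_steiger_variant():
    with pytest.raises(ValidationError):
        top_two_test((0.7, 0.4), n=50, method="steiger")
    t = top_two_test((0.7, 0.4), n=50, method="steiger", r12=0.5)
    assert 0 <= t.p_value <= 1
    # positively correlated references shrink the SE vs the independent form
    assert t.p_value < top_two_test((0.7, 0.4), n=50).p_value


def test_identification_report_counts(rng):
    m = _panel_matrix(rng)
    subjects = {"query": "S2", "ref0": "S0", "ref1": "S1", "ref2": "S2", "ref3": "S3"}
    rows = comparison_rows(m, ["query"], [f"ref{k}" for k in range(4)], subjects, "spearman")
    report = identification_report(rows, subjects)
    assert report["spearman"]["success_pct"] == 100.0
    assert report["spearman"]["rows"][0]["own_top_pct"] == 100.0
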