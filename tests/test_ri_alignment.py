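import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scentmatch.errors import AlignmentError, ValidationError
from scentmatch.peak_io import Carrier
from scentmatch.ri_alignment import (
    MarkerLadder,
    align,
    compute_ri,
    read_ladder,
    resolve_ladder,
    subtract_blanks,
    write_ladder,
)

from conftest import make_table


@pytest.mark.parametrize(
    "ladder, t, expected",
    [
        (((100, 300), (200, 600)), 450.0, 150.0),
        (((100, 300), (200, 600)), 300.0, 100.0),
        (((200, 600), (300, 900)), 660.0, 220.0),
        (((100, 300), (200, 600)), 750.0, 250.0),  # extrapolation above
        (((100, 300), (200, 600)), 150.0, 50.0),  # extrapolation below
    ],
)
def test_compute_ri_linear_interpolation(ladder, t, expected):
    assert compute_ri(t, MarkerLadder(markers=ladder)) == pytest.approx(expected)


def test_degenerate_ladder_rejected():
    with pytest.raises(ValidationError):
        MarkerLadder(markers=((100, 300), (200, 300)))
    with pytest.raises(ValidationError):
        MarkerLadder(markers=((100, 300),))


@settings(deadline=None, derandomize=True)
@given(
    rts=st.lists(st.floats(10, 5000), min_size=2, max_size=30, unique=True),
    a=st.floats(0.5, 2.0),
    b=st.floats(-50, 50),
)
def test_ri_invariant_under_joint_affine_drift(rts, a, b):
    """Distorting peaks and markers with one affine map leaves RIs unchanged."""
    ladder = MarkerLadder(markers=((400, 100.0), (800, 900.0), (1400, 2500.0)))
    drifted = MarkerLadder(
        markers=tuple((i, a * t + b) for i, t in ladder.markers)
    )
    for t in rts:
        assert compute_ri(a * t + b, drifted) == pytest.approx(compute_ri(t, ladder), abs=1e-6)


def test_ri_strictly_increasing(identity_ladder):
    ladder = MarkerLadder(markers=((400, 100.0), (800, 900.0), (1400, 2500.0)))
    ts = np.linspace(50, 3000, 500)
    ris = compute_ri(ts, ladder)
    assert (np.diff(ris) > 0).all()


def test_align_merges_within_tolerance(identity_ladder):
    t1 = make_table("s1", [(1500.0, 5.0)])
    t2 = make_table("s2", [(1500.4, 7.0)])
    merged = align([t1, t2], identity_ladder, ri_tol=1.0)
    assert len(merged.compound_ids) == 1
    assert merged.areas.iloc[:, 0].tolist() == [5.0, 7.0]
    split = align([t1, t2], identity_ladder, ri_tol=0.1)
    assert len(split.compound_ids) == 2


def test_align_sums_coeluting_duplicates(identity_ladder):
    t = make_table("s1", [(1500.0, 5.0), (1500.2, 2.0)])
    m = align([t], identity_ladder, ri_tol=1.0)
    assert m.areas.iloc[0, 0] == pytest.approx(7.0)


def test_align_corrects_per_sample_drift():
    """Three drifted samples sharing 5 compounds resolve to exactly 5 columns."""
    base = MarkerLadder(markers=((400, 200.0), (1000, 1100.0), (1400, 1700.0)))
    true_rts = [300.0, 500.0, 800.0, 1250.0, 1500.0]
    rng = np.random.default_rng(7)
    tables, ladders = [], {}
    for k, (a, b) in enumerate([(1.0, 0.0), (1.04, 12.0), (0.97, -20.0)]):
        peaks = [(a * t + b + rng.normal(0, 0.3), 10.0 + k) for t in true_rts]
        tables.append(make_table(f"s{k}", peaks))
        ladders[f"s{k}"] = MarkerLadder(
            markers=tuple((i, a * t + b) for i, t in base.markers)
        )
    m = align(tables, ladders, ri_tol=5.0)
    assert len(m.compound_ids) == 5
    assert (m.areas.to_numpy() > 0).all()  # every sample placed in every column


def test_align_permutation_invariant(identity_ladder):
    tables = [
        make_table("s1", [(300.0, 1.0), (900.0, 2.0)]),
        make_table("s2", [(300.5, 3.0)]),
        make_table("s3", [(899.0, 4.0), (1200.0, 5.0)]),
    ]
    m1 = align(tables, identity_ladder, ri_tol=5.0)
    m2 = align(tables[::-1], identity_ladder, ri_tol=5.0)
    m2_areas = m2.areas.loc[m1.areas.index]  # same sample order, columns may be relabeled
    assert sorted(map(tuple, m1.areas.T.to_numpy().tolist())) == sorted(
        map(tuple, m2_areas.T.to_numpy().tolist())
    )


def test_resolve_ladder_by_label_and_missing_markers():
    ref = MarkerLadder(
        markers=((400, 200.0), (800, 800.0), (1200, 1400.0), (1400, 1700.0)),
        labels=("m400", "m800", "m1200", "m1400"),
    )
    table = make_table(
        "s1", [(210.0, 1.0, "m400"), (815.0, 1.0, "m800"), (1425.0, 1.0, "m1200")]
    )
    resolved = resolve_ladder(table, ref, rt_window=40.0)
    assert len(resolved.markers) == 3
    assert resolved.markers[0] == (400, 210.0)
    sparse = make_table("s2", [(210.0, 1.0, "m400")])
    with pytest.raises(AlignmentError, match="ladder markers"):
        resolve_ladder(sparse, ref, rt_window=40.0)


def test_subtract_blanks_drops_contaminants(identity_ladder):
    sample = make_table("s1", [(300.0, 1.0), (600.0, 2.0), (900.0, 3.0)])
    blank = make_table("b1", [(600.2, 9.0)], carrier=Carrier.blank)
    m = align([sample, blank], identity_ladder, ri_tol=1.0)
    cleaned = subtract_blanks(m, ["b1"])
    assert len(cleaned.compound_ids) == 2


def test_subtract_blanks_empty_blank_is_identity(identity_ladder):
    sample = make_table("s1", [(300.0, 1.0)])
    blank = make_table("b1", [], carrier=Carrier.blank)
    m = align([sample, blank], identity_ladder, ri_tol=1.0)
    cleaned = subtract_blanks(m, ["b1"])
    assert cleaned.compound_ids == m.compound_ids


def test_subtract_blanks_retains_marker_compounds(identity_ladder):
    """Siloxane markers stay even though they appear in blanks."""
    sample = make_table("s1", [(300.0, 1.0, "siloxane_400"), (900.0, 2.0)])
    blank = make_table("b1", [(300.1, 0.5, "siloxane_400")], carrier=Carrier.blank)
    m = align([sample, blank], identity_ladder, ri_tol=1.0)
    keep = m.compounds_labeled("siloxane")
    assert len(keep) == 1
    cleaned = subtract_blanks(m, ["b1"], keep=keep)
    assert set(cleaned.compound_ids) == set(m.compound_ids)


def test_ladder_csv_round_trip(tmp_path):
    ladder = MarkerLadder(markers=((400, 150.0), (1400, 1650.0)), labels=("a", "b"))
    write_ladder(ladder, tmp_path / "ladder.csv")
    assert read_ladder(tmp_path / "ladder.csv") == ladder
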