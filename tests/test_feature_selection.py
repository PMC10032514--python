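import itertools

import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from scentmatch.errors import EmptyModelError, ValidationError
from scentmatch.feature_selection import (
    RatioModel,
    SelectionGrid,
    build_model,
    incidence_filter,
    least_sd_select,
    optimize,
    project,
)
from scentmatch.multivariate_stats import pca


def frame(columns):
    return pd.DataFrame(columns)


def test_incidence_filter_thresholds():
    m = frame({
        "eight_of_ten": [1.0] * 8 + [0.0] * 2,
        "seven_of_ten": [1.0] * 7 + [0.0] * 3,
        "all_ten": [2.0] * 10,
    })
    assert incidence_filter(m, 75.0) == ["eight_of_ten", "all_ten"]
    assert incidence_filter(m, 100.0) == ["all_ten"]


def test_incidence_filter_antitone_in_threshold(rng):
    """Raising the threshold can only shrink the kept set."""
    for _ in range(50):
        m = pd.DataFrame(
            rng.random((6, 8)) * (rng.random((6, 8)) > 0.4),
            columns=[f"r{k}" for k in range(8)],
        )
        thresholds = sorted(rng.uniform(1, 100, size=4))
        kept = [set(incidence_filter(m, t)) for t in thresholds]
        for at_lower_threshold, at_higher_threshold in itertools.pairwise(kept):
            assert at_lower_threshold >= at_higher_threshold


def test_least_sd_select_orders_ascending():
    m = frame({"a": [1.0, 1.1, 0.9], "b": [1.0, 2.0, 0.0], "c": [1.0, 1.3, 0.7]})
    assert least_sd_select(m, ["a", "b", "c"], 2) == ["a", "c"]
    assert least_sd_select(m, ["a", "b", "c"], 10) == ["a", "c", "b"]
    assert least_sd_select(m, [], 3) == []


def test_least_sd_tie_broken_lexicographically():
    """Verified against exhaustive enumeration on a 4-ratio fixture."""
    m = frame({
        "r3": [1.0, 2.0, 3.0], "r1": [5.0, 6.0, 7.0],  # identical SD = 1
        "r0": [1.0, 1.0, 1.0], "r2": [0.0, 9.0, 0.0],
    })
    sds = m.std(ddof=1)
    oracle = [rid for rid, _ in sorted(sds.items(), key=lambda kv: (kv[1], kv[0]))]
    assert least_sd_select(m, list(m.columns), 4) == oracle
    assert least_sd_select(m, list(m.columns), 2) == ["r0", "r1"]


def test_max_selected_sd_not_above_min_excluded(rng):
    m = pd.DataFrame(rng.lognormal(size=(10, 20)), columns=[f"r{k:02d}" for k in range(20)])
    chosen = least_sd_select(m, list(m.columns), 7)
    sds = m.std(ddof=1)
    assert sds[chosen].max() <= sds[[c for c in m.columns if c not in chosen]].min()


def _subject_frames():
    a = frame({"a": [1.0, 1.0], "b": [2.0, 2.0], "c": [5.0, 9.0], "d": [1.0, 3.0]})
    b = frame({"a": [4.0, 8.0], "b": [5.0, 9.0], "c": [3.0, 3.0], "d": [7.0, 2.0]})
    return {"S1": a, "S2": b}


def test_build_model_union_and_naming():
    model = build_model(_subject_frames(), n=2, t2=25.0)
    # S1 selects its two zero-variance ratios {a, b}; S2 selects {c} plus one more
    assert {"a", "b", "c"} <= set(model.selected_ratio_ids)
    assert model.name == "Model_2_25"
    assert model.per_subject_selected["S1"] == ("a", "b")


def test_build_model_t2_boundary_excludes_partial_ratio():
    frames = _subject_frames()
    frames["S1"] = frames["S1"].copy()
    frames["S1"].loc[0, "c"] = 0.0  # c now zero in one pooled sample
    model = build_model(frames, n=4, t2=100.0, t1=50.0)
    assert "c" not in model.selected_ratio_ids
    assert "a" in model.selected_ratio_ids


def test_build_model_subject_order_invariant():
    frames = _subject_frames()
    m1 = build_model(frames, n=2, t2=25.0)
    m2 = build_model(dict(reversed(list(frames.items()))), n=2, t2=25.0)
    assert m1.selected_ratio_ids == m2.selected_ratio_ids


def test_build_model_intersection_mode():
    frames = {
        "S1": frame({"a": [1.0, 1.0], "b": [3.0, 3.5], "c": [1.0, 9.0]}),
        "S2": frame({"a": [2.0, 2.0], "b": [1.0, 9.0], "c": [4.0, 4.5]}),
    }
    union = build_model(frames, n=2, t2=25.0, merge="union")
    assert set(union.selected_ratio_ids) == {"a", "b", "c"}  # {a,b} | {a,c}
    inter = build_model(frames, n=2, t2=25.0, merge="intersection")
    assert set(inter.selected_ratio_ids) == {"a"}


def test_empty_model_raises_with_advice():
    frames = {
        "S1": frame({"a": [1.0, 0.0], "b": [0.0, 1.0]}),
        "S2": frame({"a": [0.0, 1.0], "b": [1.0, 0.0]}),
    }
    with pytest.raises(EmptyModelError, match="lower t2"):
        build_model(frames, n=2, t2=100.0, t1=50.0)


def test_planted_zero_variance_ratios_recovered(rng):
    """Each subject's planted constant ratios all survive selection at N >= plant count."""
    ratios = [f"r{k:02d}" for k in range(12)]
    planted = {"S1": ["r00", "r01"], "S2": ["r05", "r06"], "S3": ["r09", "r10"]}
    frames = {}
    for subj, own in planted.items():
        data = pd.DataFrame(
            rng.lognormal(mean=0, sigma=1.0, size=(6, 12)) + 0.5, columns=ratios
        )
        for rid in own:
            data[rid] = 2.0  # zero variance, always nonzero
        frames[subj] = data
    model = build_model(frames, n=2, t2=50.0)
    expected = sorted(r for own in planted.values() for r in own)
    assert sorted(model.selected_ratio_ids) == expected


def test_model_json_round_trip(tmp_path):
    model = build_model(_subject_frames(), n=2, t2=25.0)
    model.to_json(tmp_path / "m.json")
    assert RatioModel.from_json(tmp_path / "m.json") == model


def test_project_reports_missing_ratios():
    model = build_model(_subject_frames(), n=2, t2=25.0)
    data = frame({"a": [1.0], "zz": [2.0]})
    with pytest.raises(ValidationError, match="absent"):
        project(data, model)


def test_selection_grid_validation():
    with pytest.raises(ValidationError):
        SelectionGrid(n_values=())
    with pytest.raises(ValidationError):
        SelectionGrid(t2_values=(0.0,))


def test_optimize_single_point_and_ranking(rng):
    frames = _subject_frames()
    ranked = optimize(frames, SelectionGrid(n_values=(2,), t2_values=(25.0,)))
    assert len(ranked) == 1
    model, var = ranked[0]
    assert model.name == "Model_2_25"
    assert 0 < var <= 100 + 1e-9


def test_optimize_uses_rank_bounded_components():
    """With fewer than 8 samples the 7-PC criterion falls back to the rank."""
    frames = _subject_frames()  # 4 pooled samples -> at most 3 components
    ranked = optimize(frames, SelectionGrid(n_values=(2, 4), t2_values=(25.0, 50.0)))
    assert all(0 < v <= 100 + 1e-9 for _, v in ranked)
    vars_ = [v for _, v in ranked]
    assert vars_ == sorted(vars_, reverse=True)


def test_optimize_top_model_separates_planted_subjects(rng):
    """A cohort with distinct subject profiles clusters by subject in PC1-2."""
    ratios = [f"r{k:02d}" for k in range(20)]
    frames = {}
    labels = []
    for s in range(3):
        center = rng.lognormal(mean=s, sigma=0.2, size=20)
        data = center * rng.lognormal(mean=0, sigma=0.05, size=(6, 20))
        frames[f"S{s}"] = pd.DataFrame(data, columns=ratios)
        labels += [f"S{s}"] * 6
    ranked = optimize(frames, SelectionGrid(n_values=(5, 10), t2_values=(25.0, 50.0)))
    model, _ = ranked[0]
    pooled = pd.concat(frames.values())
    scores = pca(project(pooled, model).to_numpy(), 2).scores
    assert silhouette_score(scores, labels) > 0
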