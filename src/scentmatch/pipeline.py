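"""Experiment orchestration: configs, run directories and end-to-end stages.

Two experiment shapes mirror the study design: *model development* (a cohort
of subjects with repeated standard samples, from which a ratio model is
selected, inspected with PCA/Mardia and benchmarked with classifiers) and
*model application* (fresh subjects giving one standard and one
fired-cartridge sample each, identified through comparison rows).  The
``full_synthetic`` experiment runs both on one simulated cohort;
``develop_model`` and ``apply_model`` run on user-supplied peak-table
directories.  Every run serialises its config and a manifest (package
versions, seed, produced files) so that re-running a saved config
reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .classification import GridSpec, benchmark, benchmark_on_pcs
from .errors import ScentMatchError, ValidationError
from .feature_selection import RatioModel, SelectionGrid, build_model, optimize, project
from .multivariate_stats import mardia_test, pca
from .peak_io import Carrier, SampleSet, read_sample_set, write_matrix, write_sample_set
from .ratio_features import ratio_matrix
from .ri_alignment import (
    CompoundMatrix,
    MarkerLadder,
    align,
    read_ladder,
    resolve_ladder,
    subtract_blanks,
    write_ladder,
)
from .similarity_id import METHODS, comparison_rows, identification_report, top_two_test
from .synthetic_data import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "build_ratio_table", "synthetic_identification"]

MARKER_PREFIX = "siloxane"


@dataclass
class RunConfig:
    """Serializable parameterisation of one experiment run."""

    experiment: str  # simulate | full_synthetic | develop_model | apply_model
    outdir: str
    seed: int = 0
    # synthetic cohort
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    n_dev_subjects: int = 5
    n_apply_subjects: int = 10
    n_standard_per_subject: int = 10
    n_cartridge_per_subject: int = 1
    # alignment
    ri_tol: float = 5.0
    # selection
    n_param: int = 75
    t1: float = 75.0
    t2: float = 50.0
    merge: str = "union"
    optimize_grid: Optional[dict] = None  # SelectionGrid overrides; None = no search
    # evaluation
    methods: tuple = tuple(METHODS)
    algorithms: tuple = ("knn", "rf")
    classifier_grid: dict = field(default_factory=dict)  # GridSpec overrides
    direction: str = "cartridge_to_standard"  # or standard_to_cartridge
    # file-based experiments
    input_dir: Optional[str] = None
    ladder_path: Optional[str] = None
    model_path: Optional[str] = None

    def to_yaml(self, path) -> None:
        # json round-trip turns tuples into plain lists for safe_dump
        payload = json.loads(json.dumps(dataclasses.asdict(self)))
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("methods", "algorithms"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def build_ratio_table(
    sample_set: SampleSet,
    ladder: MarkerLadder,
    ri_tol: float = 5.0,
) -> tuple[pd.DataFrame, CompoundMatrix]:
    """Align a cohort, subtract blank contaminants, ratio-transform.

    Resolves the marker ladder per sample, aligns all active samples into a
    compound matrix, drops every compound seen in a blank (the ladder
    markers excepted), removes the blank rows and returns the samples x
    ratios matrix plus the post-subtraction compound matrix.
    """
    tables = sample_set.active_tables()
    ladders = {t.sample_id: resolve_ladder(t, ladder) for t in tables}
    matrix = align(tables, ladders, ri_tol=ri_tol)
    blank_ids = [t.sample_id for t in tables if t.carrier is Carrier.blank]
    if blank_ids:
        keep = matrix.compounds_labeled(MARKER_PREFIX)
        matrix = subtract_blanks(matrix, blank_ids, keep=keep)
        matrix = CompoundMatrix(
            areas=matrix.areas.drop(index=blank_ids),
            compound_ri=matrix.compound_ri,
            compound_label=matrix.compound_label,
        ).drop_absent()
    return ratio_matrix(matrix), matrix


def synthetic_identification(
    cfg: SyntheticConfig,
    n_standard: int = 1,
    n_cartridge: int = 1,
    methods: Sequence[str] = ("spearman",),
    ri_tol: float = 5.0,
    model: Optional[RatioModel] = None,
    direction: str = "cartridge_to_standard",
):
    """End-to-end identification experiment on one synthetic cohort.

    Generates the cohort, aligns it, builds comparison rows for every
    fired-cartridge sample against the standards panel (or the reverse
    direction) and returns ``(report, rows, ratios)``.
    """
    sample_set, truth = generate_cohort(cfg, n_standard, n_cartridge)
    ratios, _ = build_ratio_table(sample_set, truth.ladder, ri_tol=ri_tol)
    carriers = {t.sample_id: t.carrier for t in sample_set.tables}
    cart_ids = [s for s in ratios.index if carriers[s] is Carrier.fired_cartridge]
    std_ids = [s for s in ratios.index if carriers[s] is Carrier.glass_beads]
    if direction == "cartridge_to_standard":
        queries, panel = cart_ids, std_ids
    elif direction == "standard_to_cartridge":
        queries, panel = std_ids, cart_ids
    else:
        raise ValueError(f"unknown direction {direction!r}")
    rows = []
    for method in methods:
        rows.extend(
            comparison_rows(ratios, queries, panel, truth.subject_of, method, model=model)
        )
    return identification_report(rows, truth.subject_of), rows, ratios


def _write_manifest(outdir: Path, cfg: RunConfig) -> None:
    import numpy, scipy, sklearn  # noqa: PLC0415

    manifest = {
        "scentmatch": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "seed": cfg.seed,
        "experiment": cfg.experiment,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _classify(ratios_model: pd.DataFrame, labels, cfg: RunConfig, outdir: Path) -> dict:
    overrides = {
        k: tuple(v) if isinstance(v, list) else v for k, v in cfg.classifier_grid.items()
    }
    grid = GridSpec(seed=cfg.seed, **overrides)
    results = {}
    for algo in cfg.algorithms:
        for space, fn in (("ratios", benchmark), ("first_3_pcs", benchmark_on_pcs)):
            rep = fn(ratios_model.to_numpy(), labels, algo, grid=grid, seed=cfg.seed)
            key = f"{algo}_{space}"
            results[key] = {
                "f1": rep.f1,
                "best_params": {k: str(v) for k, v in rep.best_params.items()},
                "per_class_f1": rep.per_class_f1,
            }
            rep.confusion.to_csv(outdir / f"confusion_{key}.csv")
    (outdir / "classification.json").write_text(json.dumps(results, indent=2))
    return results


def _identify(
    ratios: pd.DataFrame,
    queries: Sequence[str],
    panel: Sequence[str],
    subjects: Mapping[str, Optional[str]],
    model: RatioModel,
    cfg: RunConfig,
    outdir: Path,
) -> dict:
    rows = []
    for method in cfg.methods:
        rows.extend(comparison_rows(ratios, queries, panel, subjects, method, model=model))
    report = identification_report(rows, subjects)
    n_vec = len(model.selected_ratio_ids)  # correlations run across the model vector
    top_two = {}
    for row in rows:
        if row.method != "spearman" or len(row.scores) < 2 or n_vec <= 3:
            continue
        try:
            t = top_two_test(row, n=n_vec)
        except ValidationError:
            continue
        top_two[row.query_id] = {
            "r1": t.r1, "r2": t.r2, "p_value": t.p_value, "significant": t.significant,
        }
    report["top_two_spearman"] = top_two
    (outdir / "identification.json").write_text(json.dumps(report, indent=2))
    scores = pd.DataFrame(
        {row.query_id + ":" + row.method: pd.Series(dict(row.scores)) for row in rows}
    )
    scores.to_csv(outdir / "similarity_scores.csv", index_label="reference_id")
    return report


def run_experiment(cfg: RunConfig) -> Path:
    """Execute one experiment and populate its run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("scentmatch")
    root.addHandler(handler)
    try:
        cfg.to_yaml(outdir / "config.yaml")
        stage = "setup"
        if cfg.experiment == "simulate":
            stage = "simulate"
            _run_simulate(cfg, outdir)
        elif cfg.experiment == "full_synthetic":
            stage = "full_synthetic"
            _run_full_synthetic(cfg, outdir)
        elif cfg.experiment == "develop_model":
            stage = "develop_model"
            _run_develop(cfg, outdir)
        elif cfg.experiment == "apply_model":
            stage = "apply_model"
            _run_apply(cfg, outdir)
        else:
            raise ValidationError(f"unknown experiment {cfg.experiment!r}")
        _write_manifest(outdir, cfg)
    except ScentMatchError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise ScentMatchError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def _synthetic_config(cfg: RunConfig, n_subjects: int) -> SyntheticConfig:
    overrides = dict(cfg.synthetic)
    overrides.setdefault("seed", cfg.seed)
    overrides["n_subjects"] = n_subjects
    return SyntheticConfig(**overrides)


def _run_simulate(cfg: RunConfig, outdir: Path) -> None:
    scfg = _synthetic_config(cfg, cfg.n_dev_subjects)
    sample_set, truth = generate_cohort(
        scfg, cfg.n_standard_per_subject, cfg.n_cartridge_per_subject
    )
    data_dir = outdir / "peaks"
    write_sample_set(sample_set, data_dir)
    write_ladder(truth.ladder, outdir / "ladder.csv")
    truth.profiles.to_csv(outdir / "true_profiles_log10.csv", index_label="subject_id")
    truth.compounds.to_csv(outdir / "true_compounds.csv", index_label="name")
    logger.info("simulated %d samples into %s", len(sample_set.tables), data_dir)


def _run_full_synthetic(cfg: RunConfig, outdir: Path) -> None:
    n_total = cfg.n_dev_subjects + cfg.n_apply_subjects
    scfg = _synthetic_config(cfg, n_total)
    sample_set, truth = generate_cohort(
        scfg, cfg.n_standard_per_subject, cfg.n_cartridge_per_subject
    )
    ratios, matrix = build_ratio_table(sample_set, truth.ladder, ri_tol=cfg.ri_tol)
    write_matrix(matrix.areas, outdir / "compound_areas.csv")
    subjects = truth.subject_of
    carriers = {t.sample_id: t.carrier for t in sample_set.tables}
    dev_subjects = list(truth.profiles.index[: cfg.n_dev_subjects])
    apply_subjects = list(truth.profiles.index[cfg.n_dev_subjects :])

    # --- model development on the dev subjects' standard samples
    std_ids = [
        s for s in ratios.index
        if carriers[s] is Carrier.glass_beads and subjects[s] in dev_subjects
    ]
    dev_ids = [s for s in ratios.index if subjects[s] in dev_subjects]
    per_subject = {
        subj: ratios.loc[[s for s in std_ids if subjects[s] == subj]]
        for subj in dev_subjects
    }
    pooled = ratios.loc[dev_ids]
    if cfg.optimize_grid is not None:
        grid = SelectionGrid(**{**{"t1": cfg.t1}, **cfg.optimize_grid})
        ranked = optimize(per_subject, grid, pooled=pooled, merge=cfg.merge)
        model, var7 = ranked[0]
        pd.DataFrame(
            [(m.name, m.n_param, m.t2, len(m.selected_ratio_ids), v) for m, v in ranked],
            columns=["model", "n", "t2", "n_ratios", "explained_var_7pc"],
        ).to_csv(outdir / "model_ranking.csv", index=False)
    else:
        model = build_model(
            per_subject, cfg.n_param, cfg.t2, t1=cfg.t1, merge=cfg.merge, pooled=pooled
        )
    model.to_json(outdir / "model.json")
    logger.info("selected %s with %d ratios", model.name, len(model.selected_ratio_ids))

    # --- PCA and Mardia on the selected ratios of the dev pool
    x = project(pooled, model).to_numpy()
    k = min(7, x.shape[0] - 1, x.shape[1])
    fit = pca(x, k)
    pd.DataFrame(
        {"component": range(1, k + 1), "explained_pct": fit.explained_pct}
    ).to_csv(outdir / "pca_explained.csv", index=False)
    pd.DataFrame(fit.scores, index=pooled.index).to_csv(outdir / "pca_scores.csv")
    mardia = mardia_test(fit.scores[:, : min(3, k)])
    (outdir / "mardia.json").write_text(
        json.dumps(dataclasses.asdict(mardia), indent=2)
    )

    # --- classifier benchmark on the dev pool
    labels = [subjects[s] for s in pooled.index]
    _classify(project(pooled, model), labels, cfg, outdir)

    # --- model application on the held-out subjects (1 std + 1 cart each)
    apply_std = [
        s for s in ratios.index
        if carriers[s] is Carrier.glass_beads and subjects[s] in apply_subjects
        and s.endswith("_std_01")
    ]
    apply_cart = [
        s for s in ratios.index
        if carriers[s] is Carrier.fired_cartridge and subjects[s] in apply_subjects
        and s.endswith("_cart_01")
    ]
    queries, panel = (
        (apply_cart, apply_std)
        if cfg.direction == "cartridge_to_standard"
        else (apply_std, apply_cart)
    )
    _identify(ratios, queries, panel, subjects, model, cfg, outdir)


def _load_input(cfg: RunConfig) -> tuple[SampleSet, MarkerLadder]:
    if not cfg.input_dir:
        raise ValidationError("experiment needs input_dir")
    sample_set = read_sample_set(cfg.input_dir)
    ladder_path = cfg.ladder_path or str(Path(cfg.input_dir) / "ladder.csv")
    return sample_set, read_ladder(ladder_path)


def _run_develop(cfg: RunConfig, outdir: Path) -> None:
    sample_set, ladder = _load_input(cfg)
    ratios, matrix = build_ratio_table(sample_set, ladder, ri_tol=cfg.ri_tol)
    write_matrix(matrix.areas, outdir / "compound_areas.csv")
    subjects = {t.sample_id: t.subject_id for t in sample_set.tables}
    carriers = {t.sample_id: t.carrier for t in sample_set.tables}
    std_ids = [s for s in ratios.index if carriers[s] is Carrier.glass_beads and subjects[s]]
    per_subject_ids: dict[str, list[str]] = {}
    for s in std_ids:
        per_subject_ids.setdefault(subjects[s], []).append(s)
    per_subject = {subj: ratios.loc[ids] for subj, ids in per_subject_ids.items()}
    model = build_model(
        per_subject, cfg.n_param, cfg.t2, t1=cfg.t1, merge=cfg.merge, pooled=ratios
    )
    model.to_json(outdir / "model.json")
    labels = [subjects[s] for s in std_ids]
    _classify(project(ratios.loc[std_ids], model), labels, cfg, outdir)


def _run_apply(cfg: RunConfig, outdir: Path) -> None:
    if not cfg.model_path:
        raise ValidationError("apply_model needs model_path")
    sample_set, ladder = _load_input(cfg)
    ratios, _ = build_ratio_table(sample_set, ladder, ri_tol=cfg.ri_tol)
    model = RatioModel.from_json(cfg.model_path)
    subjects = {t.sample_id: t.subject_id for t in sample_set.tables}
    carriers = {t.sample_id: t.carrier for t in sample_set.tables}
    cart = [s for s in ratios.index if carriers[s] is Carrier.fired_cartridge]
    std = [s for s in ratios.index if carriers[s] is Carrier.glass_beads]
    queries, panel = (
        (cart, std) if cfg.direction == "cartridge_to_standard" else (std, cart)
    )
    _identify(ratios, queries, panel, subjects, model, cfg, outdir)
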