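"""Synthetic scent-cohort generator.

Emulates the statistical structure of a GCxGC human-scent study so every
pipeline stage runs without instrument data:

* each subject has a latent scent profile — per-compound log10 mean areas —
  shared by all of that subject's samples;
* repeated samples vary log-normally around the profile (``intra_cv`` is the
  natural-log sigma) and peaks drop out stochastically;
* a set of contaminant compounds (including the siloxane RI markers) is
  shared by everyone and appears even in blanks;
* firing a cartridge attenuates the least-volatile (top-RI) fraction of the
  scent peaks, adds extra dropout, and deposits a "cloud" of lubricant
  alkane contaminants;
* every sample's first-dimension retention times are distorted by a
  per-sample affine drift plus small per-peak jitter, correctable through
  the marker ladder.

All randomness flows from ``SyntheticConfig.seed`` through named
``numpy.random.SeedSequence`` children, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peak_io import Carrier, Peak, PeakTable, SampleMeta, SampleSet
from .ri_alignment import MarkerLadder, compute_ri

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "canonical_ladder",
    "generate_cohort",
    "firing_transform",
]

# stream labels for seed-sequence children
_LAYOUT, _PROFILES, _SAMPLES, _FIRING = 101, 202, 303, 404


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterisation of the simulated cohort.

    Defaults describe a cohort panel of 75 scent compounds plus 10 shared
    contaminants (6 of them siloxane RI markers), moderate within-subject
    log-normal variability, and a firing transform that attenuates the
    top-RI third of the scent peaks to 30% and adds 15 lubricant-cloud
    compounds.
    """

    n_subjects: int = 5
    n_compounds: int = 75
    n_shared_contaminants: int = 10  # includes the marker siloxanes
    n_markers: int = 6
    subject_profile_sd: float = 0.8  # log10 units, between-subject spread
    intra_cv: float = 0.4  # ln-scale sigma of within-subject noise
    dropout_p: float = 0.05
    firing_attenuation: float = 0.3
    firing_fraction: float = 1.0 / 3.0  # top-RI fraction of scent peaks affected
    firing_dropout_p: float = 0.1
    cloud_compounds: int = 15
    rt_drift_slope: float = 0.03  # per-sample slope drawn from 1 +/- this
    rt_drift_offset: float = 5.0  # per-sample offset, +/- seconds
    rt1_jitter_sd: float = 0.5  # per-peak measurement jitter, seconds
    rt2_jitter_sd: float = 0.05
    base_log10_area: float = 5.0
    contaminant_log10_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_p", "firing_dropout_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.firing_attenuation:
            raise ValidationError("firing_attenuation must be >= 0")
        if not 0.0 < self.firing_fraction <= 1.0:
            raise ValidationError("firing_fraction must be in (0, 1]")
        for name in ("subject_profile_sd", "intra_cv", "rt1_jitter_sd", "rt2_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_markers < 2 or self.n_markers > self.n_shared_contaminants:
            raise ValidationError("need 2 <= n_markers <= n_shared_contaminants")
        if self.n_subjects < 1 or self.n_compounds < 2:
            raise ValidationError("need >= 1 subject and >= 2 compounds")


def canonical_ladder(cfg: SyntheticConfig) -> MarkerLadder:
    """The undrifted siloxane marker ladder (RI 400..1400, rt1 150..1650 s)."""
    idx = np.linspace(400, 1400, cfg.n_markers)
    rts = np.linspace(150, 1650, cfg.n_markers)
    labels = tuple(f"siloxane_{int(round(i))}" for i in idx)
    return MarkerLadder(markers=tuple(zip(idx, rts)), labels=labels)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    compounds: pd.DataFrame  # name, kind, rt1, rt2, ri, shared_log10
    profiles: pd.DataFrame  # subjects x scent compounds, log10 mean areas
    ladder: MarkerLadder
    subject_of: dict[str, Optional[str]]
    config: SyntheticConfig

    @property
    def scent_compounds(self) -> list[str]:
        return list(self.compounds.index[self.compounds["kind"] == "scent"])

    @property
    def contaminant_compounds(self) -> list[str]:
        return list(self.compounds.index[self.compounds["kind"] != "scent"])


def _layout(cfg: SyntheticConfig) -> pd.DataFrame:
    """Deterministic compound placement: names, kinds, true rt1/rt2, RIs.

    Compounds sit on an evenly spaced rt1 grid inside the ladder span so
    that adjacent true RIs are separated well beyond the default clustering
    tolerance; cloud compounds occupy slots in the lower (early-eluting)
    half, mirroring where lubricant alkanes elute.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _LAYOUT]))
    ladder = canonical_ladder(cfg)
    n_other = cfg.n_shared_contaminants - cfg.n_markers
    total = cfg.n_compounds + n_other + cfg.cloud_compounds
    # evenly spaced rt1 slots, kept clear of the marker positions so marker
    # clusters never chain-merge with compound clusters
    marker_rts = np.array([m[1] for m in ladder.markers])
    cand = np.linspace(165, 1635, total + 2 * cfg.n_markers + 2)
    cand = cand[np.abs(cand[:, None] - marker_rts[None, :]).min(axis=1) > 12.0]
    positions = cand[np.round(np.linspace(0, len(cand) - 1, total)).astype(int)]

    lower = [i for i, t in enumerate(positions) if t <= 900]
    cloud_slots = sorted(rng.choice(lower, size=min(cfg.cloud_compounds, len(lower)), replace=False))
    rest = [i for i in range(total) if i not in set(cloud_slots)]
    rest = list(rng.permutation(rest))
    scent_slots, cont_slots = sorted(rest[: cfg.n_compounds]), sorted(rest[cfg.n_compounds:])

    rows = []
    for k, slot in enumerate(scent_slots):
        rows.append((f"cmpd_{k:03d}", "scent", positions[slot], float(rng.uniform(0.5, 8.0)), np.nan))
    for k, slot in enumerate(cont_slots):
        rows.append(
            (f"cont_{k:02d}", "contaminant", positions[slot], float(rng.uniform(0.5, 8.0)),
             float(rng.normal(cfg.base_log10_area + 0.5, cfg.contaminant_log10_sd)))
        )
    for k, slot in enumerate(cloud_slots):
        rows.append(
            (f"cloud_{k:02d}", "cloud", positions[slot], float(rng.uniform(0.5, 4.0)),
             float(rng.normal(cfg.base_log10_area + 0.5, cfg.contaminant_log10_sd)))
        )
    for (idx, rt), label in zip(canonical_ladder(cfg).markers, canonical_ladder(cfg).labels):
        rows.append(
            (label, "marker", rt, float(rng.uniform(0.5, 8.0)),
             float(rng.normal(cfg.base_log10_area + 1.0, 0.2)))
        )
    df = pd.DataFrame(rows, columns=["name", "kind", "rt1", "rt2", "shared_log10"])
    df = df.set_index("name")
    df["ri"] = compute_ri(df["rt1"].to_numpy(), ladder)
    return df


def _profiles(cfg: SyntheticConfig, layout: pd.DataFrame) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _PROFILES]))
    subjects = [f"S{k + 1:02d}" for k in range(cfg.n_subjects)]
    scent = list(layout.index[layout["kind"] == "scent"])
    values = rng.normal(cfg.base_log10_area, cfg.subject_profile_sd, size=(len(subjects), len(scent)))
    return pd.DataFrame(values, index=subjects, columns=scent)


def _true_table(
    sample_id: str,
    subject: Optional[str],
    carrier: Carrier,
    cfg: SyntheticConfig,
    layout: pd.DataFrame,
    profiles: pd.DataFrame,
    rng: np.random.Generator,
    include_cloud: bool = False,
) -> PeakTable:
    """Sample in true (undrifted) retention coordinates."""
    peaks: list[Peak] = []
    counter = 0

    def add(name: str, log10_mean: float, can_drop: bool) -> None:
        nonlocal counter
        if can_drop and rng.random() < cfg.dropout_p:
            return
        area = 10.0**log10_mean * math.exp(rng.normal(0.0, cfg.intra_cv))
        row = layout.loc[name]
        peaks.append(
            Peak(
                peak_id=f"{sample_id}_p{counter:03d}",
                rt1=float(row["rt1"]),
                rt2=float(row["rt2"]),
                area=area,
                label=name,
            )
        )
        counter += 1

    for name, row in layout.iterrows():
        if row["kind"] == "marker":
            add(name, row["shared_log10"], can_drop=False)  # ladder must survive
        elif row["kind"] == "contaminant":
            add(name, row["shared_log10"], can_drop=True)
        elif row["kind"] == "cloud" and include_cloud:
            add(name, row["shared_log10"], can_drop=True)
        elif row["kind"] == "scent" and subject is not None:
            add(name, profiles.loc[subject, name], can_drop=True)
    return PeakTable(sample_id=sample_id, peaks=peaks, subject_id=subject, carrier=carrier)


def _distort(table: PeakTable, cfg: SyntheticConfig, rng: np.random.Generator) -> PeakTable:
    """Apply the per-sample affine rt1 drift plus per-peak jitter."""
    a = 1.0 + rng.uniform(-cfg.rt_drift_slope, cfg.rt_drift_slope)
    b = rng.uniform(-cfg.rt_drift_offset, cfg.rt_drift_offset)
    peaks = [
        replace(
            p,
            rt1=a * (p.rt1 + rng.normal(0.0, cfg.rt1_jitter_sd)) + b,
            rt2=max(0.0, p.rt2 + rng.normal(0.0, cfg.rt2_jitter_sd)),
        )
        for p in table.peaks
    ]
    return PeakTable(
        sample_id=table.sample_id, peaks=peaks, subject_id=table.subject_id, carrier=table.carrier
    )


def firing_transform(
    table: PeakTable,
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> PeakTable:
    """Turn a projectile sample into a fired-cartridge sample.

    The top-RI (least volatile) ``firing_fraction`` of the scent peaks is
    attenuated by ``firing_attenuation``, every scent peak additionally
    drops out with ``firing_dropout_p``, lubricant-cloud contaminant peaks
    are appended, and the carrier becomes ``fired_cartridge``.  Marker and
    shared-contaminant peaks are untouched so the sample stays alignable.
    """
    if table.carrier is not Carrier.projectile:
        raise ValidationError(
            f"firing_transform expects a projectile sample, got {table.carrier.value!r}"
        )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _FIRING]))
    layout = _layout(cfg)

    def is_scent(p: Peak) -> bool:
        return bool(p.label) and p.label.startswith("cmpd_")

    scent_rts = [p.rt1 for p in table.peaks if is_scent(p)] or [p.rt1 for p in table.peaks]
    cutoff = float(np.quantile(scent_rts, 1.0 - cfg.firing_fraction))
    peaks: list[Peak] = []
    for p in table.peaks:
        if is_scent(p):
            if rng.random() < cfg.firing_dropout_p:
                continue
            if p.rt1 >= cutoff:
                p = replace(p, area=p.area * cfg.firing_attenuation)
        peaks.append(p)
    present = {p.label for p in peaks if p.label}
    for name, row in layout[layout["kind"] == "cloud"].iterrows():
        if name in present:
            continue
        area = 10.0 ** row["shared_log10"] * math.exp(rng.normal(0.0, cfg.intra_cv))
        peaks.append(
            Peak(
                peak_id=f"{table.sample_id}_{name}",
                rt1=float(row["rt1"]),
                rt2=float(row["rt2"]),
                area=area,
                label=name,
            )
        )
    return PeakTable(
        sample_id=table.sample_id,
        peaks=peaks,
        subject_id=table.subject_id,
        carrier=Carrier.fired_cartridge,
    )


def generate_cohort(
    cfg: SyntheticConfig,
    n_standard_per_subject: int = 10,
    n_cartridge_per_subject: int = 1,
    n_blanks: int = 1,
) -> tuple[SampleSet, GroundTruth]:
    """Generate a full cohort: standards, fired cartridges and blanks.

    Per subject, ``n_standard_per_subject`` glass-bead standards and
    ``n_cartridge_per_subject`` fired-cartridge samples (projectile samples
    passed through :func:`firing_transform`).  ``n_blanks`` glass blanks and
    ``n_blanks`` fired blanks carry only contaminants (the fired ones also
    the lubricant cloud).  Returns the sample set plus ground truth.
    """
    layout = _layout(cfg)
    profiles = _profiles(cfg, layout)
    root = np.random.SeedSequence([cfg.seed, _SAMPLES])
    tables: list[PeakTable] = []
    metadata: dict[str, SampleMeta] = {}
    stream = iter(root.spawn(
        cfg.n_subjects * (n_standard_per_subject + n_cartridge_per_subject) + 2 * n_blanks
    ))

    def next_rng() -> np.random.Generator:
        return np.random.default_rng(next(stream))

    for subject in profiles.index:
        for k in range(n_standard_per_subject):
            rng = next_rng()
            sid = f"{subject}_std_{k + 1:02d}"
            table = _true_table(sid, subject, Carrier.glass_beads, cfg, layout, profiles, rng)
            tables.append(_distort(table, cfg, rng))
            metadata[sid] = SampleMeta(sid, subject, Carrier.glass_beads)
        for k in range(n_cartridge_per_subject):
            rng = next_rng()
            sid = f"{subject}_cart_{k + 1:02d}"
            table = _true_table(sid, subject, Carrier.projectile, cfg, layout, profiles, rng)
            table = firing_transform(table, cfg, rng)
            tables.append(_distort(table, cfg, rng))
            metadata[sid] = SampleMeta(sid, subject, Carrier.fired_cartridge)
    for k in range(n_blanks):
        for tag, cloud in (("glass", False), ("fired", True)):
            rng = next_rng()
            sid = f"blank_{tag}_{k + 1:02d}"
            table = _true_table(sid, None, Carrier.blank, cfg, layout, profiles, rng, include_cloud=cloud)
            tables.append(_distort(table, cfg, rng))
            metadata[sid] = SampleMeta(sid, None, Carrier.blank)

    truth = GroundTruth(
        compounds=layout,
        profiles=profiles,
        ladder=canonical_ladder(cfg),
        subject_of={sid: meta.subject_id for sid, meta in metadata.items()},
        config=cfg,
    )
    return SampleSet(tables=tables, metadata=metadata), truth
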