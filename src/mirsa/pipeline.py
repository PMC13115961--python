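"""Workflow orchestration: staged runs over an artifact directory.

Stages (in dependency order): ``simulate``, ``preprocess``,
``select-features``, ``project``, ``sa-single``, ``sa-cohort``,
``sa-reference``, ``evaluate``. Each stage reads its inputs from, and
writes its outputs to, a fixed layout under the run directory, so
stages can be re-run individually; a missing prerequisite raises an
error naming the stage that produces it. Every run writes a
``manifest.json`` echoing the resolved configuration and seeds, and all
randomness is funneled through the named seeds, so two runs with equal
config and seeds produce byte-identical hotspot maps and reports.

Cohort convention: the samples (sorted by id) minus the last one form
the database cohort processed cohort-wide; the last sample is treated
as the newly added specimen and annotated via reference-based SA.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    DEFAULT_ALPHA,
    DEFAULT_ALPHA_MAX,
    DEFAULT_ALPHA_MIN,
    DEFAULT_ALPHA_STEP,
    DEFAULT_CALIBRATION_N_PERM,
    DEFAULT_N_PERM,
    HotspotDatabase,
    build_database,
    reference_sa,
)
from .evaluate import Rectangle, cohort_report, confusion
from .features import (
    DEFAULT_MAX_ERROR,
    DEFAULT_N_PER_CLASS,
    DEFAULT_N_REPEATS,
    DiscriminantFeatureSet,
    select_discriminant_features,
)
from .io import (
    PixelMask,
    read_cube,
    read_labels,
    read_mask,
    write_cube,
    write_mask,
)
from .moran import HotspotMap, build_weights, local_moran, threshold_hotspots
from .preprocess import DEFAULT_MASK_BAND, make_tissue_mask, preprocess
from .projection import DEFAULT_BASELINE, project, read_projection, write_projection
from .synthetic import SyntheticSpec, compact_spec, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "select-features",
    "project",
    "sa-single",
    "sa-cohort",
    "sa-reference",
    "evaluate",
)


class MissingArtifactError(FileNotFoundError):
    """A stage prerequisite is absent; the message names its producer."""


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run (defaults per the workflow)."""

    out_dir: Path
    seed: int = 0
    tissue: str = "tumor"
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM
    alpha_min: float = DEFAULT_ALPHA_MIN
    alpha_max: float = DEFAULT_ALPHA_MAX
    alpha_step: float = DEFAULT_ALPHA_STEP
    calibration_n_perm: int = DEFAULT_CALIBRATION_N_PERM
    n_per_class: int = DEFAULT_N_PER_CLASS
    repeats: int = DEFAULT_N_REPEATS
    max_error: float = DEFAULT_MAX_ERROR
    baseline: float = DEFAULT_BASELINE
    mask_band: float = DEFAULT_MASK_BAND
    deriv_window: int = 9
    deriv_polyorder: int = 3
    dialect: str = "envi"
    n_refs: int = 2
    compact: bool = True  # reduced-size synthetic conditions for simulate
    n_samples: int = 7

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)

    # artifact layout -------------------------------------------------
    @property
    def data_dir(self) -> Path:
        return self.out_dir / "data"

    @property
    def work_dir(self) -> Path:
        return self.out_dir / "work"

    @property
    def report_dir(self) -> Path:
        return self.out_dir / "report"

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        cfg["out_dir"] = str(self.out_dir)
        return {"version": __version__, "config": cfg}


def _sample_ids(cfg: RunConfig) -> list[str]:
    ids = sorted(p.stem for p in cfg.data_dir.glob("*.hdr"))
    if not ids:
        raise MissingArtifactError(
            "no cubes found under data/; run the 'simulate' stage or place "
            "ENVI cubes there"
        )
    return ids


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; produced by the {producer!r} stage"
        )
    return path


# ---------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> None:
    spec = (
        compact_spec(seed=cfg.seed, n_samples=cfg.n_samples)
        if cfg.compact
        else SyntheticSpec(seed=cfg.seed, n_samples=cfg.n_samples)
    )
    write_cohort(generate_cohort(spec), spec, cfg.data_dir)


def stage_preprocess(cfg: RunConfig) -> None:
    pre = cfg.work_dir / "preprocessed"
    pre.mkdir(parents=True, exist_ok=True)
    for sid in _sample_ids(cfg):
        cube = read_cube(cfg.data_dir / f"{sid}.raw", cfg.dialect)
        mask = make_tissue_mask(cube, cfg.mask_band, seed=cfg.seed)
        pc, valid = preprocess(
            cube, cfg.deriv_window, cfg.deriv_polyorder, mask=mask
        )
        write_cube(pre / f"{sid}.raw", pc, dialect="envi")
        write_mask(pre / f"{sid}_mask.png", valid)


def stage_select_features(cfg: RunConfig) -> None:
    pre = cfg.work_dir / "preprocessed"
    sids = _sample_ids(cfg)
    sid = sids[0]  # training sample: first id, contains all tissue types
    cube = read_cube(_require(pre / f"{sid}.raw", "preprocess"))
    mask = read_mask(pre / f"{sid}_mask.png")
    labels = read_labels(
        _require(cfg.data_dir / f"{sid}_labels.png", "simulate")
    )
    feats, _ = select_discriminant_features(
        cube,
        labels,
        cfg.tissue,
        n_per_class=cfg.n_per_class,
        n_repeats=cfg.repeats,
        max_error=cfg.max_error,
        seed=cfg.seed,
        mask=mask,
    )
    feats.to_json(cfg.work_dir / "features.json")


def stage_project(cfg: RunConfig) -> None:
    pre = cfg.work_dir / "preprocessed"
    feats = DiscriminantFeatureSet.from_json(
        _require(cfg.work_dir / "features.json", "select-features")
    )
    out = cfg.work_dir / "projections"
    out.mkdir(parents=True, exist_ok=True)
    for sid in _sample_ids(cfg):
        cube = read_cube(_require(pre / f"{sid}.raw", "preprocess"))
        mask = read_mask(pre / f"{sid}_mask.png")
        write_projection(out / f"{sid}.tif", project(cube, feats, mask, cfg.baseline))


def _load_projections(cfg: RunConfig) -> list:
    out = cfg.work_dir / "projections"
    projs = []
    for sid in _sample_ids(cfg):
        p = _require(out / f"{sid}.tif", "project")
        mask = read_mask(cfg.work_dir / "preprocessed" / f"{sid}_mask.png")
        projs.append(read_projection(p, mask))
    return projs


def _write_hotspot(path: Path, hot: HotspotMap, extra: dict | None = None) -> None:
    write_mask(path, PixelMask(hot.values))
    meta = {"alpha": hot.alpha, "sample_id": hot.sample_id,
            "tissue_type": hot.tissue_type}
    meta.update(extra or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def stage_sa_single(cfg: RunConfig) -> None:
    out = cfg.work_dir / "sa_single"
    out.mkdir(parents=True, exist_ok=True)
    for proj in _load_projections(cfg):
        res = local_moran(
            proj.values, build_weights(proj.mask), cfg.n_perm, cfg.seed,
            proj.sample_id,
        )
        hot = threshold_hotspots(res, cfg.alpha, proj.tissue_type)
        _write_hotspot(out / f"{proj.sample_id}.png", hot,
                       {"n_perm": cfg.n_perm, "seed": cfg.seed,
                        "global_mean": res.global_mean})


def stage_sa_cohort(cfg: RunConfig) -> None:
    projs = _load_projections(cfg)
    db = build_database(projs[:-1], cfg.alpha, cfg.n_perm, cfg.seed)
    db.save(cfg.work_dir / "db")
    out = cfg.work_dir / "sa_cohort"
    out.mkdir(parents=True, exist_ok=True)
    for e in db.entries.values():
        _write_hotspot(out / f"{e.sample_id}.png", e.hotspots,
                       {"n_perm": cfg.n_perm, "seed": cfg.seed,
                        "ratio": e.ratio})


def stage_sa_reference(cfg: RunConfig) -> None:
    projs = _load_projections(cfg)
    db_dir = cfg.work_dir / "db"
    _require(db_dir / "manifest.json", "sa-cohort")
    db = HotspotDatabase.load(db_dir)
    cal = reference_sa(
        projs[-1], db, cfg.alpha_min, cfg.alpha_max, cfg.alpha_step,
        cfg.calibration_n_perm, cfg.seed, cfg.n_refs,
    )
    out = cfg.work_dir / "reference"
    out.mkdir(parents=True, exist_ok=True)
    sid = projs[-1].sample_id
    _write_hotspot(out / f"{sid}.png", cal.new_sample_hotspots,
                   {"alpha_star": cal.alpha_star, "references": cal.references})
    (out / "calibration.json").write_text(json.dumps({
        "alpha_star": cal.alpha_star,
        "references": cal.references,
        "iou_curve": cal.iou_curve,
    }, indent=2))


def default_rectangles(shape: tuple[int, int], sample_id: str,
                       margin: int = 2) -> list[Rectangle]:
    """Three equally sized horizontal rectangles inside a margin."""
    h, w = shape
    rows = np.linspace(margin, h - margin, 4).astype(int)
    return [
        Rectangle(sample_id, f"R{i}", int(rows[i]), margin, int(rows[i + 1]),
                  w - margin)
        for i in range(3)
    ]


def stage_evaluate(cfg: RunConfig) -> None:
    sids = _sample_ids(cfg)
    counts = []
    rect_rows = []
    for sid in sids:
        if sid == sids[-1]:
            pred_path = cfg.work_dir / "reference" / f"{sid}.png"
            producer = "sa-reference"
        else:
            pred_path = cfg.work_dir / "sa_cohort" / f"{sid}.png"
            producer = "sa-cohort"
        pred = HotspotMap(
            read_mask(_require(pred_path, producer)).values,
            cfg.alpha, sid, cfg.tissue,
        )
        labels = read_labels(cfg.data_dir / f"{sid}_labels.png")
        mask = read_mask(cfg.work_dir / "preprocessed" / f"{sid}_mask.png")
        for rect in default_rectangles(labels.shape, sid):
            rect_rows.append(rect)
            counts.append(confusion(pred, labels, cfg.tissue, rect, mask))
    report = cohort_report(counts)
    cfg.report_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(r) for r in rect_rows]).to_csv(
        cfg.report_dir / "rects.csv", index=False
    )
    report.to_csv(cfg.report_dir / "report.csv")
    (cfg.report_dir / "summary.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True)
    )


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "select-features": stage_select_features,
    "project": stage_project,
    "sa-single": stage_sa_single,
    "sa-cohort": stage_sa_cohort,
    "sa-reference": stage_sa_reference,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | list[str] = STAGES) -> Path:
    """Run the requested stages in canonical order; returns the run dir."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    (cfg.out_dir / "manifest.json").write_text(
        json.dumps(cfg.manifest(), indent=2, sort_keys=True)
    )
    for stage in STAGES:
        if stage in stages:
            logger.info("running stage %s", stage)
            _STAGE_FN[stage](cfg)
    return cfg.out_dir
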