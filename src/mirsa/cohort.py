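"""Interdependent spatial autocorrelation across a sample cohort.

Cohort-wide processing stitches the per-sample projection images into a
zero-padded "super image" and runs local Moran's I once on it, so the
global moments and the conditional-permutation pool span every on-tissue
pixel of every sample. The stitched result is then disassembled back
into per-sample maps. A 1-pixel zero gutter separates adjacent tiles so
queen contiguity never crosses sample boundaries.

Reference-based processing calibrates a new sample against a previously
computed database: the new sample is stitched with two reference
samples (the database entries with the lowest and highest
hotspot-to-total-tissue-area ratio), SA runs once on the group of
three, and the confidence level is swept over a grid; the level
maximizing the mean intersection-over-union between the references'
re-thresholded maps and their database maps defines the new sample's
hotspot map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ConsistencyError, PixelMask
from .moran import HotspotMap, MoranResult, iou, local_moran, build_weights, HH
from .projection import ProjectionImage

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 999
DEFAULT_ALPHA_MIN = 0.0005
DEFAULT_ALPHA_MAX = 0.5
DEFAULT_ALPHA_STEP = 0.0005
# pseudo-p granularity with 999 permutations (0.001) is coarser than the
# 0.0005 alpha grid; 1999 permutations make every grid step resolvable
DEFAULT_CALIBRATION_N_PERM = 1999


class CalibrationDegenerateError(ValueError):
    """Every reference hotspot map in the database is empty."""


@dataclass
class Tile:
    sample_id: str
    row0: int
    col0: int
    height: int  # original sample extent within the tile
    width: int


@dataclass
class SuperImage:
    """Zero-padded, stitched cohort image with tile bookkeeping."""

    values: np.ndarray
    mask: PixelMask
    tiles: list[Tile]
    tissue_type: str
    baseline: float

    def tile_slices(self, t: Tile) -> tuple[slice, slice]:
        return slice(t.row0, t.row0 + t.height), slice(t.col0, t.col0 + t.width)

    def disassemble(self) -> list[ProjectionImage]:
        out = []
        for t in self.tiles:
            rs, cs = self.tile_slices(t)
            out.append(
                ProjectionImage(
                    self.values[rs, cs].copy(),
                    PixelMask(self.mask.values[rs, cs]),
                    self.tissue_type,
                    self.baseline,
                    t.sample_id,
                )
            )
        return out

    def disassemble_result(self, res: MoranResult) -> list[MoranResult]:
        return [res.submap(*self.tile_slices(t), sample_id=t.sample_id) for t in self.tiles]


def stitch(projections: list[ProjectionImage], gutter: int = 1) -> SuperImage:
    """Zero-pad to a common tile size and stitch into a near-square grid."""
    if len(projections) < 2:
        raise ValueError("stitching needs at least two samples")
    tissues = {p.tissue_type for p in projections}
    if len(tissues) != 1:
        raise ConsistencyError(f"mixed tissue types in cohort: {tissues}")
    th = max(p.shape[0] for p in projections)
    tw = max(p.shape[1] for p in projections)
    n = len(projections)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    H = nrows * th + (nrows - 1) * gutter
    W = ncols * tw + (ncols - 1) * gutter
    values = np.zeros((H, W))
    mask = np.zeros((H, W), dtype=bool)
    tiles = []
    for i, p in enumerate(projections):
        r, c = divmod(i, ncols)
        r0, c0 = r * (th + gutter), c * (tw + gutter)
        h, w = p.shape
        values[r0 : r0 + h, c0 : c0 + w] = np.where(p.mask.values, p.values, 0.0)
        mask[r0 : r0 + h, c0 : c0 + w] = p.mask.values
        tiles.append(Tile(p.sample_id or f"sample_{i}", r0, c0, h, w))
    return SuperImage(values, PixelMask(mask), tiles, projections[0].tissue_type,
                      projections[0].baseline)


@dataclass
class CohortSAResult:
    """Cohort-wide SA output: stitched result plus per-sample views."""

    super_image: SuperImage
    super_result: MoranResult
    results: list[MoranResult]
    hotspots: list[HotspotMap]
    alpha: float


def cohort_sa(
    projections: list[ProjectionImage],
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> CohortSAResult:
    """Run local Moran's I once on the stitched cohort and disassemble.

    Zero-valued padding/off-tissue pixels are omitted: the global mean,
    variance and the permutation pool are computed over the on-tissue
    pixels of all samples jointly, so each pixel is tested against the
    cohort-wide intensity distribution.
    """
    sup = stitch(projections)
    weights = build_weights(sup.mask)
    res = local_moran(sup.values, weights, n_perm=n_perm, seed=seed,
                      sample_id="super")
    per_sample = sup.disassemble_result(res)
    hotspots = [
        HotspotMap((r.quadrant == HH) & (r.pseudo_p <= alpha), alpha,
                   r.sample_id, sup.tissue_type)
        for r in per_sample
    ]
    return CohortSAResult(sup, res, per_sample, hotspots, alpha)


@dataclass
class DatabaseEntry:
    sample_id: str
    projection: ProjectionImage
    moran: MoranResult
    hotspots: HotspotMap
    tissue_area: int
    ratio: float  # hotspot pixels / on-tissue pixels


@dataclass
class HotspotDatabase:
    """Cohort-wide SA results kept as the reference for calibration."""

    tissue_type: str
    alpha_db: float
    n_perm: int
    seed: int
    entries: dict[str, DatabaseEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ratios(self) -> dict[str, float]:
        return {s: e.ratio for s, e in self.entries.items()}

    # -- persistence: manifest.json + one compressed grid bundle per sample
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "tissue_type": self.tissue_type,
            "alpha_db": self.alpha_db,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "samples": [
                {"sample_id": s, "tissue_area": e.tissue_area, "ratio": e.ratio}
                for s, e in self.entries.items()
            ],
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for s, e in self.entries.items():
            np.savez_compressed(
                path / f"{s}.npz",
                projection=e.projection.values,
                mask=e.projection.mask.values,
                observed_I=e.moran.observed_I,
                pseudo_p=e.moran.pseudo_p,
                quadrant=e.moran.quadrant,
                hotspots=e.hotspots.values,
                global_mean=e.moran.global_mean,
                m2=e.moran.m2,
                n_used=e.moran.n_used,
                baseline=e.projection.baseline,
            )

    @classmethod
    def load(cls, path: str | Path) -> "HotspotDatabase":
        path = Path(path)
        m = json.loads((path / "manifest.json").read_text())
        db = cls(m["tissue_type"], m["alpha_db"], m["n_perm"], m["seed"])
        for rec in m["samples"]:
            s = rec["sample_id"]
            z = np.load(path / f"{s}.npz")
            mask = PixelMask(z["mask"])
            proj = ProjectionImage(z["projection"], mask, m["tissue_type"],
                                   float(z["baseline"]), s)
            moran = MoranResult(
                z["observed_I"], z["pseudo_p"], z["quadrant"], mask.values,
                float(z["global_mean"]), float(z["m2"]), int(z["n_used"]),
                m["n_perm"], m["seed"], s,
            )
            db.entries[s] = DatabaseEntry(
                s, proj, moran,
                HotspotMap(z["hotspots"], m["alpha_db"], s, m["tissue_type"]),
                rec["tissue_area"], rec["ratio"],
            )
        return db


def build_database(
    projections: list[ProjectionImage],
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> HotspotDatabase:
    """Cohort-wide SA over the projections, stored per sample with ratios."""
    sa = cohort_sa(projections, alpha, n_perm, seed)
    db = HotspotDatabase(sa.super_image.tissue_type, alpha, n_perm, seed)
    for proj, res, hot in zip(sa.super_image.disassemble(), sa.results, sa.hotspots):
        area = proj.mask.n_on
        db.entries[proj.sample_id] = DatabaseEntry(
            proj.sample_id, proj, res, hot, area,
            hot.n_hotspot / area if area else 0.0,
        )
    return db


def pick_references(db: HotspotDatabase, n_refs: int = 2) -> list[str]:
    """Reference samples by hotspot-to-total-tissue-area ratio.

    The default two references are the entries with the lowest and the
    highest ratio (the low-high combination); additional references
    alternate inward from the extremes. Ties are broken by sample-id
    order.
    """
    if n_refs < 1 or n_refs > len(db):
        raise ValueError(f"n_refs={n_refs} outside [1, {len(db)}]")
    ordered = sorted(db.entries.values(), key=lambda e: (e.ratio, e.sample_id))
    picks, lo, hi = [], 0, len(ordered) - 1
    for j in range(n_refs):
        if j % 2 == 0:
            picks.append(ordered[lo].sample_id)
            lo += 1
        else:
            picks.append(ordered[hi].sample_id)
            hi -= 1
    return picks


@dataclass
class CalibrationResult:
    """Outcome of reference-based confidence-level adjustment."""

    alpha_star: float
    iou_curve: list[tuple[float, float]]
    references: list[str]
    new_sample_hotspots: HotspotMap
    new_sample_result: MoranResult
    reference_results: dict[str, MoranResult]


def reference_sa(
    new_projection: ProjectionImage,
    db: HotspotDatabase,
    alpha_min: float = DEFAULT_ALPHA_MIN,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    alpha_step: float = DEFAULT_ALPHA_STEP,
    n_perm: int = DEFAULT_CALIBRATION_N_PERM,
    seed: int = 0,
    n_refs: int = 2,
    mode: str = "argmax_mean",
) -> CalibrationResult:
    """Calibrate a new sample's confidence level against the database.

    The new sample is stitched with the picked references and SA runs on
    that group alone (the database's global moments are not injected).
    For every alpha on the grid the references' p-value grids are
    re-thresholded and compared to their database hotspot maps by IoU.

    ``mode="argmax_mean"`` (default) takes the single alpha maximizing
    the mean IoU over references (ties to the smallest alpha);
    ``mode="mean_argmax"`` averages each reference's own best alpha.
    """
    if len(db) < 2:
        raise ValueError("database needs at least two entries")
    if mode not in ("argmax_mean", "mean_argmax"):
        raise ValueError("mode must be 'argmax_mean' or 'mean_argmax'")
    refs = pick_references(db, n_refs)
    if all(db.entries[s].hotspots.n_hotspot == 0 for s in refs):
        raise CalibrationDegenerateError(
            "all reference hotspot maps in the database are empty"
        )
    group = [new_projection] + [db.entries[s].projection for s in refs]
    sa = cohort_sa(group, alpha=db.alpha_db, n_perm=n_perm, seed=seed)
    new_id = new_projection.sample_id or "sample_0"
    # stitch preserves order: new sample first, then the references
    # (indexing by position keeps a new sample that duplicates a
    # database id unambiguous)
    new_res = sa.results[0]
    by_id = {s: sa.results[1 + i] for i, s in enumerate(refs)}

    n_levels = int(round((alpha_max - alpha_min) / alpha_step)) + 1
    alphas = alpha_min + alpha_step * np.arange(n_levels)
    per_ref = np.empty((len(refs), n_levels))
    for i, s in enumerate(refs):
        res = by_id[s]
        db_map = db.entries[s].hotspots.values
        hh_p = np.where((res.quadrant == HH), res.pseudo_p, np.inf)
        for a, alpha in enumerate(alphas):
            per_ref[i, a] = iou(hh_p <= alpha, db_map)
    mean_curve = per_ref.mean(axis=0)
    if mode == "argmax_mean":
        alpha_star = float(alphas[int(np.argmax(mean_curve))])
    else:
        alpha_star = float(np.mean([alphas[int(np.argmax(per_ref[i]))]
                                    for i in range(len(refs))]))
    new_map = HotspotMap(
        (new_res.quadrant == HH) & (new_res.pseudo_p <= alpha_star),
        alpha_star, new_id, db.tissue_type,
    )
    return CalibrationResult(
        alpha_star=alpha_star,
        iou_curve=list(zip(alphas.tolist(), mean_curve.tolist())),
        references=refs,
        new_sample_hotspots=new_map,
        new_sample_result=new_res,
        reference_results={s: by_id[s] for s in refs},
    )
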