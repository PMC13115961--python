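"""Pixel-level agreement between SA annotations and pathology labels.

Annotations are compared inside evaluation rectangles (three equally
sized rectangles per section in the original protocol) restricted to
on-tissue pixels; truth pixels without a pathology label are not
considered. Metrics:

    standard accuracy = (TP + TN) / (TP + TN + FP + FN)
    balanced accuracy = (TPR + TNR) / 2
    PPV               = TP / (TP + FP)

Pixels the SA overlay could not assign to any tissue count as negative
predictions by default; an exclusion grid can remove them (or the
multi-assignment pixels) from the evaluated set instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LabelMap, PixelMask
from .moran import HotspotMap


class EmptyRegionError(ValueError):
    """No evaluable pixel in the rectangle."""


class UndefinedMetricError(ValueError):
    """The metric's denominator is zero for these counts."""


@dataclass(frozen=True)
class Rectangle:
    """Half-open, 0-based evaluation window [row0, row1) x [col0, col1)."""

    sample_id: str
    rect_id: str
    row0: int
    col0: int
    row1: int
    col1: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


def read_rectangles(path: str | Path) -> list[Rectangle]:
    """CSV with columns sample_id, rect_id, row0, col0, row1, col1."""
    df = pd.read_csv(path)
    return [
        Rectangle(str(r.sample_id), str(r.rect_id), int(r.row0), int(r.col0),
                  int(r.row1), int(r.col1))
        for r in df.itertuples()
    ]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int
    tissue_type: str = ""
    sample_id: str = ""
    region_id: str = ""

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.FN + other.FN, self.TN + other.TN,
            self.tissue_type if self.tissue_type == other.tissue_type else "",
        )


def confusion(
    pred: HotspotMap,
    truth: LabelMap,
    tissue: str,
    rect: Rectangle | None = None,
    mask: PixelMask | None = None,
    exclude: np.ndarray | None = None,
) -> ConfusionCounts:
    """Confusion counts of a tissue's hotspot map against the label map.

    Evaluated pixels: inside ``rect`` (whole image when omitted), inside
    ``mask`` when given, labeled in ``truth`` (unlabeled pixels are not
    considered), and not flagged in ``exclude``.
    """
    if pred.values.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    sel = np.ones(truth.shape, dtype=bool)
    if rect is not None:
        h, w = truth.shape
        if not (0 <= rect.row0 < rect.row1 <= h and 0 <= rect.col0 < rect.col1 <= w):
            raise ValueError(f"rectangle {rect} outside image bounds {(h, w)}")
        box = np.zeros_like(sel)
        box[rect.slices()] = True
        sel &= box
    if mask is not None:
        sel &= mask.values
    sel &= truth.values != truth.unlabeled_code
    if exclude is not None:
        sel &= ~np.asarray(exclude, bool)
    if not sel.any():
        raise EmptyRegionError("no evaluable pixels in region")
    is_t = truth.tissue_pixels(tissue)[sel]
    p = pred.values[sel]
    return ConfusionCounts(
        TP=int((p & is_t).sum()),
        FP=int((p & ~is_t).sum()),
        FN=int((~p & is_t).sum()),
        TN=int((~p & ~is_t).sum()),
        tissue_type=tissue,
        sample_id=rect.sample_id if rect else pred.sample_id,
        region_id=rect.rect_id if rect else "",
    )


def standard_accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("no evaluated pixels")
    return (c.TP + c.TN) / c.total


def balanced_accuracy(c: ConfusionCounts) -> float:
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise UndefinedMetricError(
            "a class is absent; report standard accuracy only"
        )
    tpr = c.TP / (c.TP + c.FN)
    tnr = c.TN / (c.TN + c.FP)
    return (tpr + tnr) / 2.0


def ppv(c: ConfusionCounts) -> float:
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("no positive predictions")
    return c.TP / (c.TP + c.FP)


@dataclass
class MetricReport:
    """Per-rectangle table plus per-tissue cohort summaries."""

    table: pd.DataFrame  # one row per sample x tissue x rectangle
    summary: dict  # per tissue: sample means, quartiles, pooled BA/PPV

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def cohort_report(counts: list[ConfusionCounts]) -> MetricReport:
    """Aggregate confusion counts the way the study protocol reports them.

    Per sample and tissue: the mean standard accuracy over its
    rectangles. Across samples: median and quartiles (linear
    interpolation) of those means. Pooled balanced accuracy and PPV are
    computed from the element-wise sum of all counts of a tissue — not
    the mean of per-rectangle values.
    """
    if not counts:
        raise ValueError("no confusion counts supplied")
    rows = []
    for c in counts:
        row = {
            "sample_id": c.sample_id, "tissue": c.tissue_type,
            "rect_id": c.region_id, "TP": c.TP, "FP": c.FP, "FN": c.FN,
            "TN": c.TN, "standard_accuracy": standard_accuracy(c),
        }
        try:
            row["balanced_accuracy"] = balanced_accuracy(c)
        except UndefinedMetricError:
            row["balanced_accuracy"] = np.nan
        try:
            row["ppv"] = ppv(c)
        except UndefinedMetricError:
            row["ppv"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(["tissue", "sample_id", "rect_id"],
                                           kind="stable").reset_index(drop=True)
    summary: dict = {}
    for tissue, sub in table.groupby("tissue"):
        sample_means = sub.groupby("sample_id")["standard_accuracy"].mean()
        pooled = ConfusionCounts(
            int(sub.TP.sum()), int(sub.FP.sum()), int(sub.FN.sum()),
            int(sub.TN.sum()), tissue,
        )
        entry = {
            "sample_mean_standard_accuracy": sample_means.to_dict(),
            "median_standard_accuracy": float(np.quantile(sample_means, 0.5)),
            "q1_standard_accuracy": float(np.quantile(sample_means, 0.25)),
            "q3_standard_accuracy": float(np.quantile(sample_means, 0.75)),
            "pooled_standard_accuracy": standard_accuracy(pooled),
        }
        try:
            entry["pooled_balanced_accuracy"] = balanced_accuracy(pooled)
        except UndefinedMetricError:
            entry["pooled_balanced_accuracy"] = None
        try:
            entry["pooled_ppv"] = ppv(pooled)
        except UndefinedMetricError:
            entry["pooled_ppv"] = None
        summary[tissue] = entry
    return MetricReport(table, summary)
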