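"""Discriminant wavenumber selection for a tissue type of interest.

Pipeline: (1) repeatedly resample a class-balanced pixel subset, fit a
random-forest classifier for the one-vs-rest task (tissue type of
interest, TTOI, against all other types) and rank bands by permutation
importance; (2) pool every band that ranked in the top ten at least
once; (3) keep only bands passing a specificity error test — there must
exist an intensity cutoff at which no tissue type has more than a
maximum fraction (default 25%) of its pixels falsely assigned; (4) tag
each surviving band as positive predictive (ppf: TTOI intensities
higher than the rest) or negative predictive (npf: lower).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .io import LabelMap, PixelMask, SpectralCube

logger = logging.getLogger(__name__)

DEFAULT_N_PER_CLASS = 500
DEFAULT_N_REPEATS = 10
DEFAULT_TOP_K = 10
DEFAULT_MAX_ERROR = 0.25
DEFAULT_CUTOFF_GRID = 512


class MissingClassError(ValueError):
    """A tissue type has no labeled on-mask pixels."""


class NoDiscriminantFeaturesError(ValueError):
    """No candidate band passed the specificity error test."""


@dataclass
class FeatureRanking:
    """Permutation-importance ranking of bands across balanced repeats."""

    wavenumbers: np.ndarray  # (bands,)
    scores: np.ndarray  # (n_repeats, bands) permutation importances
    times_in_top10: np.ndarray  # (bands,) int
    top_k: int

    @property
    def n_repeats(self) -> int:
        return self.scores.shape[0]

    @property
    def mean_importance(self) -> np.ndarray:
        return self.scores.mean(axis=0)

    @property
    def candidates(self) -> np.ndarray:
        """Bands ranking in the top ``top_k`` at least once, ascending."""
        return np.sort(self.wavenumbers[self.times_in_top10 > 0])


@dataclass
class DiscriminantFeature:
    wavenumber: float
    direction: str  # "ppf" or "npf"
    cutoff: float
    worst_class_error: float


@dataclass
class DiscriminantFeatureSet:
    """Bands selected as specific for one tissue type."""

    tissue_type: str
    features: list[DiscriminantFeature] = field(default_factory=list)
    max_error: float = DEFAULT_MAX_ERROR

    @property
    def ppf(self) -> list[float]:
        return [f.wavenumber for f in self.features if f.direction == "ppf"]

    @property
    def npf(self) -> list[float]:
        return [f.wavenumber for f in self.features if f.direction == "npf"]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "tissue": self.tissue_type,
                "max_error": self.max_error,
                "features": [
                    {
                        "wavenumber": f.wavenumber,
                        "direction": f.direction,
                        "cutoff": f.cutoff,
                        "worst_error": f.worst_class_error,
                    }
                    for f in self.features
                ],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "DiscriminantFeatureSet":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        obj = json.loads(p.read_text() if p else str(text_or_path))
        return cls(
            tissue_type=obj["tissue"],
            max_error=obj.get("max_error", DEFAULT_MAX_ERROR),
            features=[
                DiscriminantFeature(
                    f["wavenumber"], f["direction"], f["cutoff"], f["worst_error"]
                )
                for f in obj["features"]
            ],
        )


def _labeled_positions(
    labels: LabelMap, mask: PixelMask | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rows, cols, codes) of labeled, on-mask pixels."""
    lab = labels.values
    sel = lab != labels.unlabeled_code
    if mask is not None:
        sel &= mask.values
    rr, cc = np.nonzero(sel)
    return rr, cc, lab[rr, cc]


def sample_balanced_pixels(
    cube: SpectralCube,
    labels: LabelMap,
    n_per_class: int = DEFAULT_N_PER_CLASS,
    seed: int = 0,
    mask: PixelMask | None = None,
) -> pd.DataFrame:
    """Class-balanced random pixel subset as a spectra table.

    Draws ``n_per_class`` pixels per tissue type without replacement; if
    the least prevalent type has fewer labeled pixels, the draw size is
    lowered to that minimum for every class (with a warning). Columns:
    ``tissue``, ``row``, ``col`` followed by one column per wavenumber.
    """
    rr, cc, codes = _labeled_positions(labels, mask)
    classes = sorted(labels.legend)
    sizes = {c: int((codes == c).sum()) for c in classes}
    empty = [labels.legend[c] for c, s in sizes.items() if s == 0]
    if empty:
        raise MissingClassError(f"no labeled on-mask pixels for: {empty}")
    n_draw = min(n_per_class, min(sizes.values()))
    if n_draw < n_per_class:
        logger.warning(
            "least prevalent class has %d labeled pixels; drawing %d per class "
            "instead of %d",
            min(sizes.values()),
            n_draw,
            n_per_class,
        )
    rng = np.random.default_rng(seed)
    parts = []
    for c in classes:
        idx = np.nonzero(codes == c)[0]
        pick = rng.choice(idx, size=n_draw, replace=False)
        part = pd.DataFrame(
            cube.values[rr[pick], cc[pick], :], columns=cube.wavenumbers
        )
        part.insert(0, "col", cc[pick])
        part.insert(0, "row", rr[pick])
        part.insert(0, "tissue", labels.legend[c])
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def rank_wavenumbers(
    cube: SpectralCube,
    labels: LabelMap,
    tissue: str,
    n_per_class: int = DEFAULT_N_PER_CLASS,
    n_repeats: int = DEFAULT_N_REPEATS,
    top_k: int = DEFAULT_TOP_K,
    seed: int = 0,
    mask: PixelMask | None = None,
    n_estimators: int = 100,
    importance_max_samples: int | float = 500,
) -> FeatureRanking:
    """Rank bands by RF permutation importance for the one-vs-rest task.

    Each repeat draws a fresh balanced pixel subset (to absorb sampling
    variance from tissue-type balancing), fits a seeded random forest
    for TTOI-vs-rest, and computes the permutation importance of every
    band; a band is counted "in the top ten" once per repeat it reaches
    the top ``top_k``. Importance ties are broken toward the lower
    wavenumber.

    Importance is scored (balanced accuracy) on labeled pixels held out
    from the repeat's training draw: on training pixels a forest over
    strongly correlated neighboring bands reconstructs any single
    shuffled band perfectly and every importance collapses to zero.
    ``importance_max_samples`` caps the held-out scoring set.
    """
    ttoi_code = labels.code_for(tissue)  # validate early
    if len(labels.legend) < 2:
        raise MissingClassError("ranking needs at least two tissue types")
    bands = cube.wavenumbers
    eff_k = top_k
    if len(bands) < top_k:
        logger.warning("only %d bands; all become candidates", len(bands))
        eff_k = len(bands)
    rr, cc, codes = _labeled_positions(labels, mask)
    classes = sorted(labels.legend)
    sizes = {c: int((codes == c).sum()) for c in classes}
    empty = [labels.legend[c] for c, s in sizes.items() if s == 0]
    if empty:
        raise MissingClassError(f"no labeled on-mask pixels for: {empty}")
    scores = np.zeros((n_repeats, len(bands)))
    hits = np.zeros(len(bands), dtype=int)
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        # per class: disjoint train/eval halves, balanced training draw
        train_idx, eval_idx = [], []
        for c in classes:
            idx = rng.permutation(np.nonzero(codes == c)[0])
            half = max(1, len(idx) // 2)
            n_draw = min(n_per_class, half)
            train_idx.append(idx[:n_draw])
            eval_idx.append(idx[half:])
        tr = np.concatenate(train_idx)
        ev = np.concatenate(eval_idx)
        ms = importance_max_samples
        if isinstance(ms, (int, np.integer)):
            if len(ev) > ms:
                ev = rng.choice(ev, size=int(ms), replace=False)
        elif 0 < ms < 1:
            ev = rng.choice(ev, size=max(1, int(ms * len(ev))), replace=False)
        X = cube.values[rr[tr], cc[tr], :].astype(np.float64)
        y = codes[tr] == ttoi_code
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            class_weight="balanced",
            random_state=seed + rep,
            n_jobs=1,
        ).fit(X, y)
        imp = permutation_importance(
            rf,
            cube.values[rr[ev], cc[ev], :].astype(np.float64),
            codes[ev] == ttoi_code,
            n_repeats=1,
            random_state=seed + rep,
            scoring="balanced_accuracy",
            n_jobs=1,
        ).importances_mean
        scores[rep] = imp
        order = np.lexsort((bands, -imp))  # ties toward the lower wavenumber
        hits[order[:eff_k]] += 1
    return FeatureRanking(bands.copy(), scores, hits, eff_k)


def _worst_error_curve(
    v: np.ndarray, codes: np.ndarray, ttoi_code: int, cutoffs: np.ndarray, ppf: bool
) -> np.ndarray:
    """Worst per-class misassignment fraction at each cutoff.

    For a ppf band a pixel is called TTOI when its value exceeds the
    cutoff (falls below it, for npf). The error of the TTOI class is
    the fraction of its pixels on the wrong side; the error of every
    other class is the fraction of its pixels on the TTOI side. Both
    directions of misassignment count.
    """
    worst = np.zeros(len(cutoffs))
    for c in np.unique(codes):
        vals = np.sort(v[codes == c])
        frac_le = np.searchsorted(vals, cutoffs, side="right") / len(vals)
        frac_ttoi_side = (1.0 - frac_le) if ppf else frac_le
        err = (1.0 - frac_ttoi_side) if c == ttoi_code else frac_ttoi_side
        worst = np.maximum(worst, err)
    return worst


def error_test(
    cube: SpectralCube,
    labels: LabelMap,
    candidates: np.ndarray | list[float],
    tissue: str,
    max_error: float = DEFAULT_MAX_ERROR,
    n_grid: int = DEFAULT_CUTOFF_GRID,
    mask: PixelMask | None = None,
) -> DiscriminantFeatureSet:
    """Specificity error test with deterministic cutoff-grid search.

    For each candidate band the cutoff grid spans the band's observed
    intensity range (``n_grid`` steps, so the result is invariant to
    affine rescaling of the band); the cutoff minimizing the worst
    per-class error is retained, and the band is kept iff that worst
    error does not exceed ``max_error``. Direction is ppf iff the TTOI
    mean exceeds the mean over all other types.
    """
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        raise ValueError("candidate list is empty")
    rr, cc, codes = _labeled_positions(labels, mask)
    ttoi_code = labels.code_for(tissue)
    is_ttoi = codes == ttoi_code
    if not is_ttoi.any() or is_ttoi.all():
        raise MissingClassError(f"need TTOI and non-TTOI pixels for {tissue!r}")

    feats = []
    for wn in np.sort(candidates):
        v = cube.values[rr, cc, cube.band_index(wn)].astype(np.float64)
        ppf = v[is_ttoi].mean() > v[~is_ttoi].mean()
        lo, hi = v.min(), v.max()
        cutoffs = np.linspace(lo, hi, n_grid)
        worst = _worst_error_curve(v, codes, ttoi_code, cutoffs, ppf)
        best = int(np.argmin(worst))  # ties -> lowest cutoff
        if worst[best] <= max_error:
            feats.append(
                DiscriminantFeature(
                    float(wn), "ppf" if ppf else "npf", float(cutoffs[best]),
                    float(worst[best]),
                )
            )
    if not feats:
        raise NoDiscriminantFeaturesError(
            f"{tissue!r} was not computationally annotatable: no candidate band "
            f"passed the {max_error:.0%} error test"
        )
    return DiscriminantFeatureSet(tissue, feats, max_error)


def select_discriminant_features(
    cube: SpectralCube,
    labels: LabelMap,
    tissue: str,
    n_per_class: int = DEFAULT_N_PER_CLASS,
    n_repeats: int = DEFAULT_N_REPEATS,
    top_k: int = DEFAULT_TOP_K,
    max_error: float = DEFAULT_MAX_ERROR,
    n_grid: int = DEFAULT_CUTOFF_GRID,
    seed: int = 0,
    mask: PixelMask | None = None,
    n_estimators: int = 100,
    importance_max_samples: int | float = 500,
) -> tuple[DiscriminantFeatureSet, FeatureRanking]:
    """Full selection: ranking, top-10 pooling, then the error test."""
    ranking = rank_wavenumbers(
        cube, labels, tissue, n_per_class, n_repeats, top_k, seed, mask,
        n_estimators, importance_max_samples,
    )
    feats = error_test(
        cube, labels, ranking.candidates, tissue, max_error, n_grid, mask
    )
    return feats, ranking
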