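"""Local Moran's I (LISA) with conditional permutation on masked grids.

The statistic at pixel *i* is the standardized form

    I_i = (z_i / m2) * sum_j W_ij z_j,     z_i = x_i - xbar,
    m2  = (1/n) * sum_k z_k^2,

with queen-contiguity weights over the eight neighboring pixels,
off-mask neighbors removed and the remaining weights row-standardized
(so the spatial lag is the neighborhood mean of z).

Significance uses conditional permutation: the focal value is held
fixed and its neighborhood is redrawn, without replacement, from all
*other* on-mask observations; the one-sided pseudo p-value is
``(#{I_perm at least as extreme as I_obs} + 1) / (n_perm + 1)``.
Hotspots are pixels that are significant at level alpha *and* lie in
the high-high quadrant.

Each pixel owns a counter-based RNG substream keyed by the master seed
and its flat grid index, so results do not depend on traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ConsistencyError, PixelMask

# quadrant codes
OFF, HH, HL, LH, LL, ISOLATED = 0, 1, 2, 3, 4, 5
QUADRANT_NAMES = {OFF: "off", HH: "HH", HL: "HL", LH: "LH", LL: "LL", ISOLATED: "isolated"}

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class DegenerateInputError(ValueError):
    """The masked field has zero variance; Moran's I is undefined."""


@dataclass
class SpatialWeights:
    """Queen-contiguity neighbor structure for the on-mask pixels.

    ``neighbors`` is an ``(n, 8)`` array of indices into the on-mask
    ordering (raster order), padded with -1; ``counts`` gives the number
    of on-mask neighbors per pixel (0 = isolated); ``flat_index`` maps
    each on-mask pixel to its flat index in the full grid.
    """

    shape: tuple[int, int]
    mask: np.ndarray
    flat_index: np.ndarray
    neighbors: np.ndarray
    counts: np.ndarray
    style: str = "row"  # "row" (weights 1/k) or "binary" (weights 1)

    @property
    def n(self) -> int:
        return len(self.flat_index)

    @property
    def isolated(self) -> np.ndarray:
        return self.counts == 0

    def weight(self, i: int) -> float:
        """Weight attached to each neighbor of on-mask pixel ``i``."""
        k = int(self.counts[i])
        if k == 0:
            return 0.0
        return 1.0 / k if self.style == "row" else 1.0


def build_weights(mask: PixelMask, style: str = "row") -> SpatialWeights:
    """Queen-contiguity weights for a binary mask.

    Interior pixels have eight neighbors before masking; off-mask
    neighbors are dropped and (for ``style="row"``) remaining weights
    row-standardized. Pixels left without any on-mask neighbor are
    flagged isolated and excluded from inference (never from the global
    moments).
    """
    if style not in ("row", "binary"):
        raise ValueError("style must be 'row' or 'binary'")
    m = mask.values
    if not m.any():
        raise ValueError("mask has no on-tissue pixels")
    h, w = m.shape
    rank = -np.ones(m.shape, dtype=np.int64)  # on-mask ordering, raster order
    rr, cc = np.nonzero(m)
    n = len(rr)
    rank[rr, cc] = np.arange(n)

    neigh = -np.ones((n, 8), dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for dr, dc in _OFFSETS:
        r2, c2 = rr + dr, cc + dc
        ok = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
        ok[ok] &= m[r2[ok], c2[ok]]
        nb = rank[r2[ok], c2[ok]]
        neigh[np.nonzero(ok)[0], counts[ok]] = nb
        counts[ok] += 1
    return SpatialWeights(
        shape=(h, w),
        mask=m.copy(),
        flat_index=rr.astype(np.int64) * w + cc.astype(np.int64),
        neighbors=neigh,
        counts=counts,
        style=style,
    )


@dataclass
class MoranResult:
    """Per-pixel local Moran's I with conditional-permutation p-values.

    Grids are full-size; off-mask entries are NaN (``observed_I``,
    ``pseudo_p``) or 0 (``quadrant``). Re-thresholding at a different
    alpha needs no recomputation (see :func:`threshold_hotspots`).
    """

    observed_I: np.ndarray
    pseudo_p: np.ndarray
    quadrant: np.ndarray
    mask: np.ndarray
    global_mean: float
    m2: float
    n_used: int
    n_perm: int
    seed: int
    sample_id: str = ""

    def submap(self, rows: slice, cols: slice, sample_id: str = "") -> "MoranResult":
        """Windowed view (copy) used to disassemble stitched results.

        Global moments and counts describe the parent field and are
        carried over unchanged.
        """
        return MoranResult(
            observed_I=self.observed_I[rows, cols].copy(),
            pseudo_p=self.pseudo_p[rows, cols].copy(),
            quadrant=self.quadrant[rows, cols].copy(),
            mask=self.mask[rows, cols].copy(),
            global_mean=self.global_mean,
            m2=self.m2,
            n_used=self.n_used,
            n_perm=self.n_perm,
            seed=self.seed,
            sample_id=sample_id or self.sample_id,
        )


@dataclass
class HotspotMap:
    """Binary hotspot image: 1 = significant high-high cluster member."""

    values: np.ndarray
    alpha: float
    sample_id: str = ""
    tissue_type: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)

    @property
    def n_hotspot(self) -> int:
        return int(self.values.sum())


def _draw_wor(rng: np.random.Generator, n_other: int, n_perm: int, k: int) -> np.ndarray:
    """(n_perm, k) index draws into ``range(n_other)`` without replacement per row."""
    if k >= n_other:
        # fewer "others" than neighborhood slots: take a full permutation
        return np.argsort(rng.random((n_perm, n_other)), axis=1)[:, :k]
    d = rng.integers(0, n_other, size=(n_perm, k))
    if k > 1:
        while True:
            s = np.sort(d, axis=1)
            bad = (np.diff(s, axis=1) == 0).any(axis=1)
            nbad = int(bad.sum())
            if nbad == 0:
                break
            d[bad] = rng.integers(0, n_other, size=(nbad, k))
    return d


def _pixel_rng(seed: int, flat_index: int) -> np.random.Generator:
    # counter-based key -> substream independent of traversal order
    return np.random.Generator(np.random.Philox(key=(int(seed) << 32) + int(flat_index)))


def local_moran(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    sample_id: str = "",
) -> MoranResult:
    """Observed local Moran's I and conditional-permutation pseudo p-values.

    Parameters
    ----------
    values : ndarray (height, width)
        The univariate field (e.g. a projection image); only on-mask
        pixels are used.
    weights : SpatialWeights
        From :func:`build_weights`; defines mask and neighborhoods.
    n_perm : int
        Number of conditional permutations per pixel (>= 99).
    seed : int
        Master seed; per-pixel substreams are derived from it.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != weights.shape:
        raise ConsistencyError("values shape does not match weights")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if seed < 0:
        raise ValueError("seed must be non-negative")

    n = weights.n
    x = values.reshape(-1)[weights.flat_index]
    xbar = float(x.mean())
    z = x - xbar
    m2 = float((z * z).mean())
    if m2 == 0.0:
        raise DegenerateInputError("masked field has zero variance")
    if np.unique(x).size < 2:
        raise DegenerateInputError("masked field needs >= 2 distinct values")

    h, w = weights.shape
    I_grid = np.full((h, w), np.nan)
    p_grid = np.full((h, w), np.nan)
    q_grid = np.zeros((h, w), dtype=np.int8)
    rows, cols = weights.flat_index // w, weights.flat_index % w

    row_style = weights.style == "row"
    for i in range(n):
        k = int(weights.counts[i])
        r, c = int(rows[i]), int(cols[i])
        if k == 0:
            q_grid[r, c] = ISOLATED
            continue
        zn = z[weights.neighbors[i, :k]]
        lag = zn.mean() if row_style else zn.sum()
        I_obs = z[i] / m2 * lag
        I_grid[r, c] = I_obs
        if z[i] > 0:
            q_grid[r, c] = HH if lag > 0 else HL
        else:
            q_grid[r, c] = LH if lag > 0 else LL

        rng = _pixel_rng(seed, int(weights.flat_index[i]))
        d = _draw_wor(rng, n - 1, n_perm, k)
        idx = d + (d >= i)  # skip the focal observation
        lag_perm = z[idx].mean(axis=1) if row_style else z[idx].sum(axis=1)
        I_perm = z[i] / m2 * lag_perm
        if I_obs >= 0:
            count = int((I_perm >= I_obs).sum())
        else:
            count = int((I_perm <= I_obs).sum())
        p_grid[r, c] = (count + 1) / (n_perm + 1)

    return MoranResult(
        observed_I=I_grid,
        pseudo_p=p_grid,
        quadrant=q_grid,
        mask=weights.mask.copy(),
        global_mean=xbar,
        m2=m2,
        n_used=n,
        n_perm=n_perm,
        seed=seed,
        sample_id=sample_id,
    )


def threshold_hotspots(
    res: MoranResult, alpha: float = 0.01, tissue_type: str = ""
) -> HotspotMap:
    """Binary hotspot map: high-high quadrant and pseudo_p <= alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    hot = (res.quadrant == HH) & (res.pseudo_p <= alpha)
    return HotspotMap(hot, alpha, res.sample_id, tissue_type)


def threshold_coldspots(
    res: MoranResult, alpha: float = 0.01, tissue_type: str = ""
) -> HotspotMap:
    """Significant low-low clusters; exposed for completeness, unused by default."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    cold = (res.quadrant == LL) & (res.pseudo_p <= alpha)
    return HotspotMap(cold, alpha, res.sample_id, tissue_type)


@dataclass
class OverlayResult:
    """Multi-tissue assignment overlay of per-tissue hotspot maps."""

    tissues: list[str]
    stack: np.ndarray  # (n_tissues, h, w) bool
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def counts(self) -> np.ndarray:
        return self.stack.sum(axis=0)

    @property
    def unassigned(self) -> np.ndarray:
        un = self.counts == 0
        return un & self.mask if self.mask is not None else un

    @property
    def multiple(self) -> np.ndarray:
        return self.counts > 1

    def tissues_at(self, row: int, col: int) -> frozenset[str]:
        return frozenset(
            t for t, plane in zip(self.tissues, self.stack) if plane[row, col]
        )


def overlay_maps(
    maps: list[HotspotMap], mask: np.ndarray | None = None
) -> OverlayResult:
    """Overlay per-tissue hotspot maps into a multi-label assignment grid.

    Pixels assigned by no map are flagged unassigned; pixels assigned by
    more than one map are flagged multiple (border uncertainty between
    tissue types).
    """
    if not maps:
        raise ValueError("no maps to overlay")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ConsistencyError(f"hotspot maps differ in shape: {shapes}")
    return OverlayResult(
        tissues=[m.tissue_type for m in maps],
        stack=np.stack([m.values for m in maps]),
        mask=mask,
    )


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 when both empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union
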