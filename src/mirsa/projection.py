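"""Single-plane projection images fusing the selected wavenumber bands.

Per on-mask pixel k, with i over positive predictive (ppf) and j over
negative predictive (npf) bands of the tissue type's feature set:

    P_k = baseline + sum_i T_k^i - sum_j T_k^j

where T is the preprocessed (normalized second-derivative, unit-less)
transmittance and the baseline offset (default +10) shifts typical
values away from zero. Values below zero are permitted — downstream
spatial autocorrelation only uses relative values, so nothing is
clipped. Off-mask pixels are written as 0 so projections interoperate
with zero-padded stitching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .features import DiscriminantFeatureSet
from .io import ConsistencyError, PixelMask, SpectralCube

DEFAULT_BASELINE = 10.0


@dataclass
class ProjectionImage:
    """Unit-less single-plane fusion of a tissue type's selected bands."""

    values: np.ndarray
    mask: PixelMask
    tissue_type: str
    baseline: float = DEFAULT_BASELINE
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.mask.shape:
            raise ConsistencyError("projection and mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def on_mask_values(self) -> np.ndarray:
        return self.values[self.mask.values]


def project(
    cube: SpectralCube,
    feats: DiscriminantFeatureSet,
    mask: PixelMask,
    baseline: float = DEFAULT_BASELINE,
) -> ProjectionImage:
    """Fuse ppf/npf band images into one projection image.

    ppf band images are summed pixel-wise and npf band images
    subtracted, starting from the baseline offset; off-mask pixels are
    set to 0.
    """
    if cube.values.shape[:2] != mask.shape:
        raise ConsistencyError("cube and mask shapes differ")
    out = np.full(mask.shape, float(baseline))
    for f in feats.features:
        try:
            band = cube.band_image(f.wavenumber).astype(np.float64)
        except KeyError as e:
            raise KeyError(
                f"feature band {f.wavenumber} cm^-1 not present in cube"
            ) from e
        out += band if f.direction == "ppf" else -band
    out[~mask.values] = 0.0
    return ProjectionImage(out, mask, feats.tissue_type, baseline, cube.sample_id)


def write_projection(path: str | Path, proj: ProjectionImage) -> None:
    """32-bit float TIFF plus a JSON sidecar with provenance."""
    path = Path(path)
    tifffile.imwrite(path, proj.values.astype(np.float32))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(
            {
                "tissue": proj.tissue_type,
                "baseline": proj.baseline,
                "sample_id": proj.sample_id,
            }
        )
    )


def read_projection(path: str | Path, mask: PixelMask | None = None) -> ProjectionImage:
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if mask is None:
        mask = PixelMask(values != 0)
    return ProjectionImage(
        values,
        mask,
        meta.get("tissue", ""),
        float(meta.get("baseline", DEFAULT_BASELINE)),
        meta.get("sample_id", ""),
    )
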