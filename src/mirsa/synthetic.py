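"""Seeded synthetic MIR cohorts with known ground truth.

Each sample is a transmittance cube over the fingerprint region
(default 750-1798 cm^-1 at 4 cm^-1, 263 bands; 64 x 64 pixels at 25 um)
composed of:

* an organic on-tissue region and a tissue-type partition drawn from
  thresholded smoothed random fields (blob shapes resembling tumor
  nodules in a resection section);
* a shared base spectrum with broad absorption bands (including one at
  1550 cm^-1 so raw-intensity k-means masking works: tissue transmits
  less than background at that band);
* per-tissue Gaussian signature bands. A band's ``direction`` states
  the contrast expected in the *analysis domain* (after the second
  derivative and SNV): a ppf band is planted as a raw transmittance dip
  (its second derivative at the band center is positive, so the TTOI
  ends up higher there than other tissues) and an npf band as a raw
  peak;
* iid Gaussian noise, a spatially and spectrally smooth baseline drift,
  and an optional per-sample gain/offset batch effect.

A configurable fraction of samples is homogeneous: a single non-TTOI
tissue filling the whole section, emulating control specimens such as
non-tumor parenchyma. Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import LabelMap, PixelMask, SpectralCube, write_cube, write_labels, write_mask


class GeometryError(ValueError):
    """Requested geometry cannot be realized on the image grid."""


@dataclass
class SignatureBand:
    center: float  # cm^-1
    amplitude: float  # raw transmittance units
    direction: str  # "ppf" or "npf" in the preprocessed analysis domain
    bandwidth: float = 10.0  # Gaussian sigma, cm^-1


@dataclass
class TissueSpec:
    name: str
    code: int
    fraction: float  # share of on-tissue area in heterogeneous samples
    bands: list[SignatureBand] = field(default_factory=list)


def default_tissues() -> list[TissueSpec]:
    # band centers sit on the 4 cm^-1 default grid
    return [
        TissueSpec("tumor", 1, 0.35, [
            SignatureBand(1082.0, 0.08, "ppf"),
            SignatureBand(1362.0, 0.08, "npf"),
        ]),
        TissueSpec("stroma", 2, 0.35, [
            SignatureBand(1242.0, 0.08, "ppf"),
            SignatureBand(1602.0, 0.08, "npf"),
        ]),
        TissueSpec("parenchyma", 3, 0.30, [
            SignatureBand(1742.0, 0.08, "ppf"),
            SignatureBand(942.0, 0.08, "npf"),
        ]),
    ]


def compact_tissues() -> list[TissueSpec]:
    return [
        TissueSpec("tumor", 1, 0.35, [
            SignatureBand(1082.0, 0.08, "ppf"),
            SignatureBand(1362.0, 0.08, "npf"),
        ]),
        TissueSpec("stroma", 2, 0.35, [
            SignatureBand(1242.0, 0.08, "ppf"),
            SignatureBand(1434.0, 0.08, "npf"),
        ]),
        TissueSpec("parenchyma", 3, 0.30, [
            SignatureBand(1470.0, 0.08, "ppf"),
            SignatureBand(942.0, 0.08, "npf"),
        ]),
    ]


def compact_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Reduced-size study conditions for minutes-scale experiments.

    Same noise level, band amplitudes and geometry model as the default
    spec, but a 48 x 48 grid and a narrowed spectral window
    (902-1554 cm^-1, 164 bands, aligned so every signature center sits
    on the grid and the 1552 cm^-1 masking band resolves to 1550) with all signature bands relocated inside it. Use for
    benchmarks where the full 263-band cube is not the point.
    """
    kw = dict(
        image_size=(48, 48),
        wn_start=902.0,
        wn_stop=1554.0,
        tissue_types=compact_tissues(),
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic cohort."""

    n_samples: int = 7
    image_size: tuple[int, int] = (64, 64)
    pixel_size_um: float = 25.0
    wn_start: float = 750.0
    wn_stop: float = 1798.0
    wn_step: float = 4.0
    tissue_types: list[TissueSpec] = field(default_factory=default_tissues)
    ttoi: str = "tumor"
    noise_sd: float = 0.02
    baseline_drift: float = 0.02
    fraction_homogeneous: float = 1.0 / 7.0
    homogeneous_tissue: str = "parenchyma"
    on_tissue_fraction: float = 0.85
    blob_sigma: float = 8.0  # px; smoothness of the tissue-partition field
    mask_sigma: float = 16.0  # px; smoothness of the section outline
    batch_gain_sd: float = 0.0
    batch_offset_sd: float = 0.0
    seed: int = 0

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(self.wn_start, self.wn_stop + self.wn_step / 2, self.wn_step)

    def validate(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise GeometryError("image too small for blob geometry (min 16 x 16)")
        if abs(sum(t.fraction for t in self.tissue_types) - 1.0) > 1e-9:
            raise GeometryError("tissue fractions must sum to 1")
        names = [t.name for t in self.tissue_types]
        if self.ttoi not in names or self.homogeneous_tissue not in names:
            raise GeometryError("ttoi / homogeneous_tissue must be tissue types")
        wn = self.wavenumbers
        for t in self.tissue_types:
            for b in t.bands:
                if not (wn[0] <= b.center <= wn[-1]):
                    raise GeometryError(
                        f"signature band {b.center} outside range "
                        f"[{wn[0]}, {wn[-1]}] cm^-1"
                    )

    def truth_directions(self) -> dict[str, list[tuple[float, str]]]:
        """Per tissue: planted (wavenumber, analysis-domain direction)."""
        return {
            t.name: [(b.center, b.direction) for b in t.bands]
            for t in self.tissue_types
        }


@dataclass
class SyntheticSample:
    cube: SpectralCube
    mask: PixelMask
    labels: LabelMap
    homogeneous: bool = False


def _base_spectrum(wn: np.ndarray) -> np.ndarray:
    """Shared tissue transmittance: broad absorptions on a high background."""
    t = np.full_like(wn, 0.95)
    for center, amp, sig in [(1550.0, 0.30, 60.0), (1050.0, 0.15, 80.0),
                             (1650.0, 0.10, 40.0)]:
        t -= amp * np.exp(-0.5 * ((wn - center) / sig) ** 2)
    return t


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd else f


def _partition(rng: np.random.Generator, spec: SyntheticSpec,
               mask: np.ndarray) -> np.ndarray:
    """Assign exactly one tissue code to every on-tissue pixel."""
    lab = np.zeros(mask.shape, dtype=np.int32)
    remaining = mask.copy()
    remaining_frac = 1.0
    for t in spec.tissue_types[:-1]:
        f = _smooth_field(rng, mask.shape, spec.blob_sigma)
        vals = f[remaining]
        share = t.fraction / remaining_frac
        thr = np.quantile(vals, 1.0 - share)
        region = remaining & (f > thr)
        lab[region] = t.code
        remaining &= ~region
        remaining_frac -= t.fraction
    lab[remaining] = spec.tissue_types[-1].code
    return lab


def generate_sample(spec: SyntheticSpec, index: int) -> SyntheticSample:
    """One cohort sample; deterministic given (spec.seed, index)."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, index])
    h, w = spec.image_size
    wn = spec.wavenumbers

    outline = _smooth_field(rng, (h, w), spec.mask_sigma)
    thr = np.quantile(outline.ravel(), 1.0 - spec.on_tissue_fraction)
    mask = outline > thr
    if not mask.any():  # degenerate draw; keep the brightest pixel
        mask[np.unravel_index(np.argmax(outline), outline.shape)] = True

    n_hom = int(round(spec.fraction_homogeneous * spec.n_samples))
    homogeneous = index >= spec.n_samples - n_hom
    by_name = {t.name: t for t in spec.tissue_types}
    if homogeneous:
        lab = np.zeros((h, w), dtype=np.int32)
        lab[mask] = by_name[spec.homogeneous_tissue].code
    else:
        lab = _partition(rng, spec, mask)

    base = _base_spectrum(wn)
    cube = np.broadcast_to(base, (h, w, len(wn))).copy()
    for t in spec.tissue_types:
        region = lab == t.code
        if not region.any():
            continue
        delta = np.zeros_like(wn)
        for b in t.bands:
            g = np.exp(-0.5 * ((wn - b.center) / b.bandwidth) ** 2)
            # ppf in the analysis domain = raw transmittance dip
            delta += (-b.amplitude if b.direction == "ppf" else b.amplitude) * g
        cube[region] += delta

    # spatially and spectrally smooth baseline drift: quadratic in the
    # spectral coordinate with smooth random spatial coefficient maps
    if spec.baseline_drift > 0:
        u = np.linspace(-1.0, 1.0, len(wn))
        drift = np.zeros((h, w, len(wn)))
        for p, basis in enumerate([np.ones_like(u), u, u * u]):
            coeff = _smooth_field(rng, (h, w), spec.mask_sigma)
            drift += coeff[:, :, None] * basis * (spec.baseline_drift / (p + 1))
        cube += drift

    if spec.noise_sd > 0:
        cube += rng.normal(0.0, spec.noise_sd, size=cube.shape)

    if spec.batch_gain_sd > 0 or spec.batch_offset_sd > 0:
        gain = 1.0 + rng.normal(0.0, spec.batch_gain_sd) if spec.batch_gain_sd else 1.0
        offset = rng.normal(0.0, spec.batch_offset_sd) if spec.batch_offset_sd else 0.0
        cube = cube * gain + offset

    # off-tissue: near-total transmittance (no absorber in the beam)
    off = ~mask
    cube[off] = 1.0 + rng.normal(0.0, spec.noise_sd, size=(int(off.sum()), len(wn)))

    legend = {t.code: t.name for t in spec.tissue_types}
    return SyntheticSample(
        cube=SpectralCube(wn, cube, spec.pixel_size_um, f"S{index:02d}"),
        mask=PixelMask(mask),
        labels=LabelMap(lab, legend, unlabeled_code=0),
        homogeneous=homogeneous,
    )


def generate_cohort(spec: SyntheticSpec) -> list[SyntheticSample]:
    """The full cohort; homogeneous control samples come last."""
    spec.validate()
    return [generate_sample(spec, i) for i in range(spec.n_samples)]


def punch_cores(
    sample: SyntheticSample,
    centers: list[tuple[int, int]],
    diameter_um: float = 825.0,
    pixel_size_um: float | None = None,
) -> list[SyntheticSample]:
    """Digitally punch circular cores (biopsy-needle style) from a sample.

    The core diameter in pixels is ``round(diameter_um / pixel_size_um)``
    (a G18 needle at 825 um on a 25 um grid gives 33 pixels). Each core
    is a square crop of cube, mask and labels with everything outside
    the circle masked off.
    """
    px = pixel_size_um if pixel_size_um is not None else sample.cube.pixel_size
    d = int(round(diameter_um / px))
    r = d / 2.0
    h, w = sample.mask.shape
    out = []
    for ci, (cr, cc) in enumerate(centers):
        if not (0 <= cr < h and 0 <= cc < w):
            raise GeometryError(f"core center {(cr, cc)} outside image {(h, w)}")
        r0, r1 = cr - (d - 1) // 2, cr - (d - 1) // 2 + d
        c0, c1 = cc - (d - 1) // 2, cc - (d - 1) // 2 + d
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise GeometryError(f"core at {(cr, cc)} (d={d}px) exceeds bounds")
        yy, xx = np.mgrid[r0:r1, c0:c1]
        circle = (yy - cr) ** 2 + (xx - cc) ** 2 <= r * r
        out.append(
            SyntheticSample(
                cube=SpectralCube(
                    sample.cube.wavenumbers.copy(),
                    sample.cube.values[r0:r1, c0:c1],
                    sample.cube.pixel_size,
                    f"{sample.cube.sample_id}_core{ci:02d}",
                ),
                mask=PixelMask(sample.mask.values[r0:r1, c0:c1] & circle),
                labels=LabelMap(
                    np.where(circle, sample.labels.values[r0:r1, c0:c1],
                             sample.labels.unlabeled_code),
                    sample.labels.legend,
                    sample.labels.unlabeled_code,
                ),
                homogeneous=sample.homogeneous,
            )
        )
    return out


def write_cohort(samples: list[SyntheticSample], spec: SyntheticSpec,
                 out_dir: str | Path) -> None:
    """ENVI cubes, PNG masks/labels and a truth manifest for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        sid = s.cube.sample_id
        write_cube(out / f"{sid}.raw", s.cube, dialect="envi")
        write_mask(out / f"{sid}_mask.png", s.mask)
        write_labels(out / f"{sid}_labels.png", s.labels)
    (out / "truth.json").write_text(json.dumps({
        "seed": spec.seed,
        "ttoi": spec.ttoi,
        "samples": [
            {"sample_id": s.cube.sample_id, "homogeneous": s.homogeneous}
            for s in samples
        ],
        "planted_features": {
            t: [{"wavenumber": wn, "direction": d} for wn, d in bands]
            for t, bands in spec.truth_directions().items()
        },
    }, indent=2))
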