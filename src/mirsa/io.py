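"""Hyperspectral cube, mask and label-map containers plus on-disk formats.

Coordinate convention throughout the package: row-major, 0-based
``(row, col)``; image grids are ``(height, width)`` arrays and cubes are
``(height, width, bands)``.

Two cube dialects are supported:

* ``envi`` — an ASCII ``.hdr`` (``samples``, ``lines``, ``bands``,
  ``wavelength = {...}``) next to a band-sequential little-endian
  float32 raw file;
* ``per_band_matrix`` — a directory with one plain-text matrix per band,
  named ``<wavenumber>.txt``.

Masks and label maps are single-channel 8-bit PNG or TIFF.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ConsistencyError(ValueError):
    """Declared metadata disagrees with the data actually present."""


@dataclass
class SpectralCube:
    """A wavenumber-indexed image stack.

    Parameters
    ----------
    wavenumbers : ndarray, shape (bands,)
        Band centers in cm^-1, strictly monotonic increasing.
    values : ndarray, shape (height, width, bands)
        Transmittance or derived (unit-less) intensities; all finite.
    pixel_size : float
        Lateral pixel pitch in micrometres.
    sample_id : str
        Identifier carried through stitching and reporting.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    pixel_size: float = 25.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ConsistencyError("cube values must be (height, width, bands)")
        if self.wavenumbers.ndim != 1 or len(self.wavenumbers) != self.values.shape[2]:
            raise ConsistencyError(
                f"{len(self.wavenumbers)} wavenumbers for "
                f"{self.values.shape[2]} bands"
            )
        d = np.diff(self.wavenumbers)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ConsistencyError("wavenumbers must be strictly monotonic")
        if not np.all(np.isfinite(self.values)):
            raise ConsistencyError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def sampling_interval(self) -> float:
        """Median spacing of the wavenumber grid (cm^-1)."""
        if len(self.wavenumbers) < 2:
            return 0.0
        return float(np.median(np.abs(np.diff(self.wavenumbers))))

    def band_index(self, wavenumber: float, tol: float | None = None) -> int:
        """Index of the band nearest ``wavenumber``.

        ``tol`` defaults to half the median sampling interval, so on a
        4 cm^-1 grid a request for 1552 resolves to the 1550 band.
        """
        if tol is None:
            tol = self.sampling_interval / 2.0
        i = int(np.argmin(np.abs(self.wavenumbers - wavenumber)))
        if abs(self.wavenumbers[i] - wavenumber) > tol + 1e-9:
            raise KeyError(
                f"no band within {tol} cm^-1 of {wavenumber} cm^-1 "
                f"(nearest: {self.wavenumbers[i]})"
            )
        return i

    def band_image(self, wavenumber: float) -> np.ndarray:
        return self.values[:, :, self.band_index(wavenumber)]

    def sorted_ascending(self) -> "SpectralCube":
        if len(self.wavenumbers) and self.wavenumbers[0] > self.wavenumbers[-1]:
            return SpectralCube(
                self.wavenumbers[::-1].copy(),
                self.values[:, :, ::-1].copy(),
                self.pixel_size,
                self.sample_id,
            )
        return self


@dataclass
class PixelMask:
    """Binary on-tissue mask (1 = on-tissue, 0 = off-tissue)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 2:
            raise ConsistencyError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_on(self) -> int:
        return int(self.values.sum())


@dataclass
class LabelMap:
    """Integer tissue-type label image with a legend.

    ``unlabeled_code`` marks pixels without a pathology annotation; every
    other code occurring in ``values`` must appear in ``legend``.
    """

    values: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    unlabeled_code: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(np.int32)
        if self.values.ndim != 2:
            raise ConsistencyError("label map must be 2-D")
        present = set(np.unique(self.values).tolist()) - {self.unlabeled_code}
        missing = present - set(self.legend)
        if missing:
            raise ConsistencyError(f"label codes {sorted(missing)} not in legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def code_for(self, tissue: str) -> int:
        for code, name in self.legend.items():
            if name == tissue:
                return code
        raise KeyError(f"tissue type {tissue!r} not in legend")

    def tissue_pixels(self, tissue: str) -> np.ndarray:
        """Boolean image of pixels labelled as ``tissue``."""
        return self.values == self.code_for(tissue)


# ---------------------------------------------------------------------------
# ENVI-style dialect

_ENVI_DTYPE = np.dtype("<f4")  # little-endian 32-bit float, band sequential


def write_cube(path: str | Path, cube: SpectralCube, dialect: str = "envi") -> None:
    """Write a cube in the given dialect (``envi`` or ``per_band_matrix``)."""
    path = Path(path)
    if dialect == "envi":
        _write_envi(path, cube)
    elif dialect == "per_band_matrix":
        _write_per_band(path, cube)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_cube(path: str | Path, dialect: str = "envi") -> SpectralCube:
    """Read a cube; bands are returned sorted ascending by wavenumber."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "envi":
        cube = _read_envi(path)
    elif dialect == "per_band_matrix":
        cube = _read_per_band(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return cube.sorted_ascending()


def _write_envi(path: Path, cube: SpectralCube) -> None:
    hdr = path.with_suffix(".hdr")
    raw = path.with_suffix(".raw")
    h, w, b = cube.shape
    wl = ", ".join(f"{x:.6g}" for x in cube.wavenumbers)
    hdr.write_text(
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "interleave = bsq\n"
        "data type = 4\n"
        "byte order = 0\n"
        f"pixel size = {cube.pixel_size:.6g}\n"
        f"sample id = {cube.sample_id}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    # BSQ: band-major on disk
    np.ascontiguousarray(cube.values.transpose(2, 0, 1)).astype(_ENVI_DTYPE).tofile(raw)


def _parse_envi_header(hdr: Path) -> dict:
    text = hdr.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise FormatError(f"{hdr}: missing ENVI magic")
    fields: dict[str, str] = {}
    # key = value, with { ... } values possibly spanning lines
    for m in re.finditer(r"^([\w ]+?)[ \t]*=[ \t]*(\{[^}]*\}|[^\n]*)$", text, re.M):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    for key in ("samples", "lines", "bands", "wavelength"):
        if key not in fields:
            raise FormatError(f"{hdr}: missing required key {key!r}")
    out = {
        "samples": int(fields["samples"]),
        "lines": int(fields["lines"]),
        "bands": int(fields["bands"]),
        "pixel size": float(fields.get("pixel size", 25.0)),
        "sample id": fields.get("sample id", ""),
    }
    wl = fields["wavelength"].strip("{} \n")
    out["wavelength"] = [float(x) for x in re.split(r"[,\s]+", wl) if x]
    return out


def _read_envi(path: Path) -> SpectralCube:
    hdr = path.with_suffix(".hdr")
    raw = path.with_suffix(".raw")
    if not hdr.exists():
        raise FormatError(f"header {hdr} not found")
    meta = _parse_envi_header(hdr)
    h, w, b = meta["lines"], meta["samples"], meta["bands"]
    if len(meta["wavelength"]) != b:
        raise ConsistencyError(
            f"{hdr}: header declares {b} bands but lists "
            f"{len(meta['wavelength'])} wavelengths"
        )
    data = np.fromfile(raw, dtype=_ENVI_DTYPE)
    if data.size != h * w * b:
        raise ConsistencyError(
            f"{raw}: expected {h * w * b} values for {b} declared bands, "
            f"found {data.size}"
        )
    values = data.reshape(b, h, w).transpose(1, 2, 0)
    return SpectralCube(
        np.array(meta["wavelength"]), values, meta["pixel size"], meta["sample id"]
    )


# ---------------------------------------------------------------------------
# per-band matrix dialect

def _write_per_band(path: Path, cube: SpectralCube) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for i, wn in enumerate(cube.wavenumbers):
        # %.17g preserves float64 bit-exactly through the text round trip
        np.savetxt(path / f"{wn:g}.txt", cube.values[:, :, i], fmt="%.17g")
    (path / "meta.json").write_text(
        json.dumps({"pixel_size": cube.pixel_size, "sample_id": cube.sample_id})
    )


def _read_per_band(path: Path) -> SpectralCube:
    if not path.is_dir():
        raise FormatError(f"{path}: per_band_matrix dialect expects a directory")
    files = sorted(path.glob("*.txt"), key=lambda p: float(p.stem))
    if not files:
        raise FormatError(f"{path}: no <wavenumber>.txt band files found")
    wns, planes = [], []
    for f in files:
        try:
            wns.append(float(f.stem))
        except ValueError as e:
            raise FormatError(f"{f.name}: filename is not a wavenumber") from e
        planes.append(np.loadtxt(f, ndmin=2))
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise ConsistencyError(f"{path}: band matrices differ in shape: {shapes}")
    pixel_size, sample_id = 25.0, path.name
    meta = path / "meta.json"
    if meta.exists():
        m = json.loads(meta.read_text())
        pixel_size = float(m.get("pixel_size", pixel_size))
        sample_id = m.get("sample_id", sample_id)
    return SpectralCube(np.array(wns), np.stack(planes, axis=-1), pixel_size, sample_id)


# ---------------------------------------------------------------------------
# masks and label maps (8-bit PNG / TIFF)

def write_mask(path: str | Path, mask: PixelMask) -> None:
    Image.fromarray(mask.values.astype(np.uint8)).save(Path(path))


def read_mask(path: str | Path) -> PixelMask:
    arr = np.asarray(Image.open(Path(path)))
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be single-channel")
    return PixelMask(arr > 0)


def write_labels(path: str | Path, labels: LabelMap) -> None:
    path = Path(path)
    if labels.values.min() < 0 or labels.values.max() > 255:
        raise ConsistencyError("label codes must fit 8-bit for PNG/TIFF output")
    Image.fromarray(labels.values.astype(np.uint8)).save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "legend": {str(k): v for k, v in labels.legend.items()},
                "unlabeled_code": labels.unlabeled_code,
            }
        )
    )


def read_labels(path: str | Path) -> LabelMap:
    path = Path(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: label map must be single-channel")
    sidecar = path.with_suffix(path.suffix + ".json")
    legend, unlabeled = {}, 0
    if sidecar.exists():
        m = json.loads(sidecar.read_text())
        legend = {int(k): v for k, v in m.get("legend", {}).items()}
        unlabeled = int(m.get("unlabeled_code", 0))
    else:
        legend = {
            int(c): f"class_{int(c)}" for c in np.unique(arr) if int(c) != unlabeled
        }
    return LabelMap(arr.astype(np.int32), legend, unlabeled)
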