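"""Spectral preprocessing and k-means tissue masking.

The preprocessing chain is the usual one for transmittance-mode
vibrational imaging: optional background normalization (division by a
reference spectrum), a smoothing-polynomial second derivative along the
spectral axis, then standard normal variate (SNV) scaling per pixel.
Second-derivative data are reported unit-less.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import savgol_filter
from sklearn.cluster import KMeans

from .io import PixelMask, SpectralCube

logger = logging.getLogger(__name__)

DEFAULT_MASK_BAND = 1552.0  # cm^-1, raw-intensity band used for k=2 masking


class DegenerateClusteringError(ValueError):
    """The single-band image carries no intensity contrast to cluster."""


def preprocess(
    cube: SpectralCube,
    deriv_window: int = 9,
    deriv_polyorder: int = 3,
    background: np.ndarray | None = None,
    mask: PixelMask | None = None,
) -> tuple[SpectralCube, PixelMask]:
    """Background-normalize, differentiate twice, and SNV-scale a cube.

    Parameters
    ----------
    cube : SpectralCube
        Raw transmittance cube.
    deriv_window, deriv_polyorder : int
        Savitzky-Golay window length (odd) and polynomial order for the
        smoothed second derivative; ``deriv_window >= deriv_polyorder + 2``.
    background : ndarray of shape (bands,), optional
        Reference spectrum to divide out. When omitted the step is
        skipped with a logged notice.
    mask : PixelMask, optional
        On-tissue mask; defaults to all-on.

    Returns
    -------
    cube : SpectralCube
        Unit-less preprocessed cube; every valid pixel's spectrum has
        mean 0 and standard deviation 1.
    valid : PixelMask
        Input mask minus pixels with zero spectral variance after the
        derivative (e.g. spectrally constant pixels), which cannot be
        SNV-scaled and are set to 0.
    """
    if deriv_window % 2 == 0:
        raise ValueError("deriv_window must be odd")
    if deriv_window < deriv_polyorder + 2:
        raise ValueError("deriv_window must be >= deriv_polyorder + 2")
    h, w, b = cube.shape
    if b < deriv_window:
        raise ValueError(f"cube has {b} bands, fewer than deriv_window={deriv_window}")

    values = cube.values.astype(np.float64)
    if background is not None:
        background = np.asarray(background, dtype=float)
        if background.shape != (b,):
            raise ValueError("background spectrum length must equal band count")
        if np.any(background == 0):
            raise ValueError("background spectrum contains zeros")
        values = values / background
    else:
        logger.info("no background spectrum supplied; skipping normalization")

    delta = cube.sampling_interval or 1.0
    deriv = savgol_filter(
        values, deriv_window, deriv_polyorder, deriv=2, delta=delta, axis=2
    )

    mu = deriv.mean(axis=2, keepdims=True)
    sd = deriv.std(axis=2, keepdims=True)
    # zero spectral variance up to float rounding (e.g. constant or pure
    # polynomial spectra): relative to the pixel's derivative scale
    scale = np.abs(deriv).max(axis=2)
    flat = sd[:, :, 0] <= 1e-8 * np.maximum(scale, 1.0)
    if mask is None:
        mask = PixelMask(np.ones((h, w), bool))
    valid = PixelMask(mask.values & ~flat)
    n_flagged = int((flat & mask.values).sum())
    if n_flagged:
        logger.warning(
            "%d pixel(s) with zero spectral variance masked off before SNV",
            n_flagged,
        )
    sd = np.where(flat[:, :, None], 1.0, sd)
    out = (deriv - mu) / sd
    out[~valid.values] = 0.0
    return (
        SpectralCube(cube.wavenumbers.copy(), out, cube.pixel_size, cube.sample_id),
        valid,
    )


def make_tissue_mask(
    cube: SpectralCube,
    mask_band: float = DEFAULT_MASK_BAND,
    seed: int = 0,
    polarity: str = "low",
) -> PixelMask:
    """Two-means tissue/background segmentation of a single raw band.

    The band image (default 1552 cm^-1, nearest grid band) is split into
    two intensity clusters with k-means (k=2). ``polarity`` picks which
    cluster is tissue: ``"low"`` (default) marks the lower-transmittance
    cluster, i.e. higher absorbance, as on-tissue; ``"high"`` the
    opposite.
    """
    if polarity not in ("low", "high"):
        raise ValueError("polarity must be 'low' or 'high'")
    band = cube.band_image(mask_band).astype(np.float64)
    if np.ptp(band) == 0:
        raise DegenerateClusteringError(
            f"band {mask_band} cm^-1 is constant; cannot separate tissue"
        )
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    lab = km.fit_predict(band.reshape(-1, 1)).reshape(band.shape)
    means = km.cluster_centers_.ravel()
    tissue_cluster = int(np.argmin(means)) if polarity == "low" else int(np.argmax(means))
    return PixelMask(lab == tissue_cluster)
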