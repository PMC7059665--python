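"""Plant segmentation and pixel-spectra preprocessing.

The analysis chain for one reflectance cube is fixed:

    segment -> extract pixel spectra -> crop to 434-953 nm
            -> wavelet denoise (db9, level 3) -> moving average (7 points)
            -> mean spectrum per sample

Denoising keeps only the level-3 Daubechies-9 approximation (all detail
coefficients zeroed) — the parameter-free reading of "wavelet transform at
level 3" — followed by a centered 7-point moving average whose window
shrinks symmetrically at the band-range edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from skimage import measure

from .hypercube import GeometryError, HyperCube

__all__ = [
    "PixelSpectra", "SegmentationError",
    "segment_plant", "extract_pixel_spectra", "crop_bands",
    "wavelet_denoise", "moving_average", "mean_spectrum",
    "preprocess_pixel_spectra",
]

BAND_LO_NM = 434.0
BAND_HI_NM = 953.0
WAVELET = "db9"
WAVELET_LEVEL = 3
MA_WINDOW = 7


class SegmentationError(RuntimeError):
    pass


@dataclass
class PixelSpectra:
    """Per-pixel spectra of one sample's region of interest.

    ``spectra`` is (n_pixels, n_bands); ``coords`` the matching (row, col)
    pixel coordinates in row-major scan order.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    coords: np.ndarray
    sample_id: str | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.spectra.ndim != 2:
            raise GeometryError("spectra must be 2-D (pixels x bands)")
        if self.spectra.shape[1] != len(self.wavelengths):
            raise GeometryError(
                f"{self.spectra.shape[1]} bands vs {len(self.wavelengths)} wavelengths")
        if self.coords.shape != (self.spectra.shape[0], 2):
            raise GeometryError("coords must be (n_pixels, 2)")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("pixel coordinates must be unique")

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]


def segment_plant(cube: HyperCube, threshold: float = 0.4,
                  min_size: int = 20) -> np.ndarray:
    """Vegetation mask from the normalized difference (R800-R680)/(R800+R680).

    Pixels above ``threshold`` are kept; connected components smaller than
    ``min_size`` pixels are removed.  Raises :class:`SegmentationError` if
    nothing survives.
    """
    r680 = cube.data[:, :, cube.band_index(680.0)].astype(float)
    r800 = cube.data[:, :, cube.band_index(800.0)].astype(float)
    denom = r800 + r680
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.where(np.abs(denom) > 0, (r800 - r680) / denom, 0.0)
    mask = index > threshold
    labeled = measure.label(mask, connectivity=2)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0  # background
    mask = np.isin(labeled, np.nonzero(sizes >= min_size)[0])
    if not mask.any():
        raise SegmentationError(
            f"no vegetation pixels: normalized-difference index never exceeded "
            f"threshold {threshold} (after removing components < {min_size} px)")
    return mask


def extract_pixel_spectra(cube: HyperCube, mask: np.ndarray,
                          sample_id: str | None = None,
                          label: int | None = None) -> PixelSpectra:
    """One spectrum per masked pixel, rows in row-major scan order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise GeometryError(
            f"mask shape {mask.shape} does not match cube spatial shape "
            f"{cube.shape[:2]}")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    coords = np.argwhere(mask)  # row-major sorted
    return PixelSpectra(cube.data[mask].astype(float), cube.wavelengths.copy(),
                        coords, sample_id=sample_id, label=label)


def crop_bands(px: PixelSpectra, lo_nm: float = BAND_LO_NM,
               hi_nm: float = BAND_HI_NM) -> PixelSpectra:
    """Restrict to the band window covering [lo_nm, hi_nm].

    The retained window runs from the last band at or below ``lo_nm``
    through the first band at or above ``hi_nm``, so the requested range is
    fully covered; on the 512-band 380-1030 nm axis the 434-953 nm default
    yields exactly 410 bands.  Idempotent for fixed limits.
    """
    if lo_nm > hi_nm:
        raise ValueError(f"lo_nm={lo_nm} exceeds hi_nm={hi_nm}")
    wl = px.wavelengths
    if hi_nm < wl[0] or lo_nm > wl[-1]:
        raise ValueError(
            f"band range [{lo_nm}, {hi_nm}] nm does not intersect the axis "
            f"[{wl[0]:.1f}, {wl[-1]:.1f}] nm")
    at_or_below = np.nonzero(wl <= lo_nm)[0]
    i0 = int(at_or_below[-1]) if at_or_below.size else 0
    at_or_above = np.nonzero(wl >= hi_nm)[0]
    i1 = int(at_or_above[0]) if at_or_above.size else len(wl) - 1
    return replace(px, spectra=px.spectra[:, i0:i1 + 1],
                   wavelengths=wl[i0:i1 + 1])


def wavelet_denoise(spectrum: np.ndarray, wavelet: str = WAVELET,
                    level: int = WAVELET_LEVEL) -> np.ndarray:
    """Low-pass reconstruction: zero all detail coefficients at ``level``.

    Works along the last axis of a 1-D or 2-D array; symmetric boundary
    extension; output has the input's length.
    """
    x = np.asarray(spectrum, dtype=float)
    n = x.shape[-1]
    w = pywt.Wavelet(wavelet)
    if pywt.dwt_max_level(n, w.dec_len) < level:
        raise ValueError(
            f"input of length {n} is too short for a level-{level} {wavelet} "
            f"decomposition (needs >= {(w.dec_len - 1) * 2**level})")
    coeffs = pywt.wavedec(x, w, mode="symmetric", level=level, axis=-1)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, w, mode="symmetric", axis=-1)
    return rec[..., :n]


def moving_average(spectrum: np.ndarray, window: int = MA_WINDOW) -> np.ndarray:
    """Centered moving average along the last axis.

    ``window`` must be odd; at the edges the window shrinks symmetrically
    so the output is unbiased for locally symmetric signals and has the
    input's length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(spectrum, dtype=float)
    if window == 1:
        return x.copy()
    n = x.shape[-1]
    half = window // 2
    csum = np.cumsum(x, axis=-1)
    out = np.empty_like(x)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        lo, hi = i - h, i + h  # inclusive
        total = csum[..., hi] - (csum[..., lo - 1] if lo > 0 else 0.0)
        out[..., i] = total / (2 * h + 1)
    return out


def mean_spectrum(px: PixelSpectra) -> np.ndarray:
    """Band-wise arithmetic mean over the sample's pixels."""
    if px.n_pixels < 1:
        raise ValueError("no pixels")
    return px.spectra.mean(axis=0)


def preprocess_pixel_spectra(px: PixelSpectra, lo_nm: float = BAND_LO_NM,
                             hi_nm: float = BAND_HI_NM, wavelet: str = WAVELET,
                             level: int = WAVELET_LEVEL,
                             window: int = MA_WINDOW) -> PixelSpectra:
    """Crop to the analyzed range, denoise and smooth every pixel spectrum."""
    cropped = crop_bands(px, lo_nm, hi_nm)
    smoothed = moving_average(wavelet_denoise(cropped.spectra, wavelet, level),
                              window)
    return replace(cropped, spectra=smoothed)
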