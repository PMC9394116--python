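"""Image-to-curve preprocessing chain.

From a raw hyperspectral cube to a modelling-ready curve the steps are:

1. black-white reflectance calibration,
   I = (I_raw - I_black) / (I_white - I_black);
2. per-pixel wavelet denoising of each spectrum (Daubechies-8, 3
   decomposition levels, soft universal threshold by default);
3. averaging the pixel spectra inside a leaf or stem region-of-interest
   mask into one curve per organ;
4. truncating the reflectance curve to the low-noise 454-957 nm window
   (396 bands on the emulated instrument's grid);
5. maximum normalization (divide by the curve maximum).

Fluorescence kinetic curves go through steps 3 and 5 only: wavelet
denoising is applied to reflectance spectra, kinetic curves are only
ROI-averaged and maximum-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt


class DegenerateReferenceError(ValueError):
    """White and black references coincide somewhere they are used."""


class DegenerateCurveError(ValueError):
    """A curve whose maximum is not positive cannot be max-normalized."""


@dataclass(frozen=True)
class CalibrationSet:
    """Raw image plus black/white reference images (broadcastable shapes)."""

    raw: np.ndarray
    black: np.ndarray
    white: np.ndarray


@dataclass(frozen=True)
class ROISet:
    """A calibrated cube (rows x cols x channels) with leaf/stem masks."""

    cube: np.ndarray
    leaf_mask: np.ndarray
    stem_mask: np.ndarray

    def __post_init__(self):
        if self.cube.ndim != 3:
            raise ValueError("cube must be rows x cols x channels")
        for name, mask in (("leaf_mask", self.leaf_mask), ("stem_mask", self.stem_mask)):
            if mask.shape != self.cube.shape[:2]:
                raise ValueError(f"{name} shape {mask.shape} != cube spatial shape {self.cube.shape[:2]}")


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet denoising settings.

    Defaults follow the common chemometrics choice for spectra of a few
    hundred points: Daubechies-8 family, 3 decomposition levels, soft
    universal threshold with the noise level estimated from the
    median absolute deviation of the finest detail coefficients.
    """

    family: str = "db8"
    levels: int = 3
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError("threshold_mode must be 'soft' or 'hard'")
        if self.threshold_rule != "universal":
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")


@dataclass(frozen=True)
class BandWindow:
    """Wavelength axis plus a closed retention interval [low, high] in nm."""

    wavelengths: np.ndarray
    low: float = 454.0
    high: float = 957.0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelengths must be a 1-D vector")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not self.low < self.high:
            raise ValueError("low must be < high")
        object.__setattr__(self, "wavelengths", wl)


def calibrate(cs: CalibrationSet) -> np.ndarray:
    """Black-white reflectance calibration: (raw - black) / (white - black)."""
    raw = np.asarray(cs.raw, dtype=float)
    black = np.asarray(cs.black, dtype=float)
    white = np.asarray(cs.white, dtype=float)
    denom = white - black
    if np.any(denom <= 0):
        raise DegenerateReferenceError("white - black must be strictly positive")
    out = (raw - black) / denom
    return np.broadcast_to(out, raw.shape).copy() if out.shape != raw.shape else out


def _mad_sigma(detail: np.ndarray) -> float:
    # Robust noise-level estimate from the finest detail coefficients.
    return float(np.median(np.abs(detail)) / 0.6745)


def denoise_curve(signal: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> np.ndarray:
    """Wavelet-denoise one curve; output has the input's length.

    Multilevel DWT with symmetric boundary extension, thresholding of all
    detail coefficients at the universal level sigma * sqrt(2 ln n) with
    sigma estimated by the MAD of the finest-level details, then inverse
    transform (trimmed back to the original length).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a nonempty 1-D vector")
    n = x.size
    coeffs = pywt.wavedec(x, spec.family, mode="symmetric", level=spec.levels)
    sigma = _mad_sigma(coeffs[-1])
    thr = sigma * np.sqrt(2.0 * np.log(n))
    coeffs = [coeffs[0]] + [
        pywt.threshold(c, thr, mode=spec.threshold_mode) for c in coeffs[1:]
    ]
    rec = pywt.waverec(coeffs, spec.family, mode="symmetric")
    return rec[:n]


def roi_mean_curve(
    rs: ROISet, which: str, spec: WaveletSpec | None = None,
    pixelwise: bool = True,
) -> np.ndarray:
    """Average the per-pixel curves inside a leaf or stem ROI mask.

    When a :class:`WaveletSpec` is given, each pixel curve is denoised
    before averaging (denoise-then-average).  With thresholding this is
    not equivalent to denoising the mean; ``pixelwise=False`` selects the
    cheaper average-then-denoise path (one transform instead of one per
    pixel), off by default.
    """
    if which not in ("leaf", "stem"):
        raise ValueError("which must be 'leaf' or 'stem'")
    mask = rs.leaf_mask if which == "leaf" else rs.stem_mask
    mask = np.asarray(mask, dtype=bool)
    pixels = np.asarray(rs.cube, dtype=float)[mask]  # (n_pixels, channels)
    if pixels.shape[0] == 0:
        raise ValueError(f"{which} mask selects no pixels")
    if spec is not None and pixelwise:
        pixels = np.stack([denoise_curve(p, spec) for p in pixels])
    mean = pixels.mean(axis=0)
    if spec is not None and not pixelwise:
        mean = denoise_curve(mean, spec)
    return mean


def truncate_bands(curve: np.ndarray, win: BandWindow) -> np.ndarray:
    """Keep the entries whose wavelength lies in the closed window."""
    x = np.asarray(curve, dtype=float)
    if x.shape != win.wavelengths.shape:
        raise ValueError(
            f"curve length {x.size} != wavelengths length {win.wavelengths.size}"
        )
    keep = (win.wavelengths >= win.low) & (win.wavelengths <= win.high)
    if not keep.any():
        raise ValueError("no wavelength falls inside the window")
    return x[keep]


def max_normalize(curve: np.ndarray) -> np.ndarray:
    """Divide by the curve maximum; the output's maximum is exactly 1."""
    x = np.asarray(curve, dtype=float)
    m = x.max() if x.size else 0.0
    if not m > 0:
        raise DegenerateCurveError("curve maximum must be positive")
    return x / m
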