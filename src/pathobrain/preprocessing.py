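"""Image loading, grayscale conversion and Wiener denoising.

The unit of data flowing through this stage is a 2D float64 array of
intensities in [0, 1] ("Image2D").  Raw rasters (GIF/JPG/PNG, 8- or
16-bit, single- or 3-channel) are normalised by their type maximum and
collapsed to luminance; denoising uses the adaptive local-statistics
Wiener filter by default, with a Fourier-domain Wiener deconvolution
mode available when a blur transfer function is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

#: ITU-R BT.601 luminance weights for RGB -> gray.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

STANDARD_SHAPE = (256, 256)


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check Image2D invariants: 2D, finite, within [0,1], sides >= 8."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={img.ndim}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"image too small: {img.shape} (sides must be >= 8)")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return img


def to_grayscale(raw: np.ndarray) -> np.ndarray:
    """Convert a raw raster to a double-precision grayscale image in [0,1].

    Accepts a 2D array or an (H, W, 3) RGB array.  Integer dtypes are
    scaled by their type maximum (255 for uint8, 65535 for uint16);
    floating inputs must already lie in [0, 1].  RGB channels are
    combined with BT.601 luminance weights (0.299, 0.587, 0.114).
    """
    raw = np.asarray(raw)
    if raw.ndim == 3:
        if raw.shape[2] != 3:
            raise ValueError(
                f"unsupported channel count {raw.shape[2]}; expected 1 or 3"
            )
    elif raw.ndim != 2:
        raise ValueError(f"unsupported image rank {raw.ndim}")

    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype if raw.dtype.kind == "u" else np.uint8)
        scale = float(info.max)
        pix = raw.astype(np.float64) / scale
    else:
        pix = raw.astype(np.float64)

    if raw.ndim == 3:
        pix = pix @ LUMA_WEIGHTS
    return validate_image(np.clip(pix, 0.0, 1.0))


@dataclass
class WienerSpec:
    """Configuration of the Wiener denoising stage.

    mode 'adaptive_local' estimates per-pixel local mean/variance over a
    sliding window and shrinks toward the local mean where the local
    variance approaches the estimated noise power.  mode
    'frequency_domain' applies the classical Fourier Wiener
    deconvolution W = H* Sxx / (|H|^2 Sxx + Snn), where H is the blur
    transfer function and Sxx/Snn are signal/noise power spectra (pass
    the string "estimate" to estimate them from the image).
    """

    mode: str = "adaptive_local"
    window: int = 3
    H: Union[np.ndarray, None] = None
    snn: Union[np.ndarray, float, str] = "estimate"
    sxx: Union[np.ndarray, float, str] = "estimate"

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive_local", "frequency_domain"):
            raise ValueError(f"unknown Wiener mode {self.mode!r}")
        if self.mode == "adaptive_local":
            if self.window % 2 == 0 or self.window < 3:
                raise ValueError("Wiener window must be an odd integer >= 3")
        for name, s in (("snn", self.snn), ("sxx", self.sxx)):
            if isinstance(s, str):
                if s != "estimate":
                    raise ValueError(f"{name} must be a spectrum or 'estimate'")
            elif np.any(np.asarray(s) < 0):
                raise ValueError(f"{name} must be nonnegative")


def _local_stats(img: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    # reflect padding at the boundary via ndimage's mode='reflect'
    m = ndimage.uniform_filter(img, size=window, mode="reflect")
    msq = ndimage.uniform_filter(img * img, size=window, mode="reflect")
    s2 = np.maximum(msq - m * m, 0.0)
    return m, s2


def estimate_noise_power(img: np.ndarray, window: int = 3) -> float:
    """Noise power estimate: the mean of all local window variances."""
    _, s2 = _local_stats(np.asarray(img, dtype=np.float64), window)
    return float(s2.mean())


def wiener_filter(img: np.ndarray, spec: WienerSpec | None = None) -> np.ndarray:
    """Denoise an Image2D with the configured Wiener filter.

    Adaptive mode output per pixel:
        m + max(0, s^2 - sigma^2) / max(s^2, sigma^2) * (x - m)
    with m, s^2 the local window mean/variance and sigma^2 the mean of
    all local variances (the estimated noise power).  Frequency mode
    returns the real part of the inverse FFT of W(f) X(f).  Output is
    clipped to [0, 1] in both modes.
    """
    img = validate_image(img)
    spec = spec or WienerSpec()

    if spec.mode == "adaptive_local":
        m, s2 = _local_stats(img, spec.window)
        sigma2 = s2.mean()
        if sigma2 == 0.0:
            return img.copy()
        gain = np.maximum(s2 - sigma2, 0.0) / np.maximum(s2, sigma2)
        out = m + gain * (img - m)
        return np.clip(out, 0.0, 1.0)

    # frequency_domain
    H = np.ones(img.shape, dtype=complex) if spec.H is None else np.asarray(spec.H, dtype=complex)
    if H.shape != img.shape:
        raise ValueError(f"H shape {H.shape} does not match image shape {img.shape}")
    if not np.any(H):
        raise ValueError("transfer function H is identically zero")

    X = np.fft.fft2(img)
    npix = img.size
    if isinstance(spec.snn, str):
        snn = estimate_noise_power(img) * np.ones(img.shape)
    else:
        snn = np.broadcast_to(np.asarray(spec.snn, dtype=np.float64), img.shape)
    if isinstance(spec.sxx, str):
        # periodogram of the observation minus the noise floor
        sxx = np.maximum(np.abs(X) ** 2 / npix - snn, 0.0)
    else:
        sxx = np.broadcast_to(np.asarray(spec.sxx, dtype=np.float64), img.shape)

    num = np.conj(H) * sxx
    den = (np.abs(H) ** 2) * sxx + snn
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out = np.real(np.fft.ifft2(W * X))
    return np.clip(out, 0.0, 1.0)


def load_image(
    path: Union[str, Path],
    resize: bool = False,
    denoise: bool = False,
    spec: WienerSpec | None = None,
) -> np.ndarray:
    """Read a GIF/JPG/PNG slice and return a preprocessed Image2D.

    Non-256x256 images are rejected unless ``resize=True``, in which
    case they are bilinearly resampled to 256x256.
    """
    raw = iio.imread(Path(path))
    img = to_grayscale(raw)
    if img.shape != STANDARD_SHAPE:
        if not resize:
            raise ValueError(
                f"{path}: image is {img.shape}, expected {STANDARD_SHAPE} "
                "(pass resize=True to resample)"
            )
        zoom = (STANDARD_SHAPE[0] / img.shape[0], STANDARD_SHAPE[1] / img.shape[1])
        img = np.clip(ndimage.zoom(img, zoom, order=1), 0.0, 1.0)
    if denoise:
        img = wiener_filter(img, spec)
    return img
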