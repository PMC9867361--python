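"""Radiograph enhancement chain applied before texture extraction.

The chain mirrors a manual enhancement workflow on lateral neck X-rays:
window (brightness/contrast) adjustment, optional rectangular ROI crop,
repeated 3x3 mean smoothing, unsharp sharpening, Sobel edge detection,
a re-window to the 0-108 gray band, an FFT band-pass with optional
scan-line stripe suppression, a final window, and standardisation to a
256x256 8-bit raster.  All 3x3 kernels use edge replication so borders
do not darken and bias downstream co-occurrence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize


@dataclass
class GrayImage:
    """2-D 8-bit grayscale raster with calibration and provenance."""

    pixels: np.ndarray
    pixel_size: float = 0.175                 # mm per pixel
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("image must be 2-D, at least 2x2")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self):
        return self.pixels.shape

    def with_pixels(self, px: np.ndarray, step: str) -> "GrayImage":
        return GrayImage(px, self.pixel_size, self.provenance + [step])


@dataclass
class PreprocessConfig:
    window: tuple = (0, 108)          # gray band stretched to full range
    smooth_iterations: int = 3
    bandpass_large: float = 40.0      # structures larger than this (px) removed
    bandpass_small: float = 3.0       # structures smaller than this (px) removed
    stripe_suppression: str = "none"  # none | horizontal | vertical
    stripe_tolerance: float = 5.0     # wedge half-width, percent
    output_size: tuple = (256, 256)
    roi: tuple | None = None          # optional (row0, row1, col0, col1)

    def __post_init__(self):
        lo, hi = self.window
        if lo >= hi:
            raise ValueError("window low must be < high")
        if self.bandpass_small >= self.bandpass_large:
            raise ValueError("bandpass_small must be < bandpass_large")
        if not 0 <= self.stripe_tolerance <= 100:
            raise ValueError("stripe tolerance must be in [0, 100]")


def _to_u8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def adjust_window(img: GrayImage, low: float, high: float) -> GrayImage:
    """Linearly map the gray band [low, high] onto [0, 255], clipping outside."""
    if low >= high:
        raise ValueError("degenerate window: low must be < high")
    px = img.pixels.astype(float)
    out = (px - low) * 255.0 / (high - low)
    return img.with_pixels(_to_u8(out), f"window({low},{high})")


def smooth(img: GrayImage, iterations: int) -> GrayImage:
    """Repeated 3x3 mean filter with edge replication; 0 iterations = identity."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    px = img.pixels.astype(float)
    for _ in range(iterations):
        px = ndimage.uniform_filter(px, size=3, mode="nearest")
    return img.with_pixels(_to_u8(px), f"smooth(x{iterations})")


_SHARPEN = np.array([[0, -1, 0], [-1, 5, -1], [0, -1, 0]], dtype=float)


def sharpen(img: GrayImage) -> GrayImage:
    """Unsharp-style 3x3 Laplacian sharpening with edge replication."""
    px = ndimage.convolve(img.pixels.astype(float), _SHARPEN, mode="nearest")
    return img.with_pixels(_to_u8(px), "sharpen")


def detect_edges(img: GrayImage) -> GrayImage:
    """Sobel gradient magnitude, min-max rescaled to the 8-bit range."""
    if min(img.shape) < 3:
        raise ValueError("edge detection requires at least a 3x3 image")
    px = img.pixels.astype(float)
    gx = ndimage.sobel(px, axis=1, mode="nearest")
    gy = ndimage.sobel(px, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    if mag.max() > 0:
        mag = mag * (255.0 / mag.max())
    return img.with_pixels(_to_u8(mag), "edges")


def _bandpass_transfer(shape, large_px: float, small_px: float) -> np.ndarray:
    """Difference-of-Gaussians transfer function on the centred FFT grid.

    A structure of characteristic size s pixels concentrates near
    frequency f = 1/(2 s) cycles/pixel; the Gaussian cut sigmas follow
    sigma_f = 1/(2 s) for the two declared sizes.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    r2 = fy * fy + fx * fx
    s_lo = 1.0 / (2.0 * large_px)   # frequencies below: too-large structures
    s_hi = 1.0 / (2.0 * small_px)   # frequencies above: too-small specks
    keep_high = 1.0 - np.exp(-r2 / (2.0 * s_lo**2))
    keep_low = np.exp(-r2 / (2.0 * s_hi**2))
    return keep_high * keep_low


def _stripe_mask(shape, direction: str, tolerance_pct: float) -> np.ndarray:
    """Zero a wedge around the frequency axis carrying periodic scan stripes.

    Horizontal stripes (intensity varying with the row index) live on the
    vertical frequency axis; the wedge half-angle is tolerance% of 90 deg.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    ang = np.arctan2(np.abs(fy), np.abs(fx))   # 0 = fx axis, pi/2 = fy axis
    half = np.deg2rad(90.0 * tolerance_pct / 100.0)
    if direction == "horizontal":
        wedge = ang > (np.pi / 2 - half)
    elif direction == "vertical":
        wedge = ang < half
    else:
        raise ValueError(f"unknown stripe direction: {direction}")
    mask = np.ones(shape)
    mask[wedge] = 0.0
    mask[0, 0] = 1.0   # never remove the DC term
    return mask


def fft_bandpass_response(pixels: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Linear band-pass stage (float in, float out, no rescale).

    Exposed separately so the linearity of the frequency-domain filter
    can be exercised without the final 8-bit normalisation.
    """
    px = np.asarray(pixels, dtype=float)
    spec = np.fft.fft2(px)
    h = _bandpass_transfer(px.shape, config.bandpass_large, config.bandpass_small)
    if config.stripe_suppression != "none":
        h = h * _stripe_mask(px.shape, config.stripe_suppression,
                             config.stripe_tolerance)
    h[0, 0] = 1.0   # preserve the mean
    return np.real(np.fft.ifft2(spec * h))


def fft_bandpass(img: GrayImage, config: PreprocessConfig) -> GrayImage:
    """Frequency-domain Gaussian band-pass with optional stripe suppression.

    Structures larger than ``bandpass_large`` px and smaller than
    ``bandpass_small`` px are attenuated; the output mean equals the
    input mean, then the result is min-max rescaled to 8 bits.
    """
    if min(img.shape) < 2 * config.bandpass_small:
        raise ValueError("image too small for the requested band-pass")
    out = fft_bandpass_response(img.pixels, config)
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return img.with_pixels(_to_u8(out), "fft_bandpass")
    out = (out - lo) * 255.0 / (hi - lo)
    return img.with_pixels(_to_u8(out), "fft_bandpass")


def standardize(img: GrayImage, output_size=(256, 256)) -> GrayImage:
    """Bilinear resample to the target raster and 8-bit grayscale."""
    scale = img.shape[0] / output_size[0]
    out = _sk_resize(img.pixels.astype(float), output_size, order=1,
                     mode="edge", anti_aliasing=False)
    res = GrayImage(_to_u8(out), img.pixel_size * scale,
                    img.provenance + [f"standardize{tuple(output_size)}"])
    return res


def crop_roi(img: GrayImage, roi: tuple) -> GrayImage:
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
        raise ValueError(f"ROI {roi} outside image {img.shape}")
    return img.with_pixels(img.pixels[r0:r1, c0:c1], f"roi{roi}")


def preprocess_pipeline(img: GrayImage, config: PreprocessConfig | None = None) -> GrayImage:
    """Full nine-step enhancement chain, in order.

    window -> (optional ROI crop) -> smooth -> sharpen -> edges ->
    window(0,108) -> band-pass -> window -> standardize.  The provenance
    list of the returned image records each applied step.
    """
    if config is None:
        config = PreprocessConfig()
    out = adjust_window(img, 0, 255)            # initial brightness/contrast pass
    out = crop_roi(out, config.roi) if config.roi else out.with_pixels(out.pixels, "roi(full)")
    out = smooth(out, config.smooth_iterations)
    out = sharpen(out)
    out = detect_edges(out)
    out = adjust_window(out, *config.window)
    out = fft_bandpass(out, config)
    out = adjust_window(out, 0, 255)
    out = standardize(out, config.output_size)
    return out
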