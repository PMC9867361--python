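"""Gray-level co-occurrence matrix and the four texture features.

The co-occurrence matrix V counts how often a pixel with quantised gray
level i sits at a fixed spatial offset from a pixel with level j; P is V
normalised to unit sum.  Four scalars summarise P:

* contrast     sum_ij P(i,j) (i-j)^2
* homogeneity  sum_ij P(i,j) / (1 + (i-j)^2)
* correlation  sum_ij P(i,j) (i-mu_i)(j-mu_j) / sqrt(var_i var_j)
* energy       sqrt(sum_ij P(i,j)^2)

Energy is the square root of the angular second moment (many libraries
call the un-rooted sum "energy"; the rooted form is used throughout).
Correlation is undefined when a marginal variance vanishes (e.g. a
constant image); it is returned as a NaN-flagged value, never raised, so
batch extraction cannot abort.

Gray levels are quantised into uniform bins over the full 8-bit range
[0, 255] regardless of the image content, for determinism across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import GrayImage


@dataclass
class GLCMatrix:
    P: np.ndarray            # N x N normalised co-occurrence probabilities
    V: np.ndarray            # N x N raw pair counts
    levels: int
    offset: tuple            # (dy, dx) in pixels
    symmetric: bool
    mu_i: float
    mu_j: float
    var_i: float
    var_j: float


@dataclass
class TextureFeatures:
    contrast: float
    homogeneity: float
    correlation: float       # NaN when undefined (zero marginal variance)
    energy: float

    @property
    def correlation_defined(self) -> bool:
        return not np.isnan(self.correlation)


@dataclass
class GLCMConfig:
    offsets: tuple = ((0, 1),)   # default: distance 1, direction 0 deg
    levels: int = 8
    symmetric: bool = True


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin 8-bit gray values into ``levels`` classes."""
    px = np.asarray(pixels)
    if px.dtype != np.uint8:
        px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return (px.astype(np.int64) * levels) // 256


def compute_glcm(img: GrayImage | np.ndarray, offset=(0, 1), levels: int = 8,
                 symmetric: bool = True) -> GLCMatrix:
    """Co-occurrence matrix of one offset over all in-bounds pixel pairs."""
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    dy, dx = offset
    if dy == 0 and dx == 0:
        raise ValueError("offset must be nonzero")
    h, w = pixels.shape
    if h <= abs(dy) or w <= abs(dx):
        raise ValueError(f"image {pixels.shape} too small for offset {offset}")
    q = quantize(pixels, levels)

    ys = slice(max(0, -dy), h - max(0, dy))
    xs = slice(max(0, -dx), w - max(0, dx))
    src = q[ys, xs]
    dst = q[max(0, dy):h - max(0, -dy), max(0, dx):w - max(0, -dx)]
    V = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(V, (src.ravel(), dst.ravel()), 1)
    if symmetric:
        V = V + V.T
    P = V.astype(float) / V.sum()

    i = np.arange(levels, dtype=float)
    p_i, p_j = P.sum(axis=1), P.sum(axis=0)
    mu_i, mu_j = float(i @ p_i), float(i @ p_j)
    var_i = float(((i - mu_i) ** 2) @ p_i)
    var_j = float(((i - mu_j) ** 2) @ p_j)
    return GLCMatrix(P, V, levels, (dy, dx), symmetric, mu_i, mu_j, var_i, var_j)


def glcm_features(G: GLCMatrix) -> TextureFeatures:
    """Evaluate the four texture scalars of a normalised GLCM."""
    n = G.levels
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    diff2 = (i - j) ** 2
    contrast = float((G.P * diff2).sum())
    homogeneity = float((G.P / (1.0 + diff2)).sum())
    energy = float(np.sqrt((G.P ** 2).sum()))
    if G.var_i <= 0 or G.var_j <= 0:
        correlation = float("nan")
    else:
        correlation = float(
            (G.P * (i - G.mu_i) * (j - G.mu_j)).sum() / np.sqrt(G.var_i * G.var_j)
        )
    return TextureFeatures(contrast, homogeneity, correlation, energy)


def extract_features(img: GrayImage | np.ndarray,
                     config: GLCMConfig | None = None) -> TextureFeatures:
    """Texture features of a preprocessed image, averaged over offsets.

    With several configured offsets, each feature is the arithmetic mean
    over offsets; correlation averages only the offsets where it is
    defined (NaN if none are).
    """
    if config is None:
        config = GLCMConfig()
    feats = [glcm_features(compute_glcm(img, off, config.levels, config.symmetric))
             for off in config.offsets]
    corr = [f.correlation for f in feats if not np.isnan(f.correlation)]
    return TextureFeatures(
        contrast=float(np.mean([f.contrast for f in feats])),
        homogeneity=float(np.mean([f.homogeneity for f in feats])),
        correlation=float(np.mean(corr)) if corr else float("nan"),
        energy=float(np.mean([f.energy for f in feats])),
    )
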