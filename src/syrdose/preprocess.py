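"""Silhouette extraction: grayscale, Otsu threshold, morphology, smoothing.

The preprocessing chain turns a raw syringe photograph into a clean binary
silhouette on which corner detection can operate:

    to_gray -> otsu_threshold + binarize -> open -> close -> fill holes
            -> Gaussian smoothing -> re-binarize at 0.5

Otsu's threshold maximizes the between-class variance
``sigma_b^2(k) = w0 * w1 * (mu1 - mu0)^2`` over all candidate gray levels
``k``, where class ``C0`` holds levels ``i < k`` (the dark target) and
``C1`` holds ``i >= k`` (the bright background).  Which binary class is the
syringe is decided automatically afterwards: the class touching fewer image
border pixels is taken as the foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    DegenerateImageError,
    EmptyInputError,
    InvalidGaussianError,
    ThresholdRangeError,
    UnsupportedImageError,
)

# Rec.601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Histogram:
    """Gray-level counts and occurrence probabilities P_i = n_i / (N*M)."""

    counts: np.ndarray
    probabilities: np.ndarray

    @property
    def levels(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class OtsuResult:
    """Optimal threshold plus the full class statistics behind it.

    ``threshold`` is the smallest ``k`` maximizing the between-class
    variance; ``curve`` holds sigma_b^2 for every candidate ``k`` so the
    selection can be audited.  The within-class variances are reported but
    play no role in the selection rule.
    """

    threshold: int
    class_weights: tuple[float, float]
    class_means: tuple[float, float]
    class_variances: tuple[float, float]
    between_class_variance: float
    curve: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class GaussianParams:
    """Isotropic Gaussian smoothing parameters (sigma in pixels, odd size)."""

    sigma: float = 1.0
    size: int = 5

    def __post_init__(self):
        if self.sigma <= 0 or self.size < 1 or self.size % 2 == 0:
            raise InvalidGaussianError(
                f"invalid Gaussian parameters: sigma={self.sigma}, size={self.size}"
            )


def to_gray(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Reduce a raster to one intensity channel in ``[0, levels-1]``.

    2-D inputs pass through; 3-channel (or 4-channel, alpha dropped)
    inputs are combined with Rec.601 luminance weights and rounded.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise EmptyInputError("empty input")
    if image.ndim == 2:
        gray = image.astype(np.float64)
    elif image.ndim == 3 and image.shape[2] in (3, 4):
        gray = np.round(image[..., :3].astype(np.float64) @ _LUMA)
    elif image.ndim == 3 and image.shape[2] == 1:
        gray = image[..., 0].astype(np.float64)
    else:
        raise UnsupportedImageError(f"unsupported image shape {image.shape}")
    return np.clip(gray, 0, levels - 1).astype(np.uint8)


def histogram(img: np.ndarray, levels: int = 256) -> Histogram:
    """Per-level pixel counts and probabilities; probabilities sum to 1."""
    img = np.asarray(img)
    counts = np.bincount(img.ravel().astype(np.int64), minlength=levels)
    return Histogram(counts=counts, probabilities=counts / img.size)


def otsu_threshold(hist: Histogram) -> OtsuResult:
    """Maximum between-class-variance threshold over all gray levels.

    Scans every candidate ``k`` in ``[0, L-1]`` with class split
    ``C0 = {i < k}``, ``C1 = {i >= k}`` and returns the smallest ``k``
    attaining the maximal ``w0*w1*(mu1-mu0)^2``.  Raises
    :class:`DegenerateImageError` when fewer than two levels carry mass.
    """
    p = np.asarray(hist.probabilities, dtype=np.float64)
    L = p.size
    if np.count_nonzero(p) < 2:
        raise DegenerateImageError("degenerate image: single gray level")
    i = np.arange(L, dtype=np.float64)
    # w0[k] = sum_{i<k} p_i  (k = 0..L-1); mu terms via cumulative moments
    cw = np.concatenate(([0.0], np.cumsum(p)))[:L]
    cm = np.concatenate(([0.0], np.cumsum(i * p)))[:L]
    mu_t = float(np.sum(i * p))
    w0 = cw
    w1 = 1.0 - cw
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, cm / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu_t - cm) / w1, 0.0)
    curve = w0 * w1 * (mu1 - mu0) ** 2
    k = int(np.argmax(curve))  # argmax returns the first (smallest) maximizer

    in0 = i < k
    p0, p1 = p[in0], p[~in0]
    i0, i1 = i[in0], i[~in0]
    v0 = float(np.sum((i0 - mu0[k]) ** 2 * p0) / w0[k]) if w0[k] > 0 else 0.0
    v1 = float(np.sum((i1 - mu1[k]) ** 2 * p1) / w1[k]) if w1[k] > 0 else 0.0
    return OtsuResult(
        threshold=k,
        class_weights=(float(w0[k]), float(w1[k])),
        class_means=(float(mu0[k]), float(mu1[k])),
        class_variances=(v0, v1),
        between_class_variance=float(curve[k]),
        curve=curve,
    )


def binarize(img: np.ndarray, k: int, levels: int = 256) -> np.ndarray:
    """Split at ``k``: pixel < k -> 0 (target C0), pixel >= k -> 1 (background C1)."""
    if not 0 <= k <= levels - 1:
        raise ThresholdRangeError(f"threshold out of range: {k}")
    return (np.asarray(img) >= k).astype(np.uint8)


def structuring_element(size: int = 3) -> np.ndarray:
    """Flat square structuring element of odd side ``size``."""
    if size < 1 or size % 2 == 0:
        raise ValueError(f"structuring element side must be odd and >= 1, got {size}")
    return np.ones((size, size), dtype=bool)


def erode(b: np.ndarray, se: np.ndarray) -> np.ndarray:
    # Pads with foreground so the image frame is not treated as an edge;
    # this is the convention under which open/close duality holds exactly.
    return ndi.binary_erosion(b.astype(bool), structure=se, border_value=1).astype(np.uint8)


def dilate(b: np.ndarray, se: np.ndarray) -> np.ndarray:
    return ndi.binary_dilation(b.astype(bool), structure=se, border_value=0).astype(np.uint8)


def open_op(b: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Erosion then dilation: removes foreground specks; anti-extensive."""
    return dilate(erode(b, se), se)


def close_op(b: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Dilation then erosion: bridges narrow gaps; extensive."""
    return erode(dilate(b, se), se)


def fill_holes(b: np.ndarray) -> np.ndarray:
    """Fill background components not 4-connected to the image border."""
    return ndi.binary_fill_holes(b.astype(bool)).astype(np.uint8)


def gaussian_kernel(p: GaussianParams) -> np.ndarray:
    """Discrete 2-D Gaussian sampled at integer offsets, renormalized to sum 1."""
    r = p.size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    xx, yy = np.meshgrid(x, x)
    g = np.exp(-(xx**2 + yy**2) / (2.0 * p.sigma**2)) / (2.0 * np.pi * p.sigma**2)
    return g / g.sum()


def gaussian_smooth(img: np.ndarray, p: GaussianParams) -> np.ndarray:
    """Convolve with the discrete Gaussian; reflect padding at the borders."""
    kernel = gaussian_kernel(p)
    return ndi.convolve(np.asarray(img, dtype=np.float64), kernel, mode="reflect")


@dataclass
class PipelineResult:
    """Final silhouette plus every intermediate stage for inspection."""

    gray: np.ndarray
    otsu: OtsuResult
    binary: np.ndarray
    foreground_class: int  # 0 or 1: which Otsu class was deemed the syringe
    opened: np.ndarray
    closed: np.ndarray
    filled: np.ndarray
    smoothed: np.ndarray
    silhouette: np.ndarray  # binary, 1 = syringe


def _select_polarity(binary: np.ndarray) -> int:
    """Return the class label (0 or 1) that touches fewer border pixels."""
    border = np.concatenate(
        [binary[0, :], binary[-1, :], binary[1:-1, 0], binary[1:-1, -1]]
    )
    n1 = int(border.sum())
    n0 = border.size - n1
    return 0 if n0 <= n1 else 1


def preprocess_pipeline(image: np.ndarray, cfg=None) -> PipelineResult:
    """Run the full preprocessing chain on a raw raster.

    Returns the smoothed, re-binarized silhouette (1 = syringe) together
    with all intermediate stages.  Raises :class:`DegenerateImageError`
    for a constant image.
    """
    from .config import PipelineConfig

    cfg = cfg or PipelineConfig()
    gray = to_gray(image, levels=cfg.levels)
    otsu = otsu_threshold(histogram(gray, levels=cfg.levels))
    binary = binarize(gray, otsu.threshold, levels=cfg.levels)
    fg_class = _select_polarity(binary)
    mask = (binary == fg_class).astype(np.uint8)
    se = structuring_element(cfg.se_size)
    opened = open_op(mask, se)
    closed = close_op(opened, se)
    filled = fill_holes(closed)
    smoothed = gaussian_smooth(filled, cfg.gaussian)
    silhouette = (smoothed >= 0.5).astype(np.uint8)
    return PipelineResult(
        gray=gray,
        otsu=otsu,
        binary=binary,
        foreground_class=fg_class,
        opened=opened,
        closed=closed,
        filled=filled,
        smoothed=smoothed,
        silhouette=silhouette,
    )
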