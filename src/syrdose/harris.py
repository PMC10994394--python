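"""Harris corner detection on the preprocessed silhouette.

Per pixel, the structure tensor

    M = [[A, C], [C, B]],  A = sum w * Ix^2,  B = sum w * Iy^2,
                           C = sum w * Ix * Iy

is accumulated over a Gaussian window ``w``, and the corner response

    CRF = det(M) - k * tr(M)^2 = (A*B - C^2) - k * (A + B)^2

is positive where both eigenvalues of M are large (a corner), negative on
ideal step edges and zero on flat regions.  Detected corners are the
thresholded, non-max-suppressed local maxima of CRF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ImageTooSmallError, NoCornersError
from .preprocess import GaussianParams, gaussian_kernel


@dataclass(frozen=True)
class HarrisParams:
    """Detector parameters.

    window_sigma : Gaussian window scale for the structure tensor (px).
    sensitivity  : the Harris constant k in CRF = det(M) - k tr(M)^2.
    nms_radius   : Chebyshev suppression radius between corners (px).
    rel_threshold: keep responses >= rel_threshold * max response.
    """

    window_sigma: float = 1.0
    sensitivity: float = 0.04
    nms_radius: int = 5
    rel_threshold: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.sensitivity < 0.25:
            raise ValueError(f"sensitivity must be in (0, 0.25), got {self.sensitivity}")
        if not 0.0 < self.rel_threshold <= 1.0:
            raise ValueError(f"rel_threshold must be in (0, 1], got {self.rel_threshold}")
        if self.nms_radius < 1:
            raise ValueError(f"nms_radius must be >= 1, got {self.nms_radius}")
        if self.window_sigma <= 0:
            raise ValueError(f"window_sigma must be > 0, got {self.window_sigma}")


@dataclass(frozen=True)
class GradientField:
    ix: np.ndarray
    iy: np.ndarray


@dataclass(frozen=True)
class StructureTensorField:
    a: np.ndarray  # sum w * Ix^2
    b: np.ndarray  # sum w * Iy^2
    c: np.ndarray  # sum w * Ix*Iy
    window: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class CornerSet:
    """Response field plus surviving corners as (x, y, response), sorted
    by descending response."""

    response: np.ndarray = field(repr=False)
    corners: list[tuple[int, int, float]] = field(default_factory=list)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (x, y) corner coordinates."""
        return np.array([(x, y) for x, y, _ in self.corners], dtype=float).reshape(-1, 2)


def gradients(img: np.ndarray) -> GradientField:
    """Sobel derivatives (x = columns, y = rows) with reflect padding."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ImageTooSmallError(f"image too small for gradients: {img.shape}")
    ix = ndi.sobel(img, axis=1, mode="reflect")
    iy = ndi.sobel(img, axis=0, mode="reflect")
    return GradientField(ix=ix, iy=iy)


def _window(sigma: float) -> np.ndarray:
    size = 2 * int(np.ceil(3.0 * sigma)) + 1
    return gaussian_kernel(GaussianParams(sigma=sigma, size=size))


def structure_tensor(g: GradientField, p: HarrisParams) -> StructureTensorField:
    """Windowed sums of gradient products under a normalized Gaussian window."""
    w = _window(p.window_sigma)
    a = ndi.convolve(g.ix * g.ix, w, mode="reflect")
    b = ndi.convolve(g.iy * g.iy, w, mode="reflect")
    c = ndi.convolve(g.ix * g.iy, w, mode="reflect")
    return StructureTensorField(a=a, b=b, c=c, window=w)


def corner_response(t: StructureTensorField, p: HarrisParams) -> np.ndarray:
    """CRF = det(M) - sensitivity * tr(M)^2 per pixel."""
    return (t.a * t.b - t.c**2) - p.sensitivity * (t.a + t.b) ** 2


def detect_corners(response: np.ndarray, p: HarrisParams) -> CornerSet:
    """Threshold at ``rel_threshold * max`` and apply greedy Chebyshev NMS.

    Candidates are visited by descending response, ties broken by (y, x);
    a candidate is kept if no stronger kept corner lies within
    ``nms_radius`` in Chebyshev distance.  The result depends only on the
    response matrix, never on scan order.
    """
    response = np.asarray(response, dtype=np.float64)
    rmax = float(response.max()) if response.size else 0.0
    if not np.isfinite(rmax) or rmax <= 0.0:
        raise NoCornersError("no corners found: response has no positive peak")
    ys, xs = np.nonzero(response >= p.rel_threshold * rmax)
    vals = response[ys, xs]
    order = np.lexsort((xs, ys, -vals))
    kept: list[tuple[int, int, float]] = []
    for idx in order:
        x, y, v = int(xs[idx]), int(ys[idx]), float(vals[idx])
        if all(max(abs(x - kx), abs(y - ky)) > p.nms_radius for kx, ky, _ in kept):
            kept.append((x, y, v))
    return CornerSet(response=response, corners=kept)


def harris_corners(img: np.ndarray, p: HarrisParams | None = None) -> CornerSet:
    """Convenience chain: gradients -> structure tensor -> CRF -> corners."""
    p = p or HarrisParams()
    return detect_corners(corner_response(structure_tensor(gradients(img), p), p), p)
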