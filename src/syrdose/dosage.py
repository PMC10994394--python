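"""Landmark selection and distance-ratio dose computation.

Three landmarks determine the drawn volume: the barrel tip vertex
``(x1, y1)``, the piston position ``(x2, y2)`` and the barrel end vertex
``(x3, y3)``.  The recognized dose is

    L = d((x1,y1), (x2,y2)) / d((x1,y1), (x3,y3)) * R

with Euclidean pixel distances ``d`` and nominal syringe capacity ``R`` in
ml: the piston's fractional position along the barrel, scaled to capacity.

Roles are assigned from the Harris corner set using the silhouette's
principal axis; each landmark's coordinate along that axis is then snapped
to the silhouette itself (foreground extent and the liquid/air transition),
because raw response peaks can sit a pixel inside a corner and a coherent
one-pixel bias at three landmarks is already visible in the last decimal
of a 20 ml reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    DegenerateLandmarksError,
    InvalidCapacityError,
    LandmarksNotFoundError,
    NoPrincipalAxisError,
    PipelineError,
    SyrdoseError,
)
from .harris import CornerSet, HarrisParams, harris_corners
from .preprocess import PipelineResult, preprocess_pipeline

# Corners this close (px, along the axis) to the silhouette extremes are
# treated as end-vertex candidates.
_END_TOL = 4.0
# A piston corner must lie within this many axis-px of the liquid/air
# transition; candidates inside this margin (fraction of the axis span)
# of either extreme are never piston candidates.
_PISTON_TOL = 6.0
_END_MARGIN = 0.04
# Half-width (px) of the thin corridor along the axis used for the
# transition scan and for tip-end disambiguation.
_CORRIDOR = 2.0
# Minimum eigenvalue ratio of the silhouette covariance for a usable axis.
_MIN_ANISOTROPY = 1.5


@dataclass(frozen=True)
class SyringeLandmarks:
    """The three dose landmarks, (x, y) pixel coordinates."""

    tip_vertex: tuple[float, float]
    piston_point: tuple[float, float]
    end_vertex: tuple[float, float]


@dataclass(frozen=True)
class DoseResult:
    dose_ml: float
    fill_fraction: float
    capacity_ml: float
    landmarks: SyringeLandmarks
    raw_dose_ml: float


def _principal_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Barrel center and unit (axis, perpendicular) vectors.

    The axis is the long side of the minimum-area bounding rectangle of
    the foreground (rotating calipers over the convex hull).  Unlike the
    mass-covariance eigenvector, this is exact for a rectangular barrel
    even when interior content (liquid column, an occluder band over the
    graduations) is distributed asymmetrically.  The returned center is
    the rectangle center, i.e. the true barrel centerline, not the mass
    centroid.
    """
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(coords)
    except QhullError as exc:
        raise NoPrincipalAxisError(f"no principal axis: {exc}") from exc
    pts = coords[hull.vertices]
    edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    best = None
    for e in edges:
        norm = float(np.hypot(e[0], e[1]))
        if norm == 0:
            continue
        u = e / norm
        v = np.array([-u[1], u[0]])
        s = pts @ u
        d = pts @ v
        area = (s.max() - s.min()) * (d.max() - d.min())
        if best is None or area < best[0]:
            best = (area, u, v, s.min(), s.max(), d.min(), d.max())
    if best is None:
        raise NoPrincipalAxisError("no principal axis: degenerate silhouette")
    _, u, v, s0, s1, d0, d1 = best
    if (s1 - s0) < (d1 - d0):  # make u the long direction
        u, v = v, -u
        s0, s1, d0, d1 = d0, d1, -s1, -s0
    if (d1 - d0) <= 0 or (s1 - s0) / (d1 - d0) < _MIN_ANISOTROPY:
        raise NoPrincipalAxisError("no principal axis: silhouette too isotropic")
    c = 0.5 * (s0 + s1) * u + 0.5 * (d0 + d1) * v
    return c, u, v


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n <= 1:
        return mask.astype(bool)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def select_landmarks(
    corners: CornerSet, silhouette: np.ndarray, tip_end: str = "auto"
) -> SyringeLandmarks:
    """Assign tip, piston and end landmarks from corners + silhouette.

    Procedure: (1) principal axis of the largest silhouette component;
    (2) corners projected onto it; (3) the two extreme-projection corners
    (chosen on the same barrel side) become the tip/end vertices, the tip
    being the end whose axis corridor is covered by liquid (foreground);
    (4) the piston landmark is the in-between corner nearest the
    foreground-to-background transition along the axis corridor.  Axial
    coordinates are refined against the silhouette extent.

    ``tip_end``: ``"auto"`` (liquid-side detection), ``"left"`` or
    ``"right"`` to force which image side holds the tip.
    """
    mask = _largest_component(np.asarray(silhouette) > 0)
    if not mask.any():
        raise LandmarksNotFoundError("landmarks not found: empty silhouette")
    if len(corners.corners) < 3:
        raise LandmarksNotFoundError(
            f"landmarks not found: need >= 3 corners, got {len(corners.corners)}"
        )
    ys, xs = np.nonzero(mask)
    coords = np.column_stack([xs, ys]).astype(np.float64)
    c, u, v = _principal_axis(coords)

    s_fg = (coords - c) @ u
    d_fg = (coords - c) @ v
    s_lo, s_hi = float(s_fg.min()), float(s_fg.max())
    span = s_hi - s_lo

    corridor = np.abs(d_fg) <= _CORRIDOR
    s_cor = s_fg[corridor]
    if s_cor.size == 0:
        raise LandmarksNotFoundError("landmarks not found: hollow silhouette")

    # Which end is the tip (liquid side)?  The liquid column fills the
    # corridor next to the tip; behind the piston the corridor is empty.
    win = 0.15 * span
    n_lo = int(np.count_nonzero(s_cor <= s_lo + win))
    n_hi = int(np.count_nonzero(s_cor >= s_hi - win))
    if tip_end == "auto":
        tip_at_lo = n_lo >= n_hi
    elif tip_end in ("left", "right"):
        x_lo = (c + s_lo * u)[0]
        x_hi = (c + s_hi * u)[0]
        lo_is_left = x_lo <= x_hi
        tip_at_lo = lo_is_left == (tip_end == "left")
    else:
        raise ValueError(f"tip_end must be auto|left|right, got {tip_end!r}")
    if not tip_at_lo:  # orient the axis tip -> end
        u, v = -u, -v
        s_fg, d_fg = -s_fg, -d_fg
        s_cor = -s_cor
        s_lo, s_hi = -s_hi, -s_lo

    pts = corners.coordinates()
    s_c = (pts - c) @ u
    d_c = (pts - c) @ v
    order_key = [(y, x) for x, y, _ in corners.corners]

    tip_idx = [i for i in range(len(s_c)) if s_c[i] <= s_lo + _END_TOL]
    end_idx = [i for i in range(len(s_c)) if s_c[i] >= s_hi - _END_TOL]
    if not tip_idx or not end_idx:
        raise LandmarksNotFoundError("landmarks not found: no extreme corners")
    # pick the tip/end pair on the same barrel side
    ti, ei = min(
        ((i, j) for i in tip_idx for j in end_idx),
        key=lambda p: (abs(d_c[p[0]] - d_c[p[1]]), order_key[p[0]], order_key[p[1]]),
    )

    # Liquid/air transition along the axis: the corridor-foreground
    # boundary that is not at a barrel extreme.  Normally the liquid
    # block hangs off the tip, so the piston face is its far edge; under
    # a forced tip_end override the block may hang off the other end.
    if float(s_cor.min()) - s_lo <= s_hi - float(s_cor.max()):
        s_trans, trans_edge = float(s_cor.max()), 0.5
    else:
        s_trans, trans_edge = float(s_cor.min()), -0.5
    margin = _END_MARGIN * span
    mid_idx = [
        i
        for i in range(len(s_c))
        if s_lo + margin < s_c[i] < s_hi - margin and i not in (ti, ei)
    ]
    mid_idx = [i for i in mid_idx if abs(s_c[i] - s_trans) <= _PISTON_TOL]
    if not mid_idx:
        raise LandmarksNotFoundError(
            "landmarks not found: no corner near the piston transition"
        )
    # Among corners at the transition, prefer the one on the same barrel
    # side as the tip vertex: that is the piston/wall junction nearest
    # the tip's wall, whereas e.g. a graduation mark ending at the same
    # axial position sits closer to the axis (and the opposite wall's
    # junction would cross the barrel diagonally).
    pi = min(
        mid_idx,
        key=lambda i: (
            int(abs(s_c[i] - s_trans) // 3.0),
            abs(d_c[i] - d_c[ti]),
            order_key[i],
        ),
    )

    tip_pt = c + (s_lo - 0.5) * u + d_c[ti] * v
    end_pt = c + (s_hi + 0.5) * u + d_c[ei] * v
    pis_pt = c + (s_trans + trans_edge) * u + d_c[pi] * v
    return SyringeLandmarks(
        tip_vertex=(float(tip_pt[0]), float(tip_pt[1])),
        piston_point=(float(pis_pt[0]), float(pis_pt[1])),
        end_vertex=(float(end_pt[0]), float(end_pt[1])),
    )


def compute_dose(
    lm: SyringeLandmarks, capacity_ml: float, rounding: int = 2
) -> DoseResult:
    """Apply the distance-ratio formula to a landmark triple."""
    if capacity_ml <= 0:
        raise InvalidCapacityError(f"invalid capacity: {capacity_ml}")
    d12 = math.dist(lm.tip_vertex, lm.piston_point)
    d13 = math.dist(lm.tip_vertex, lm.end_vertex)
    if d13 == 0:
        raise DegenerateLandmarksError("degenerate landmarks: zero axis length")
    frac = d12 / d13
    raw = frac * capacity_ml
    scale = 10.0**rounding
    return DoseResult(
        dose_ml=math.floor(raw * scale + 0.5) / scale,
        fill_fraction=frac,
        capacity_ml=float(capacity_ml),
        landmarks=lm,
        raw_dose_ml=raw,
    )


def measure_dose(
    image: np.ndarray,
    capacity_ml: float,
    cfg=None,
    return_stages: bool = False,
):
    """Full pipeline: preprocess -> Harris corners -> landmarks -> dose.

    With ``return_stages=True`` also returns the
    :class:`~syrdose.preprocess.PipelineResult` and the corner set.
    Stage failures are re-raised as :class:`PipelineError` carrying the
    stage name.
    """
    from .config import PipelineConfig

    cfg = cfg or PipelineConfig()
    if capacity_ml <= 0:
        raise InvalidCapacityError(f"invalid capacity: {capacity_ml}")

    def _run(stage, fn):
        try:
            return fn()
        except SyrdoseError as exc:
            raise PipelineError(stage, exc) from exc

    pre: PipelineResult = _run("preprocess", lambda: preprocess_pipeline(image, cfg))
    corners = _run(
        "harris", lambda: harris_corners(pre.silhouette.astype(np.float64), cfg.harris)
    )
    lm = _run(
        "landmarks",
        lambda: select_landmarks(corners, pre.silhouette, tip_end=cfg.tip_end),
    )
    result = _run("dose", lambda: compute_dose(lm, capacity_ml, rounding=cfg.rounding))
    if return_stages:
        return result, pre, corners
    return result
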