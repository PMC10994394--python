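"""Deterministic synthetic syringe-scene renderer with ground truth.

Scenes emulate a photographed syringe lying on a contrasting tray: the
graduated barrel section (walls open at both ends — the nozzle is out of
frame), a liquid column flush with the tip end, a dark piston band whose
air-side face marks the drawn volume, optional graduation tick marks
(visible, light-washed, or occluded by an erasure band), in-plane rotation,
additive Gaussian noise and random-erasure patches.  Every scene is fully
determined by its seed, so rendered fixtures are bit-reproducible.

Intensities are chosen so that the maximum between-class-variance
threshold separates the syringe (walls + liquid + piston) from the
background on clean scenes, for colorless (low-contrast) and colored
(high-contrast) liquid alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidSceneError

#: Renderer gray palette (0-255).  Background bright, syringe parts dark
#: enough that Otsu's split lands between the syringe and the background.
PALETTE = {
    "background": 230,
    "wall": 120,
    "liquid_colorless": 170,
    "liquid_colored": 80,
    "piston": 40,
    "tick": 20,
    "tick_blurred": 210,
    # tape-like occluder over the graduations: darker than the background
    # but lighter than the liquid, so losing the scale never drags the
    # threshold below the liquid intensity
    "occluder": 160,
    "erase_fill": 60,
}

# Barrel geometry at the 480-px reference scale (pixels).
_REF = {"length": 420, "width": 100, "wall": 6, "piston": 16, "tick_len": 12, "tick_w": 2}


@dataclass(frozen=True)
class SynthScene:
    """Parameters of one synthetic scene; ``seed`` fixes all randomness."""

    capacity_ml: float = 5.0
    fill_fraction: float = 0.5
    liquid: str = "colorless"  # 'colorless' | 'colored'
    rotation_deg: float = 0.0
    scale_marks: str = "visible"  # 'visible' | 'blurred' | 'occluded'
    noise_sigma: float = 0.0
    erase_patches: int = 0
    erase_size: tuple[int, int] = (10, 40)
    seed: int = 0
    image_size: tuple[int, int] = (480, 640)  # (H, W)

    def __post_init__(self):
        if not 0.0 <= self.fill_fraction <= 1.0:
            raise InvalidSceneError(f"invalid scene: fill_fraction {self.fill_fraction}")
        if self.capacity_ml <= 0:
            raise InvalidSceneError(f"invalid scene: capacity {self.capacity_ml}")
        if self.liquid not in ("colorless", "colored"):
            raise InvalidSceneError(f"invalid scene: liquid {self.liquid!r}")
        if self.scale_marks not in ("visible", "blurred", "occluded"):
            raise InvalidSceneError(f"invalid scene: scale_marks {self.scale_marks!r}")
        if self.noise_sigma < 0:
            raise InvalidSceneError(f"invalid scene: noise_sigma {self.noise_sigma}")


@dataclass
class SceneTruth:
    """Ground truth of a rendered scene, post-rotation pixel coordinates."""

    true_dose_ml: float
    tip: tuple[float, float]
    piston: tuple[float, float]
    end: tuple[float, float]
    barrel_mask: np.ndarray = field(repr=False)
    liquid_mask: np.ndarray = field(repr=False)

    def landmarks_dict(self) -> dict:
        return {"tip": list(self.tip), "piston": list(self.piston), "end": list(self.end)}


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def rotate_points(points: np.ndarray, angle_deg: float, shape: tuple[int, int]) -> np.ndarray:
    """Map (x, y) points through the exact rotation the renderer applies."""
    h, w = shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rot = _rotation_matrix(angle_deg)
    pts = np.atleast_2d(points).astype(float)
    rc = pts[:, ::-1]  # (x, y) -> (row, col)
    out = (rc - center) @ rot.T + center
    return out[:, ::-1]


def _rotate_image(img: np.ndarray, angle_deg: float, cval: float) -> np.ndarray:
    h, w = img.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rot = _rotation_matrix(angle_deg)
    inv = rot.T  # inverse of a rotation
    offset = center - inv @ center
    return ndi.affine_transform(img, inv, offset=offset, order=0, mode="constant", cval=cval)


def add_gaussian_noise(
    image: np.ndarray, sigma: float, seed: int | None = None, rng=None
) -> np.ndarray:
    """Additive per-pixel Gaussian noise, clipped to [0, 255]; sigma=0 is identity."""
    if sigma < 0:
        raise InvalidSceneError(f"invalid noise sigma: {sigma}")
    if sigma == 0:
        return image.copy()
    rng = rng if rng is not None else np.random.default_rng(seed)
    noisy = image.astype(np.float64) + rng.normal(0.0, sigma, size=image.shape)
    return np.clip(np.round(noisy), 0, 255).astype(np.uint8)


def random_erase(
    image: np.ndarray,
    patches: int,
    size_range: tuple[int, int] = (10, 40),
    seed: int | None = None,
    rng=None,
    fill: int = PALETTE["erase_fill"],
) -> np.ndarray:
    """Overwrite ``patches`` random axis-aligned rectangles with a constant."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = image.copy()
    h, w = out.shape[:2]
    lo, hi = size_range
    if hi > min(h, w):
        raise InvalidSceneError(f"erase patch size {hi} exceeds image {image.shape}")
    for _ in range(patches):
        ph = int(rng.integers(lo, hi + 1))
        pw = int(rng.integers(lo, hi + 1))
        y = int(rng.integers(0, h - ph + 1))
        x = int(rng.integers(0, w - pw + 1))
        out[y : y + ph, x : x + pw] = fill
    return out


def render(scene: SynthScene) -> tuple[np.ndarray, SceneTruth]:
    """Render a scene to a uint8 grayscale image plus its ground truth."""
    h, w = scene.image_size
    sfac = min(h, w) / 480.0
    length = round(_REF["length"] * sfac)
    width = round(_REF["width"] * sfac)
    wall = max(2, round(_REF["wall"] * sfac))
    piston_w = max(4, round(_REF["piston"] * sfac))
    tick_len = max(4, round(_REF["tick_len"] * sfac))
    tick_w = max(1, round(_REF["tick_w"] * sfac))

    x0 = (w - length) // 2
    y0 = (h - width) // 2
    if x0 < 0 or y0 < 0:
        raise InvalidSceneError(f"invalid scene: image {scene.image_size} too small")

    img = np.full((h, w), PALETTE["background"], dtype=np.uint8)
    img[y0 : y0 + wall, x0 : x0 + length] = PALETTE["wall"]
    img[y0 + width - wall : y0 + width, x0 : x0 + length] = PALETTE["wall"]

    # piston air-side face offset from the tip end, in pixels
    xm = max(round(scene.fill_fraction * length), piston_w)
    liq_val = PALETTE[f"liquid_{scene.liquid}"]
    iy0, iy1 = y0 + wall, y0 + width - wall
    liquid_mask = np.zeros((h, w), dtype=bool)
    if scene.fill_fraction > 0:
        liquid_mask[iy0:iy1, x0 : x0 + xm - piston_w] = True
        img[liquid_mask] = liq_val
    img[iy0:iy1, x0 + xm - piston_w : x0 + xm] = PALETTE["piston"]

    if scene.scale_marks in ("visible", "blurred"):
        tick_val = PALETTE["tick" if scene.scale_marks == "visible" else "tick_blurred"]
        n_major = max(int(round(scene.capacity_ml)), 1)
        for j in range(n_major + 1):
            xt = x0 + round(j * length / n_major)
            lo = max(xt - tick_w // 2, x0)
            hi = min(lo + tick_w, x0 + length)
            img[iy0 : iy0 + tick_len, lo:hi] = tick_val
    else:  # occluded: an erasure band hides the whole graduation strip
        img[iy0 : iy0 + tick_len + 2, x0 : x0 + length] = PALETTE["occluder"]

    barrel_mask = np.zeros((h, w), dtype=bool)
    barrel_mask[y0 : y0 + width, x0 : x0 + length] = True

    # landmark truth at continuous region edges (pixel i spans i +/- 0.5)
    tip = (x0 - 0.5, y0 - 0.5)
    end = (x0 + length - 0.5, y0 - 0.5)
    piston = (x0 + xm - 0.5, y0 + wall - 0.5)

    if scene.rotation_deg % 360 != 0:
        img = _rotate_image(img, scene.rotation_deg, cval=PALETTE["background"])
        barrel_mask = _rotate_image(
            barrel_mask.astype(np.uint8), scene.rotation_deg, cval=0
        ).astype(bool)
        liquid_mask = _rotate_image(
            liquid_mask.astype(np.uint8), scene.rotation_deg, cval=0
        ).astype(bool)
        pts = rotate_points(
            np.array([tip, piston, end]), scene.rotation_deg, (h, w)
        )
        tip, piston, end = (tuple(map(float, p)) for p in pts)

    rng = np.random.default_rng(scene.seed)
    if scene.noise_sigma > 0:
        img = add_gaussian_noise(img, scene.noise_sigma, rng=rng)
    if scene.erase_patches > 0:
        img = random_erase(img, scene.erase_patches, scene.erase_size, rng=rng)

    truth = SceneTruth(
        true_dose_ml=scene.fill_fraction * scene.capacity_ml,
        tip=tip,
        piston=piston,
        end=end,
        barrel_mask=barrel_mask,
        liquid_mask=liquid_mask,
    )
    return img, truth


# Recognized-dose experiment layout: 10 scenario groups per liquid type and
# capacity.  Groups 1-4: graduations clearly visible (control); 5-6: piston
# sitting between graduations; 7-8: graduations washed out by light/angle;
# 9-10: graduations occluded.  Expected doses (ml) per capacity column.
_EXPECTED = {
    "colorless": {
        5: [2, 2.4, 3, 3.2, 3.3, 3.7, 3.5, 4, 4.5, 4.6],
        10: [5, 5.6, 6, 7.4, 8.1, 8.5, 8.2, 8.5, 9.2, 9.5],
        20: [10, 11.5, 12, 12.5, 12.8, 13.6, 13.5, 14, 15.5, 17.8],
    },
    "colored": {
        5: [1, 1.6, 2, 2.5, 2.7, 3.5, 3.7, 4, 4.3, 4.5],
        10: [6, 6.4, 5, 7.7, 8.3, 8.5, 8.8, 9.2, 9.5, 9.3],
        20: [11, 12.5, 10, 13.7, 14.2, 13.6, 14.2, 15.7, 16.6, 18.5],
    },
}


def _group_marks(group: int) -> str:
    if group <= 6:
        return "visible"
    if group <= 8:
        return "blurred"
    return "occluded"


def table_scenarios() -> list[tuple[SynthScene, float]]:
    """The full scenario grid: 2 liquid types x 3 capacities x 10 groups.

    Returns (scene, expected_dose_ml) pairs; the expected dose determines
    each scene's fill fraction.
    """
    out = []
    for liq_i, liquid in enumerate(("colorless", "colored")):
        for capacity, doses in _EXPECTED[liquid].items():
            for group, expected in enumerate(doses, start=1):
                scene = SynthScene(
                    capacity_ml=float(capacity),
                    fill_fraction=expected / capacity,
                    liquid=liquid,
                    scale_marks=_group_marks(group),
                    seed=1000 * liq_i + 10 * int(capacity) + group,
                )
                out.append((scene, float(expected)))
    return out
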