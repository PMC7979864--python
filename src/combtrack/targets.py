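"""Rendering of training targets from point annotations.

Bees are annotated as a tuple (x, y, b, alpha): the body center in image
coordinates (x = column, y = row, origin top-left), the class b (1 = fully
visible bee, 2 = bee inside a comb cell with only the abdomen showing), and
the body orientation alpha in degrees, measured clockwise from vertical-up
(alpha is fixed at 0 for cell-bees). Capped brood cells are annotated by their
center point only.

From these the module renders the three pixel maps a segmentation network is
trained on: a class map whose foreground blobs cover only the central third of
each body (small enough that blobs of neighbouring bees do not merge), an
angle map carrying each bee's orientation on its blob and -1 elsewhere, and a
positive weight map that up-weights bee regions with an oriented Gaussian to
counter the foreground/background class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeeAnnotation",
    "BroodAnnotation",
    "BeeGeometry",
    "SegmentationTarget",
    "render_bee_targets",
    "render_weight_map",
    "render_brood_targets",
    "ellipse_mask",
]

FULL_BEE = 1
CELL_BEE = 2


@dataclass(frozen=True)
class BeeAnnotation:
    """One bee in one frame: center (x, y), class b, orientation alpha (deg)."""

    x: float
    y: float
    b: int = FULL_BEE
    alpha: float = 0.0

    def __post_init__(self):
        if self.b not in (FULL_BEE, CELL_BEE):
            raise ValueError(f"class must be 1 (full-bee) or 2 (cell-bee), got {self.b}")
        if not 0.0 <= self.alpha < 360.0:
            raise ValueError(f"alpha must lie in [0, 360), got {self.alpha}")
        if self.b == CELL_BEE and self.alpha != 0.0:
            raise ValueError("cell-bees carry no orientation; alpha must be 0")


@dataclass(frozen=True)
class BroodAnnotation:
    """Center point of one capped brood cell."""

    x: float
    y: float


@dataclass(frozen=True)
class BeeGeometry:
    """Pixel dimensions of a bee and of the rendered target blobs.

    body_length / body_width: full body extents; region_fraction: the fraction
    of those extents covered by the target blob (1/3 keeps blobs of adjacent
    bees separate); brood_radius: radius of the circular brood-cell marker.
    """

    body_length: float = 80.0
    body_width: float = 30.0
    region_fraction: float = 1.0 / 3.0
    brood_radius: float = 10.0

    def __post_init__(self):
        if min(self.body_length, self.body_width, self.brood_radius) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if not 0.0 < self.region_fraction < 1.0:
            raise ValueError("region_fraction must lie in (0, 1)")

    @property
    def region_semi_major(self) -> float:
        return self.region_fraction * self.body_length / 2.0

    @property
    def region_semi_minor(self) -> float:
        return self.region_fraction * self.body_width / 2.0


@dataclass
class SegmentationTarget:
    """class map (0/1/2), angle map (deg on foreground, -1 background), weight map (>0)."""

    class_map: np.ndarray
    angle_map: np.ndarray
    weight_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.weight_map is None:
            self.weight_map = np.ones_like(self.angle_map)


def heading_vector(alpha_deg: float) -> tuple[float, float]:
    """Unit body-axis vector (dx, dy) for an angle clockwise from vertical-up.

    In image coordinates (x right, y down): 0 deg points up (-y), 90 deg right (+x).
    """
    a = np.deg2rad(alpha_deg)
    return float(np.sin(a)), float(-np.cos(a))


def _check_inside(x: float, y: float, shape: tuple[int, int], index: int, kind: str) -> None:
    h, w = shape
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(
            f"{kind} annotation {index} at (x={x}, y={y}) lies outside image of shape {shape}"
        )


def ellipse_mask(shape: tuple[int, int], cx: float, cy: float,
                 semi_major: float, semi_minor: float, alpha_deg: float) -> np.ndarray:
    """Boolean mask of the oriented ellipse (major axis along alpha)."""
    h, w = shape
    ux, uy = heading_vector(alpha_deg)
    r = int(np.ceil(max(semi_major, semi_minor))) + 1
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 2)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 2)
    mask = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    along = dx * ux + dy * uy
    across = dx * (-uy) + dy * ux
    mask[y0:y1, x0:x1] = (along / semi_major) ** 2 + (across / semi_minor) ** 2 <= 1.0
    return mask


def disk_mask(shape: tuple[int, int], cx: float, cy: float, radius: float) -> np.ndarray:
    return ellipse_mask(shape, cx, cy, radius, radius, 0.0)


def render_bee_targets(annotations: list[BeeAnnotation], shape: tuple[int, int],
                       geom: BeeGeometry = BeeGeometry()) -> SegmentationTarget:
    """Render class and angle maps from bee annotations.

    Full-bees become oriented ellipses (semi-axes a third of the half body
    dimensions), cell-bees disks of the same major diameter; later annotations
    overwrite earlier ones where blobs overlap.
    """
    class_map = np.zeros(shape, dtype=np.int64)
    angle_map = np.full(shape, -1.0)
    for i, ann in enumerate(annotations):
        _check_inside(ann.x, ann.y, shape, i, "bee")
        if ann.b == FULL_BEE:
            m = ellipse_mask(shape, ann.x, ann.y, geom.region_semi_major,
                             geom.region_semi_minor, ann.alpha)
        else:
            m = disk_mask(shape, ann.x, ann.y, geom.region_semi_major)
        class_map[m] = ann.b
        angle_map[m] = ann.alpha
    return SegmentationTarget(class_map, angle_map)


def _oriented_gaussian(shape: tuple[int, int], cx: float, cy: float,
                       sigma_major: float, sigma_minor: float, alpha_deg: float,
                       out: np.ndarray, scale: float) -> None:
    """Add scale * unit-peak oriented Gaussian into `out` (local support, 5 sigma)."""
    h, w = shape
    ux, uy = heading_vector(alpha_deg)
    r = int(np.ceil(5 * max(sigma_major, sigma_minor))) + 1
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 2)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    along = dx * ux + dy * uy
    across = dx * (-uy) + dy * ux
    out[y0:y1, x0:x1] += scale * np.exp(
        -0.5 * ((along / sigma_major) ** 2 + (across / sigma_minor) ** 2))


def render_weight_map(annotations: list[BeeAnnotation], shape: tuple[int, int],
                      geom: BeeGeometry, bg_fg_ratio: float) -> np.ndarray:
    """Loss-balancing weights: 1 + sum of per-bee oriented Gaussians scaled by bg_fg_ratio.

    bg_fg_ratio is the training-set ratio of background to bee-region pixels,
    computed once per dataset. Gaussian sigmas equal the target blob semi-axes
    and the axes follow the bee's orientation.
    """
    if bg_fg_ratio <= 0:
        raise ValueError("bg_fg_ratio must be positive")
    out = np.ones(shape)
    for i, ann in enumerate(annotations):
        _check_inside(ann.x, ann.y, shape, i, "bee")
        if ann.b == FULL_BEE:
            _oriented_gaussian(shape, ann.x, ann.y, geom.region_semi_major,
                               geom.region_semi_minor, ann.alpha, out, bg_fg_ratio)
        else:
            _oriented_gaussian(shape, ann.x, ann.y, geom.region_semi_major,
                               geom.region_semi_major, 0.0, out, bg_fg_ratio)
    return out


def render_brood_targets(annotations: list[BroodAnnotation], shape: tuple[int, int],
                         geom: BeeGeometry = BeeGeometry()) -> tuple[np.ndarray, np.ndarray]:
    """Binary brood mask (union of radius-`brood_radius` disks) and its weight map.

    The weight map is 1 + 10 * unit-peak isotropic Gaussian per cell, the
    brood-specific class-balance compensation.
    """
    mask = np.zeros(shape, dtype=bool)
    weight = np.ones(shape)
    for i, ann in enumerate(annotations):
        _check_inside(ann.x, ann.y, shape, i, "brood")
        mask |= disk_mask(shape, ann.x, ann.y, geom.brood_radius)
        _oriented_gaussian(shape, ann.x, ann.y, geom.brood_radius, geom.brood_radius,
                           0.0, weight, 10.0)
    return mask, weight


def background_foreground_ratio(targets: list[SegmentationTarget]) -> float:
    """Dataset-level ratio of background to foreground pixels across targets."""
    fg = sum(int((t.class_map != 0).sum()) for t in targets)
    total = sum(t.class_map.size for t in targets)
    if fg == 0:
        raise ValueError("no foreground pixels in the target set")
    return (total - fg) / fg
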