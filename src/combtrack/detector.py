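"""Segmentation-based dense bee detection.

A U-Net style encoder–decoder predicts, per pixel, one of three classes
(background / full-bee / cell-bee) plus an orientation angle. A recurrent
variant concatenates the penultimate feature map of the previous video frame
with the current one before the output heads; the temporal prior lets the
encoder/decoder widths shrink to a quarter of the original at every level
(~94% fewer trainable parameters) without losing accuracy. Detections are
read off the output maps as connected foreground blobs: the blob centroid is
the bee position, the majority pixel class its class, and for full bees the
principal axis of the blob — disambiguated by the predicted pixel angles —
its orientation.

The same machinery, without recurrence and with binary targets, detects
capped brood cells on temporally extracted background images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.measure import label, regionprops

from . import nn
from .targets import BeeGeometry, BroodAnnotation, SegmentationTarget, FULL_BEE

__all__ = [
    "DetectorConfig",
    "Detection",
    "RecurrentUNet",
    "build_network",
    "build_brood_network",
    "class_loss",
    "angle_loss",
    "maps_to_detections",
    "infer_tiled",
    "fine_tune",
    "extract_background",
    "detect_brood",
    "circular_mean_deg",
    "save_checkpoint",
    "load_checkpoint",
]

ORIGINAL_WIDTHS = (64, 128, 256, 512, 1024)
REDUCED_WIDTHS = (16, 32, 64, 128, 256)

# squared-norm floor in the orientation head's atan2 backward pass: keeps the
# 1/r gradient factor bounded for near-zero (sin, cos) outputs
ANGLE_NORM_FLOOR = 1e-2


@dataclass
class DetectorConfig:
    """Architecture and post-processing settings of the detection network."""

    encoder_widths: tuple[int, ...] = REDUCED_WIDTHS
    n_classes: int = 3
    recurrent: bool = True
    tile: int = 512
    tile_margin: int = 50
    blob_min: int = 10
    blob_max: int = 1000
    lr: float = 1e-4
    fps: float = 10.0

    def __post_init__(self):
        w = tuple(self.encoder_widths)
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValueError("encoder widths must be strictly increasing")
        if self.tile_margin >= self.tile / 2:
            raise ValueError("tile_margin must be smaller than half the tile size")
        if self.blob_min >= self.blob_max:
            raise ValueError("blob_min must be below blob_max")
        self.encoder_widths = w


@dataclass(frozen=True)
class Detection:
    """One detected bee: frame index, time, position, class, orientation, blob area."""

    frame: int
    t: float
    x: float
    y: float
    b: int
    alpha: float | None
    blob_area: int

    def __post_init__(self):
        if self.b not in (1, 2):
            raise ValueError("detection class must be 1 or 2")
        if (self.alpha is not None) != (self.b == FULL_BEE):
            raise ValueError("alpha must be present exactly for full-bee detections")


class RecurrentUNet:
    """Encoder–decoder segmentation network with an optional temporal prior.

    forward(image, prior) -> (class logits (K,H,W), angle map (H,W), new prior).
    The prior is the penultimate feature map of the previous frame (zeros for
    the first frame); when ``recurrent`` it is concatenated with the current
    penultimate features before the two 1x1 output heads.
    """

    def __init__(self, config: DetectorConfig, rng: np.random.Generator | None = None,
                 in_channels: int = 1, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.in_channels = in_channels
        w = config.encoder_widths
        self.depth = len(w)

        def conv(ci, co, k=3):
            return nn.Conv2d(ci, co, k=k, rng=rng, dtype=dtype)

        def norm(c):
            return nn.InstanceNorm2d(c, dtype=dtype)

        # conv -> instance norm -> relu; normalization keeps the tiny nets
        # trainable with single-frame batches
        self.enc = []
        c_prev = in_channels
        for wi in w:
            self.enc.append((conv(c_prev, wi), norm(wi), nn.ReLU(),
                             conv(wi, wi), norm(wi), nn.ReLU()))
            c_prev = wi
        self.pools = [nn.MaxPool2() for _ in range(self.depth - 1)]
        self.ups = []
        self.dec = []
        for i in range(self.depth - 2, -1, -1):
            self.ups.append((nn.UpsampleNearest2(), conv(w[i + 1], w[i]),
                             norm(w[i]), nn.ReLU()))
            self.dec.append((conv(2 * w[i], w[i]), norm(w[i]), nn.ReLU(),
                             conv(w[i], w[i]), norm(w[i]), nn.ReLU()))
        head_in = w[0] * (2 if config.recurrent else 1)
        self.class_head = conv(head_in, config.n_classes, k=1)
        # the angle is regressed as a (sin, cos) pair and decoded with atan2:
        # a bounded parameterization without wrap-around discontinuities
        self.angle_head = conv(head_in, 2, k=1)

    # -- parameters -------------------------------------------------------
    def layers(self):
        out = []
        for block in self.enc + self.ups + self.dec:
            out.extend(block)
        out += [self.class_head, self.angle_head]
        return out

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def count_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def zero_prior(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        return np.zeros((1, self.config.encoder_widths[0], h, w), dtype=np.float32)

    # -- forward / backward ----------------------------------------------
    def forward(self, image: np.ndarray, prior: np.ndarray | None = None):
        if image.ndim != 2:
            raise ValueError("expected a single-channel 2D image")
        h, w = image.shape
        if h % 2 ** (self.depth - 1) or w % 2 ** (self.depth - 1):
            raise ValueError("image dims must be divisible by 2**(depth-1)")
        x = image[None, None].astype(np.float32)
        skips = []
        for i, block in enumerate(self.enc):
            for layer in block:
                x = layer.forward(x)
            if i < self.depth - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        for upblock, dblock, skip in zip(self.ups, self.dec, reversed(skips)):
            for layer in upblock:
                x = layer.forward(x)
            x = np.concatenate([skip, x], axis=1)
            for layer in dblock:
                x = layer.forward(x)
        penult = x
        if self.config.recurrent:
            if prior is None:
                prior = self.zero_prior(image.shape)
            if prior.shape != penult.shape:
                raise ValueError(
                    f"prior shape {prior.shape} does not match penultimate {penult.shape}")
            x = np.concatenate([penult, prior.astype(penult.dtype)], axis=1)
        logits = self.class_head.forward(x)
        sc = self.angle_head.forward(x)
        s, c = sc[0, 0], sc[0, 1]
        # clamp the norm in the backward chain: atan2 gradients scale with
        # 1/r and would blow up through the shared trunk for tiny (s, c)
        r2 = s ** 2 + c ** 2
        self._angle_cache = (s, c, np.maximum(r2, ANGLE_NORM_FLOOR))
        angle = np.rad2deg(np.arctan2(s, c)) % 360.0
        self._penult_channels = penult.shape[1]
        return logits[0], angle, penult.copy()

    def backward(self, dlogits: np.ndarray, dangle: np.ndarray) -> None:
        """Accumulate parameter gradients for the last forward pass."""
        g = self.class_head.backward(dlogits[None].astype(np.float32))
        # chain through alpha_deg = (180/pi) * atan2(s, c)
        s, c, r2 = self._angle_cache
        drad = dangle * (180.0 / np.pi)
        dsc = np.stack([drad * c / r2, -drad * s / r2])[None]
        g = g + self.angle_head.backward(dsc.astype(np.float32))
        if self.config.recurrent:
            g = g[:, : self._penult_channels]  # the prior is a constant input
        # decoder block j consumed the skip from encoder level depth-2-j
        skip_grads: list[np.ndarray | None] = [None] * (self.depth - 1)
        for j in range(len(self.dec) - 1, -1, -1):
            for layer in reversed(self.dec[j]):
                g = layer.backward(g)
            c_skip = g.shape[1] // 2
            g_skip, g = g[:, :c_skip], g[:, c_skip:]
            for layer in reversed(self.ups[j]):
                g = layer.backward(g)
            skip_grads[self.depth - 2 - j] = g_skip
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                g = self.pools[i].backward(g) + skip_grads[i]
            for layer in reversed(self.enc[i]):
                g = layer.backward(g)

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()


def build_network(config: DetectorConfig, seed: int = 0, in_channels: int = 1) -> RecurrentUNet:
    """Construct the detection network from its configuration."""
    return RecurrentUNet(config, rng=np.random.default_rng(seed), in_channels=in_channels)


def build_brood_network(widths: tuple[int, ...] = (8, 16, 32), seed: int = 0) -> RecurrentUNet:
    """Binary (background/brood) segmentation network without recurrence."""
    cfg = DetectorConfig(encoder_widths=widths, n_classes=2, recurrent=False)
    return build_network(cfg, seed=seed)


# ---------------------------------------------------------------------------
# losses (scalar surface; gradient-carrying versions live in combtrack.nn)
# ---------------------------------------------------------------------------

def class_loss(logits: np.ndarray, class_map: np.ndarray,
               weight_map: np.ndarray | None = None) -> float:
    """Weighted 3-way cross-entropy averaged over pixels."""
    loss, _ = nn.softmax_cross_entropy(logits[None].astype(np.float64),
                                       class_map[None].astype(np.int64),
                                       None if weight_map is None else weight_map[None])
    return loss


def angle_loss(pred_deg: np.ndarray, angle_map: np.ndarray) -> float:
    """Mean foreground sin^2((pred - target)/2); 0 on empty foreground."""
    pred = np.asarray(pred_deg, dtype=np.float64)
    target = np.asarray(angle_map, dtype=np.float64)
    loss, _ = nn.masked_angle_loss(pred, target)
    return loss


# ---------------------------------------------------------------------------
# output-map post-processing
# ---------------------------------------------------------------------------

def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Resultant-vector circular mean, degrees, period 360."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    return float(np.rad2deg(np.arctan2(np.sin(a).mean(), np.cos(a).mean()))) % 360.0


def _axis_angle_deg(coords: np.ndarray) -> float | None:
    """First principal component of blob pixel coordinates, as an angle
    clockwise from vertical-up, mod 180. None if the blob has no extent."""
    ys, xs = coords[:, 0].astype(float), coords[:, 1].astype(float)
    cov = np.cov(np.stack([xs, ys]), bias=True)
    if not np.isfinite(cov).all() or np.allclose(cov, 0):
        return None
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, int(np.argmax(evals))]
    if np.isclose(evals[0], evals[1]):
        return None
    return float(np.rad2deg(np.arctan2(vx, -vy))) % 180.0


def maps_to_detections(class_map: np.ndarray, angle_map: np.ndarray,
                       config: DetectorConfig, frame: int = 0,
                       t: float | None = None) -> list[Detection]:
    """Turn segmentation output into detections.

    8-connected foreground components with area in [blob_min, blob_max];
    position = mean pixel coordinate; class = pixel majority; full-bee
    orientation = blob principal axis oriented toward the circular mean of the
    member pixels' predicted angles.
    """
    if class_map.shape != angle_map.shape:
        raise ValueError("class and angle maps must share a shape")
    if t is None:
        t = frame / config.fps
    lbl = label(class_map != 0, connectivity=2)
    out: list[Detection] = []
    for region in regionprops(lbl):
        area = int(region.area)
        if area < config.blob_min or area > config.blob_max:
            continue
        coords = region.coords  # (row, col)
        cy, cx = coords.mean(axis=0)
        classes = class_map[coords[:, 0], coords[:, 1]]
        b = 1 if int((classes == 1).sum()) >= int((classes == 2).sum()) else 2
        alpha = None
        if b == FULL_BEE:
            pix_mean = circular_mean_deg(angle_map[coords[:, 0], coords[:, 1]])
            axis = _axis_angle_deg(coords)
            if axis is None:
                alpha = pix_mean
            else:
                c1, c2 = axis, (axis + 180.0) % 360.0
                def half_turn_err(c):
                    return np.sin(np.deg2rad(c - pix_mean) / 2.0) ** 2
                alpha = c1 if half_turn_err(c1) <= half_turn_err(c2) else c2
        out.append(Detection(frame=frame, t=float(t), x=float(cx), y=float(cy),
                             b=b, alpha=alpha, blob_area=area))
    return out


# ---------------------------------------------------------------------------
# tiled inference
# ---------------------------------------------------------------------------

def _tile_origins(extent: int, tile: int, step: int) -> list[int]:
    if extent <= tile:
        return [0]
    origins = list(range(0, extent - tile, step))
    origins.append(extent - tile)
    return origins


def infer_tiled(image: np.ndarray, model: RecurrentUNet,
                priors: dict[tuple[int, int], np.ndarray] | None = None
                ) -> tuple[np.ndarray, np.ndarray, dict[tuple[int, int], np.ndarray]]:
    """Run the network over overlapping tiles and stitch full-frame maps.

    Tiles of ``config.tile`` px overlap so that each tile contributes only its
    interior (``tile_margin`` cropped on each side except at frame borders);
    objects therefore land in exactly one tile's kept region. Returns
    (class_map, angle_map, new_priors); priors are kept per tile origin.
    """
    cfg = model.config
    h, w = image.shape
    ph, pw = max(h, cfg.tile), max(w, cfg.tile)
    # round up to the network's divisibility requirement
    div = 2 ** (model.depth - 1)
    ph += (-ph) % div
    pw += (-pw) % div
    padded = np.zeros((ph, pw), dtype=image.dtype)
    padded[:h, :w] = image
    step = cfg.tile - 2 * cfg.tile_margin
    oys = _tile_origins(ph, cfg.tile, step)
    oxs = _tile_origins(pw, cfg.tile, step)
    class_map = np.zeros((ph, pw), dtype=np.int64)
    angle_out = np.full((ph, pw), -1.0)
    new_priors: dict[tuple[int, int], np.ndarray] = {}
    priors = priors or {}
    for oy in oys:
        for ox in oxs:
            tile_img = padded[oy:oy + cfg.tile, ox:ox + cfg.tile]
            logits, angle, penult = model.forward(tile_img, priors.get((oy, ox)))
            new_priors[(oy, ox)] = penult
            cls = logits.argmax(axis=0)
            m = cfg.tile_margin
            y0 = 0 if oy == 0 else m
            x0 = 0 if ox == 0 else m
            y1 = cfg.tile if oy + cfg.tile >= ph else cfg.tile - m
            x1 = cfg.tile if ox + cfg.tile >= pw else cfg.tile - m
            class_map[oy + y0:oy + y1, ox + x0:ox + x1] = cls[y0:y1, x0:x1]
            angle_out[oy + y0:oy + y1, ox + x0:ox + x1] = angle[y0:y1, x0:x1]
    angle_out[class_map == 0] = -1.0
    return class_map[:h, :w], angle_out[:h, :w], new_priors


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def fine_tune(model: RecurrentUNet, labeled_frames: list[tuple[np.ndarray, SegmentationTarget]],
              n_iter: int = 10, lr: float | None = None,
              optimizer: nn.Adam | None = None, angle_weight: float = 1.0) -> list[float]:
    """Train the network for ``n_iter`` passes over an ordered frame sequence.

    The recurrent prior is threaded through the sequence (zeros at the start
    of each pass) and treated as a constant input. Returns the per-pass mean
    combined loss.
    """
    if not labeled_frames:
        raise ValueError("fine_tune requires at least one labeled frame")
    opt = optimizer or nn.Adam(model.params(), lr=model.config.lr if lr is None else lr)
    if lr is not None:
        opt.lr = lr
    history: list[float] = []
    for _ in range(n_iter):
        prior = None
        total = 0.0
        for image, target in labeled_frames:
            logits, angle, penult = model.forward(image, prior)
            prior = penult
            l_cls, dlogits = nn.softmax_cross_entropy(
                logits[None], target.class_map[None].astype(np.int64),
                target.weight_map[None])
            l_ang, dangle = nn.masked_angle_loss(angle, target.angle_map)
            model.zero_grad()
            model.backward(dlogits[0], angle_weight * dangle)
            opt.step()
            total += l_cls + angle_weight * l_ang
        history.append(total / len(labeled_frames))
    return history


# ---------------------------------------------------------------------------
# brood pipeline
# ---------------------------------------------------------------------------

def extract_background(frames: np.ndarray, motion_sigma_factor: float = 3.0) -> np.ndarray:
    """Temporal background from a stack of frames (T, H, W).

    A sample is treated as static at a pixel when its absolute difference to
    the previous frame stays below ``motion_sigma_factor`` robust standard
    deviations (MAD-based) of all frame differences; the background is the
    per-pixel median over static samples, falling back to the plain median at
    pixels that are never static.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 3:
        raise ValueError("extract_background needs at least 3 frames")
    diffs = np.abs(np.diff(frames, axis=0))
    med = np.median(diffs)
    mad = np.median(np.abs(diffs - med))
    thr = med + motion_sigma_factor * 1.4826 * mad
    static = np.empty(frames.shape, dtype=bool)
    static[1:] = diffs <= thr
    static[0] = static[1]
    vals = np.where(static, frames, np.nan)
    with np.errstate(all="ignore"):
        bg = np.nanmedian(vals, axis=0)
    fallback = ~static.any(axis=0)
    if fallback.any():
        bg[fallback] = np.median(frames, axis=0)[fallback]
    return bg


def _lattice_disk_area(radius: float) -> int:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return int((xx ** 2 + yy ** 2 <= radius ** 2).sum())


def detect_brood(background: np.ndarray, brood_model,
                 geom: BeeGeometry = BeeGeometry(),
                 min_area: float | None = None) -> list[BroodAnnotation]:
    """Detect capped brood cells on a background image.

    ``brood_model`` is either a RecurrentUNet (binary head) or any callable
    returning a foreground mask/probability map. Components smaller than half
    a brood disk are discarded; component centroids are the cell centers.
    """
    if isinstance(brood_model, RecurrentUNet):
        logits, _, _ = brood_model.forward(background.astype(np.float32))
        fg = logits.argmax(axis=0) == 1
    else:
        out = np.asarray(brood_model(background))
        fg = out > 0.5 if out.dtype != bool else out
    if min_area is None:
        min_area = _lattice_disk_area(geom.brood_radius) / 2.0
    lbl = label(fg, connectivity=2)
    cells = []
    for region in regionprops(lbl):
        if region.area < min_area:
            continue
        cy, cx = region.coords.mean(axis=0)
        cells.append(BroodAnnotation(x=float(cx), y=float(cy)))
    return cells


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: RecurrentUNet, path: str | Path) -> None:
    """Weights as NPZ next to a JSON sidecar holding the configuration."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, **arrays)
    sidecar = {"config": asdict(model.config), "in_channels": model.in_channels}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> RecurrentUNet:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cfg = DetectorConfig(**{**sidecar["config"],
                            "encoder_widths": tuple(sidecar["config"]["encoder_widths"])})
    model = build_network(cfg, in_channels=sidecar["in_channels"])
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    return model
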