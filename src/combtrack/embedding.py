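"""Appearance embeddings of bee detections, trained with a triplet objective.

Seemingly identical bees carry enough distinct visual detail ("pixel
personality") to separate neighbours in embedding space. A convolutional
backbone maps a detection-centered crop to a 64-d vector f(i); training
minimizes the hinge

    L(i1, i2, i3) = max(||f(i1)-f(i2)||^2 - ||f(i1)-f(i3)||^2 + margin, 0)

over triplets of (anchor, same bee later, different bee at the same later
frame). Two devices make training converge at a practical cost: triplets are
sampled only inside the tracker's time/space matching limits — exactly the
configurations where identity swaps can happen — and triplets that still
violate the hinge are fed back into the next batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as sk_rotate

from . import nn
from .targets import BeeGeometry, ellipse_mask
from .tracker import TrackerParams, Trajectory, distance_cutoff

__all__ = [
    "EmbeddingConfig",
    "DetRef",
    "Triplet",
    "EmbeddingNet",
    "triplet_loss",
    "batch_loss",
    "sample_triplets",
    "hard_example_feedback",
    "augment_crops",
    "extract_crop",
    "mask_background",
    "rotate_to_upright",
    "train_embedding",
    "embed_detections",
]


@dataclass
class EmbeddingConfig:
    """Embedding dimensionality, triplet margin and training settings."""

    dim: int = 64
    margin: float = 0.5
    batch_size: int = 32
    lr: float = 1e-4
    crop_size: int = 128
    augment: bool = False
    mask_background: bool = False
    channels: tuple[int, int] = (8, 16)
    batch_rule: str = "clamped"  # 'clamped' divisor or 'mean_violating'

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("embedding dimensionality must be at least 2")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass(frozen=True)
class DetRef:
    """Reference to one detection inside a trajectory."""

    traj_id: int
    frame: int
    x: float
    y: float
    b: int
    alpha: float


@dataclass(frozen=True)
class Triplet:
    anchor: DetRef
    positive: DetRef
    negative: DetRef

    def __post_init__(self):
        if self.positive.frame != self.negative.frame:
            raise ValueError("positive and negative must come from the same frame")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def triplet_loss(f1: np.ndarray, f2: np.ndarray, f3: np.ndarray,
                 margin: float = 0.5) -> float:
    """Hinge on squared Euclidean distances: anchor-positive vs anchor-negative."""
    f1, f2, f3 = (np.asarray(f, dtype=float) for f in (f1, f2, f3))
    if not (f1.shape == f2.shape == f3.shape):
        raise ValueError("embeddings must share a dimensionality")
    d_pos = float(np.sum((f1 - f2) ** 2))
    d_neg = float(np.sum((f1 - f3) ** 2))
    return max(d_pos - d_neg + margin, 0.0)


def batch_loss(losses, rule: str = "clamped") -> float:
    """Batch objective: sum of losses over max(1, number of zero-loss triplets).

    ``rule='mean_violating'`` instead averages over the violating triplets.
    """
    losses = np.asarray(list(losses), dtype=float)
    if losses.size == 0:
        raise ValueError("batch is empty")
    n_zero = int((losses == 0).sum())
    if rule == "clamped":
        return float(losses.sum() / max(1, n_zero))
    if rule == "mean_violating":
        n_pos = losses.size - n_zero
        return float(losses.sum() / max(1, n_pos))
    raise ValueError(f"unknown batch rule {rule!r}")


def hard_example_feedback(triplets: list, losses) -> list:
    """Triplets with positive loss, queued for the next training batch."""
    losses = np.asarray(list(losses), dtype=float)
    if len(triplets) != losses.size:
        raise ValueError("losses must align with triplets")
    return [t for t, l in zip(triplets, losses) if l > 0]


# ---------------------------------------------------------------------------
# triplet sampling under the matcher's limits
# ---------------------------------------------------------------------------

def _ref(traj: Trajectory, k: int) -> DetRef:
    return DetRef(traj.id, traj.frames[k], traj.xs[k], traj.ys[k],
                  traj.bs[k], traj.alphas[k])


def sample_triplets(trajectories: list[Trajectory], params: TrackerParams,
                    rng: np.random.Generator, n: int, dt_frames: int = 1
                    ) -> list[Triplet]:
    """Sample ``n`` triplets whose negatives satisfy the matcher's c_d cutoff.

    The anchor is a random trajectory detection with a successor ``dt_frames``
    later; the positive is that successor; the negative is a different
    trajectory's detection in the positive's frame, within the anchor
    trajectory's distance cutoff. Anchors without an admissible negative are
    skipped. Deterministic under the rng's seed.
    """
    trajs = [tr for tr in trajectories if len(tr) >= 2]
    if not trajs:
        return []
    by_frame: dict[int, list[tuple[Trajectory, int]]] = {}
    for tr in trajs:
        for k, f in enumerate(tr.frames):
            by_frame.setdefault(f, []).append((tr, k))
    out: list[Triplet] = []
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        tr = trajs[rng.integers(len(trajs))]
        # anchor index with a successor dt_frames later
        k = int(rng.integers(len(tr) - 1))
        target_frame = tr.frames[k] + dt_frames
        try:
            kp = tr.frames.index(target_frame, k + 1)
        except ValueError:
            continue
        anchor = _ref(tr, k)
        positive = _ref(tr, kp)
        # a stub trajectory state at the anchor gives the matcher's cutoff
        head = Trajectory(tr.id)
        for j in range(max(0, k - 9), k + 1):
            head.append(tr.frames[j], tr.ts[j], tr.xs[j], tr.ys[j], tr.bs[j],
                        tr.alphas[j], tr.rows[j] if tr.rows else j)
        t_pos = tr.ts[kp]
        c_d = distance_cutoff(head, t_pos, params)
        negatives = [
            _ref(otr, ok) for otr, ok in by_frame.get(target_frame, [])
            if otr.id != tr.id and
            np.hypot(otr.xs[ok] - anchor.x, otr.ys[ok] - anchor.y) <= c_d
        ]
        if not negatives:
            continue
        out.append(Triplet(anchor, positive,
                           negatives[int(rng.integers(len(negatives)))]))
    return out


# ---------------------------------------------------------------------------
# crops
# ---------------------------------------------------------------------------

def extract_crop(image: np.ndarray, x: float, y: float, size: int) -> np.ndarray:
    """Square crop centered on (x, y), zero-padded at frame borders."""
    h, w = image.shape
    half = size // 2
    cx, cy = int(round(x)), int(round(y))
    out = np.zeros((size, size), dtype=image.dtype)
    x0, x1 = cx - half, cx - half + size
    y0, y1 = cy - half, cy - half + size
    sx0, sy0 = max(0, x0), max(0, y0)
    sx1, sy1 = min(w, x1), min(h, y1)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return out


def augment_crops(crops: tuple[np.ndarray, ...], rng: np.random.Generator
                  ) -> tuple[np.ndarray, ...]:
    """One random 90-degree rotation / mirror transform applied to all crops.

    Sampling the transform once per triplet preserves the orientation
    relationship among its images.
    """
    for c in crops:
        if c.shape[0] != c.shape[1]:
            raise ValueError("augmentation requires square crops")
    k = int(rng.integers(4))
    flip_h = bool(rng.integers(2))
    flip_v = bool(rng.integers(2))

    def tf(c):
        c = np.rot90(c, k)
        if flip_h:
            c = c[:, ::-1]
        if flip_v:
            c = c[::-1, :]
        return c.copy()

    return tuple(tf(c) for c in crops)


def mask_background(crop: np.ndarray, b: int, alpha: float,
                    geom: BeeGeometry = BeeGeometry()) -> np.ndarray:
    """Zero everything outside the centered full-body ellipse (or abdomen disk)."""
    h, w = crop.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    if b == 1:
        m = ellipse_mask(crop.shape, cx, cy, geom.body_length / 2.0,
                         geom.body_width / 2.0, alpha if np.isfinite(alpha) else 0.0)
    else:
        r = geom.body_width / 2.0
        m = ellipse_mask(crop.shape, cx, cy, r, r, 0.0)
    out = np.zeros_like(crop)
    out[m] = crop[m]
    return out


def rotate_to_upright(crop: np.ndarray, alpha: float) -> np.ndarray:
    """Rotate a crop so the bee's body axis points up (removes orientation cues)."""
    if not np.isfinite(alpha) or alpha == 0.0:
        return crop
    return sk_rotate(crop, -alpha, preserve_range=True).astype(crop.dtype)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class EmbeddingNet:
    """Small convolutional backbone with a 64-d linear head.

    Two conv/pool stages, adaptive average pooling to a 4x4 grid and a dense
    projection; swap in any object with the same embed/backward surface for a
    larger backbone.
    """

    def __init__(self, config: EmbeddingConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        c1, c2 = config.channels
        self.config = config
        self.conv1 = nn.Conv2d(1, c1, 3, rng=rng, dtype=dtype)
        self.relu1 = nn.ReLU()
        self.pool1 = nn.MaxPool2()
        self.conv2 = nn.Conv2d(c1, c2, 3, rng=rng, dtype=dtype)
        self.relu2 = nn.ReLU()
        self.pool2 = nn.MaxPool2()
        self.gap = nn.AdaptiveAvgPool(4, 4)
        self.head = nn.Dense(c2 * 16, config.dim, rng=rng, dtype=dtype)

    def params(self):
        out = []
        for layer in (self.conv1, self.conv2, self.head):
            out.extend(layer.params())
        return out

    def count_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def embed(self, crops: np.ndarray) -> np.ndarray:
        """(N, H, W) crops -> (N, dim) embeddings; deterministic given weights."""
        if crops.ndim == 2:
            crops = crops[None]
        if crops.shape[1] != crops.shape[2] or crops.shape[1] % 4:
            raise ValueError("crops must be square with size divisible by 4")
        x = crops[:, None].astype(np.float32)
        x = self.pool1.forward(self.relu1.forward(self.conv1.forward(x)))
        x = self.pool2.forward(self.relu2.forward(self.conv2.forward(x)))
        x = self.gap.forward(x)
        self._gap_shape = x.shape
        return self.head.forward(x.reshape(x.shape[0], -1))

    __call__ = embed

    def backward(self, dF: np.ndarray) -> None:
        g = self.head.backward(dF.astype(np.float32)).reshape(self._gap_shape)
        g = self.gap.backward(g)
        g = self.conv2.backward(self.relu2.backward(self.pool2.backward(g)))
        self.conv1.backward(self.relu1.backward(self.pool1.backward(g)))

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _crop_for(ref: DetRef, frames: np.ndarray, config: EmbeddingConfig,
              geom: BeeGeometry) -> np.ndarray:
    crop = extract_crop(frames[ref.frame], ref.x, ref.y, config.crop_size)
    if config.mask_background:
        crop = mask_background(crop, ref.b, ref.alpha, geom)
    return crop


def train_embedding(frames: np.ndarray, trajectories: list[Trajectory],
                    config: EmbeddingConfig, params: TrackerParams,
                    seed: int = 0, n_batches: int = 100,
                    model: EmbeddingNet | None = None,
                    geom: BeeGeometry = BeeGeometry()) -> tuple[EmbeddingNet, dict]:
    """Train the embedding network with matcher-constrained triplets.

    Violating triplets are re-queued (hard-example feedback); the rest of
    each batch is freshly sampled. Returns the model and a history with the
    per-batch violating fraction.
    """
    rng = np.random.default_rng(seed)
    model = model or EmbeddingNet(config, rng=np.random.default_rng(seed + 1))
    opt = nn.Adam(model.params(), lr=config.lr)
    queued: list[Triplet] = []
    history = {"batch_loss": [], "violating_fraction": [], "seed": seed}
    for _ in range(n_batches):
        fresh = sample_triplets(trajectories, params, rng,
                                max(0, config.batch_size - len(queued)))
        batch = (queued + fresh)[:config.batch_size]
        if not batch:
            break
        crops = []
        for trip in batch:
            c = tuple(_crop_for(r, frames, config, geom)
                      for r in (trip.anchor, trip.positive, trip.negative))
            if config.augment:
                c = augment_crops(c, rng)
            crops.append(c)
        m = len(batch)
        stack = np.stack([c for trip_crops in crops for c in trip_crops])
        F = model.embed(stack).astype(np.float64)
        f1, f2, f3 = F[0::3], F[1::3], F[2::3]
        d_pos = ((f1 - f2) ** 2).sum(axis=1)
        d_neg = ((f1 - f3) ** 2).sum(axis=1)
        losses = np.maximum(d_pos - d_neg + config.margin, 0.0)
        active = losses > 0
        n_zero = int((~active).sum())
        divisor = max(1, n_zero) if config.batch_rule == "clamped" \
            else max(1, int(active.sum()))
        dF = np.zeros_like(F)
        a = active[:, None]
        dF[0::3] = np.where(a, 2 * (f3 - f2), 0.0) / divisor
        dF[1::3] = np.where(a, -2 * (f1 - f2), 0.0) / divisor
        dF[2::3] = np.where(a, 2 * (f1 - f3), 0.0) / divisor
        model.zero_grad()
        model.backward(dF)
        opt.step()
        history["batch_loss"].append(float(losses.sum() / divisor))
        history["violating_fraction"].append(float(active.mean()))
        queued = hard_example_feedback(batch, losses)[:config.batch_size]
    return model, history


def save_embedding_model(model: EmbeddingNet, path) -> None:
    """Weights as NPZ plus a JSON sidecar with the embedding configuration."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, **arrays)
    cfg = asdict(model.config)
    cfg["channels"] = list(cfg["channels"])
    Path(str(path) + ".json").write_text(json.dumps(cfg, indent=2))


def load_embedding_model(path) -> EmbeddingNet:
    import json
    from pathlib import Path

    cfg = json.loads(Path(str(path) + ".json").read_text())
    cfg["channels"] = tuple(cfg["channels"])
    model = EmbeddingNet(EmbeddingConfig(**cfg))
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    return model


def embed_detections(model: EmbeddingNet, frames: np.ndarray, det,
                     config: EmbeddingConfig,
                     rotate_upright: bool = False,
                     geom: BeeGeometry = BeeGeometry()) -> np.ndarray:
    """Embed every detection row of a table with frame,x,y,b,alpha columns."""
    crops = []
    for _, r in det.iterrows():
        crop = extract_crop(frames[int(r["frame"])], r["x"], r["y"], config.crop_size)
        if config.mask_background:
            crop = mask_background(crop, int(r["b"]), r.get("alpha", np.nan), geom)
        if rotate_upright and int(r["b"]) == 1:
            crop = rotate_to_upright(crop, r.get("alpha", np.nan))
        crops.append(crop)
    return model.embed(np.stack(crops))
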