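"""Synthetic honey-bee colonies with known ground truth.

The simulator emulates the statistical structure of comb-side hive recordings
at a scale where every downstream module can be exercised end to end:

* trajectories — a run-and-turn correlated random walk per bee with
  reflecting arena walls, interludes inside comb cells (position frozen,
  only the abdomen visible), and entries/exits through an entrance region;
* frames — textured oriented ellipses (full bees) and abdomen disks
  (cell-bees) drawn in stable painter's order over a hexagonal comb
  background with sensor noise;
* appearance — per-identity 64-d embedding centers at a controlled pairwise
  separation plus per-frame isotropic noise, standing in for a trained
  re-identification network in tracker tests;
* sociometric series — ~24-h oscillating bee counts, brood counts coupled
  negatively to the windowed bee counts, and a nightly cell-bee excess with a
  configurable peak hour.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .targets import BeeAnnotation, BroodAnnotation, BeeGeometry, heading_vector

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_trajectories",
    "render_frames",
    "render_frame",
    "oracle_embeddings",
    "simulate_count_series",
    "detection_scene_config",
    "tracking_scene_config",
    "DiskRegion",
    "RectRegion",
]


@dataclass(frozen=True)
class DiskRegion:
    cx: float
    cy: float
    r: float

    def contains(self, x, y):
        return (np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2 <= self.r ** 2


@dataclass(frozen=True)
class RectRegion:
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic colony."""

    n_bees: int = 50
    arena: tuple[int, int] = (512, 512)  # (height, width) px
    fps: float = 10.0
    duration_s: float = 120.0
    seed: int = 0
    # motion model: per-frame speed ~ Gamma(k, mean/k)/fps, heading diffusion
    mean_speed: float = 40.0        # px/s of a walking bee
    speed_shape: float = 3.0
    turn_std: float = 0.3           # rad per frame heading jitter
    # comb-cell interludes
    cell_rate: float = 0.01         # per-bee entries per second
    cell_dwell_s: float = 20.0      # mean dwell inside a cell
    # entrance traffic
    entrance: DiskRegion | None = None  # default: bottom-center disk
    exit_rate: float = 0.0          # per-second exit probability near the entrance
    entry_rate: float = 0.05        # per-second re-entry probability while absent
    exclusion: float | None = None  # isotropic exclusion distance, px
    #                                 (None: anisotropic body-ellipse contact)
    climb_prob: float = 0.15        # chance an encounter becomes a climb-over
    climb_duration_s: float = 1.5   # mean duration of a climb-over episode
    # appearance oracle
    embed_dim: int = 64
    embed_separation: float = 2.0
    embed_noise: float = 0.1
    # rendering
    geometry: BeeGeometry = field(default_factory=BeeGeometry)
    bg_level: float = 0.35
    comb_contrast: float = 0.08
    bee_contrast: float = 0.35
    sensor_noise: float = 0.02
    n_brood: int = 30

    def entrance_region(self) -> DiskRegion:
        if self.entrance is not None:
            return self.entrance
        h, w = self.arena
        return DiskRegion(cx=w / 2.0, cy=h - 1.0, r=min(h, w) / 8.0)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


def detection_scene_config(seed: int = 0) -> SimConfig:
    """Desk-scale detection scene: 256x256 frames with ~15 bees of 44x16 px.

    Bodies exclude each other and no climb-overs occur: the scene probes the
    detection machinery (rendering, training, blob extraction) on touching
    but not interpenetrating bees; occlusion handling is the tracking
    scene's concern.
    """
    return SimConfig(
        n_bees=15, arena=(256, 256), fps=10.0, duration_s=3.0, seed=seed,
        mean_speed=30.0, cell_rate=0.05, cell_dwell_s=10.0, climb_prob=0.0,
        geometry=BeeGeometry(body_length=44.0, body_width=16.0),
        n_brood=0,
    )


def tracking_scene_config(seed: int = 0, n_bees: int = 50) -> SimConfig:
    """Dense tracking scene: 50 identities at hive-like density (about one bee
    per 145x145 px of comb), with crossings and comb-cell interludes."""
    return SimConfig(
        n_bees=n_bees, arena=(1024, 1024), fps=10.0, duration_s=120.0, seed=seed,
        mean_speed=40.0, cell_rate=0.01, cell_dwell_s=8.0,
    )


@dataclass
class GroundTruth:
    """Per-frame per-identity state plus the static brood layout."""

    config: SimConfig
    x: np.ndarray        # (T, n)
    y: np.ndarray
    b: np.ndarray        # (T, n) int, 1 full / 2 cell
    alpha: np.ndarray    # (T, n) degrees, 0 for cell-bees
    visible: np.ndarray  # (T, n) bool
    brood: list[BroodAnnotation]

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_bees(self) -> int:
        return self.x.shape[1]

    def annotations(self, frame: int, occlusion=None) -> list[BeeAnnotation]:
        """Annotatable bees of one frame; with ``occlusion`` (as in
        ``_unoccluded``) bees whose centers are painted over are omitted — a
        labeler cannot mark what is not visible."""
        vis = self._unoccluded(frame, occlusion)
        out = []
        for i in vis:
            out.append(BeeAnnotation(
                x=float(self.x[frame, i]), y=float(self.y[frame, i]),
                b=int(self.b[frame, i]),
                alpha=float(self.alpha[frame, i]) if self.b[frame, i] == 1 else 0.0))
        return out

    def _unoccluded(self, frame: int, occlusion) -> np.ndarray:
        """Visible identities of a frame minus painter's-order occlusions.

        ``occlusion`` is None (keep everything), a center-distance radius in
        px, or "body": drop a bee whose center is painted over by a
        later-drawn bee's body (the geometrically faithful criterion).
        """
        vis = np.flatnonzero(self.visible[frame])
        if occlusion is None or vis.size <= 1:
            return vis
        geom = self.config.geometry
        xs, ys = self.x[frame, vis], self.y[frame, vis]
        keep = []
        for a, i in enumerate(vis):
            covered = False
            for b_idx in range(a + 1, vis.size):  # higher id = drawn on top
                j = vis[b_idx]
                dx, dy = xs[a] - xs[b_idx], ys[a] - ys[b_idx]
                if occlusion == "body":
                    if self.b[frame, j] == 1:
                        ux, uy = heading_vector(self.alpha[frame, j])
                        along = dx * ux + dy * uy
                        across = -dx * uy + dy * ux
                        covered = (along / (geom.body_length / 2)) ** 2 + \
                            (across / (geom.body_width / 2)) ** 2 <= 1.0
                    else:
                        covered = np.hypot(dx, dy) <= geom.body_width / 2
                else:
                    covered = np.hypot(dx, dy) <= float(occlusion)
                if covered:
                    break
            if not covered:
                keep.append(i)
        return np.array(keep, dtype=int)

    def detections(self, occlusion=None) -> pd.DataFrame:
        """All detectable states as a table with a truth_id column.

        ``occlusion`` as in ``_unoccluded``: None, a radius, or "body".
        """
        rows = []
        for t in range(self.n_frames):
            vis = self._unoccluded(t, occlusion)
            for i in vis:
                rows.append((t, t / self.config.fps, self.x[t, i], self.y[t, i],
                             int(self.b[t, i]),
                             float(self.alpha[t, i]) if self.b[t, i] == 1 else np.nan,
                             int(i)))
        return pd.DataFrame(rows, columns=["frame", "t", "x", "y", "b", "alpha", "truth_id"])

    def trajectories(self) -> list:
        """Ground-truth trajectories as tracker Trajectory objects (one per identity)."""
        from .tracker import Trajectory  # local import; tracker imports this module

        out = []
        for i in range(self.n_bees):
            tr = Trajectory(i)
            for t in range(self.n_frames):
                if self.visible[t, i]:
                    tr.append(t, t / self.config.fps, self.x[t, i], self.y[t, i],
                              int(self.b[t, i]),
                              float(self.alpha[t, i]) if self.b[t, i] == 1 else np.nan,
                              row=t * self.n_bees + i)
            if len(tr):
                out.append(tr)
        return out

    def counts(self) -> pd.DataFrame:
        full = ((self.b == 1) & self.visible).sum(axis=1)
        cell = ((self.b == 2) & self.visible).sum(axis=1)
        t = np.arange(self.n_frames) / self.config.fps
        return pd.DataFrame({"t": t, "full": full, "cell": cell,
                             "visible": full + cell,
                             "brood": len(self.brood)})


def _brood_layout(config: SimConfig, rng: np.random.Generator) -> list[BroodAnnotation]:
    """Hex-packed brood patch in the upper-left quadrant."""
    if config.n_brood == 0:
        return []
    h, w = config.arena
    pitch = 2.2 * config.geometry.brood_radius
    cx0, cy0 = w * 0.25, h * 0.25
    cells: list[BroodAnnotation] = []
    ring = 0
    while len(cells) < config.n_brood:
        if ring == 0:
            cand = [(cx0, cy0)]
        else:
            ang = np.linspace(0, 2 * np.pi, 6 * ring, endpoint=False)
            cand = [(cx0 + ring * pitch * np.cos(a), cy0 + ring * pitch * np.sin(a))
                    for a in ang]
        for cx, cy in cand:
            if len(cells) < config.n_brood and 0 <= cx < w and 0 <= cy < h:
                cells.append(BroodAnnotation(x=float(cx), y=float(cy)))
        ring += 1
    return cells


def simulate_trajectories(config: SimConfig) -> GroundTruth:
    """Run the colony motion model; deterministic under config.seed."""
    n, T = config.n_bees, config.n_frames
    h, w = config.arena
    margin = config.geometry.body_length / 2.0
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    x = np.zeros((T, n))
    y = np.zeros((T, n))
    b = np.ones((T, n), dtype=np.int64)
    alpha = np.zeros((T, n))
    visible = np.ones((T, n), dtype=bool)
    brood = _brood_layout(config, rng)
    if n == 0:
        return GroundTruth(config, x, y, b, alpha, visible, brood)

    entrance = config.entrance_region()
    px = rng.uniform(margin, w - margin, size=n)
    py = rng.uniform(margin, h - margin, size=n)
    heading = rng.uniform(0, 360, size=n)
    # start the comb-cell process at its stationary occupancy so short scenes
    # carry a representative share of cell-bees from the first frame
    in_cell = np.zeros(n, dtype=int)      # remaining frames of the cell episode
    occ = config.cell_rate * config.cell_dwell_s
    if occ > 0:
        start_in = rng.random(n) < occ / (1.0 + occ)
        if start_in.any():
            dur = np.maximum(1, rng.exponential(config.cell_dwell_s,
                                                size=int(start_in.sum()))
                             * config.fps)
            in_cell[start_in] = dur.astype(int)
    absent = np.zeros(n, dtype=bool)
    touching: dict[tuple[int, int], int] = {}  # contact pair -> climb frames left
    for t in range(T):
        # cell-episode entry/exit
        start = (~absent) & (in_cell == 0) & (rng.random(n) < config.cell_rate / config.fps)
        if start.any():
            dur = np.maximum(1, rng.exponential(config.cell_dwell_s,
                                                size=int(start.sum())) * config.fps)
            in_cell[start] = dur.astype(int)
        # entrance traffic
        near = entrance.contains(px, py) & ~absent & (in_cell == 0)
        if config.exit_rate > 0:
            leave = near & (rng.random(n) < config.exit_rate / config.fps)
            absent |= leave
        back = absent & (rng.random(n) < config.entry_rate / config.fps)
        if back.any():
            k = int(back.sum())
            ang = rng.uniform(0, 2 * np.pi, k)
            rad = entrance.r * np.sqrt(rng.random(k))
            px[back] = np.clip(entrance.cx + rad * np.cos(ang), margin, w - margin)
            py[back] = np.clip(entrance.cy + rad * np.sin(ang), margin, h - margin)
            heading[back] = rng.uniform(0, 360, k)
            absent[back] = False
        # motion of walking full-bees
        moving = (~absent) & (in_cell == 0)
        if config.mean_speed > 0:
            speed = rng.gamma(config.speed_shape,
                              config.mean_speed / config.speed_shape, size=n)
        else:
            speed = np.zeros(n)
        heading = np.where(moving,
                           heading + np.rad2deg(rng.normal(0, config.turn_std, n)),
                           heading) % 360.0
        ux = np.sin(np.deg2rad(heading))
        uy = -np.cos(np.deg2rad(heading))
        step = np.where(moving, speed / config.fps, 0.0)
        px = px + step * ux
        py = py + step * uy
        # body exclusion: bees cannot interpenetrate; overlapping pairs are
        # pushed apart along the connecting line until their body ellipses no
        # longer overlap (frozen cell-bees stay put, the walker yields).
        # Climb-overs: a fraction of encounters lets one bee walk over the
        # other — the occlusion events a detector faces.
        geom = config.geometry
        a_len, b_wid = geom.body_length / 2.0, geom.body_width / 2.0

        def body_radius(idx, nx, ny):
            """Ellipse radius of bee idx along direction (nx, ny)."""
            if in_cell[idx] > 0:
                return b_wid  # only the abdomen shows
            ux = np.sin(np.deg2rad(heading[idx]))
            uy = -np.cos(np.deg2rad(heading[idx]))
            co = nx * ux + ny * uy
            si = nx * (-uy) + ny * ux
            return a_len * b_wid / np.hypot(b_wid * co, a_len * si)

        reach = geom.body_length if config.exclusion is None else config.exclusion
        if reach > 0 and n > 1:
            dx = px[:, None] - px[None, :]
            dy = py[:, None] - py[None, :]
            dist = np.hypot(dx, dy)
            ii, jj = np.where(np.triu(dist < reach, k=1))
            contacts = set()
            for a_i, a_j in zip(ii, jj):
                if absent[a_i] or absent[a_j]:
                    continue
                d = dist[a_i, a_j]
                if d < 1e-6:
                    nx, ny = 1.0, 0.0
                else:
                    nx, ny = dx[a_i, a_j] / d, dy[a_i, a_j] / d
                if config.exclusion is None:
                    r_req = body_radius(a_i, nx, ny) + body_radius(a_j, nx, ny)
                else:
                    r_req = config.exclusion
                if d >= r_req:
                    continue
                pair = (int(a_i), int(a_j))
                contacts.add(pair)
                if pair not in touching:
                    climb = rng.random() < config.climb_prob
                    dur = int(max(1, rng.exponential(config.climb_duration_s)
                                  * config.fps)) if climb else 0
                    touching[pair] = dur
                if touching[pair] > 0:  # climbing over: no exclusion push
                    touching[pair] -= 1
                    continue
                # bounded push: deep overlaps (e.g., an expired climb)
                # disengage over several frames instead of teleporting
                push = min(r_req - d, 0.3 * geom.body_width)
                w_i = 0.0 if in_cell[a_i] > 0 else (0.5 if in_cell[a_j] == 0 else 1.0)
                w_j = 1.0 - w_i if in_cell[a_j] == 0 else 0.0
                px[a_i] += w_i * push * nx
                py[a_i] += w_i * push * ny
                px[a_j] -= w_j * push * nx
                py[a_j] -= w_j * push * ny
            touching = {p: c for p, c in touching.items() if p in contacts}
        # reflecting walls
        for arr, lim in ((px, w), (py, h)):
            low = arr < margin
            high = arr > lim - margin
            arr[low] = 2 * margin - arr[low]
            arr[high] = 2 * (lim - margin) - arr[high]
            np.clip(arr, margin, lim - margin, out=arr)
        heading = np.where((px <= margin) | (px >= w - margin) |
                           (py <= margin) | (py >= h - margin),
                           (heading + 180.0) % 360.0, heading)

        x[t], y[t] = px, py
        b[t] = np.where(in_cell > 0, 2, 1)
        alpha[t] = np.where(in_cell > 0, 0.0, heading)
        visible[t] = ~absent
        in_cell = np.maximum(0, in_cell - 1)
    return GroundTruth(config, x, y, b, alpha, visible, brood)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _comb_background(config: SimConfig) -> np.ndarray:
    """Hexagonal comb pattern plus frozen speckle, deterministic per seed."""
    h, w = config.arena
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    lam = max(6.0, config.geometry.body_width)
    k = 2 * np.pi / lam
    pat = (np.cos(k * xx)
           + np.cos(k * (xx / 2 + np.sqrt(3) * yy / 2))
           + np.cos(k * (xx / 2 - np.sqrt(3) * yy / 2))) / 3.0
    speckle = rng.normal(0, 1, size=(h, w))
    return config.bg_level + config.comb_contrast * pat + 0.01 * speckle


def _identity_appearance(config: SimConfig):
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n = config.n_bees
    base = 0.55 + 0.35 * rng.random(n)       # per-identity body brightness
    stripe_lambda = rng.uniform(6.0, 14.0, n)
    stripe_phase = rng.uniform(0, 2 * np.pi, n)
    return base, stripe_lambda, stripe_phase


def render_frame(truth: GroundTruth, frame: int, background: np.ndarray | None = None,
                 noise_rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one frame; bees are drawn in identity order (stable occlusion)."""
    config = truth.config
    geom = config.geometry
    img = (_comb_background(config) if background is None else background).copy()
    base, lam, phase = _identity_appearance(config)
    h, w = config.arena
    for i in range(truth.n_bees):
        if not truth.visible[frame, i]:
            continue
        cx, cy = truth.x[frame, i], truth.y[frame, i]
        if truth.b[frame, i] == 1:
            a, bw = geom.body_length / 2.0, geom.body_width / 2.0
            ux, uy = heading_vector(truth.alpha[frame, i])
        else:
            a = bw = geom.body_width / 2.0
            ux, uy = 0.0, -1.0
        r = int(np.ceil(a)) + 1
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 2)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 2)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        along = dx * ux + dy * uy
        across = dx * (-uy) + dy * ux
        inside = (along / a) ** 2 + (across / bw) ** 2 <= 1.0
        tex = base[i] * config.bee_contrast * (
            1.0 + 0.4 * np.cos(2 * np.pi * along / lam[i] + phase[i])
            + 0.3 * along / max(a, 1.0))     # head-to-tail gradient fixes the half-turn
        patch = img[y0:y1, x0:x1]
        patch[inside] = config.bg_level + tex[inside]
    if config.sensor_noise > 0 and noise_rng is not None:
        img = img + noise_rng.normal(0, config.sensor_noise, img.shape)
    return np.clip(img, 0.0, 1.0)


def render_frames(truth: GroundTruth, config: SimConfig | None = None) -> np.ndarray:
    """Render the full sequence as a (T, H, W) float array in [0, 1]."""
    config = config or truth.config
    bg = _comb_background(config)
    noise_rng = (np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
                 if config.sensor_noise > 0 else None)
    return np.stack([render_frame(truth, t, background=bg, noise_rng=noise_rng)
                     for t in range(truth.n_frames)])


# ---------------------------------------------------------------------------
# appearance oracle
# ---------------------------------------------------------------------------

def oracle_embeddings(truth: GroundTruth, config: SimConfig | None = None) -> np.ndarray:
    """(T, n, dim) embeddings: identity centers + per-frame isotropic noise.

    For n <= dim the centers are orthogonal with norm separation/sqrt(2), so
    every between-identity squared distance equals separation**2 exactly.
    """
    config = config or truth.config
    if config.embed_separation <= 0:
        raise ValueError("embedding separation must be positive")
    n, T, d = truth.n_bees, truth.n_frames, config.embed_dim
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    s = config.embed_separation
    if n <= d:
        centers = np.eye(n, d) * (s / np.sqrt(2))
    else:
        g = rng.standard_normal((n, d))
        centers = g / np.linalg.norm(g, axis=1, keepdims=True) * (s / np.sqrt(2))
    emb = np.broadcast_to(centers, (T, n, d)).copy()
    if config.embed_noise > 0:
        emb += rng.normal(0, config.embed_noise, size=(T, n, d))
    return emb


def embeddings_for_detections(det: pd.DataFrame, emb: np.ndarray) -> np.ndarray:
    """Row-align oracle embeddings (T, n, d) with a truth-labeled detections table."""
    return emb[det["frame"].to_numpy(int), det["truth_id"].to_numpy(int)]


# ---------------------------------------------------------------------------
# sociometric count series
# ---------------------------------------------------------------------------

def simulate_count_series(days: float = 14.0, interval_s: float = 120.0,
                          period_h: float = 24.0, phase_h: float = 14.0,
                          baseline: float = 1000.0, amplitude: float = 150.0,
                          trend: float = 0.0, coupling: float = 1.0,
                          brood_baseline: float = 600.0, noise: float = 20.0,
                          cell_baseline: float = 250.0, cell_amplitude: float = 80.0,
                          cell_peak_hour: float = 2.0, seed: int = 0) -> pd.DataFrame:
    """Timelapse count series (visible bees, cell-bees, brood) over several days.

    Visible bees oscillate with the configured period (peak at ``phase_h``
    o'clock) around ``baseline`` with an optional linear ``trend`` per day;
    brood counts are ``brood_baseline`` minus ``coupling`` times the 12-h
    windowed bee excess; cell-bee counts carry a nightly excess peaking at
    ``cell_peak_hour``. Counts are integer and non-negative.
    """
    if days < 2:
        raise ValueError("simulate at least 2 days")
    rng = np.random.default_rng(seed)
    t = np.arange(0, days * 86400.0, interval_s)
    hours = (t / 3600.0) % 24.0
    phase = 2 * np.pi * (t / 3600.0 - phase_h) / period_h
    bees = baseline + amplitude * np.cos(phase) + trend * t / 86400.0 \
        + rng.normal(0, noise, t.size)
    # brood follows the 12-h windowed bee excess with negative coupling
    win = max(1, int(round(12 * 3600 / interval_s)))
    kernel = np.ones(win) / win
    smoothed = np.convolve(bees - baseline, kernel, mode="same")
    brood = brood_baseline - coupling * smoothed + rng.normal(0, noise / 4, t.size)
    # nightly cell-bee excess: von-Mises-shaped bump around the peak hour
    bump = np.exp(2.0 * (np.cos(2 * np.pi * (hours - cell_peak_hour) / 24.0) - 1.0))
    cell = cell_baseline + cell_amplitude * bump + rng.normal(0, noise / 2, t.size)
    full = np.maximum(0, np.round(bees - cell)).astype(int)
    cell = np.maximum(0, np.round(cell)).astype(int)
    brood = np.maximum(0, np.round(brood)).astype(int)
    return pd.DataFrame({"t": t, "full": full, "cell": cell,
                         "visible": full + cell, "brood": brood})
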