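"""Greedy assembly of bee detections into trajectories.

Every detection starts as a length-one trajectory. Frame by frame, open
trajectories are paired with new detections under a class-dependent distance
cutoff c_d (a*sqrt(dt) for walking bees, a/3 for bees inside comb cells,
with a = half a body length) and — in embedding modes — an appearance cutoff
V < c_v, where V is the minimum squared embedding distance to the
trajectory's recent detections. Admissible pairs are ranked by the cost

    D = B*E + V + l          (embedding modes; D = E + l in position mode)

with E the Euclidean distance, l = A*(1 - |T_j|/max|T_i|) a length factor
that favours extending long trajectories, and optionally 0.25*sin^2(da/2)
for the orientation-difference variants. Matching is greedy in increasing D
with deterministic tie-breaking. Unmatched trajectories close once their gap
exceeds a class/location-dependent cutoff (10 s for cell-bees, 1 s near the
hive entrance, 3 s otherwise) and are retained only if they span at least a
minute. Long recordings can be tracked per one-minute segment and stitched
at the boundaries with the same criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import DiskRegion, RectRegion  # region containers are shared

__all__ = [
    "TrackerParams",
    "Trajectory",
    "distance_cutoff",
    "length_factor",
    "visual_similarity",
    "angle_difference_term",
    "pair_cost",
    "match_frame",
    "close_stale",
    "track",
    "track_parallel",
    "score_against_truth",
    "MODES",
]

MODES = ("position", "position+angle", "embedding", "embedding+angle", "rotated+angle")
_EMB_MODES = ("embedding", "embedding+angle", "rotated+angle")
_ANGLE_MODES = ("position+angle", "embedding+angle", "rotated+angle")


@dataclass
class TrackerParams:
    """Matching constants; defaults are the operating point of the method."""

    a: float = 40.0            # half body length, px
    A: float = 30.0            # length-factor scale
    B: float = 0.033           # Euclidean-distance scale in embedding modes
    c_v: float = 1.75          # appearance cutoff on V
    angle_scale: float = 0.25  # weight of the orientation-difference term
    gap_cell: float = 10.0     # s, cell-bee trajectories
    gap_entrance: float = 1.0  # s, trajectories ending near the entrance
    gap_default: float = 3.0   # s
    min_traj: float = 60.0     # s, retention threshold
    lookback: int = 10         # detections considered for V and class votes
    entrance_region: DiskRegion | RectRegion | None = None
    fps: float = 10.0
    dt_in_frames: bool = True  # measure dt of c_d in frames (at fps) vs seconds

    def __post_init__(self):
        if min(self.a, self.A, self.B, self.c_v, self.gap_cell, self.gap_entrance,
               self.gap_default, self.min_traj, self.fps) <= 0:
            raise ValueError("tracker parameters must be positive")
        if self.lookback < 1:
            raise ValueError("lookback must be at least 1")


class Trajectory:
    """Time-ordered detections of one putative identity."""

    __slots__ = ("id", "frames", "ts", "xs", "ys", "bs", "alphas", "rows",
                 "embeddings", "status")

    def __init__(self, traj_id: int):
        self.id = traj_id
        self.frames: list[int] = []
        self.ts: list[float] = []
        self.xs: list[float] = []
        self.ys: list[float] = []
        self.bs: list[int] = []
        self.alphas: list[float] = []
        self.rows: list[int] = []        # row indices into the detections table
        self.embeddings: list[np.ndarray] = []
        self.status = "open"

    def __len__(self):
        return len(self.ts)

    def append(self, frame, t, x, y, b, alpha, row, embedding=None):
        if self.ts and t <= self.ts[-1]:
            raise ValueError("detections must be appended in increasing time")
        self.frames.append(int(frame))
        self.ts.append(float(t))
        self.xs.append(float(x))
        self.ys.append(float(y))
        self.bs.append(int(b))
        self.alphas.append(float(alpha) if alpha is not None and np.isfinite(alpha)
                           else np.nan)
        self.rows.append(int(row))
        if embedding is not None:
            self.embeddings.append(np.asarray(embedding, dtype=float))

    @property
    def span(self) -> float:
        return self.ts[-1] - self.ts[0]

    def majority_full_bee(self, window: int = 10) -> bool:
        recent = self.bs[-min(window, len(self.bs)):]
        return sum(1 for b in recent if b == 1) > len(recent) / 2

    def extend_with(self, other: "Trajectory") -> None:
        for name in ("frames", "ts", "xs", "ys", "bs", "alphas", "rows", "embeddings"):
            getattr(self, name).extend(getattr(other, name))

    def trim_before(self, t0: float) -> "Trajectory | None":
        """Copy without detections earlier than t0; None if nothing remains."""
        k = next((i for i, t in enumerate(self.ts) if t >= t0), None)
        if k is None:
            return None
        out = Trajectory(self.id)
        for name in ("frames", "ts", "xs", "ys", "bs", "alphas", "rows"):
            setattr(out, name, getattr(self, name)[k:])
        if self.embeddings:
            out.embeddings = self.embeddings[k:]
        out.status = self.status
        return out


# ---------------------------------------------------------------------------
# matching criteria
# ---------------------------------------------------------------------------

def distance_cutoff(traj: Trajectory, t_i: float, params: TrackerParams) -> float:
    """c_d = a*sqrt(dt) for mostly-full-bee histories, a/3 for cell-bees."""
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    t_j = traj.ts[-1]
    if t_i <= t_j:
        raise ValueError("t_i must exceed the trajectory's last time")
    if not traj.majority_full_bee(window=10):
        return params.a / 3.0
    dt = (t_i - t_j) * params.fps if params.dt_in_frames else (t_i - t_j)
    return params.a * np.sqrt(dt)


def length_factor(traj_len: int, max_len: int, A: float) -> float:
    """l = A*(1 - |T_j|/max|T_i|); 0 when there are no trajectories yet."""
    if max_len <= 0:
        return 0.0
    if traj_len > max_len:
        raise ValueError("trajectory length exceeds the maximum")
    return A * (1.0 - traj_len / max_len)


def visual_similarity(traj: Trajectory, det_embedding: np.ndarray,
                      lookback: int = 10) -> float:
    """Minimum squared embedding distance over the trajectory's recent window."""
    if not traj.embeddings:
        raise ValueError("trajectory has no embeddings")
    recent = traj.embeddings[-min(lookback, len(traj.embeddings)):]
    d = np.asarray(recent) - np.asarray(det_embedding, dtype=float)
    return float(np.min(np.einsum("ij,ij->i", d, d)))


def angle_difference_term(alpha_traj: float, alpha_det: float) -> float:
    """d_a = sin^2((difference)/2), degrees in; 0 when either angle is missing."""
    if alpha_traj is None or alpha_det is None or \
            not (np.isfinite(alpha_traj) and np.isfinite(alpha_det)):
        return 0.0
    return float(np.sin(np.deg2rad(alpha_det - alpha_traj) / 2.0) ** 2)


def pair_cost(E: float, V: float | None, l: float, mode: str,
              d_a: float = 0.0, params: TrackerParams | None = None) -> float:
    """Matching cost D for one trajectory/detection pair."""
    params = params or TrackerParams()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if E < 0:
        raise ValueError("E must be non-negative")
    if mode in _EMB_MODES:
        if V is None:
            raise ValueError("embedding modes require V")
        D = params.B * E + V + l
    else:
        D = E + l
    if mode in _ANGLE_MODES:
        D += params.angle_scale * d_a
    return D


# ---------------------------------------------------------------------------
# per-frame greedy matching
# ---------------------------------------------------------------------------

@dataclass
class MatchStats:
    n_candidates: int = 0
    n_rejected_distance: int = 0
    n_rejected_appearance: int = 0


def match_frame(open_trajs: list[Trajectory], detections: pd.DataFrame,
                params: TrackerParams, mode: str = "embedding",
                embeddings: np.ndarray | None = None,
                stats: MatchStats | None = None) -> dict[int, Trajectory]:
    """Greedily assign the frame's detections to open trajectories.

    ``detections`` holds one frame (positional rows; the index gives the row
    ids recorded in trajectories); ``embeddings`` aligns with those rows.
    Returns {detection position -> matched trajectory}; unmatched detections
    are left for the caller to seed as new trajectories.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if len(detections) == 0 or not open_trajs:
        return {}
    t_i = float(detections["t"].iloc[0])
    xs = detections["x"].to_numpy(float)
    ys = detections["y"].to_numpy(float)
    alphas = detections["alpha"].to_numpy(float) if "alpha" in detections else \
        np.full(len(detections), np.nan)
    max_len = max(len(tr) for tr in open_trajs)
    pairs = []  # (D, traj_id, det_pos, traj)
    for traj in open_trajs:
        c_d = distance_cutoff(traj, t_i, params)
        E = np.hypot(xs - traj.xs[-1], ys - traj.ys[-1])
        in_range = np.flatnonzero(E <= c_d)
        if stats is not None:
            stats.n_rejected_distance += len(detections) - in_range.size
        l = length_factor(len(traj), max_len, params.A)
        for di in in_range:
            V = None
            if mode in _EMB_MODES:
                if embeddings is None:
                    raise ValueError("embedding modes require detection embeddings")
                V = visual_similarity(traj, embeddings[di], params.lookback)
                if V >= params.c_v:
                    if stats is not None:
                        stats.n_rejected_appearance += 1
                    continue
            d_a = angle_difference_term(traj.alphas[-1], alphas[di]) \
                if mode in _ANGLE_MODES else 0.0
            D = pair_cost(float(E[di]), V, l, mode, d_a, params)
            pairs.append((D, traj.id, int(di), traj))
            if stats is not None:
                stats.n_candidates += 1
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    assigned: dict[int, Trajectory] = {}
    used_trajs: set[int] = set()
    for D, tid, di, traj in pairs:
        if tid in used_trajs or di in assigned:
            continue
        assigned[di] = traj
        used_trajs.add(tid)
    return assigned


def _gap_cutoff(traj: Trajectory, params: TrackerParams) -> float:
    if not traj.majority_full_bee(window=10):
        return params.gap_cell
    if params.entrance_region is not None and \
            bool(params.entrance_region.contains(traj.xs[-1], traj.ys[-1])):
        return params.gap_entrance
    return params.gap_default


def close_stale(open_trajs: list[Trajectory], t_now: float, params: TrackerParams
                ) -> tuple[list[Trajectory], list[Trajectory], list[Trajectory]]:
    """Split (still open, finished, discarded) by the gap and retention rules."""
    still, finished, discarded = [], [], []
    for traj in open_trajs:
        if t_now - traj.ts[-1] > _gap_cutoff(traj, params):
            if traj.span >= params.min_traj:
                traj.status = "finished"
                finished.append(traj)
            else:
                traj.status = "discarded"
                discarded.append(traj)
        else:
            still.append(traj)
    return still, finished, discarded


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _track_core(det: pd.DataFrame, params: TrackerParams, mode: str,
                embeddings: np.ndarray | None, next_id: int, flush: bool
                ) -> tuple[list[Trajectory], list[Trajectory], list[Trajectory], int]:
    """Sequential matching over a sorted detections table.

    Returns (finished, discarded, open_at_end, next_id); with ``flush`` the
    open set is emptied through the retention rule instead of being returned.
    """
    frames = det["frame"].to_numpy()
    if np.any(np.diff(frames) < 0):
        raise ValueError("detections must be sorted by frame")
    open_trajs: list[Trajectory] = []
    finished: list[Trajectory] = []
    discarded: list[Trajectory] = []
    for frame, group in det.groupby("frame", sort=True):
        t_now = float(group["t"].iloc[0])
        if open_trajs:
            open_trajs, fin, dis = close_stale(open_trajs, t_now, params)
            finished += fin
            discarded += dis
        pos = group.reset_index()  # keep original row ids in 'index'
        emb = embeddings[group.index.to_numpy()] if embeddings is not None else None
        assigned = match_frame(open_trajs, pos, params, mode, emb)
        for di, traj in assigned.items():
            r = pos.iloc[di]
            traj.append(r["frame"], r["t"], r["x"], r["y"], r["b"], r.get("alpha"),
                        r["index"], emb[di] if emb is not None else None)
        for di in range(len(pos)):
            if di in assigned:
                continue
            traj = Trajectory(next_id)
            next_id += 1
            r = pos.iloc[di]
            traj.append(r["frame"], r["t"], r["x"], r["y"], r["b"], r.get("alpha"),
                        r["index"], emb[di] if emb is not None else None)
            open_trajs.append(traj)
    if flush:
        for traj in open_trajs:
            if traj.span >= params.min_traj:
                traj.status = "finished"
                finished.append(traj)
            else:
                traj.status = "discarded"
                discarded.append(traj)
        open_trajs = []
    return finished, discarded, open_trajs, next_id


def _prepare(det: pd.DataFrame) -> pd.DataFrame:
    det = det.reset_index(drop=True)
    if "alpha" not in det.columns:
        det = det.assign(alpha=np.nan)
    return det


def track(det: pd.DataFrame, params: TrackerParams | None = None,
          mode: str = "embedding", embeddings: np.ndarray | None = None
          ) -> list[Trajectory]:
    """Assemble trajectories from a sorted detections table.

    ``embeddings`` (rows aligned with ``det``) are required in embedding
    modes. Returns the retained (finished) trajectories.
    """
    params = params or TrackerParams()
    det = _prepare(det)
    finished, _, _, _ = _track_core(det, params, mode, embeddings, next_id=0, flush=True)
    return sorted(finished, key=lambda tr: tr.id)


def _stitch_cost(left: Trajectory, right: Trajectory, params: TrackerParams,
                 mode: str, max_len: int) -> float | None:
    t_i = right.ts[0]
    if t_i <= left.ts[-1]:
        return None
    if t_i - left.ts[-1] > _gap_cutoff(left, params):
        return None
    c_d = distance_cutoff(left, t_i, params)
    E = float(np.hypot(right.xs[0] - left.xs[-1], right.ys[0] - left.ys[-1]))
    if E > c_d:
        return None
    V = None
    if mode in _EMB_MODES:
        V = visual_similarity(left, right.embeddings[0], params.lookback)
        if V >= params.c_v:
            return None
    d_a = angle_difference_term(left.alphas[-1], right.alphas[0]) \
        if mode in _ANGLE_MODES else 0.0
    return pair_cost(E, V, length_factor(len(left), max_len, params.A), mode, d_a, params)


def track_parallel(det: pd.DataFrame, params: TrackerParams | None = None,
                   mode: str = "embedding", embeddings: np.ndarray | None = None,
                   segment_s: float = 60.0) -> list[Trajectory]:
    """Track per time segment, then stitch segment boundaries with the same criteria.

    Stitching is iterated to a fixed point so a carried trajectory can absorb
    a chain of short within-segment pieces; trajectory pieces then close at
    each boundary under the ordinary gap/retention rules.
    """
    params = params or TrackerParams()
    det = _prepare(det)
    t_all = det["t"].to_numpy(float)
    seg_ids = (t_all // segment_s).astype(int)
    finished: list[Trajectory] = []
    carried: list[Trajectory] = []  # open at the previous boundary
    next_id = 0
    segments = np.unique(seg_ids)
    warm_s = params.lookback / params.fps  # context so V has its full window
    for seg in segments:
        seg_start = seg * segment_s
        lo = seg_start - (warm_s if seg != segments[0] else 0.0)
        sub = det[(t_all >= lo) & (seg_ids <= seg) & (t_all < (seg + 1) * segment_s)]
        fin, discarded, opened, next_id = _track_core(sub, params, mode, embeddings,
                                                      next_id, flush=False)

        def trimmed(trs):
            out = []
            for tr in trs:
                cut = tr.trim_before(seg_start)
                if cut is not None and len(cut):
                    out.append(cut)
            return out

        if seg != segments[0]:
            fin, discarded, opened = trimmed(fin), trimmed(discarded), trimmed(opened)
        pieces = sorted(fin + opened, key=lambda tr: (tr.ts[0], tr.id))
        if carried:
            # short pieces near the segment start may continue a carried
            # trajectory even though the segment run gap-closed them
            early = [tr for tr in discarded
                     if tr.ts[0] - seg_start <= params.gap_cell]
            remaining = {id(tr): tr for tr in pieces + early}
            while True:
                pairs = []
                max_len = max(len(tr) for tr in carried)
                for left in carried:
                    for right in remaining.values():
                        D = _stitch_cost(left, right, params, mode, max_len)
                        if D is not None:
                            pairs.append((D, left.id, right.id, left, right))
                pairs.sort(key=lambda p: (p[0], p[1], p[2]))
                used_l: set[int] = set()
                merges = []
                for D, lid, rid, left, right in pairs:
                    if lid in used_l or id(right) not in remaining:
                        continue
                    used_l.add(lid)
                    del remaining[id(right)]
                    merges.append((left, right))
                if not merges:
                    break
                for left, right in merges:
                    left.extend_with(right)
            early_ids = {id(tr) for tr in early}
            pieces = carried + sorted(
                (tr for tr in remaining.values() if id(tr) not in early_ids),
                key=lambda tr: (tr.ts[0], tr.id))
        # close pieces at the boundary under the ordinary gap rules
        t_boundary = (seg + 1) * segment_s
        if seg == segments[-1]:
            for traj in pieces:
                if traj.span >= params.min_traj:
                    traj.status = "finished"
                    finished.append(traj)
                else:
                    traj.status = "discarded"
            carried = []
        else:
            carried, fin_b, _ = close_stale(pieces, t_boundary, params)
            finished += fin_b
    return sorted(finished, key=lambda tr: (tr.ts[0], tr.id))


# ---------------------------------------------------------------------------
# scoring against ground truth
# ---------------------------------------------------------------------------

def score_against_truth(trajectories: list[Trajectory], det: pd.DataFrame,
                        majority: float = 0.8, coverage: float = 0.8) -> dict:
    """Proportion of correct trajectories relative to mean detections per frame.

    A trajectory is correct when one ground-truth identity accounts for at
    least ``majority`` of its detections and those detections cover at least
    ``coverage`` of that identity's visible frames; each identity is credited
    at most once.
    """
    if "truth_id" not in det.columns:
        raise ValueError("detections table must carry a truth_id column")
    det = det.reset_index(drop=True)
    truth_counts = det["truth_id"].value_counts()
    n_frames = det["frame"].nunique()
    mean_dets = len(det) / max(1, n_frames)
    credited: set[int] = set()
    n_correct = 0
    for traj in trajectories:
        ids = det.loc[traj.rows, "truth_id"].to_numpy()
        vals, counts = np.unique(ids, return_counts=True)
        m = int(vals[np.argmax(counts)])
        frac = counts.max() / len(ids)
        if frac < majority or m in credited:
            continue
        if counts.max() < coverage * truth_counts[m]:
            continue
        credited.add(m)
        n_correct += 1
    return {"n_correct": n_correct, "mean_detections": mean_dets,
            "proportion": n_correct / mean_dets if mean_dets else 0.0}


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories to a table traj_id,frame,t,x,y,b,alpha."""
    rows = []
    for traj in trajectories:
        for k in range(len(traj)):
            rows.append((traj.id, traj.frames[k], traj.ts[k], traj.xs[k],
                         traj.ys[k], traj.bs[k], traj.alphas[k]))
    return pd.DataFrame(rows, columns=["traj_id", "frame", "t", "x", "y", "b", "alpha"])
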