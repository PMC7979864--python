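"""Colony-level sociometry and per-trajectory motion analytics.

Sociometric statistics operate on count time series sampled every 1–2 min
over days to months: spectral detection of the ~24-h rhythm, a Rayleigh test
for the clustering of nightly cell-bee excess hours, 12-h-windowed
bee/brood correlation, and bee-to-brood distance comparisons between
classes. Motion analytics summarize individual trajectories from 10-FPS
tracking: speed, angular speed, path length, motion span, a diffusion
coefficient from the mean-squared displacement, comb-cell visits, and a
permutation test for the spatial enrichment of selected trajectories (e.g.,
putative waggle dancers) near the hive entrance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.spatial import cKDTree

__all__ = [
    "CountSeries",
    "MotionSummary",
    "periodogram",
    "rayleigh_test",
    "nightly_high_counts",
    "windowed_correlation",
    "brood_distance_stats",
    "motion_summary",
    "entrance_enrichment",
]


@dataclass
class CountSeries:
    """Uniformly sampled per-frame colony counts."""

    t: np.ndarray          # s
    full: np.ndarray
    cell: np.ndarray
    brood: np.ndarray | None = None
    interval_s: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for name in ("full", "cell", "brood"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v)
            if (v < 0).any():
                raise ValueError(f"{name} counts must be non-negative")
            setattr(self, name, v)
        if self.interval_s is None and self.t.size > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0]):
                raise ValueError("count series must be uniformly sampled")
            self.interval_s = float(dt[0])

    @property
    def visible(self) -> np.ndarray:
        return self.full + self.cell

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountSeries":
        return cls(t=df["t"].to_numpy(), full=df["full"].to_numpy(),
                   cell=df["cell"].to_numpy(),
                   brood=df["brood"].to_numpy() if "brood" in df else None)


@dataclass(frozen=True)
class MotionSummary:
    """Aggregate motion metrics of one trajectory (px and seconds unless scaled)."""

    mean_speed: float            # px/s
    mean_angular_speed: float    # rad/s
    path_length: float           # px
    motion_span: float           # px, bbox diagonal
    diffusion_coefficient: float  # px^2/s
    cell_visits: int


# ---------------------------------------------------------------------------
# spectral / circular statistics
# ---------------------------------------------------------------------------

def periodogram(values: np.ndarray, interval_s: float,
                min_period_h: float = 2.0, max_period_h: float = 48.0):
    """Power spectral density of a mean-subtracted count series.

    Returns (frequencies in 1/h, power, dominant period in h), the dominant
    period being the power maximum among periods in [min_period_h,
    max_period_h]. Requires at least two days of data.
    """
    values = np.asarray(values, dtype=float)
    if values.size * interval_s < 2 * 86400:
        raise ValueError("periodogram requires at least 2 days of data")
    fs = 3600.0 / interval_s  # samples per hour
    freqs, power = signal.periodogram(values - values.mean(), fs=fs)
    with np.errstate(divide="ignore"):
        periods = 1.0 / freqs
    band = (periods >= min_period_h) & (periods <= max_period_h)
    if not band.any():
        raise ValueError("no frequency bin inside the period band")
    dominant = float(periods[band][np.argmax(power[band])])
    return freqs, power, dominant


def rayleigh_test(hours: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity for hours on the 24-h clock.

    Returns (z = n * Rbar^2, p) using the standard finite-n corrected
    approximation p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)), R = n*Rbar.
    p is monotone decreasing in the resultant length at fixed n.
    """
    hours = np.asarray(hours, dtype=float)
    n = hours.size
    if n < 5:
        raise ValueError("rayleigh_test requires at least 5 samples")
    ang = 2 * np.pi * hours / 24.0
    C, S = np.cos(ang).sum(), np.sin(ang).sum()
    R = np.hypot(C, S)
    z = R ** 2 / n
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - R ** 2)) - (1 + 2 * n)))
    return float(z), min(1.0, p)


def nightly_high_counts(t: np.ndarray, cell_counts: np.ndarray,
                        min_day_coverage: float = 0.5):
    """Hour histogram of above-daily-median cell-bee counts.

    For each calendar day with at least ``min_day_coverage`` of its expected
    samples, samples strictly above that day's median are binned into 24 1-h
    bins. Returns (24-bin histogram, circular mean hour of the above-median
    samples, the hours themselves).
    """
    t = np.asarray(t, dtype=float)
    cell = np.asarray(cell_counts, dtype=float)
    if t.size < 2:
        return np.zeros(24, dtype=int), np.nan, np.array([])
    interval = np.median(np.diff(t))
    expected = 86400.0 / interval
    days = (t // 86400).astype(int)
    hist = np.zeros(24, dtype=int)
    high_hours = []
    for day in np.unique(days):
        sel = days == day
        if sel.sum() < min_day_coverage * expected:
            continue
        med = np.median(cell[sel])
        above = sel & (cell > med)
        hrs = (t[above] % 86400) / 3600.0
        high_hours.append(hrs)
        hist += np.histogram(hrs, bins=24, range=(0, 24))[0]
    if not high_hours or sum(h.size for h in high_hours) == 0:
        return hist, np.nan, np.array([])
    hours = np.concatenate(high_hours)
    ang = 2 * np.pi * hours / 24.0
    mean_hour = (np.rad2deg(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()))
                 / 360.0 * 24.0) % 24.0
    return hist, float(mean_hour), hours


def windowed_correlation(t_bees: np.ndarray, bees: np.ndarray,
                         t_brood: np.ndarray, brood: np.ndarray,
                         window_s: float = 12 * 3600.0) -> tuple[float, float]:
    """Pearson correlation of window-averaged, mean-subtracted series.

    Both series are averaged inside common ``window_s`` windows; each
    windowed series has its mean removed before correlating. Returns (r, p).
    """
    def window_means(t, v):
        idx = (np.asarray(t, float) // window_s).astype(int)
        df = pd.DataFrame({"w": idx, "v": np.asarray(v, float)})
        return df.groupby("w")["v"].mean()

    wb = window_means(t_bees, bees)
    wr = window_means(t_brood, brood)
    common = wb.index.intersection(wr.index)
    if len(common) < 3:
        raise ValueError("windowed correlation requires at least 3 common windows")
    xb = wb.loc[common].to_numpy() - wb.loc[common].mean()
    xr = wr.loc[common].to_numpy() - wr.loc[common].mean()
    r, p = stats.pearsonr(xb, xr)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def brood_distance_stats(det: pd.DataFrame, brood_xy: np.ndarray,
                         px_per_mm: float = 1.0, min_n: int = 2) -> dict:
    """Nearest-brood distances per detection and a cell-bee vs full-bee rank-sum test.

    Returns per-class mean distances in mm, their difference (positive when
    cell-bees sit closer to the brood), and the two-sided Wilcoxon rank-sum p.
    """
    brood_xy = np.asarray(brood_xy, dtype=float)
    if brood_xy.size == 0:
        raise ValueError("brood set is empty")
    tree = cKDTree(brood_xy.reshape(-1, 2))
    d_px, _ = tree.query(det[["x", "y"]].to_numpy(float))
    d_mm = d_px / px_per_mm
    b = det["b"].to_numpy(int)
    d_cell, d_full = d_mm[b == 2], d_mm[b == 1]
    if len(d_cell) < min_n or len(d_full) < min_n:
        raise ValueError(
            f"need at least {min_n} detections per class for the rank-sum test "
            f"(got {len(d_full)} full-bee, {len(d_cell)} cell-bee)")
    stat, p = stats.ranksums(d_full, d_cell)
    return {
        "mean_cell_mm": float(d_cell.mean()),
        "mean_full_mm": float(d_full.mean()),
        "difference_mm": float(d_full.mean() - d_cell.mean()),
        "statistic": float(stat),
        "p": float(p),
        "distances_mm": d_mm,
    }


# ---------------------------------------------------------------------------
# motion analytics
# ---------------------------------------------------------------------------

def motion_summary(x: np.ndarray, y: np.ndarray, b: np.ndarray | None = None,
                   fps: float = 10.0, px_per_mm: float | None = None,
                   msd_max_lag_s: float = 10.0) -> MotionSummary:
    """Motion metrics of one trajectory sampled at ``fps``.

    Speed comes from successive displacements; angular speed from successive
    displacement-heading changes wrapped to (-pi, pi]; the diffusion
    coefficient is slope/4 of a linear MSD fit over lags up to
    ``msd_max_lag_s``. Passing ``px_per_mm`` converts distances to mm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("motion_summary requires at least 2 detections")
    scale = 1.0 if px_per_mm is None else 1.0 / px_per_mm
    dx, dy = np.diff(x), np.diff(y)
    step = np.hypot(dx, dy)
    mean_speed = float(step.mean() * fps) * scale
    path_length = float(step.sum()) * scale
    span = float(np.hypot(x.max() - x.min(), y.max() - y.min())) * scale
    moving = step > 0
    if moving.sum() >= 2:
        headings = np.arctan2(dy[moving], dx[moving])
        dth = np.diff(headings)
        dth = (dth + np.pi) % (2 * np.pi) - np.pi
        mean_ang = float(np.abs(dth).mean() * fps)
    else:
        mean_ang = 0.0
    max_lag = max(1, min(int(round(msd_max_lag_s * fps)), x.size - 1))
    lags = np.arange(1, max_lag + 1)
    msd = np.array([np.mean((x[k:] - x[:-k]) ** 2 + (y[k:] - y[:-k]) ** 2)
                    for k in lags])
    slope = np.polyfit(lags / fps, msd, 1)[0] if lags.size > 1 else msd[0] * fps
    diffusion = float(max(0.0, slope) / 4.0) * scale ** 2
    visits = 0
    if b is not None:
        b = np.asarray(b, dtype=int)
        visits = int(((b[:-1] == 1) & (b[1:] == 2)).sum())
    return MotionSummary(mean_speed, mean_ang, path_length, span, diffusion, visits)


def entrance_enrichment(positions: list[np.ndarray], top_idx: np.ndarray,
                        region, n_perm: int = 999, seed: int = 0) -> dict:
    """Fold enrichment of selected trajectories' positions inside a region.

    ``positions`` holds one (m_i, 2) array of (x, y) per trajectory;
    ``top_idx`` indexes the selected (e.g., highest-angular-speed)
    trajectories. The observed in-region fraction of the selected
    trajectories' positions is divided by its mean under random reselection;
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if region is None:
        raise ValueError("entrance region is required")
    if n_perm < 999:
        raise ValueError("use at least 999 permutations")
    top_idx = np.asarray(top_idx, dtype=int)
    k, n = top_idx.size, len(positions)
    if k == 0 or k > n:
        raise ValueError("invalid top-k selection")
    inside = np.array([float(np.mean(region.contains(p[:, 0], p[:, 1])))
                       if len(p) else 0.0 for p in positions])
    weights = np.array([len(p) for p in positions], dtype=float)

    def frac(idx):
        w = weights[idx]
        return float((inside[idx] * w).sum() / w.sum()) if w.sum() else 0.0

    observed = frac(top_idx)
    rng = np.random.default_rng(seed)
    perm = np.array([frac(rng.choice(n, size=k, replace=False))
                     for _ in range(n_perm)])
    baseline = perm.mean()
    fold = observed / baseline if baseline > 0 else np.inf
    p = (1 + int((perm >= observed).sum())) / (1 + n_perm)
    return {"fold": float(fold), "p": float(p), "observed": observed,
            "baseline": float(baseline)}
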