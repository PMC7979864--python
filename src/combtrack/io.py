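"""Frame and table I/O.

All tabular exchange is CSV with header rows (UTF-8, full float precision);
frames are PNG/TIFF directories or multi-page TIFFs; configuration is YAML.
The frame index is authoritative for time — timestamps are derived from the
configured frame rate.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .targets import BeeAnnotation, BroodAnnotation

__all__ = [
    "SchemaError",
    "read_frames",
    "write_frames",
    "read_detections",
    "write_detections",
    "read_trajectories",
    "write_trajectories",
    "read_counts",
    "write_counts",
    "read_bee_annotations",
    "read_brood_annotations",
    "read_embeddings",
    "write_embeddings",
    "write_targets",
    "read_targets",
    "default_config",
    "load_config",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


class SchemaError(ValueError):
    """A table is missing required columns or violates a column contract."""


def _to_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float64) / 65535.0
    return img.astype(np.float64)


def read_frames(path: str | Path):
    """Iterate (index, image) over a frame folder or a multi-page TIFF.

    Folder frames are taken in lexicographic filename order. All frames must
    share one shape; a corrupt file raises an error naming it.
    """
    path = Path(path)
    shape = None
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        for i, f in enumerate(files):
            try:
                img = _to_float(iio.imread(f))
            except Exception as exc:  # noqa: BLE001 - report the offending file
                raise OSError(f"could not read frame file {f}: {exc}") from exc
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"frame {f} has shape {img.shape}, expected {shape}")
            yield i, img
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{path} does not hold a 2D frame stack")
        for i in range(arr.shape[0]):
            yield i, _to_float(arr[i])
    else:
        raise ValueError(f"{path} is neither a frame directory nor a TIFF")


def write_frames(frames: np.ndarray, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"{i:06d}.png"
        iio.imwrite(p, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _require(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {', '.join(missing)}")


def _check_classes(df: pd.DataFrame, what: str) -> None:
    bad = set(df["b"].dropna().astype(int)) - {1, 2}
    if bad:
        raise SchemaError(f"{what} table has invalid class labels: {sorted(bad)}")


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("frame", "t", "x", "y", "b"), "detections")
    _check_classes(df, "detections")
    if "alpha" not in df.columns:
        df["alpha"] = np.nan
    return df


def write_detections(df: pd.DataFrame, path) -> None:
    _require(df, ("frame", "t", "x", "y", "b"), "detections")
    df.to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("traj_id", "frame", "t", "x", "y", "b"), "trajectories")
    _check_classes(df, "trajectories")
    return df


def write_trajectories(df: pd.DataFrame, path) -> None:
    _require(df, ("traj_id", "frame", "t", "x", "y", "b"), "trajectories")
    df.to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("t", "full", "cell"), "counts")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    _require(df, ("t", "full", "cell"), "counts")
    df.to_csv(path, index=False)


def read_bee_annotations(path) -> dict[int, list[BeeAnnotation]]:
    """Bee annotation CSV (frame,x,y,b,alpha) -> per-frame annotation lists."""
    df = pd.read_csv(path)
    _require(df, ("frame", "x", "y", "b", "alpha"), "bee annotations")
    _check_classes(df, "bee annotations")
    out: dict[int, list[BeeAnnotation]] = {}
    for _, r in df.iterrows():
        out.setdefault(int(r["frame"]), []).append(
            BeeAnnotation(x=float(r["x"]), y=float(r["y"]), b=int(r["b"]),
                          alpha=float(r["alpha"]) if int(r["b"]) == 1 else 0.0))
    return out


def read_brood_annotations(path) -> dict[int, list[BroodAnnotation]]:
    df = pd.read_csv(path)
    _require(df, ("frame", "x", "y"), "brood annotations")
    out: dict[int, list[BroodAnnotation]] = {}
    for _, r in df.iterrows():
        out.setdefault(int(r["frame"]), []).append(
            BroodAnnotation(x=float(r["x"]), y=float(r["y"])))
    return out


def write_embeddings(det: pd.DataFrame, embeddings: np.ndarray, path) -> None:
    """Embeddings as rows of floats keyed by (frame, detection row)."""
    emb = np.asarray(embeddings)
    cols = {f"e{i}": emb[:, i] for i in range(emb.shape[1])}
    out = pd.DataFrame({"frame": det["frame"].to_numpy(), "det": np.arange(len(det)),
                        **cols})
    out.to_csv(path, index=False)


def read_embeddings(path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("e")]
    if not cols:
        raise SchemaError("embeddings table has no embedding columns")
    return df[sorted(cols, key=lambda c: int(c[1:]))].to_numpy(float)


def write_targets(target, path) -> None:
    """Persist a rendered SegmentationTarget as an NPZ archive.

    Arrays: ``class_map`` (int), ``angle_map`` (float, -1 background) and
    ``weight_map`` (float) under those keys.
    """
    np.savez_compressed(path, class_map=target.class_map,
                        angle_map=target.angle_map, weight_map=target.weight_map)


def read_targets(path):
    from .targets import SegmentationTarget

    data = np.load(path)
    return SegmentationTarget(class_map=data["class_map"],
                              angle_map=data["angle_map"],
                              weight_map=data["weight_map"])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """All numeric defaults of the pipeline in one nested mapping."""
    return {
        "version": 1,
        "detector": {
            "encoder_widths": [16, 32, 64, 128, 256],
            "n_classes": 3, "recurrent": True,
            "tile": 512, "tile_margin": 50,
            "blob_min": 10, "blob_max": 1000, "lr": 1.0e-4, "fps": 10.0,
        },
        "geometry": {
            "body_length": 80.0, "body_width": 30.0,
            "region_fraction": 1.0 / 3.0, "brood_radius": 10.0,
        },
        "embedding": {
            "dim": 64, "margin": 0.5, "batch_size": 32, "lr": 1.0e-4,
            "crop_size": 128, "augment": False, "mask_background": False,
        },
        "tracker": {
            "a": 40.0, "A": 30.0, "B": 0.033, "c_v": 1.75, "angle_scale": 0.25,
            "gap_cell": 10.0, "gap_entrance": 1.0, "gap_default": 3.0,
            "min_traj": 60.0, "lookback": 10, "fps": 10.0,
        },
        "px_per_mm": 4.4,
        "entrance": {"shape": "disk", "cx": 256.0, "cy": 511.0, "r": 64.0},
    }


def load_config(path=None) -> dict:
    """Defaults, deep-updated by an optional YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg
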