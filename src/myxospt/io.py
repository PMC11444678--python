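"""Movies and on-disk formats.

A :class:`Movie` is a T×H×W intensity stack with physical calibration
(pixel size in nm, frame interval in s).  On disk it is a multi-page 16-bit
grayscale TIFF plus a JSON sidecar carrying the calibration, seed and config
hash.  Tables (localizations, trajectories, ground truth, kinematics) are
plain CSV via pandas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

LOCALIZATION_COLUMNS = [
    "frame", "x_nm", "y_nm", "amplitude", "sigma_nm", "offset", "rss", "cell_id",
]


@dataclass
class Movie:
    """An image stack with acquisition calibration attached."""

    frames: np.ndarray  # (T, H, W)
    pixel_size_nm: float
    frame_interval_s: float
    source: str = "memory"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise ValueError("frames must be a T×H×W stack with T,H,W ≥ 1")
        if not (self.pixel_size_nm > 0 and self.frame_interval_s > 0):
            raise ValueError("calibration values must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def sidecar_path(tiff_path: str | Path) -> Path:
    p = Path(tiff_path)
    return p.with_suffix(p.suffix + ".json")


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as 16-bit TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.clip(np.rint(movie.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "pixel_size_nm": movie.pixel_size_nm,
        "frame_interval_s": movie.frame_interval_s,
        "source": movie.source,
        **movie.meta,
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_movie(path: str | Path) -> Movie:
    """Read a TIFF stack; calibration comes from the JSON sidecar."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sp = sidecar_path(path)
    if not sp.exists():
        raise FileNotFoundError(f"missing calibration sidecar: {sp}")
    meta = json.loads(sp.read_text())
    for key in ("pixel_size_nm", "frame_interval_s"):
        if key not in meta:
            raise KeyError(f"sidecar {sp} is missing required key '{key}'")
    return Movie(
        frames=frames,
        pixel_size_nm=float(meta.pop("pixel_size_nm")),
        frame_interval_s=float(meta.pop("frame_interval_s")),
        source=str(path),
        meta=meta,
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
    return path


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
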