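"""Motion classification and population summaries.

The central rule: a tracked particle that explored an area smaller than one
camera pixel (160 nm × 160 nm) during its 0.4–1.2 s in focus is *immotile* —
in gliding bacteria these are motor proteins bound in focal-adhesion
complexes that stay fixed relative to the substrate.  Everything else is
motile; motile tracks get a diffusion coefficient from an ordinary
least-squares fit of the mean-squared displacement (MSD = 4·D·Δt + b in
2-D, the intercept b absorbing localization noise), and a coarse
stationary / directed / diffusive mode from the MSD scaling exponent α.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ClassifyConfig
from .io import Movie

NM2_PER_UM2 = 1e6


def bounding_span(xy_nm: np.ndarray) -> tuple[float, float]:
    """Per-axis extent (max − min) of a track's point set, in nm.

    A pure function of the point set: order-independent.
    """
    xy = np.asarray(xy_nm, dtype=float)
    if xy.size == 0:
        raise ValueError("empty trajectory")
    ext = xy.max(axis=0) - xy.min(axis=0)
    return float(ext[0]), float(ext[1])


def classify_immotile(xy_nm: np.ndarray, box_nm: float = 160.0) -> bool:
    """One-pixel rule: immotile iff both spans fit in a ``box_nm`` square."""
    sx, sy = bounding_span(xy_nm)
    return sx <= box_nm and sy <= box_nm


def compute_msd(xy_nm: np.ndarray) -> np.ndarray:
    """Time-averaged MSD over all ordered pairs, lags 1..T−1.

    Returns an (T−1, 2) array of (lag_index, msd_um2).
    """
    xy = np.asarray(xy_nm, dtype=float)
    t = len(xy)
    if t < 2:
        raise ValueError("need at least 2 points for an MSD")
    out = np.empty((t - 1, 2))
    for k in range(1, t):
        d = xy[k:] - xy[:-k]
        out[k - 1] = (k, np.mean(np.sum(d * d, axis=1)) / NM2_PER_UM2)
    return out


def estimate_D(
    msd: np.ndarray,
    dt_s: float,
    fit_lags: int = 3,
) -> tuple[float, float, bool]:
    """OLS fit MSD = 4·D·Δt + b over the first ``fit_lags`` lags.

    Returns (D_hat µm²/s, intercept µm², clamped).  A negative slope is
    clamped to D = 0 and flagged.
    """
    msd = np.asarray(msd, dtype=float)
    if len(msd) < fit_lags:
        raise ValueError(f"need ≥ {fit_lags} MSD points, got {len(msd)}")
    x = msd[:fit_lags, 0] * dt_s
    y = msd[:fit_lags, 1]
    slope, intercept = np.polyfit(x, y, 1)
    clamped = slope < 0
    d_hat = max(slope, 0.0) / 4.0
    return float(d_hat), float(intercept), bool(clamped)


def msd_alpha(msd: np.ndarray, dt_s: float, n_lags: int = 4) -> Optional[float]:
    """Scaling exponent α from log–log OLS of MSD over the first lags."""
    msd = np.asarray(msd, dtype=float)
    if len(msd) < n_lags:
        return None
    x = msd[:n_lags, 0] * dt_s
    y = msd[:n_lags, 1]
    if (y <= 0).any():
        return None
    alpha, _ = np.polyfit(np.log(x), np.log(y), 1)
    return float(alpha)


def classify_mode(
    xy_nm: np.ndarray,
    dt_s: float,
    alpha_directed: float = 1.5,
    box_nm: float = 160.0,
) -> str:
    """stationary (one-pixel rule) / directed (α ≥ threshold) / diffusive.

    Tracks too short for 4 MSD lags (fewer than 5 points) that are not
    stationary come back ``ambiguous``.
    """
    if classify_immotile(xy_nm, box_nm):
        return "stationary"
    alpha = msd_alpha(compute_msd(xy_nm), dt_s, n_lags=4)
    if alpha is None:
        return "ambiguous"
    return "directed" if alpha >= alpha_directed else "diffusive"


@dataclass
class PopulationSummary:
    """Headline numbers of one condition: counts, fractions, D statistics."""

    n_total: int
    n_immotile: int
    immotile_fraction: float
    mode_counts: dict
    d_motile_mean: Optional[float]
    d_motile_sd: Optional[float]
    d_motile_sem: Optional[float]
    n_motile: int
    provenance: dict

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_immotile": self.n_immotile,
            "immotile_fraction": self.immotile_fraction,
            "immotile_percent": 100.0 * self.immotile_fraction,
            "mode_counts": self.mode_counts,
            "d_motile_mean_um2_s": self.d_motile_mean,
            "d_motile_sd_um2_s": self.d_motile_sd,
            "d_motile_sem_um2_s": self.d_motile_sem,
            "n_motile": self.n_motile,
            "provenance": self.provenance,
        }


def analyze_trajectories(
    trajectories: pd.DataFrame,
    dt_s: float,
    cfg: ClassifyConfig | None = None,
) -> pd.DataFrame:
    """Per-track motion summary table.

    Input: localization table with a ``particle_id`` column (already passed
    through the 4–12-frame filter).  Output columns: particle_id, cell_id,
    n_frames, span_x_nm, span_y_nm, immotile, D_um2_s, msd_intercept_um2,
    d_clamped, alpha, mode.
    """
    cfg = cfg or ClassifyConfig()
    rows = []
    for pid, grp in trajectories.groupby("particle_id"):
        grp = grp.sort_values("frame")
        n = len(grp)
        if not (cfg.min_frames <= n <= cfg.max_frames):
            raise ValueError(
                f"track {pid} has {n} frames; classify only tracks inside the "
                f"{cfg.min_frames}–{cfg.max_frames}-frame window"
            )
        xy = grp[["x_nm", "y_nm"]].to_numpy()
        sx, sy = bounding_span(xy)
        immotile = sx <= cfg.box_nm and sy <= cfg.box_nm
        msd = compute_msd(xy)
        d_hat = intercept = np.nan
        clamped = False
        if not immotile and len(msd) >= cfg.fit_lags:
            d_hat, intercept, clamped = estimate_D(msd, dt_s, cfg.fit_lags)
        alpha = msd_alpha(msd, dt_s)
        mode = classify_mode(xy, dt_s, cfg.alpha_directed, cfg.box_nm)
        cell_id = grp["cell_id"].iloc[0] if "cell_id" in grp else np.nan
        rows.append((pid, cell_id, n, sx, sy, immotile, d_hat, intercept,
                     clamped, np.nan if alpha is None else alpha, mode))
    return pd.DataFrame(rows, columns=[
        "particle_id", "cell_id", "n_frames", "span_x_nm", "span_y_nm",
        "immotile", "D_um2_s", "msd_intercept_um2", "d_clamped", "alpha", "mode",
    ])


def summarize_population(
    motion: pd.DataFrame,
    provenance: dict | None = None,
) -> PopulationSummary:
    """Aggregate per-track summaries into the per-condition report."""
    if len(motion) == 0:
        raise ValueError("no tracks to summarize")
    n_total = int(len(motion))
    n_imm = int(motion["immotile"].sum())
    motile = motion[~motion["immotile"].astype(bool)]
    d = motile["D_um2_s"].dropna()
    mode_counts = motion["mode"].value_counts().to_dict()
    if len(d) > 0:
        mean = float(d.mean())
        sd = float(d.std(ddof=1)) if len(d) > 1 else None
        sem = float(sd / np.sqrt(len(d))) if sd is not None else None
    else:
        mean = sd = sem = None
    return PopulationSummary(
        n_total=n_total,
        n_immotile=n_imm,
        immotile_fraction=n_imm / n_total,
        mode_counts={str(k): int(v) for k, v in mode_counts.items()},
        d_motile_mean=mean,
        d_motile_sd=sd,
        d_motile_sem=sem,
        n_motile=int(len(motile)),
        provenance=provenance or {},
    )


def composite_projection(
    movie: Movie, n_frames: int = 100, mode: str = "max"
) -> np.ndarray:
    """Project the first ``n_frames`` frames to one image (max | mean | sum)."""
    if movie.n_frames < n_frames:
        raise ValueError(
            f"movie has {movie.n_frames} frames; composite needs {n_frames}"
        )
    stack = movie.frames[:n_frames].astype(float)
    if mode == "max":
        return stack.max(axis=0)
    if mode == "mean":
        return stack.mean(axis=0)
    if mode == "sum":
        return stack.sum(axis=0)
    raise ValueError(f"unknown projection mode {mode!r}")
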