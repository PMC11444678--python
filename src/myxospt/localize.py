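"""Spot detection and subpixel localization.

Candidate particles are local maxima of a band-passed frame above a robust
background threshold; each candidate is then fit with a symmetric 2-D
Gaussian ``A·exp(−((x−x₀)²+(y−y₀)²)/(2σ²)) + c`` by least squares, and the
fitted centre taken as the particle position.

Coordinate convention: 0-based pixel indices; the centre of pixel (row i,
col j) sits at continuous coordinate (x, y) = (j+0.5, i+0.5) pixels, and
nm = pixels × pixel_size_nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

from .config import DetectionConfig
from .io import LOCALIZATION_COLUMNS, Movie

SIGMA_BOUNDS_PX = (0.5, 3.0)


@dataclass
class FitResult:
    """One fitted spot, in pixel units relative to the full frame."""

    x_px: float
    y_px: float
    amplitude: float
    sigma_px: float
    offset: float
    rss: float
    converged: bool
    reason: str = ""


def detect_spots(
    frame: np.ndarray,
    k_sd: float = 5.0,
    min_separation_px: int = 4,
    dog_low_px: float = 1.0,
    dog_high_px: float = 4.0,
) -> np.ndarray:
    """Candidate spot pixels, as an (N, 2) array of (row, col).

    The frame is band-passed (difference of Gaussians); candidates are local
    maxima strictly above median + k_sd × 1.4826·MAD of the band-passed
    frame.  Maxima closer than ``min_separation_px`` collapse to the
    brighter one.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    bp = difference_of_gaussians(frame, dog_low_px, dog_high_px)
    med = np.median(bp)
    mad = np.median(np.abs(bp - med))
    thr = med + k_sd * 1.4826 * mad
    peaks = peak_local_max(bp, min_distance=min_separation_px, exclude_border=False)
    if len(peaks) == 0:
        return peaks.reshape(0, 2)
    keep = bp[peaks[:, 0], peaks[:, 1]] > thr
    return peaks[keep]


def _init_params(windows: np.ndarray) -> np.ndarray:
    """Moment-based initial (x0, y0, A, sigma, c) per window."""
    n, wh, ww = windows.shape
    c0 = windows.min(axis=(1, 2))
    a0 = windows.max(axis=(1, 2)) - c0
    a0 = np.maximum(a0, 1e-6)
    yy, xx = np.mgrid[0:wh, 0:ww]
    xc, yc = xx + 0.5, yy + 0.5
    wgt = np.maximum(windows - c0[:, None, None], 0.0)
    tot = wgt.sum(axis=(1, 2)) + 1e-12
    x0 = (wgt * xc).sum(axis=(1, 2)) / tot
    y0 = (wgt * yc).sum(axis=(1, 2)) / tot
    s0 = np.full(n, 1.0)
    return np.stack([x0, y0, a0, s0, c0], axis=1)


def _model_and_jac(theta: np.ndarray, xc: np.ndarray, yc: np.ndarray):
    x0, y0, a, s, c = (theta[:, i][:, None] for i in range(5))
    dx = xc[None, :] - x0
    dy = yc[None, :] - y0
    e = np.exp(-(dx * dx + dy * dy) / (2.0 * s * s))
    f = a * e + c
    j = np.empty(theta.shape[:1] + xc.shape + (5,))
    j[..., 0] = a * e * dx / (s * s)
    j[..., 1] = a * e * dy / (s * s)
    j[..., 2] = e
    j[..., 3] = a * e * (dx * dx + dy * dy) / (s ** 3)
    j[..., 4] = 1.0
    return f, j


def fit_gaussian2d_batch(windows: np.ndarray, n_iter: int = 40) -> np.ndarray:
    """Levenberg–Marquardt fit of a symmetric Gaussian to many windows.

    Returns an (N, 7) array: x0, y0, amplitude, sigma, offset, rss,
    converged(0/1), with positions in window pixel coordinates.
    """
    windows = np.asarray(windows, dtype=float)
    n, wh, ww = windows.shape
    yy, xx = np.mgrid[0:wh, 0:ww]
    xc = (xx + 0.5).ravel()
    yc = (yy + 0.5).ravel()
    data = windows.reshape(n, -1)
    theta = _init_params(windows)
    lam = np.full(n, 1e-3)
    f, j = _model_and_jac(theta, xc, yc)
    resid = f - data
    cost = (resid * resid).sum(axis=1)
    eye = np.eye(5)
    for _ in range(n_iter):
        jtj = np.einsum("npk,npl->nkl", j, j)
        g = np.einsum("npk,np->nk", j, resid)
        a_mat = jtj + lam[:, None, None] * eye * np.maximum(
            np.einsum("nkk->n", jtj)[:, None, None] / 5.0, 1e-12
        )
        try:
            step = np.linalg.solve(a_mat, g[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - damping keeps A PD
            step = np.stack([
                np.linalg.lstsq(a_mat[i], g[i], rcond=None)[0] for i in range(n)
            ])
        cand = theta - step
        cand[:, 0] = np.clip(cand[:, 0], 0.0, ww)
        cand[:, 1] = np.clip(cand[:, 1], 0.0, wh)
        cand[:, 2] = np.maximum(cand[:, 2], 1e-9)
        cand[:, 3] = np.clip(cand[:, 3], *SIGMA_BOUNDS_PX)
        f2, j2 = _model_and_jac(cand, xc, yc)
        r2 = f2 - data
        c2 = (r2 * r2).sum(axis=1)
        better = c2 < cost
        theta[better] = cand[better]
        resid[better] = r2[better]
        f[better] = f2[better]
        j[better] = j2[better]
        cost[better] = c2[better]
        lam = np.where(better, lam * 0.4, lam * 3.0)
        lam = np.clip(lam, 1e-9, 1e6)
    # a fit is usable if the optimizer is not pinned at the sigma bounds
    converged = (
        (theta[:, 3] > SIGMA_BOUNDS_PX[0] + 1e-6)
        & (theta[:, 3] < SIGMA_BOUNDS_PX[1] - 1e-6)
        & (theta[:, 2] > 0)
    )
    return np.column_stack([theta, cost, converged.astype(float)])


def fit_gaussian2d(
    frame: np.ndarray,
    candidate_px: tuple[int, int],
    window_px: int = 7,
) -> FitResult:
    """Fit a single candidate (row, col) in a frame; positions in frame px."""
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    half = window_px // 2
    r, c = int(candidate_px[0]), int(candidate_px[1])
    r0 = min(max(r - half, 0), max(h - window_px, 0))
    c0 = min(max(c - half, 0), max(w - window_px, 0))
    win = frame[r0:r0 + window_px, c0:c0 + window_px]
    if win.shape != (window_px, window_px):
        return FitResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         False, "window outside frame")
    out = fit_gaussian2d_batch(win[None])[0]
    ok = bool(out[6])
    return FitResult(
        x_px=out[0] + c0, y_px=out[1] + r0, amplitude=out[2], sigma_px=out[3],
        offset=out[4], rss=out[5], converged=ok,
        reason="" if ok else "sigma at bound",
    )


def localize_movie(movie: Movie, cfg: DetectionConfig | None = None) -> pd.DataFrame:
    """Detect and fit spots in every frame of a movie.

    Returns a localization table with columns
    frame, x_nm, y_nm, amplitude, sigma_nm, offset, rss, cell_id (NaN here;
    filled by :func:`assign_to_cells`).  Non-converged fits are dropped.
    """
    cfg = cfg or DetectionConfig()
    win = cfg.window_px
    half = win // 2
    t_, h, w = movie.shape
    frames_idx: list[int] = []
    origins: list[tuple[int, int]] = []
    wins: list[np.ndarray] = []
    for t in range(movie.n_frames):
        frame = movie.frames[t].astype(float)
        peaks = detect_spots(frame, cfg.k_sd, cfg.min_separation_px,
                             cfg.dog_low_px, cfg.dog_high_px)
        for r, c in peaks:
            r0 = min(max(r - half, 0), max(h - win, 0))
            c0 = min(max(c - half, 0), max(w - win, 0))
            patch = frame[r0:r0 + win, c0:c0 + win]
            if patch.shape != (win, win):
                continue
            frames_idx.append(t)
            origins.append((r0, c0))
            wins.append(patch)
    if not wins:
        return pd.DataFrame(columns=LOCALIZATION_COLUMNS)
    fits = fit_gaussian2d_batch(np.stack(wins))
    org = np.asarray(origins, dtype=float)
    px = movie.pixel_size_nm
    df = pd.DataFrame({
        "frame": np.asarray(frames_idx, dtype=int),
        "x_nm": (fits[:, 0] + org[:, 1]) * px,
        "y_nm": (fits[:, 1] + org[:, 0]) * px,
        "amplitude": fits[:, 2],
        "sigma_nm": fits[:, 3] * px,
        "offset": fits[:, 4],
        "rss": fits[:, 5],
        "cell_id": np.nan,
    })
    df = df[fits[:, 6] > 0].reset_index(drop=True)
    # de-duplicate anything that collapsed onto the same position after fitting
    df = _drop_close_duplicates(df, cfg.min_separation_px * px)
    return df


def _drop_close_duplicates(df: pd.DataFrame, min_sep_nm: float) -> pd.DataFrame:
    keep = np.ones(len(df), dtype=bool)
    for _, idx in df.groupby("frame").groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        pts = df.loc[idx, ["x_nm", "y_nm"]].to_numpy()
        amp = df.loc[idx, "amplitude"].to_numpy()
        order = np.argsort(-amp)
        taken: list[int] = []
        for k in order:
            if taken and (np.linalg.norm(pts[taken] - pts[k], axis=1) < min_sep_nm).any():
                keep[idx[k]] = False
            else:
                taken.append(k)
    return df[keep].reset_index(drop=True)


def assign_to_cells(
    localizations: pd.DataFrame,
    cell_mask: np.ndarray,
    pixel_size_nm: float,
) -> tuple[pd.DataFrame, int]:
    """Label each localization with the cell mask value under it.

    Localizations on background (label 0) are discarded.  Returns the
    labelled subset and the number discarded.
    """
    if len(localizations) == 0:
        return localizations.copy(), 0
    col = np.floor(localizations["x_nm"].to_numpy() / pixel_size_nm).astype(int)
    row = np.floor(localizations["y_nm"].to_numpy() / pixel_size_nm).astype(int)
    h, w = cell_mask.shape
    if (col < 0).any() or (col >= w).any() or (row < 0).any() or (row >= h).any():
        raise ValueError("localization grid does not match the mask grid")
    labels = cell_mask[row, col]
    out = localizations.copy()
    out["cell_id"] = labels
    n_discarded = int((labels == 0).sum())
    return out[out["cell_id"] > 0].reset_index(drop=True), n_discarded
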