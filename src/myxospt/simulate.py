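"""Synthetic sptPALM data with known ground truth.

Emulates sparse-photoactivation single-particle imaging of membrane proteins
in rod-shaped cells: a small number of fluorophores per cell is active at any
time, each moving in one of three dynamic patterns (stationary, directed,
diffusive), emitting an integrated Gaussian PSF onto a noisy camera until it
photobleaches.  Also provides gliding-cell centroid tracks and growth-curve
fixtures for the kinematics and stiffness calculators.

Every stochastic operation takes an explicit ``numpy.random.Generator`` (or
a seed); identical seed and config give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .config import (
    CellLayoutConfig,
    MotionDefaults,
    PhotophysicsConfig,
    RenderConfig,
    SimulateConfig,
)
from .geometry import CellGeometry, make_cell
from .io import Movie

MODES = ("stationary", "directed", "diffusive")


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class MotionParams:
    """Parameters of one motion mode.

    Only the fields of the declared ``mode`` are read:
    ``D_um2_s`` for diffusive; ``v_um_s``, ``period_um`` (axial distance per
    transverse oscillation, the 2-D shadow of a helix pitch) and
    ``amplitude_um`` for directed.  ``loc_noise_sd_nm`` applies to the
    render-free observation path in all modes.
    """

    mode: str
    D_um2_s: float = 0.0
    v_um_s: float = 0.0
    period_um: float = 1.0
    amplitude_um: float = 0.0
    loc_noise_sd_nm: float = 25.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.D_um2_s < 0 or self.v_um_s < 0:
            raise ValueError("D and v must be ≥ 0")


def simulate_trajectory(
    cell: CellGeometry,
    params: MotionParams,
    n_frames: int,
    dt_s: float,
    rng: np.random.Generator | int | None = None,
    start_um: Optional[np.ndarray] = None,
) -> np.ndarray:
    """True positions (nm, shape ``(n_frames, 2)``) of one particle.

    stationary — a fixed uniform-random point in the cell;
    diffusive — Brownian increments of per-axis variance ``2 D dt``,
    reflected at the spherocylinder outline;
    directed — constant-speed axial advance with a sinusoidal transverse
    component, reversing at the poles.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    rng = _as_rng(rng)
    mode = params.mode

    if mode == "stationary":
        p0 = cell.sample_inside(1, rng)[0] if start_um is None else np.asarray(start_um)
        pos = np.tile(p0, (n_frames, 1))
    elif mode == "diffusive":
        p0 = cell.sample_inside(1, rng)[0] if start_um is None else np.asarray(start_um)
        sd = np.sqrt(2.0 * params.D_um2_s * dt_s)
        steps = rng.normal(0.0, sd, size=(n_frames - 1, 2))
        free = p0 + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        if cell.contains(free).all():
            pos = free  # never touched the wall: no reflection needed
        else:
            pos = np.empty((n_frames, 2))
            pos[0] = p0
            for i in range(1, n_frames):
                pos[i] = cell.reflect_inside(pos[i - 1] + steps[i - 1])[0]
    elif mode == "directed":
        half = cell.half_axis_um
        amp = min(params.amplitude_um, 0.95 * cell.radius_um)
        if start_um is None:
            u0 = rng.uniform(-half, half)
        else:
            u0 = float(np.clip(cell.to_axis_frame(start_um)[0, 0], -half, half))
        direction = rng.choice([-1.0, 1.0])
        phase = rng.uniform(0.0, 2.0 * np.pi)
        u = np.empty(n_frames)
        u[0] = u0
        s = np.empty(n_frames)
        s[0] = direction
        step = params.v_um_s * dt_s
        travelled = np.zeros(n_frames)
        for i in range(1, n_frames):
            nxt = u[i - 1] + s[i - 1] * step
            d = s[i - 1]
            # reflect at the pole caps
            if nxt > half:
                nxt = 2 * half - nxt
                d = -d
            elif nxt < -half:
                nxt = -2 * half - nxt
                d = -d
            u[i], s[i] = nxt, d
            travelled[i] = travelled[i - 1] + step
        if amp > 0 and params.period_um > 0:
            v = amp * np.sin(2.0 * np.pi * travelled / params.period_um + phase)
        else:
            v = np.zeros(n_frames)
        pos = cell.from_axis_frame(np.stack([u, v], axis=-1))
    else:  # pragma: no cover - guarded in MotionParams
        raise ValueError(f"unknown mode {mode!r}")
    return pos * 1000.0  # µm → nm


def simulate_photophysics(
    n_particles: int,
    frames_total: int,
    mean_on_frames: float,
    max_active_per_cell: int = 1,
    rng: np.random.Generator | int | None = None,
    cell_ids: Optional[Sequence[int]] = None,
    min_dark_frames: int = 1,
) -> pd.DataFrame:
    """Activation/bleach schedule for sparse photoactivation.

    Each particle draws a uniform desired activation frame and a geometric
    on-duration with the given mean; within each cell at most
    ``max_active_per_cell`` particles may be active simultaneously, so excess
    activations are deferred until a slot frees up.  Successive emitters that
    share a slot are additionally separated by ``min_dark_frames`` dark
    frames — without a dark gap two consecutive emitters in one
    diffraction-limited cell would be indistinguishable from one particle.

    Returns a DataFrame with ``particle_id, cell_id, activation_frame,
    bleach_frame`` (both inclusive, ``activation_frame ≤ bleach_frame``).
    """
    if mean_on_frames < 1:
        raise ValueError("mean_on_frames must be ≥ 1")
    rng = _as_rng(rng)
    if cell_ids is None:
        cell_ids = np.zeros(n_particles, dtype=int)
    cell_ids = np.asarray(cell_ids, dtype=int)
    import heapq

    desired = rng.integers(0, frames_total, size=n_particles)
    durations = rng.geometric(1.0 / mean_on_frames, size=n_particles)
    rows = []
    order = np.argsort(desired, kind="stable")
    busy: dict[int, list[int]] = {}  # per cell: heap of active bleach frames
    for idx in order:
        cid = int(cell_ids[idx])
        heap = busy.setdefault(cid, [])
        start = int(desired[idx])
        while heap and heap[0] < start - min_dark_frames:
            heapq.heappop(heap)  # slots free (incl. dark gap) before start
        if len(heap) >= max_active_per_cell:
            start = heapq.heappop(heap) + 1 + min_dark_frames
        end = start + int(durations[idx]) - 1
        heapq.heappush(heap, end)
        rows.append((int(idx), cid, start, end))
    df = pd.DataFrame(rows, columns=["particle_id", "cell_id", "activation_frame", "bleach_frame"])
    return df.sort_values("particle_id").reset_index(drop=True)


def _psf_window(x_px: float, y_px: float, sigma_px: float, photons: float,
                shape: tuple[int, int], half: int):
    """Integrated symmetric Gaussian over a pixel window; returns (r0, c0, patch)."""
    h, w = shape
    cx, cy = int(np.floor(x_px)), int(np.floor(y_px))
    c0, c1 = max(cx - half, 0), min(cx + half + 1, w)
    r0, r1 = max(cy - half, 0), min(cy + half + 1, h)
    if c0 >= c1 or r0 >= r1:
        return r0, c0, np.zeros((0, 0))
    xs = np.arange(c0, c1)
    ys = np.arange(r0, r1)
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 1 - x_px) / s) - erf((xs - x_px) / s))
    fy = 0.5 * (erf((ys + 1 - y_px) / s) - erf((ys - y_px) / s))
    return r0, c0, photons * np.outer(fy, fx)


def render_movie(
    truth: pd.DataFrame,
    cfg: RenderConfig,
    rng: np.random.Generator | int | None = None,
    n_frames: Optional[int] = None,
) -> Movie:
    """Render ground-truth emitter positions into a noisy camera stack.

    Each active particle-frame contributes an integrated symmetric 2-D
    Gaussian of total expected ``photons_per_frame`` photons; Poisson shot
    noise is applied to signal + background, then Gaussian read noise.
    ``truth`` needs columns ``particle_id, frame, x_nm, y_nm``.
    """
    rng = _as_rng(rng)
    h, w = cfg.image_shape
    if n_frames is None:
        n_frames = int(truth["frame"].max()) + 1 if len(truth) else 1
    x_px = truth["x_nm"].to_numpy() / cfg.pixel_size_nm
    y_px = truth["y_nm"].to_numpy() / cfg.pixel_size_nm
    bad = (x_px < 0) | (x_px >= w) | (y_px < 0) | (y_px >= h)
    if bad.any():
        ids = sorted(set(truth["particle_id"].to_numpy()[bad].tolist()))
        raise ValueError(f"positions outside the image for particle ids {ids}")
    sigma_px = cfg.psf_sigma_nm / cfg.pixel_size_nm
    half = max(3, int(np.ceil(4 * sigma_px)))
    signal = np.zeros((n_frames, h, w))
    frames_idx = truth["frame"].to_numpy().astype(int)
    for t, xx, yy in zip(frames_idx, x_px, y_px):
        if t < 0 or t >= n_frames:
            continue
        r0, c0, patch = _psf_window(xx, yy, sigma_px, cfg.photons_per_frame, (h, w), half)
        if patch.size:
            signal[t, r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] += patch
    stack = rng.poisson(signal + cfg.background_level).astype(float)
    if cfg.read_noise_sd > 0:
        stack = stack + rng.normal(0.0, cfg.read_noise_sd, size=stack.shape)
    stack = np.clip(np.rint(stack), 0, None).astype(np.uint16)
    return Movie(
        frames=stack,
        pixel_size_nm=cfg.pixel_size_nm,
        frame_interval_s=cfg.frame_interval_s,
        source="simulated",
    )


def layout_cells(
    cfg: CellLayoutConfig, render: RenderConfig
) -> list[CellGeometry]:
    """Tile identical horizontal rod cells over the field of view."""
    h, w = render.image_shape
    fov_w_um = w * render.pixel_size_nm / 1000.0
    fov_h_um = h * render.pixel_size_nm / 1000.0
    pitch_x = cfg.length_um + cfg.margin_um
    pitch_y = cfg.width_um + cfg.margin_um
    n_cols = int((fov_w_um - cfg.margin_um) // pitch_x)
    n_rows = int((fov_h_um - cfg.margin_um) // pitch_y)
    if n_cols < 1 or n_rows < 1:
        raise ValueError("field of view too small for a single cell")
    cells = []
    cid = 1
    for r in range(n_rows):
        for c in range(n_cols):
            cx = cfg.margin_um + cfg.length_um / 2 + c * pitch_x
            cy = cfg.margin_um + cfg.width_um / 2 + r * pitch_y
            cells.append(make_cell(cfg.length_um, cfg.width_um, 0.0, (cx, cy), id=cid))
            cid += 1
    return cells


def cell_mask_image(cells: Sequence[CellGeometry], render: RenderConfig) -> np.ndarray:
    """Label image of the cell layout (0 = background)."""
    h, w = render.image_shape
    mask = np.zeros((h, w), dtype=np.int32)
    pix_um = render.pixel_size_nm / 1000.0
    for cell in cells:
        inside = cell.rasterize((h, w), pix_um)
        mask[inside] = cell.id
    return mask


@dataclass
class SimulationResult:
    """Movie (optional), ground truth and geometry from one population run."""

    truth: pd.DataFrame          # particle_id, cell_id, frame, x_nm, y_nm, mode
    cells: list[CellGeometry]
    mask: np.ndarray
    movie: Optional[Movie] = None
    observed: Optional[pd.DataFrame] = None  # render-free noisy observations
    meta: dict = field(default_factory=dict)


def _mode_params(mode: str, motion: MotionDefaults, width_um: float) -> MotionParams:
    if mode == "diffusive":
        return MotionParams("diffusive", D_um2_s=motion.diffusive_D_um2_s,
                            loc_noise_sd_nm=motion.loc_noise_sd_nm)
    if mode == "directed":
        return MotionParams(
            "directed",
            v_um_s=motion.directed_v_um_s,
            period_um=motion.directed_period_um,
            amplitude_um=motion.directed_amplitude_frac * width_um / 2.0,
            loc_noise_sd_nm=motion.loc_noise_sd_nm,
        )
    return MotionParams("stationary", loc_noise_sd_nm=motion.loc_noise_sd_nm)


def simulate_population(
    cfg: SimulateConfig,
    rng: np.random.Generator | int | None = None,
    render: bool = True,
    frames_total: Optional[int] = None,
) -> SimulationResult:
    """Simulate a mixed population of emitters and (optionally) its movie.

    Particle modes are drawn i.i.d. from ``cfg.fractions``; particles are
    spread over a tiled lawn of cells and given sparse-activation schedules.
    With ``render=False`` the result instead carries ``observed``: true
    positions plus isotropic Gaussian localization noise, for stage-isolated
    tests of the downstream analysis.
    """
    rng = _as_rng(rng)
    fr = {m: cfg.fractions.get(m, 0.0) for m in MODES}
    if abs(sum(fr.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1 within 1e-9")
    cells = layout_cells(cfg.cells, cfg.render)
    mask = cell_mask_image(cells, cfg.render)
    n = cfg.n_tracks
    modes = rng.choice(MODES, size=n, p=[fr[m] for m in MODES])
    cell_idx = np.arange(n) % len(cells)
    if frames_total is None:
        per_cell = int(np.ceil(n / len(cells)))
        frames_total = int(np.ceil(2.2 * per_cell * cfg.photophysics.mean_on_frames)) + 20
    cell_ids = np.array([cells[i].id for i in cell_idx])
    schedule = simulate_photophysics(
        n, frames_total, cfg.photophysics.mean_on_frames,
        cfg.photophysics.max_active_per_cell, rng, cell_ids=cell_ids,
    )
    rows = []
    for pid, cid, act, bleach in schedule.itertuples(index=False):
        last = min(int(bleach), frames_total - 1)
        if last < act:
            continue
        nf = last - int(act) + 1
        cell = cells[cell_idx[pid]]
        mode = str(modes[pid])
        params = _mode_params(mode, cfg.motion, cfg.cells.width_um)
        pos_nm = simulate_trajectory(cell, params, nf, cfg.render.frame_interval_s, rng)
        for k in range(nf):
            rows.append((pid, int(cid), int(act) + k, pos_nm[k, 0], pos_nm[k, 1], mode))
    truth = pd.DataFrame(
        rows, columns=["particle_id", "cell_id", "frame", "x_nm", "y_nm", "mode"]
    )
    meta = {
        "frames_total": frames_total,
        "pixel_size_nm": cfg.render.pixel_size_nm,
        "frame_interval_s": cfg.render.frame_interval_s,
        "n_cells": len(cells),
    }
    result = SimulationResult(truth=truth, cells=cells, mask=mask, meta=meta)
    if render:
        result.movie = render_movie(truth, cfg.render, rng, n_frames=frames_total)
    else:
        obs = truth.copy()
        noise = rng.normal(0.0, cfg.motion.loc_noise_sd_nm, size=(len(obs), 2))
        obs["x_nm"] = obs["x_nm"] + noise[:, 0]
        obs["y_nm"] = obs["y_nm"] + noise[:, 1]
        result.observed = obs
    return result


def simulate_diffusive_tracks(
    D_um2_s: float,
    n_tracks: int,
    dt_s: float = 0.1,
    mean_on_frames: float = 6.0,
    min_frames: int = 4,
    max_frames: int = 12,
    loc_noise_sd_nm: float = 25.0,
    rng: np.random.Generator | int | None = None,
) -> list[np.ndarray]:
    """Unconfined Brownian tracks with PALM-like durations, for recovery tests.

    Durations are geometric (given mean) truncated to the analysis window
    [min_frames, max_frames]; positions carry isotropic localization noise.
    Returns a list of (n_i, 2) arrays in nm.
    """
    rng = _as_rng(rng)
    sd_step = np.sqrt(2.0 * D_um2_s * dt_s) * 1000.0
    tracks = []
    while len(tracks) < n_tracks:
        m = rng.geometric(1.0 / mean_on_frames, size=4 * (n_tracks - len(tracks)) + 16)
        m = m[(m >= min_frames) & (m <= max_frames)]
        for nf in m[: n_tracks - len(tracks)]:
            steps = rng.normal(0.0, sd_step, size=(nf - 1, 2))
            pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            pos += rng.normal(0.0, loc_noise_sd_nm, size=pos.shape)
            tracks.append(pos)
    return tracks


def simulate_gliding_track(
    v_um_min: float,
    reversal_prob_per_step: float = 0.0,
    pause_prob_per_step: float = 0.0,
    pause_mean_steps: float = 3.0,
    n_steps: int = 60,
    dt_s: float = 10.0,
    lateral_jitter_um: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centroid track of a gliding cell sampled every ``dt_s`` seconds.

    The centroid advances ±``v·dt`` along a fixed axis, flips direction at
    reversal events, and stalls during pauses (geometric durations of the
    given mean).  Returns ``(track, events)``: the track has columns
    ``t_s, x_um, y_um``; events have ``step, kind, duration_steps`` with
    kind in {"reversal", "pause"} and step the 0-based index of the step
    (displacement from point ``step`` to ``step + 1``) where the event
    begins.
    """
    if not (0 <= reversal_prob_per_step <= 1 and 0 <= pause_prob_per_step <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = _as_rng(rng)
    step_um = v_um_min * dt_s / 60.0
    x = np.zeros(n_steps + 1)
    y = np.zeros(n_steps + 1)
    direction = 1.0
    pause_left = 0
    events = []
    for k in range(n_steps):
        if pause_left > 0:
            pause_left -= 1
            x[k + 1] = x[k]
        elif pause_prob_per_step > 0 and rng.random() < pause_prob_per_step:
            dur = max(int(rng.geometric(1.0 / pause_mean_steps)), 1)
            events.append((k, "pause", dur))
            pause_left = dur - 1
            x[k + 1] = x[k]
        else:
            if reversal_prob_per_step > 0 and rng.random() < reversal_prob_per_step:
                direction = -direction
                events.append((k, "reversal", 0))
            x[k + 1] = x[k] + direction * step_um
        if lateral_jitter_um > 0:
            y[k + 1] = rng.normal(0.0, lateral_jitter_um)
    track = pd.DataFrame({"t_s": np.arange(n_steps + 1) * dt_s, "x_um": x, "y_um": y})
    ev = pd.DataFrame(events, columns=["step", "kind", "duration_steps"])
    return track, ev


def gliding_events_to_tables(
    events: pd.DataFrame, n_steps: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a simulator event log into oracle pause and reversal tables.

    Returns (pauses, reversals): pauses with start_step, end_step
    (inclusive), n_steps — the same layout the detector emits — and
    reversals with a ``step`` column.
    """
    pauses = []
    for _, ev in events[events["kind"] == "pause"].iterrows():
        start = int(ev.step)
        end = min(start + int(ev.duration_steps) - 1, n_steps - 1)
        pauses.append((start, end, end - start + 1))
    reversals = events.loc[events["kind"] == "reversal", ["step"]].astype(int)
    return (
        pd.DataFrame(pauses, columns=["start_step", "end_step", "n_steps"]),
        reversals.reset_index(drop=True),
    )


def simulate_growth_curves(
    ratio_agarose: float,
    ratio_liquid: float,
    od_ref_curve: pd.DataFrame,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Mutant/reference OD600 curves in liquid and agarose-embedded culture.

    The mutant curve in each medium is the reference curve scaled by the
    given ratio plus Gaussian noise.  ``od_ref_curve`` needs columns
    ``time_h, od600``.  Long-format output: strain, medium, time_h, od600.
    """
    if not (ratio_agarose > 0 and ratio_liquid > 0):
        raise ValueError("ratios must be > 0")
    if (od_ref_curve["od600"] < 0).any():
        raise ValueError("reference OD600 values must be ≥ 0")
    rng = _as_rng(rng)
    t = od_ref_curve["time_h"].to_numpy(dtype=float)
    od = od_ref_curve["od600"].to_numpy(dtype=float)
    frames = []
    for medium, ratio in (("liquid", ratio_liquid), ("agarose", ratio_agarose)):
        for strain, scale in (("reference", 1.0), ("mutant", ratio)):
            vals = od * scale
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, size=len(vals))
            frames.append(pd.DataFrame(
                {"strain": strain, "medium": medium, "time_h": t, "od600": vals}
            ))
    out = pd.concat(frames, ignore_index=True)
    if (out["od600"] < 0).any():
        raise ValueError("noise drove an OD600 value negative; lower noise_sd")
    return out
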