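"""Cell morphometry and gliding kinematics.

Morphology: rod length and width are read off a binary mask via its medial
axis — length is the geodesic length of the longest (spur-pruned) skeleton
path plus one end-cap radius at each pole; width is twice the median
distance-transform value along that path.

Kinematics: centroid tracks sampled at uniform intervals (10 s in the
source experiments) yield gliding velocity (path length over non-pause
time), pause events (sustained sub-threshold speed), reversal events
(sustained direction flip of the smoothed heading) and gliding persistency
(path length of each segment between consecutive events).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize


@dataclass
class MorphologyRecord:
    cell_id: int
    length_um: float
    width_um: float
    area_px: int


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pix:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in pix:
                    g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    if g.number_of_nodes() == 0 and pix:
        g.add_nodes_from(pix)
    return g


def _prune_spurs(g: nx.Graph, dist: np.ndarray) -> nx.Graph:
    """Iteratively remove endpoint branches shorter than the local radius.

    The medial axis of a capped rod grows short Y-branches into the poles;
    each is shorter than the cap radius, so trimming endpoint branches whose
    geodesic length is below the distance-transform value at their junction
    leaves only the true axis.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        ends = [n for n in g.nodes if g.degree(n) == 1]
        for e in ends:
            if e not in g:
                continue
            branch = [e]
            blen = 0.0
            node = e
            while g.degree(node) <= 2:
                nbrs = [m for m in g.neighbors(node) if m not in branch]
                if not nbrs:
                    break
                nxt = nbrs[0]
                blen += g[node][nxt]["weight"]
                if g.degree(nxt) >= 3:
                    if blen < float(dist[nxt]):
                        g.remove_nodes_from(branch)
                        changed = True
                    break
                branch.append(nxt)
                node = nxt
    return g


def _longest_path(g: nx.Graph):
    """Longest weighted shortest-path across the skeleton (its diameter).

    Prefers true endpoints (degree ≤ 1); loopy 8-connected skeletons may
    have none, in which case a double Dijkstra sweep finds the diameter.
    """
    nodes = list(g.nodes)
    if len(nodes) == 1:
        return 0.0, nodes
    ends = [n for n in nodes if g.degree(n) <= 1]
    if ends:
        best = (0.0, [nodes[0]])
        for a in ends:
            lengths, paths = nx.single_source_dijkstra(g, a, weight="weight")
            for b, dlen in lengths.items():
                if g.degree(b) <= 1 and dlen > best[0]:
                    best = (dlen, paths[b])
        return best
    lengths, _ = nx.single_source_dijkstra(g, nodes[0], weight="weight")
    a = max(lengths, key=lengths.get)
    lengths, paths = nx.single_source_dijkstra(g, a, weight="weight")
    b = max(lengths, key=lengths.get)
    return lengths[b], paths[b]


def _smoothed_path_length(path: list[tuple[int, int]], window: int = 5) -> float:
    """Euclidean length of a boxcar-smoothed skeleton polyline.

    Discrete skeletons of rods with even pixel width staircase between the
    two centre rows; summing raw 8-connected steps then overestimates the
    axis length by up to √2.  Smoothing the node coordinates (window
    shrinking toward the anchored endpoints) recovers the underlying curve.
    """
    pts = np.asarray(path, dtype=float)
    if len(pts) < 2:
        return 0.0
    half = window // 2
    sm = np.empty_like(pts)
    for i in range(len(pts)):
        w = min(i, len(pts) - 1 - i, half)
        sm[i] = pts[i - w:i + w + 1].mean(axis=0)
    return float(np.linalg.norm(np.diff(sm, axis=0), axis=1).sum())


def measure_morphology(
    cell_mask: np.ndarray, pixel_size_um: float, cell_id: int = 0
) -> MorphologyRecord:
    """Length and width of a single connected rod-shaped mask.

    The spur-pruned medial axis gives the pole-to-pole axis length P (caps
    excluded); width then follows from the capped-rod area relation
    area = P·W + π(W/2)², i.e. W = (−P + √(P² + π·area)) / (π/2), and
    length = P + W (one cap radius beyond the axis at each pole).  For a
    disk P ≈ 0 and both collapse to the diameter.  Raises on empty or
    multi-component masks.
    """
    mask = np.asarray(cell_mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    from scipy.ndimage import label

    lab, n_comp = label(mask)
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected component, got {n_comp}")
    skel = skeletonize(mask)
    dist = distance_transform_edt(mask)
    g = _skeleton_graph(skel)
    pruned = _prune_spurs(g, dist)
    if pruned.number_of_nodes() == 0:
        pruned = g
    _, path = _longest_path(pruned)
    # trim end nodes that wandered into the pole caps (distance below the
    # rod radius); the lost axial extent at each end is radius − dist there,
    # because inside a cap the distance transform falls with slope 1
    dv = np.array([dist[p] for p in path])
    r_est = float(np.quantile(dv, 0.9))
    i0, i1 = 0, len(path)
    while i0 < i1 - 1 and dv[i0] < r_est - 0.5:
        i0 += 1
    while i1 - 1 > i0 and dv[i1 - 1] < r_est - 0.5:
        i1 -= 1
    axis_px = _smoothed_path_length(path[i0:i1])
    # EDT distances run to background pixel centres, ~0.5 px past the edge
    d01 = float(dv[i0] + dv[i1 - 1]) - 1.0
    area = float(mask.sum())
    # spherocylinder area = axis·W + π(W/2)², with the full axis being
    # axis_px + (W − d01): closed-form W, then L = axis + W
    a = 1.0 + np.pi / 4.0
    b = axis_px - d01
    width_px = (-b + np.sqrt(b * b + 4.0 * a * area)) / (2.0 * a)
    length_px = axis_px + 2.0 * width_px - d01
    return MorphologyRecord(
        cell_id=cell_id,
        length_um=length_px * pixel_size_um,
        width_um=width_px * pixel_size_um,
        area_px=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# gliding kinematics on centroid tracks


def _check_track(track: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, float]:
    t = track["t_s"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need ≥ 3 time points")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("track must be uniformly sampled")
    xy = track[["x_um", "y_um"]].to_numpy(dtype=float)
    return t, xy, float(dt[0])


def step_speeds_um_min(track: pd.DataFrame) -> np.ndarray:
    """Instantaneous speed of each step, µm/min."""
    _, xy, dt = _check_track(track)
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return d / dt * 60.0


def detect_pauses(
    track: pd.DataFrame,
    speed_floor_um_min: float = 0.3,
    min_steps: int = 2,
) -> pd.DataFrame:
    """Maximal runs of ≥ min_steps consecutive sub-threshold steps.

    Returns a table with start_step, end_step (inclusive, 0-based step
    indices) and n_steps.
    """
    slow = step_speeds_um_min(track) < speed_floor_um_min
    events = []
    i = 0
    while i < len(slow):
        if slow[i]:
            j = i
            while j + 1 < len(slow) and slow[j + 1]:
                j += 1
            if j - i + 1 >= min_steps:
                events.append((i, j, j - i + 1))
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(events, columns=["start_step", "end_step", "n_steps"])


def detect_reversals(
    track: pd.DataFrame,
    smoothing_window: int = 3,
    pauses: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sustained direction flips of the smoothed heading.

    The step vectors are boxcar-smoothed over ``smoothing_window`` steps; a
    reversal is scored at step t when the smoothed vectors before and after
    t have negative dot product for ≥ 2 consecutive t.  Steps inside
    detected pauses (pass the pause table) are excluded — a stalled cell's
    jitter has no meaningful heading.  Returns a table with the step index
    of each event.
    """
    _, xy, _ = _check_track(track)
    steps = np.diff(xy, axis=0)
    n = len(steps)
    w = smoothing_window
    if n < 2 * w:
        raise ValueError(f"need ≥ {2 * w} steps for smoothing window {w}")
    paused = np.zeros(n, dtype=bool)
    if pauses is not None:
        for _, ev in pauses.iterrows():
            paused[int(ev.start_step):int(ev.end_step) + 1] = True
    dots = np.full(n, np.nan)
    for t in range(w, n - w + 1):
        if paused[max(t - w, 0):min(t + w, n)].any():
            continue
        before = steps[t - w:t].mean(axis=0)
        after = steps[t:t + w].mean(axis=0)
        dots[t] = float(before @ after)
    neg = dots < 0
    events = []
    i = 0
    while i < n:
        if neg[i]:
            j = i
            while j + 1 < n and neg[j + 1]:
                j += 1
            if j - i + 1 >= 2:
                events.append(i + (j - i) // 2)  # centre of the flip
            i = j + 1
        else:
            i += 1
    return pd.DataFrame({"step": events})


def gliding_velocity(
    track: pd.DataFrame,
    pauses: pd.DataFrame | None = None,
) -> tuple[float, bool]:
    """Moving velocity: non-pause path length over non-pause time, µm/min.

    Returns (velocity, all_paused).  An all-pause track reports 0 with the
    flag set.
    """
    _, xy, dt = _check_track(track)
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    moving = np.ones(len(d), dtype=bool)
    if pauses is not None:
        for _, ev in pauses.iterrows():
            moving[int(ev.start_step):int(ev.end_step) + 1] = False
    if not moving.any():
        return 0.0, True
    v = d[moving].sum() / (moving.sum() * dt) * 60.0
    return float(v), False


def gliding_persistency(
    track: pd.DataFrame,
    pauses: pd.DataFrame,
    reversals: pd.DataFrame,
) -> list[float]:
    """Path length (µm) of each maximal segment between consecutive events.

    Event boundaries are pause intervals and reversal steps; the track start
    and end close the outermost runs.  Pause steps contribute no path.
    """
    _, xy, _ = _check_track(track)
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    n = len(d)
    in_pause = np.zeros(n, dtype=bool)
    for _, ev in pauses.iterrows():
        in_pause[int(ev.start_step):int(ev.end_step) + 1] = True
    boundaries = set()
    for _, ev in pauses.iterrows():
        boundaries.add(int(ev.start_step))
        boundaries.add(int(ev.end_step) + 1)
    for s in reversals["step"].tolist():
        boundaries.add(int(s))
    cuts = sorted(b for b in boundaries if 0 < b < n)
    runs = []
    prev = 0
    for b in cuts + [n]:
        seg = d[prev:b][~in_pause[prev:b]]
        runs.append(float(seg.sum()))
        prev = b
    return runs


def analyze_gliding(
    track: pd.DataFrame,
    speed_floor_um_min: float = 0.3,
    min_pause_steps: int = 2,
    smoothing_window: int = 3,
    cell_id: int = 0,
) -> dict:
    """One-call kinematics record for a single centroid track."""
    pauses = detect_pauses(track, speed_floor_um_min, min_pause_steps)
    reversals = detect_reversals(track, smoothing_window, pauses)
    v, all_paused = gliding_velocity(track, pauses)
    runs = gliding_persistency(track, pauses, reversals)
    return {
        "cell_id": cell_id,
        "velocity_um_min": v,
        "all_paused": all_paused,
        "n_pauses": int(len(pauses)),
        "n_reversals": int(len(reversals)),
        "persistency_runs_um": runs,
        "mean_run_um": float(np.mean(runs)) if runs else 0.0,
    }
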