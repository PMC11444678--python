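"""Frame-to-frame trajectory linking and the in-focus duration filter.

Linking is greedy nearest-neighbour between consecutive frames (adequate at
PALM sparsity, and deliberately simple so it can be swapped out): candidate
pairs are sorted by distance, pairs farther than ``max_disp_nm`` are never
linked, and each localization joins at most one trajectory.  When a
``cell_id`` column is present, links never cross cell boundaries.

Analysis then keeps only trajectories that stayed in focus for 4–12
consecutive frames (0.4–1.2 s at 10 Hz) — tracks shorter than the window
carry too little information, longer ones are vanishingly rare for single
fluorophores and likely aggregates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


def link(
    localizations: pd.DataFrame,
    max_disp_nm: float = 500.0,
    max_gap: int = 0,
) -> pd.DataFrame:
    """Assign a ``particle_id`` to every localization by greedy linking.

    Ties are broken by smaller distance, then by smaller particle id.
    Unlinked localizations become singleton trajectories, so the output is a
    partition of the input rows.
    """
    df = localizations.sort_values(["frame"], kind="stable").reset_index(drop=True)
    n = len(df)
    pid = -np.ones(n, dtype=int)
    if n == 0:
        out = df.copy()
        out["particle_id"] = pid[:0]
        return out
    frames = df["frame"].to_numpy(dtype=int)
    pts = df[["x_nm", "y_nm"]].to_numpy()
    cell = df["cell_id"].to_numpy() if "cell_id" in df else np.zeros(n)
    next_pid = 0
    by_frame = {f: np.flatnonzero(frames == f) for f in np.unique(frames)}
    all_frames = sorted(by_frame)
    # active trajectory heads: row index of last localization per open track
    heads: list[int] = []
    last_seen: dict[int, int] = {}
    for f in all_frames:
        rows = by_frame[f]
        # close heads that exceeded the allowed gap
        heads = [h for h in heads if f - frames[h] <= max_gap + 1]
        if heads:
            tree = cKDTree(pts[heads])
            cand = tree.query_ball_point(pts[rows], r=max_disp_nm)
            pairs = []
            for ri, neigh in zip(rows, cand):
                for hj in neigh:
                    h = heads[hj]
                    if cell[h] != cell[ri]:
                        continue
                    d = float(np.hypot(*(pts[h] - pts[ri])))
                    pairs.append((d, pid[h], h, ri))
            pairs.sort(key=lambda p: (p[0], p[1]))
            used_heads: set[int] = set()
            used_rows: set[int] = set()
            for d, _, h, ri in pairs:
                if h in used_heads or ri in used_rows:
                    continue
                used_heads.add(h)
                used_rows.add(ri)
                pid[ri] = pid[h]
        for ri in rows:
            if pid[ri] < 0:
                pid[ri] = next_pid
                next_pid += 1
        # update heads: newest localization of each open track
        for ri in rows:
            last_seen[pid[ri]] = ri
        heads = [r for t, r in last_seen.items() if f - frames[r] <= max_gap]
    out = df.copy()
    out["particle_id"] = pid
    return out


def trajectory_lengths(trajectories: pd.DataFrame) -> pd.Series:
    return trajectories.groupby("particle_id")["frame"].size()


def filter_in_focus(
    trajectories: pd.DataFrame,
    min_frames: int = 4,
    max_frames: int = 12,
) -> tuple[pd.DataFrame, dict]:
    """Keep tracks with min_frames ≤ n_frames ≤ max_frames.

    Returns the filtered table plus a report with counts of tracks excluded
    for being too short / too long.
    """
    if min_frames > max_frames:
        raise ValueError("min_frames must be ≤ max_frames")
    sizes = trajectory_lengths(trajectories)
    short = sizes.index[sizes < min_frames]
    long_ = sizes.index[sizes > max_frames]
    kept_ids = sizes.index[(sizes >= min_frames) & (sizes <= max_frames)]
    kept = trajectories[trajectories["particle_id"].isin(kept_ids)].reset_index(drop=True)
    report = {
        "n_tracks_in": int(len(sizes)),
        "n_tracks_kept": int(len(kept_ids)),
        "excluded_short": int(len(short)),
        "excluded_long": int(len(long_)),
        "min_frames": min_frames,
        "max_frames": max_frames,
    }
    return kept, report
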