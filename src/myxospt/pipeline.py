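"""End-to-end orchestration: simulate → localize → track → classify.

Library-level functions used both from Python and from the thin CLI.  Every
artifact written to disk records the config hash and seed so that any output
row can be traced to the exact settings that produced it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .classify import analyze_trajectories, composite_projection, summarize_population
from .config import PipelineConfig, config_hash
from .io import Movie, read_movie, write_json, write_movie, write_table
from .localize import assign_to_cells, localize_movie
from .simulate import SimulationResult, simulate_population
from .track import filter_in_focus, link

log = logging.getLogger("myxospt")


def _provenance(cfg: PipelineConfig) -> dict:
    return {"config_hash": config_hash(cfg), "seed": cfg.seed, "version": __version__}


def run_simulate(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Simulate a population movie and write movie/masks/ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sim = simulate_population(cfg.simulate, rng, render=True)
    prov = _provenance(cfg)
    sim.movie.meta.update(prov)
    movie_path = write_movie(sim.movie, outdir / "movie.tif")
    tifffile.imwrite(outdir / "masks.tif", sim.mask.astype(np.uint16))
    truth = sim.truth.copy()
    write_table(truth, outdir / "ground_truth.csv")
    write_json({**prov, **sim.meta}, outdir / "simulation.json")
    log.info("simulate: %d particles, %d frames, %d cells",
             truth["particle_id"].nunique(), sim.meta["frames_total"], sim.meta["n_cells"])
    return {"movie": movie_path, "masks": outdir / "masks.tif",
            "ground_truth": outdir / "ground_truth.csv", "sim": sim}


def analyze_movie(
    movie: Movie,
    cell_mask: np.ndarray,
    cfg: PipelineConfig,
) -> dict:
    """Full in-memory analysis chain on one movie.

    Returns a dict with the localization table, linked trajectories, the
    4–12-frame subset, per-track motion summaries, the population summary
    and per-stage counts.
    """
    locs = localize_movie(movie, cfg.detection)
    n_spots = len(locs)
    locs, n_discarded = assign_to_cells(locs, cell_mask, movie.pixel_size_nm)
    linked = link(locs, cfg.linking.max_disp_nm, cfg.linking.max_gap)
    filtered, filter_report = filter_in_focus(
        linked, cfg.classify.min_frames, cfg.classify.max_frames
    )
    motion = analyze_trajectories(filtered, movie.frame_interval_s, cfg.classify)
    prov = _provenance(cfg)
    counts = {
        "n_localizations": n_spots,
        "n_outside_cells": n_discarded,
        **filter_report,
    }
    if len(motion):
        population = summarize_population(motion, {**prov, **counts}).as_dict()
    else:
        population = {
            "n_total": 0, "empty": True, "provenance": {**prov, **counts},
        }
    for stage, n in counts.items():
        log.info("analyze: %s = %s", stage, n)
    return {
        "localizations": locs,
        "trajectories": linked,
        "filtered": filtered,
        "motion": motion,
        "population": population,
        "counts": counts,
    }


def run_analyze(
    movie_path: str | Path,
    masks_path: str | Path,
    cfg: PipelineConfig,
    outdir: str | Path,
) -> dict:
    """Disk-to-disk analysis: reads TIFF + sidecar + masks, writes tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    movie = read_movie(movie_path)
    mask = tifffile.imread(masks_path).astype(int)
    res = analyze_movie(movie, mask, cfg)
    write_table(res["localizations"], outdir / "localizations.csv")
    write_table(
        res["filtered"][["particle_id", "frame", "x_nm", "y_nm", "cell_id"]],
        outdir / "trajectories.csv",
    )
    write_table(res["motion"], outdir / "motion.csv")
    write_json(res["population"], outdir / "population.json")
    write_json({**_provenance(cfg), **res["counts"]}, outdir / "linking_report.json")
    return res


def run_report(results_dirs: list[str | Path], outdir: str | Path,
               composite_frames: int = 100) -> pd.DataFrame:
    """Summary table over analyzed conditions (one row per condition).

    Each input directory must hold motion.csv + population.json from
    :func:`run_analyze`; the immotile fraction is recomputed from the
    per-track table so the report is internally consistent.  If the
    condition directory also holds a movie.tif, a composite projection of
    its first frames is written alongside.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in results_dirs:
        d = Path(d)
        missing = [f for f in ("motion.csv", "population.json") if not (d / f).exists()]
        if missing:
            raise FileNotFoundError(f"{d}: missing {missing}")
        motion = pd.read_csv(d / "motion.csv")
        pop = json.loads((d / "population.json").read_text())
        n = len(motion)
        frac = float(motion["immotile"].mean()) if n else float("nan")
        motile_d = motion.loc[~motion["immotile"].astype(bool), "D_um2_s"].dropna() if n else []
        rows.append({
            "condition": d.name,
            "n_tracks": n,
            "immotile_fraction": frac,
            "immotile_percent": 100 * frac,
            "d_motile_mean_um2_s": float(np.mean(motile_d)) if len(motile_d) else np.nan,
            "d_motile_sd_um2_s": float(np.std(motile_d, ddof=1)) if len(motile_d) > 1 else np.nan,
            "reported_fraction": pop.get("immotile_fraction", np.nan),
        })
        movie_path = d / "movie.tif"
        if movie_path.exists():
            movie = read_movie(movie_path)
            nf = min(composite_frames, movie.n_frames)
            comp = composite_projection(movie, nf, mode="max")
            tifffile.imwrite(outdir / f"{d.name}_composite.tif",
                             comp.astype(np.uint16))
    table = pd.DataFrame(rows)
    write_table(table, outdir / "population_table.csv")
    return table


def simulate_and_analyze(cfg: PipelineConfig) -> tuple[SimulationResult, dict]:
    """Convenience: simulate in memory and run the full analysis chain."""
    rng = np.random.default_rng(cfg.seed)
    sim = simulate_population(cfg.simulate, rng, render=True)
    res = analyze_movie(sim.movie, sim.mask, cfg)
    return sim, res
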