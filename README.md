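# myxospt

Single-particle tracking PALM (sptPALM) analysis for bacterial gliding
motility studies, with a ground-truth simulator.

Gliding bacteria such as *Myxococcus xanthus* move by coupling inner-membrane
motor proteins to the substrate through bacterial focal adhesion complexes
(bFACs).  In sptPALM experiments, sparsely photoactivated fluorophore-tagged
motor proteins are imaged at 10 Hz and 160 nm pixels; each tracked particle
is either **immotile** (bound in a substrate-fixed bFAC), in **directed**
motion (motor transport), or freely **diffusive** in the membrane.  The
fraction of immotile particles is the assay's readout of bFAC assembly.

This package implements that analysis chain as a tested, reusable library:

- **simulate** — synthetic sptPALM movies of rod-shaped (spherocylinder)
  cells with stationary/directed/diffusive emitters, geometric
  photobleaching, integrated-Gaussian PSF rendering with Poisson + read
  noise; plus gliding-cell centroid tracks and growth-curve fixtures.
  Ground truth is returned for every particle.
- **localize** — difference-of-Gaussians detection and subpixel symmetric
  2-D Gaussian fitting, `A·exp(−((x−x₀)²+(y−y₀)²)/2σ²)+c`.
- **track** — greedy nearest-neighbour linking (≤500 nm/frame, no gaps)
  and the 4–12-frame (0.4–1.2 s) in-focus filter.
- **classify** — the one-pixel immotile rule (bounding box ≤160 × 160 nm),
  per-track MSD fits `MSD = 4·D·Δt + b` (lags 1–3, free intercept),
  MSD-exponent mode calls, population summaries, composite projections.
- **cellmetrics** — rod length/width from mask medial axes; gliding
  velocity, pause/reversal detection, persistency run lengths.
- **assays** — GRABS stiffness scores
  `(OD_mut,agarose/OD_ref,agarose) − (OD_mut,liquid/OD_ref,liquid)` and
  replicate mean ± SD summaries.

A thin CLI (`myxospt simulate|analyze|report|gliding|morphology|grabs`)
wraps the library for shell use; `examples/` has one narrative script per
capability.

## Worked example

```python
import myxospt as m

cfg = m.PipelineConfig(seed=42)
cfg.simulate.fractions = {"stationary": 0.321, "directed": 0.3395,
                          "diffusive": 0.3395}
cfg.simulate.n_tracks = 600

sim, res = m.simulate_and_analyze(cfg)   # render → localize → link →
pop = res["population"]                  # filter → classify
print(pop["immotile_percent"], pop["n_total"])
```

Running `python examples/01_simulate_and_analyze.py` prints:

```
simulated particles : 586
localizations       : 3369
tracks in 4-12 frame window : 269
immotile fraction   : 37.2%  (ground truth 32.1%)
motile D (mean ± SD): 0.154 ± 0.104 µm²/s
```

At this small n the recovered immotile fraction carries ~3-point sampling
error plus ~2 points of slow-diffuser contamination (see
`docs/methods.md`); at the validation scale of ≥2,000 filtered tracks it
recovers the ground-truth fraction to within ±5 percentage points.  The
motile-D statistic pools directed and diffusive tracks, so it sits well
above the pure-diffusion coefficient.

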