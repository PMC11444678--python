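# Methods

`myxospt` analyzes single-particle-tracking PALM (sptPALM) data of membrane
proteins in gliding bacteria and ships a simulator that generates such data
with known ground truth, so every stage of the analysis chain can be
validated by parameter recovery.  This note records the models, the
defaults, and the numerical choices, and states explicitly what the
synthetic data do and do not demonstrate.

## Imaging and motion model

Cells are 2-D spherocylinders: the set of points within `width/2` of a
central axis segment of length `length − width`.  Membership, reflection
and uniform sampling are exact closed-form operations on this outline.

Each fluorophore moves in one of three dynamic patterns:

- **stationary** — a fixed point in the cell (a motor bound in a
  substrate-anchored focal-adhesion complex);
- **diffusive** — Brownian motion with per-axis increment variance
  `2·D·Δt`, reflected at the cell outline.  Reflection mirrors a proposed
  point across its nearest boundary point; this keeps the marginal step
  variance approximately correct, whereas absorbing walls would bias D
  downward;
- **directed** — constant-speed advance along the cell axis with a
  sinusoidal transverse component (the 2-D shadow of a helical track),
  reversing at the poles.

Photophysics: each emitter activates at a uniformly random frame and stays
on for a geometric number of frames (default mean 6, so most tracks fall in
the 4–12-frame analysis window).  At most one emitter per cell is active at
a time (configurable); emitters sharing a cell are separated by at least
one dark frame, since two temporally adjacent emitters in one
diffraction-limited cell would be indistinguishable from a single particle.

Rendering: each active emitter deposits an integrated symmetric 2-D
Gaussian PSF (total expected photons `photons_per_frame`) onto the pixel
grid; Poisson shot noise is applied to signal + uniform background, then
Gaussian read noise, and the frame is quantized to 16-bit counts.

### Simulator defaults (the simulated study conditions)

| parameter | default | unit | rationale |
|---|---|---|---|
| pixel size | 160 | nm | EMCCD effective pixel of the source experiments |
| frame interval | 0.1 | s | 10 Hz acquisition |
| PSF σ | 120 | nm | ≈0.21·λ/NA for 580 nm emission at NA 1.49 |
| photons/frame | 500 | — | typical photoactivatable-FP yield |
| background | 10 | counts/px | HILO-like residual background |
| read noise σ | 2 | counts | modern EMCCD scale |
| cell size | 6.0 × 0.7 | µm | typical rod dimensions |
| mean on-time | 6 | frames | places most tracks in the 4–12-frame window |
| diffusive D | 0.06 | µm²/s | free membrane-protein diffusion; see below |
| directed v | 1.0 | µm/s | motor-speed placeholder, config-exposed |
| helix period / amplitude | 1.0 µm / 0.8·(w/2) | | transverse oscillation of the directed mode |
| localization noise (render-free path) | 25 | nm | matches typical fitted precision at these photon levels |

The diffusive-mode default deserves a note.  The classification rule (below)
calls a track immotile when its 0.4–1.2 s bounding box fits in one pixel.
A diffusive population with D ≲ 0.03 µm²/s places 15–25% of its 4–12-frame
tracks inside that box — such a mode is not operationally "motile" under
the rule, and a mixture built from it cannot be recovered without bias by
*any* classifier applying the rule.  The generator therefore defaults to
D = 0.06 µm²/s, a realistic free-diffusion coefficient for a bacterial
inner-membrane protein, which keeps the three modes mutually
distinguishable (expected slow-diffuser contamination of the immotile class
≈ 2 percentage points).  The slower measured coefficients (1.8 × 10⁻² and
2.9 × 10⁻² µm²/s) are used directly as generating values in the
diffusion-recovery validations, where no classification is involved.

## Analysis chain

**Detection.**  Each frame is band-passed with a difference of Gaussians
(σ 1 and 4 px); candidates are local maxima strictly above
median + k·1.4826·MAD of the band-passed frame (default k = 5, a robust
5-sigma rule).  Maxima closer than 4 px collapse to the brighter one.

**Localization.**  A symmetric 2-D Gaussian `A·exp(−((x−x₀)²+(y−y₀)²)/2σ²)+c`
is least-squares fit in a 7×7 px window by a damped (Levenberg–Marquardt)
Gauss–Newton solver batched over all candidate windows of a movie.  σ is
initialized at 1 px and bounded to [0.5, 3] px; fits pinned at a σ bound are
dropped as non-converged.  Least squares (not MLE) keeps the estimator
noise-model-free.  Coordinates are 0-based with the centre of pixel (i, j)
at (i+0.5, j+0.5) px; nm = px × pixel size.  On noiseless input the centre
error is < 0.02 px; at 100–2000 photons and low background the empirical
precision stays within 2× the photon-limited bound σ_psf/√N (with strong
background the background term dominates and that bound does not apply).

**Linking.**  Greedy nearest-neighbour assignment between consecutive
frames: candidate pairs sorted by distance (ties by smaller particle id),
pairs beyond `max_disp` = 500 nm never link, links never cross cell masks,
and `max_gap` = 0 (an uninterrupted-detection reading of "remained in
focus").  500 nm is ≳3× the per-frame RMS displacement of the fastest
default mode, giving a low miss rate without cross-linking sparse PALM
data.  Greedy assignment is adequate at this sparsity and is documented as
swappable.

**Focus filter.**  Only trajectories of 4–12 consecutive frames
(0.4–1.2 s at 10 Hz) are analyzed, both bounds inclusive.

**Immotile rule.**  A track is immotile iff its per-axis position spans
satisfy `span_x ≤ 160 nm` and `span_y ≤ 160 nm` — the explored area fits in
one camera pixel.  This axis-aligned bounding-box reading is the simplest
operationalization of "within one pixel"; a convex-hull-area variant would
be stricter for diagonal motion but needs an area convention.  The rule is
invariant under time reversal and rigid translation, and spans are
monotone under track extension.  With 25 nm localization noise, fewer than
0.1% of truly stationary 4–12-frame tracks leave the box; misclassification
up to 5% is tolerated in validation.

**Diffusion estimation.**  Per-track time-averaged MSD over all ordered
pairs; ordinary least squares of `MSD = 4·D·Δt + b` over lags 1–3 with a
free intercept absorbing `4σ_loc²`.  Negative slopes clamp to D = 0 with a
quality flag rather than being dropped (dropping would bias the population
upward).  Per-track estimates are reported as population mean ± SD (SEM is
also provided, since either convention appears in the literature).  A
small-sample caveat: per-track D̂ from 4–12-frame tracks is strongly
right-skewed, so its *median* underestimates D by ~17–25% depending on the
lag choice even though the mean is unbiased to within a few percent; the
population statistic of record here is the mean.

**Mode classification.**  Immotile ⇒ stationary; otherwise the MSD scaling
exponent α from a log–log OLS over lags 1–4 separates directed (α ≥ 1.5)
from diffusive; non-stationary tracks too short for 4 lags are ambiguous.
The α threshold is a config default — the three patterns are standard but
no universal cut exists.

**Composite projection.**  Per-pixel maximum (or mean/sum) over the first
100 frames, the conventional way to display bFAC positions accumulated by
many transient emitters.

## Cell morphometry

Length and width come from a mask's skeleton: the medial axis is extracted
(`skimage.morphology.skeletonize`), endpoint branches shorter than the
local radius are pruned (cap spurs), and the skeleton diameter path is
taken.  Two discrete artifacts are corrected: staircase zigzag (the path
coordinates are boxcar-smoothed before summing segment lengths) and the
half-pixel offset of the Euclidean distance transform (distances run to
background pixel centres).  The axis intrudes a distance `r − d_end` short
of each pole centre, so total axis length and width satisfy the capped-rod
area relation `area = axis·W + π(W/2)²`, solved in closed form for W; then
`length = axis + W`.  A disk degenerates to `length = width = diameter`
exactly.  Accuracy on synthetic rods is ≲1 px for the standard geometry and
≲1.5 px across tested aspect ratios; the estimator assumes a roughly
constant-width rod and is not a general blob morphometer.

## Gliding kinematics

Centroid tracks sampled at uniform 10-s intervals.  Pauses are maximal runs
of ≥2 consecutive steps below 0.3 µm/min; reversals are steps where
boxcar-smoothed (window 3) heading vectors before and after have negative
dot product sustained for ≥2 steps, evaluated outside pause windows.
Velocity is non-pause path length over non-pause time; persistency runs are
the path lengths between consecutive event boundaries (track ends count as
boundaries), and conserve total non-pause path length by construction.
Both thresholds are config-exposed: the source experiments quantify pauses
and reversals without stating operational criteria, so measured velocities
and persistencies from real data are context for these defaults, not
reproduction targets.  Single-step pauses are invisible to a 2-step
detection floor; recovery validations therefore use mean pause durations of
4 steps.

## GRABS and replicate statistics

`score = OD_mut,agarose/OD_ref,agarose − OD_mut,liquid/OD_ref,liquid`,
defined only when all four ODs are positive; positive scores = stiffer than
reference.  The score is computed at every shared time point and reported
at the final (24 h) point by default, the full time course being retained —
the assay's headline values are endpoint ratios and the evaluation time is
otherwise a free choice.  Replicate summaries are mean and sample SD
(n−1); SD is reported absent at n = 1.

## What the synthetic data do not show

The generator has no 3-D PSF or defocus (particles never blur out of
focus — the 4–12-frame window is imposed by photobleaching alone), no HILO
illumination profile, no EM-gain excess noise, no fluorophore blinking, no
stage drift, and only straight cells on a regular lawn.  Passing recovery
tests therefore certifies the *analysis chain* — detection, fitting,
linking, filtering, classification, estimation — under a faithful but
simplified acquisition model; it does not certify robustness to the above
optical effects in real data.

## Validation scales

Diffusion recovery uses 5,000 tracks per coefficient; end-to-end
immotile-fraction recovery uses 5,600 simulated particles per condition
(≥2,000 tracks survive the focus filter); stationary-misclassification
Monte Carlo uses 10⁴ tracks; localization precision uses 500 replicates per
photon level.  These sizes give sampling errors several times smaller than
the corresponding acceptance bands.
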