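# Methods

`resectrack` quantifies DNA double-strand-break (DSB) end resection and the
accompanying chromatin-mobility changes from live-cell fluorescence movies of
ParB/INT-labelled loci, and ships a synthetic-movie generator that provides
ground truth for validating every stage.

## The measurement model

A site-specific endonuclease (HO at the yeast *MAT* locus) cuts a fraction of
induced cells. Two ParB-bound cassettes flank the cut: INT1 spans 76–1231 nt
and INT2 spans 3400–7612 nt from the cut site. ParB binds only double-stranded
DNA, so when the 5′→3′ resection front converts a cassette to single strands
its fluorescent focus fades and finally disappears when the front reaches the
cassette's **distal** edge. Focus-loss times therefore time-stamp the
resection front:

- duration to INT1 loss = `t_loss − t_cleave_earliest`, with the earliest
  cleavage anchored at 10 min after induction (per-cell cleavage times are
  unobservable in this assay);
- slow-phase speed = 1231 nt / duration;
- fast-phase speed = (7612 − 1231) nt / (t_loss_INT2 − t_loss_INT1) in cells
  losing both foci;
- commitment delay = mean INT1 loss time (wild type) − mean INT1 loss time
  (*yku70*), since the Ku complex delays the onset of resection but not its
  speed.

Chromatin mobility is summarized by the diffusion coefficient `D = slope/4`
of an ordinary-least-squares line fitted to the ensemble 2-D MSD over lags
≤ 2 s. The fit includes an intercept even though the idealized model passes
through the origin: static localization noise σ_loc adds `4 σ_loc²` to every
lag of the MSD and would otherwise inflate D. Mobility is also reported as
`100 · D / D_ref` with `D_ref = 0.019 µm²/s`, the uncut-locus reference.

## Synthetic movies

The generator emulates the acquisition (65-nm pixels, bursts of 50 × 200-ms
frames every 2 min for *yku70* or 5 min for wild type, starting 8 min after
induction) and the biology:

- **Cleavage**: each cell is cut with probability `p_cut` (0.6); cleavage
  times are Gaussian (mean 13 min, sd 1.5 min) truncated at the 10-min floor
  by redrawing. Resection starts after a genotype-specific commitment lag
  (10 min wild type, 0 in *yku70*).
- **Resection front**: advances at `v_slow` to the phase switch at 1231 nt,
  then at `v_fast` (1900 nt/min) when the fast phase is enabled (*yku70*);
  in wild type the front halts after INT1 (homology search curtails it).
  A focus amplitude declines *linearly* while the front traverses its
  cassette (ParB coats the cassette roughly uniformly) and reaches zero
  exactly at the distal edge.
- **Preset calibration**: the wild-type loss window of roughly 22–31 min and
  the *yku70* window of 12–19 min (mean 15) are jointly reproduced with a
  *single* post-onset slow speed `v_slow = 615.5 nt/min` (= 1231 nt / 2 min)
  and the cleavage law above. The familiar 82 nt/min figure is the
  *cleavage-anchored* effective speed (1231 nt / 15 min); it folds the
  10-min commitment lag into the duration and is reproduced by the
  mean-anchored report on wild-type cohorts.
- **Motion**: free motion uses exact Brownian increments (per-axis variance
  `2 D Δt`); confined motion uses the exact discrete Ornstein–Uhlenbeck (OU)
  update `x' = a + (x−a) e^(−Δt/τ) + sqrt(D τ (1−e^(−2Δt/τ))) ξ` anchored at
  the position where confinement began. Confinement (D = 0.003 µm²/s,
  τ_c = 20 s) starts 5.5 min after cleavage and reverts 30 min (wild type)
  or 18 min (*yku70*) after cleavage. Sub-diffusion is approximated by this
  confined-OU model rather than fractional Brownian motion: the analysis
  uses only the first-2-s slope and the plateau, which OU captures.
- **Nuclear territory in movies**: unbounded Brownian motion would leave the
  4-µm field over a one-hour movie with certainty, so inside `generate_movie`
  the "free" regime is an OU tether with τ = 10 s (stationary sd ≈ 0.44 µm,
  the scale of a chromosomal territory). At the 0.2–2 s lags used for
  fitting this is Brownian to within ~10%. `simulate_trajectory`'s free mode
  remains exactly Brownian and is what the closed-form checks and the
  diffusion-recovery experiments use.
- **Rendering**: pixel-integrated Gaussian PSF (σ = 1.3 px), 3000 expected
  photons per intact focus (peak SNR ≈ 14 over a 100 photon/px background),
  exponential background photobleaching (τ = 20 min, which makes the raw
  focus/background ratio of an intact focus *rise* during early
  acquisition), Poisson shot noise, Gaussian read noise (sd 3), gain 1,
  clipped to 16 bits. One root seed is split per cell (and per stream within
  a cell) so any cell's movie is reproducible in isolation.

What the generator does **not** emulate: anomalous-exponent sub-diffusion,
3-D optics and defocus, nuclear-envelope geometry, cell-to-cell brightness
variation, vibration/drift, and multi-nucleus fields. Passing tests
therefore demonstrate that the estimators recover what this model injects at
realistic SNR and sampling; they do not certify performance on real movies
with those additional nuisances.

## Detection, tracking, quantification

Detection follows the classic particle-detector recipe with radius 4 px:
boxcar (9 px) background subtraction, Gaussian matched filter (σ = radius/2),
local maxima within one radius, retention of maxima in the top 0.1% of
filtered pixel intensities with score > 0, and sub-pixel refinement by
intensity-weighted centroid. Note the percentile gate is global: on a 64×64
field it keeps ≈ 4 pixels, i.e. essentially one focus per channel — adequate
here because each channel carries a single focus, but a parameter to revisit
for crowded fields. Linking is greedy globally-nearest-neighbour with a
10 px gate, ties broken toward the lower frame-local index, no gap closing;
tracks must span strictly more than 15 consecutive frames to be scored.
Linking is performed within bursts only (the locus moves many pixels between
bursts). The greedy rule can under-match relative to a minimal-total-distance
assignment on constructed counterexamples (documented in the test suite); on
well-separated foci the two coincide.

The intensity readout sums a 9-px horizontal line through the focus and
divides by an equally long line displaced by 15 px (eight compass directions
are tried if the preferred line is out of frame or near a detected spot),
normalized to 100% at the first timepoint. After focus loss the line stays at
the last tracked position.

### Loss calling

Three rules are implemented, all reporting the first qualifying timestamp on
the burst time base:

1. **intensity** — excess ratio (above the post-loss plateau) falls below
   `threshold_fraction` (0.5) of its pre-onset level for 3 consecutive
   points. A contrast gate (the plateau must sit ≥ 20% of the pre-onset
   median below it) prevents fluctuations of intact foci from triggering
   calls on uncut cells.
2. **detection-absence** — first burst whose frames contain no persistent
   track, confirmed by 3 consecutive empty bursts. Presence requires one
   track covering ≥ 50% of a burst's frames; spurious noise maxima do not
   form long tracks.
3. **extrapolate** (pipeline default) — because extinction is linear in
   time, the threshold rule is early by `threshold × traversal time` and the
   absence rule is late by about one burst. This rule fits a line to the
   mid-fade points of the excess ratio and reports its zero crossing; when
   the fade completes between two bursts it falls back to the midpoint of
   the bracketing burst times. It is unbiased for both slow (INT1) and fast
   (INT2) fades, which matters when estimating the fast-phase speed from the
   short INT1→INT2 interval.

## Numerical and design choices

- Pixel (i, j) spans `[j·px, (j+1)·px) × [i·px, (i+1)·px)` in µm; detector
  coordinates place a pixel's center at integer (x, y), so µm = (px + 0.5)·65 nm.
  Constant offsets cancel in all displacements.
- Burst timestamps: all kinetics use the burst start time (the 10-s
  within-burst span is negligible on the minutes axis).
- MSD ensemble averaging is an unweighted mean over per-track time-averaged
  curves (a pair-count-weighted variant is available via `weighted=True`).
- Mobility-schedule transitions take effect at the next simulated step; with
  burst acquisition this quantizes transitions to at most one burst interval.
- `estimate_D` on confined motion is biased low by ~5–10% because a straight
  line is fitted to a saturating curve over the 2-s window — an estimator
  property, not a generator defect; recovery experiments equilibrate confined
  tracks (100-s burn-in) so they measure the stationary regime the assay sees.
- Degenerate inputs fail loudly: non-increasing timestamps, negative D,
  missing τ_c, empty track lists, traces shorter than the persistence
  window, loss times before the earliest-cleavage anchor.

## Problem sizes

The validation suite uses cohorts of 6–28 cells, 16–20 frames per burst and
movies of 28–52 min, and 100–500 simulated tracks for estimator checks;
these sizes were chosen so each experiment's Monte-Carlo error is well inside
the tolerance it asserts. The end-to-end recovery experiment injects
(v_slow, v_fast, lag) = (82 nt/min, 1900 nt/min, 10 min) and recovers them
within (15%, 15%, 1.5 min) through the full imaging pipeline; burst-interval
quantization dominates its error budget.

## Known limitations

- The percentile detector gate is global, not per-tile; crowded fields would
  need a larger retained fraction.
- No gap closing: a single missed frame splits a track (harmless for MSD,
  which pools tracks, and for presence, which needs only half a burst).
- Censoring is reported only as `fraction_lost`; no survival-analysis
  treatment of never-lost cells.
- The commitment delay estimated from loss-time means inherits any
  between-genotype difference in cleavage-time distributions; the simulator
  uses a shared cleavage law, as the underlying model assumes.
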