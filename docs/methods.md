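# Methods

`axoquant` quantifies three readouts of axonal health in compartmentalized
(microfluidic-chamber, MFC) motoneuron cultures — organelle trafficking,
growth-cone regeneration after axotomy, and immunofluorescence marker levels —
and ships a ground-truthed synthetic-scene generator so that every stage of
the pipeline is verifiable without microscopy data. This note records the
models, the parameters that matter, and the choices made where the design was
genuinely open.

## Synthetic scenes

**Organelle movies.** A movie is a single-channel stack (default 400 frames,
512×512 px at 229.55 nm/px, 3.3 frames/s) containing two horizontal corridors
that stand in for MFC microchannels. Each organelle belongs to one of three
motility classes: *stationary*, *jitter* (zero-mean Gaussian random walk,
default step 0.05 µm/frame, confined to its corridor), or *processive*
(constant per-object speed drawn once from N(`speed_mean`, `speed_sd`)
truncated at 0, moving anterogradely with probability
`anterograde_fraction`). Classes can be given as explicit counts or as a
total plus a `moving_fraction` (Bernoulli per organelle; non-movers split
stationary/jitter by a fair coin). Organelles are rendered as Gaussian
profiles — isotropic with FWHM = diameter for lysosomes (default 0.8 µm),
anisotropic along the corridor axis for mitochondria (default 1.6 × 0.4 µm
axes, i.e. aspect ratio 4). Noise is Poisson shot noise on a constant
background (default 100 counts) plus additive Gaussian read noise (SD 2), the
standard EMCCD model; SNR is defined as peak spot amplitude over the
background noise SD (default 10). All draws come from one
`numpy.random.default_rng(seed)` in a fixed, documented order, so identical
configs are bit-identical.

What this does *not* emulate: axon geometry within a corridor, organelle
fission/fusion, photobleaching, motor pausing/reversals, or inter-channel
crosstalk. Passing tests therefore demonstrate that the measurement chain is
correct for data matching its stated model, not that the detector is optimal
for every real movie.

**Growth-cone movies.** A bright-field-like stack (default 360 frames = 2 h at
3 frames/min, 128×128 px at 160 nm/px) holds one dark deformable ellipse (the
cone; axes fluctuate per frame by `shape_fluctuation_amplitude`, symmetric
about the center) trailing a thin darker axon shaft, on a light background
with Gaussian noise. The cone advances with a fixed per-frame step length —
the per-movie speed drawn once from the configured normal law, truncated at 0
— along a heading that random-walks and steers away from a field margin. A
straight 2-hour drift at physiological speed would cover ~480 µm, far beyond
any practical field of view; real cones meander, and the measured quantity
(mean travel distance between consecutive frames) is independent of
direction, so the meandering path preserves the quantity under study while
keeping the scene finite.

**IF stills.** A multi-channel image (channel 0: Hoechst nuclei; then one
channel per marker) with `n_cells` nuclei placed by rejection sampling at a
minimum separation (default 26 px, so segmentation errors do not confound
counting statistics). Marker positivity is Bernoulli per cell at the
configured fraction; a marker may be *conditional* on a parent (e.g. SMI32
within MAP2), in which case its fraction applies inside the parent-positive
population only. Positive somata render at `marker_intensity_pos` (default
120 over a background of 20, noise SD 3), negatives at 5 — chosen so the
default positivity rule (blank mean + 3 blank SDs) separates the populations
by construction, as the study's fixed-threshold convention assumes. Optional
neurites are straight faint lines sharing geometry across channels.

## Organelle tracking

Detection is a scale-normalized Laplacian-of-Gaussian band-pass at
σ = radius/√2, with non-maximum suppression at one blob radius and a quality
threshold expressed in robust (MAD-based) noise SDs of the response;
positions refine to the background-subtracted intensity centroid. Defaults:
blob radius 0.4 µm — matched to the generator's default lysosome — and
threshold 5 SD. The threshold default follows from extreme-value arithmetic:
a 512×512 frame has ~2.6·10⁵ response pixels, so 3-SD noise peaks number in
the hundreds while the observed noise-peak ceiling is ≈4.8 SD and SNR-5
spots score ≥5.2 SD; 5 SD is the separating value. Both are configurable per
dataset.

Linking is greedy globally-nearest frame-to-frame assignment (candidate pairs
sorted by distance, threshold 1 µm per frame of gap, no gap closing by
default, no splitting/merging). For well-separated objects this equals the
exhaustive minimum-total-distance assignment, which the tests verify on
small instances.

Each track with ≥2 spots yields the master parameter set: duration, net
displacement, mean/max/min/median speed and speed SD (per-step Euclidean
distances over elapsed time; SD is the sample SD, ddof = 1), summed path
length, a *moving* flag (net displacement ≥ 1 µm, inclusive), and a direction
(anterograde/retrograde by the sign of net x-displacement under the declared
proximal→distal axis; |net x| < 1 px ⇒ "none", excluded from the ratio).
Movie-level summaries average parameters over tracks, report percent moving
over all ≥2-spot tracks, and the anterograde/retrograde count ratio (NaN when
no retrograde track exists).

Shape is measured on the movie's first frame: threshold at background median
+ 3 robust noise SDs (a bimodality-assuming threshold such as Otsu lands
inside the noise on sparse-spot frames), connected components, then per
particle the maximum Feret diameter (for lysosomes) and the moment-fitted
ellipse major/minor ratio (for mitochondria). Each track receives the shape
of the particle nearest its first spot. Note the convention gap: a Gaussian
spot of FWHM 0.8 µm measures ≈1.2–1.4 µm across at a 3-SD threshold; Feret
values are therefore comparable *between* conditions, not absolute physical
diameters.

## High-content profiles

A condition is (genotype pool, treatment, marker, position). Its 11
parameters, per movie, feed the 44-entry profile ordered mito-distal (1–11),
mito-proximal (12–22), lyso-distal (23–33), lyso-proximal (34–44). Every
entry is a Z-score against the *untreated control proximal* baseline of the
matching marker — distal entries included, which is why untreated-control
proximal entries are exactly zero while its distal entries show the natural
proximal→distal gradient. The baseline spread is the SD across per-movie
baseline values (the only replication level available per condition;
per-organelle spread is exposed as an alternative through the condition
tables). A zero baseline SD is rejected as degenerate rather than silently
propagated.

Line profiles pool entrywise (mean ± SD across lines). Pairwise condition
comparisons fit a two-way ANOVA (condition × parameter index) on per-line
Z-scores and Bonferroni-adjust the condition main-effect p by the number of
pairs — the replicate unit is the line profile, matching how the pooled
error bars are defined.

## Growth-cone tracking

Per frame, the ROI is contrast-stretched (0.1% saturation split equally
between tails), inverted (light background), background-corrected with a
rolling ball of radius 20 px, thresholded with the percentile rule, and
despeckled (components < 20 px dropped). Two numerical choices matter:

* **Rolling ball.** The exact ball costs ~50 ms per 128² frame; the package
  uses the shrink-and-roll strategy (block-minimum shrink ×4, ball at
  radius/4, 3×3 mean smooth, bilinear re-enlargement, clipped below the
  image) that FIJI itself applies for radii above 10 px. Mean deviation from
  the exact ball is ~1 grey level on noise and ≤3.5 on smooth gradients;
  `shrink=1` selects the exact ball.
* **Percentile threshold.** Defined as the smallest intensity at which the
  below-threshold fraction reaches the target. The default target is 0.98:
  in a migration-covering ROI the cone plus shaft occupy on the order of 2%
  of pixels, and a 0.5 target would flood half the ROI into one percolating
  foreground component. The target is configurable for tighter ROIs.

The center per frame comes from a shrinking circular search region around the
previous center (radius 3× the expected per-frame displacement): the radius
is reduced until a single component remains, that component is recovered in
full, and its intensity-weighted centroid is taken. Two robustness rules
guard the selection: components far smaller than the largest candidate in
the search region (shaft fragments, debris) are not eligible, and the
centroid is computed over the component's intensity core (≥50% of its peak
corrected intensity) within the search region, so a fainter connected axon
shaft cannot drag the center backwards. Ties break by distance, then larger
area. Missed frames are gaps (excluded from step statistics); a gap longer
than 5 frames ends the trajectory. Mean outgrowth speed is the mean over
consecutive detected pairs of Euclidean distance × pixel size / elapsed
time. On synthetic cones across the physiological speed range the
recovered-vs-true regression slope is within [0.9, 1.1] and per-movie errors
are below 1% away from the extremes.

The axotomy check fixes an Otsu foreground threshold on the pre-axotomy
still and reports the residual foreground fraction of the post-axotomy
still against a configurable blank threshold.

## IF quantification

Nuclei are segmented on the Hoechst channel (Otsu + minimum area); a cell is
marker-positive when the mean marker intensity over its 3-px-dilated nuclear
region exceeds the marker threshold. Thresholds default to *blank* statistics
— the 32×32 tile of lowest mean intensity stands in for a manually chosen
blank area — at mean + 3 SD, applied identically across conditions. The CC3
(apoptosis) fraction is computed among cells whose dilated nuclear region
overlaps the despeckled MAP2 mask, restricting the readout to neurons.
Intensity per neurite length divides the background-corrected integrated
intensity of the thresholded neurite mask by the skeleton length (skeleton
pixel count × pixel size — a slight underestimate on diagonal segments). The
acetylated/α-tubulin ratio compares background-corrected channel means over
the α-tubulin (structural) mask.

## Statistics layer

Normality screening is a one-sample Kolmogorov–Smirnov test against a normal
law with the sample's own mean and SD (n ≥ 3; constant samples rejected). In
`auto` mode, group comparison uses one-way ANOVA with Bonferroni-adjusted
pairwise t-tests when all groups pass, otherwise Kruskal–Wallis with
Bonferroni-adjusted pairwise Mann–Whitney U tests (the closest standard
reading of a "Kruskal–Wallis post-hoc test"; the exact pairwise test is
configurable). Bonferroni adjustment is exactly min(1, m·p) for m pairwise
comparisons, and results carry the conventional star tiers.

## Pipeline and problem sizes

`run_full_pipeline` wires simulate → track → profile → compare per condition
cell, derives one seed per movie from the master seed via SHA-256 (so any
subset is reproducible independently), and writes CSVs plus a manifest;
reruns are bit-identical. The scenario table expresses biology purely as
generator parameters; the shipped default encodes a distal-only mutant
deficit (≈60% of control speed and moving fraction) rescued at 10 Hz and
10/2 Hz but not at 2 Hz, with proximal conditions physiological everywhere.

Problem sizes are deliberately scaled: tests run movies of 30–120 frames at
96–256 px and small designs; `scripts/acceptance.py` runs the growth-cone
recovery at full movie length (360 frames, 2 h at 3 frames/min) with 200
movies per pool — the pool-law draw, not the tracker, dominates the error at
these sizes, and 200 draws put its SEM near 3% — and the IF recovery at the
study's convention of 10 images × 200 cells. The replication defaults on
`ExperimentDesign` (45 movies per condition, 3 experiments, 10 images)
mirror the study design and are practical for batch runs, not for unit
tests.

## Known limitations

* The synthetic scenes are minimal statistical stand-ins; none of the
  generators attempts optical realism (no PSF model beyond Gaussian blur, no
  DIC shear physics, no photobleaching or focus drift).
* Min/median/max speed conventions are per-step within a track; instruments
  or plugins that define them per-track-window will differ.
* The growth-cone module tracks a single cone per ROI by design; several
  cones require several ROIs.
* Treatment effects enter only as configured parameter shifts; nothing in
  the package models the physics of field exposure beyond the waveform and
  schedule definitions.
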