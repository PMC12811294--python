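# Methods

`imnpheno` implements the quantitative pipeline used to phenotype
cultures of induced motor neurons (iMN) produced by direct conversion of
fibroblasts: single-cell segmentation and morphological classification,
neurite and TDP-43 morphometry, mitochondrial membrane-potential and
motility measurements, longitudinal viability tracking with survival
statistics, and extracellular-flux / biosensor trace analysis. Because
the original imaging data cannot ship with the code, every stage is
validated against a synthetic-data generator that renders the same kinds
of inputs with known ground truth.

## Synthetic data model

The generator emulates the study's imaging conditions, not microscope
physics. Optics are reduced to hard-edged or Gaussian intensity
profiles; noise is additive Gaussian on a flat background (photon
statistics and PSF modelling are deliberately out of scope). The three
standard magnifications carry pixel sizes 0.69 µm (10×, viability
tracking), 0.345 µm (20×, neurite morphology) and 0.1725 µm (40×,
organelle imaging).

Cell archetypes encode the morphological criteria that separate the
three classes in converted cultures:

- **iMN** — disk soma of radius 5–10 µm, bright, with 1–5 neurites drawn
  as random-walk polylines (width ≈ 1 µm, length 20–60 µm);
- **non-iMN** — large flat dim ellipse, major axis ≥ 30 µm,
  eccentricity ≥ 0.7;
- **dead** — 2–4 bright fragments ≤ 4 µm across with a small condensed
  (pyknotic) nucleus.

Cells are placed by rejection sampling under a configurable soma-overlap
bound (default: overlap area ≤ 10 % of the smaller soma); an
unsatisfiable request raises a placement error. Somata claim label
pixels before neurites so that a neurite crossing another cell's body
never owns its pixels. Channels rendered per field: cytoplasm
(eGFP-like), nuclei (Hoechst-like), mitochondrial puncta (TMRM-like) and
an antibody-like channel painted at each cell's true cytoplasm/nucleus
intensity ratio (drawn from 0.2–1.2).

Time-lapse movies follow the viability-imaging schedule (every second
day, D12–D46, 18 timepoints). Each cell's death time is exponential with
rate `baseline_hazard · exp(log HR)`; a cell dying on day *d* is present
in frames with day < *d* (half-open presence), so observed duration
equals death day − entry day. All cells enter at the first imaging day
by default; the recognition-day spread of real cultures is configurable
but not calibrated, since no value is published. A death that would fall
exactly on the final scheduled day is censored there: without later
frames a disappearance at the last timepoint cannot be confirmed, and
this keeps the invariant "event = 0 whenever end = final day" exact.

Kymograph stacks render mitochondria as Gaussian puncta (σ ≈ 0.3 µm,
diffraction-scale) moving along a gently curved neurite path. Frame
count for duration *D* at frame rate *f* is `floor(D·f) + 1` including
t = 0 (10 min at 0.33 Hz → 199 frames); the same rule is used by the
analyzers. Motile mitochondria move at a constant speed drawn from
1.5–3 µm/min with rare direction reversals and reflection at the path
ends; stationary ones jitter with σ = 0.02 µm, far below the motility
threshold. The generator validates that the requested speed range can
exceed the threshold within the experiment duration.

Flux plates follow the mito-stress-test injection protocol (baseline,
oligomycin, FCCP, antimycin A + rotenone + 2-deoxy-D-glucose; 3
measurement cycles per phase, 6 wells per line). Raw OCR per phase is
the true parameter plus the non-mitochondrial term; ECAR analogously
with the non-glycolytic term. Biosensor series: MitoSOX intensity is
linear in time (every 10 min for 3 h, 19 samples); PercevalHR 490/405
ratios are piecewise constant with transitions at the oligomycin (5 min)
and 2-DG (15 min) injections.

What passing tests on these fixtures do **not** show: robustness to
uneven illumination, focus drift, photobleaching, cell migration,
overlapping neurite fascicles, or detector noise correlations — none of
which the generator emulates.

## Segmentation and classification

Cell bodies and nuclei are found classically: Gaussian blur (sigma in
µm, so parameters transfer across magnifications), thresholding (Otsu,
a robust background rule median + k·MAD, or a fixed value), then
size/roundness exclusion (roundness = 4πA/P², default minimum 0.5 for
somata, disabled for nuclei). Background subtraction uses grey-opening
with a decomposed disk footprint — the rolling-ball idea — and is
validated against `skimage.restoration.rolling_ball` on synthetic spots.

The enhanced-contrast composite equalizes each channel exactly by ranks
(average ranks on ties, output in [0, 1]) and sums them pixelwise. This
composite serves as the watershed *relief* only: its rank-flattened
histogram carries no threshold information, so the foreground comes
from robust background thresholds of the raw channels. Single-cell
segmentation is nucleus-seeded: detected nuclei seed a watershed on the
inverted composite constrained to the foreground, and each region then
yields a body mask by per-region adaptive thresholding (pixels above
70 % of the region's 95th intensity percentile), which adapts to each
archetype's own brightness scale.

The learned crop classifier of the original workflow is replaced by a
deterministic feature-based classifier with the same three-class output
contract: multinomial logistic regression on seven features (soma area,
roundness, fragment count in a 27.6 µm centre crop, neurite count,
neurite skeleton length, mean and max intensity), standardized, trained
on labelled synthetic archetypes with a seeded 75/25 validation split.
Exact posterior ties break dead > non-iMN > iMN, biasing against
inflating transformation efficiency. A thresholds-only rule classifier
provides the same contract where no training data exists, and any
external model with `predict(features) → labels` can be plugged in.
Transformation efficiency is iMN count over all detected cells (dead
included; configurable), reported per line with across-batch SEM.

## Morphometry

Skeletons come from topology-preserving thinning. The pixel graph
weights diagonal steps √2 × pixel size and drops a diagonal edge
whenever an orthogonal two-step path exists, so no spurious triangles
inflate lengths. The graph is condensed into branches between nodes
(endpoints and clusters of junction pixels); terminal spurs shorter
than 2 µm (configurable) are pruned before branch counting, because
thinning artifacts otherwise dominate. Neurite metrics exclude skeleton
pixels inside the soma by default. TDP-43 localization uses mean (not
integrated) intensity in nucleus and cytoplasm, making the ratio
independent of compartment areas and exactly invariant to intensity
rescaling; nuclei pair to the cell containing their centroid, and
multinucleate or anuclear cells are excluded from ratio statistics and
listed in a QC report.

## Mitochondria and motility

Per-cell mitochondrial segmentation thresholds the
Laplacian-of-Gaussian response (Otsu within the cell) with an absolute
intensity gate at median + 6·MAD of the in-cell signal — Otsu alone
always "finds" structure in pure noise. Objects closer than 0.2 µm fuse
(morphological closing); per-object area, mean intensity, skeleton
length and elongation are averaged per cell.

Kymographs sample the neurite path at pixel-size steps, taking the
maximum across a 3-pixel-wide normal per position; row 0 is the soma
end, so positive displacement is anterograde. Ridges are detected per
timepoint (`scipy.signal.find_peaks` with prominence ≥ 5·MAD **and**
height above median + 8·MAD — the absolute gate prevents self-sustaining
noise tracks) and refined to sub-pixel by parabolic interpolation.
Linking is greedy nearest-to-prediction with a constant-velocity
prediction whose velocity is the median slope over the last 13 real
observations: a long robust window keeps the estimate anchored to the
track's own motion while it is briefly matched to a wrong ridge at a
crossing, so identity swaps self-correct. The match cost adds a
velocity-consistency term (weight 4). When two mitochondria cross and
their peaks merge, the losing track coasts on its own prediction rather
than adopting the shared peak — this keeps stationary tracks from being
dragged along motile ridges. Tracks may gap up to 15 frames (occlusions
last tens of frames at these speeds); gaps are filled by linear
interpolation, and track duration is the spanned time, not the count of
observed frames.

Motility scoring: total movement is the cumulative path length Σ|Δs| (a
back-and-forth mitochondrion is biologically motile; net displacement
available by flag); the threshold rule is inclusive — total ≥ 12.5 µm
over the 10 min recording ⇒ motile. Anterograde and retrograde distances
sum positive and negative steps, so their sum equals total movement
exactly. Tracks shorter than the full recording are scored on their own
duration but flagged and excluded from motile-fraction defaults, since
the threshold is defined over the whole experiment. Motile-fraction
recovery is assessed on 50-mitochondrion fixtures (150 µm path; mean
over three fixtures, mirroring per-cell averaging of the fraction).

## Viability tracking and survival statistics

Detection in time-lapse frames is the classical stand-in for a learned
detector: blob detection with neuronal-morphology criteria (compact
bright round somata), optionally filtered by the fitted classifier.
Cultures are nearly static, so linking is a deterministic greedy
one-to-one IoU matcher (association IoU ≥ 0.3, gap tolerance 1 frame,
ties broken by higher IoU then smaller track id) run both forward and
backward in time; the tracker interface is pluggable for motion-model
trackers. Tracks from overlapping tiles and both directions merge when
they share ≥ 1 day with mean IoU ≥ 0.5 over shared days; merging is
transitive, and each merged day keeps the highest-score source box.
Duplicate resolution across tiles happens only through merging, not
detection-level suppression.

Start-end-censor conversion: start = first sighting; death = first
missed scheduled timepoint after the last sighting (event = 1);
presence at the final day censors (event = 0), including the boundary
case above. MOTA is computed per frame with persistent identities:
previous matches survive while still above the IoU threshold, remaining
objects match greedily by IoU, and MOTA = 1 − (FN + FP + IDSW)/GT.
Tracker parameters are tuned by seeded random search over a declared
space, maximizing mean MOTA on ground-truth movies; the optimizer is a
swappable hook because the objective and space, not the search
strategy, define the result. Cohort subsampling takes 500 cells per
group uniformly without replacement, returning undersized groups whole
with a flag.

Kaplan–Meier estimation and the pairwise logrank test are delegated to
lifelines (raw p-values always reported; Bonferroni over pairs by
default). Cox proportional hazards goes through statsmodels `PHReg`
with Breslow tie handling by default (adequate at the tie density of a
2-day schedule; Efron by flag); 95 % CIs are estimate ± 1.96 SE on the
log scale. Monotone likelihoods (complete separation) are detected via
runaway estimates, exploding standard errors, or optimizer warnings and
reported with `converged=False`. The fit is cross-checked against
lifelines' `CoxPHFitter` in a test. Per-cell phenotype comparisons use
one-way ANOVA with Dunnett many-to-one adjustment against the control
(`scipy.stats.dunnett`, seeded generator for reproducibility).

## Bioenergetics

The post-inhibitors phase mean defines non-mitochondrial OCR and
non-glycolytic ECAR; both are subtracted from every value of their
series, wells with any negative corrected phase mean are discarded with
a reason, and surviving rates are divided by the well's cell count
(consumed as provided metadata). Parameters per well: basal =
baseline-phase mean, maximal = post-FCCP mean (full phase means, no
max-of-cycles picking — robust to single-cycle noise; a last-cycle
switch exists), oligomycin-sensitive = basal − post-oligomycin, spare =
maximal − basal (exact identity), OCR/ECAR computed per well before
averaging to respect well pairing; line-level values are across-well
means ± SEM. PercevalHR analysis forms the pointwise 490/405 ratio and
phase means split at the 5 and 15 min injections. MitoSOX slopes are
per-cell OLS on raw intensities in units per hour; photobleaching
correction is out of scope and negative slopes are flagged downstream.

## Problem sizes and numerical choices

Simulation-backed checks use: Cox calibration at 500 replicates of
500 cells/arm; logrank type-I error at 1000 two-arm null simulations;
end-to-end tracking on a 30-cell, 18-frame field; classification on
three training scenes and one held-out scene of 40 cells each; motility
on three 50-mitochondrion kymographs; MitoSOX recovery at 500 cells.
All randomness flows from explicit integer seeds; identical spec + seed
reproduces outputs bit-for-bit. Degenerate inputs (empty masks, zero
records, missing phases, seeds outside the foreground) raise typed
errors rather than returning silent defaults.

## Known limitations

The synthetic renderer is deliberately simple (see above); classifier
accuracy and tracking scores on it bound what the same code would
achieve on real images only loosely. The greedy tracker has no motion
model and will fragment under real cell migration. Kymograph tracking
assumes diffraction-limited puncta on a traced path and degrades when
many mitochondria occupy the same few micrometres. The Cox
implementation does not handle time-varying covariates, frailty, or
interval censoring; the 2-day observation grid is treated as exact
event times under Breslow ties.
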