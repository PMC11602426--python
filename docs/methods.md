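# Methods

`haircelltox` implements the quantitative workflow for distinguishing
acute from delayed aminoglycoside (AG)-induced hair-cell death in the
zebrafish lateral line: 3-D segmentation of neuromasts, hair cells and
AG-carrying vesicles; vesicle/cytoplasm accumulation statistics; calcium-
transient classification; and Hill-curve HC50 dose–response analysis.
Because the underlying microscopy and fish-count data are not deposited,
every stage is exercised against synthetic data with known ground truth;
this note records the models, parameter choices and their limits.

## Image phantoms (`synthetic_data.gen_neuromast_stack`)

A neuromast is modelled as a rosette of `n_cells` (default 12)
superellipsoidal hair cells — quartic along z (flat apical/basal caps),
quadratic in-plane — whose centres sit on a ring of radius
`rosette_ring_factor x` the in-plane cell radius (default 1.6 x 4 µm).
Neighbouring cells interpenetrate; overlaps are resolved to the nearest
normalized centre, producing the wedge-shaped territories of a real
rosette that converges centrally. The ground-truth neuromast mask is the
slice-wise hole-filled union of the cells.

The structural reporter channel emulates a cytoplasmic transgene:
per-cell expression drawn lognormal (σ = 0.25), an intracellular radial
gradient (membrane at 50 % of the centre intensity), and a dim membrane
band (attenuation 0.3 over ~2 px) at cell–cell interfaces. The membrane
band matters: it is what gives the Sauvola foreground its inter-cell
necks, and hence the seeded watershed its boundaries, exactly as the
dark membrane lines do in real cytoplasmic-GFP images.

Vesicles are hard spheres (radius uniform in 0.35–0.55 µm) blurred by a
light optical PSF (σ = 0.35 px); the ground-truth vesicle mask extends
0.1 µm past the core so that ≥ 98 % of each vesicle's rendered signal
lies inside its own mask. Per-cell vesicle counts are negative binomial
(mean 5, dispersion 0.1); centres are drawn uniformly from the cell's
wedge interior with a minimum pairwise separation (sum of radii
+ 0.25 µm) so vesicles remain individually resolvable. A fraction
`diffuse_fraction` of the total AG signal is spread uniformly over the
cytoplasm — low values emulate the punctate G418 distribution, high
values the mixed diffuse + punctate neomycin distribution. The GPN
regime (`gpn_like`) halves the vesicle count and doubles per-vesicle
volume at constant voxel intensity, i.e. fewer but larger vesicles with
conserved totals, matching the observed pattern (count down; volume and
fluorescence per hair cell unchanged).

Noise is Poisson shot noise (gain 500 photons per intensity unit) plus
additive Gaussian read noise; `snr` is defined as (mean in-structure
signal − background) / read-noise SD, and `snr=None` disables noise.
Voxels default to 0.3 × 0.25 × 0.25 µm on a 40 × 128 × 128 grid — a
compromise between the sub-0.1-µm super-resolution grids of the original
acquisitions and tractable test runtimes. No PSF convolution is applied
to the reporter channel; cells have hard edges.

What the phantom does **not** emulate: hair-bundle/kinocilium structure,
supporting cells, depth-dependent attenuation, anisotropic PSF tails,
vesicle motion, or real vesicle sub-structure. Segmentation scores on
phantoms therefore certify the pipeline's mask algebra, parameter
plumbing and detector behaviour — not its accuracy on real tissue.

## Pre-segmentation corrections (`imaging`)

* **Rigid alignment** — frame-to-frame (time lapse, on the max-z
  projection of the chosen channel) or slice-to-slice (z stacks), always
  with "previous" as reference and transforms composed cumulatively,
  then applied identically to every channel. Translation is estimated
  by sub-pixel phase correlation (classic normalization, which is more
  accurate than phase-normalized correlation on smooth microscopy
  frames); rotation, when enabled, by a deterministic coarse-to-fine
  angle search (0.5° grid within ±10°, refined to 0.05°) scored by
  masked mean-squared difference. Bilinear interpolation; out-of-field
  pixels are zero-filled and excluded from the cost via a validity
  mask. Cumulative shifts beyond half the field are flagged.
* **Rolling-ball background subtraction** — grey-scale opening with a
  flat disk footprint (default radius 10 px), applied slice-wise, with
  edge-replicate padding so monotone backgrounds are removed exactly up
  to the image border. Anti-extensive by construction.
* **Intensity normalization** — percentile clip (default none / 99.9 in
  pipelines) followed by min–max scaling to [0, 1]; constant images are
  rejected rather than silently scaled.

## Segmentation (`segmentation`)

The parameter set follows the published recipe: Gaussian σ = 6 px +
triangle threshold for the neuromast body; 5-class multi-Otsu background
mask, background replacement with 1.0e-7, slice-wise Sauvola threshold
(window 45 px, k = 0.2, dynamic-range parameter R = half the data
range), Euclidean-distance-transform seeded watershed for hair cells;
slice-wise dot + filament detectors fused for vesicles, with the two
published presets shipped as YAML (`rab7_vesicles`, `g418_vesicles`).

Pixel-unit parameters are tied to the acquisition pixel size (~0.05 µm
in-plane for the super-resolution images the recipe was tuned on);
`params_at_voxel_size` rescales σ and the Sauvola window to other
grids — at the phantom's 0.25 µm pixels, σ = 1.2 px and window = 9 px.

Two implementation points deserve note:

* Sauvola's threshold is always below the local mean, so a uniform
  region — including the background after constant replacement — passes
  it. The replaced background is therefore excluded from the foreground
  explicitly; that is the operational meaning of the background-
  replacement step. The inverted neuromast mask may be used as the
  background mask (the published alternative for structural channels)
  by passing `region=`/`background=` to `segment_hair_cells`.
* With `region` set (typically the neuromast mask), watershed labels
  tile the whole region while the distance transform — and hence the
  inter-cell boundaries — still comes from the Sauvola foreground, whose
  membrane gaps carve the necks. This reflects that hair cells jointly
  occupy the neuromast body; without it, labels would exclude the thin
  membrane bands.

Dot detector: per-slice scale-normalized negated Laplacian-of-Gaussian
at σ = √(scale/2), thresholded at the cutoff (a matched Gaussian spot of
amplitude A peaks at A/2). Filament detector: per-slice Hessian
eigenvalues from Gaussian derivatives at σ = scale (σ²-normalized);
bright-ridge response |λ₂| damped by a Frangi-type blobness term
(β = 0.5). Fused masks are hole-filled, cleaned at `min_object_voxels`
(default 4; the small-artifact threshold is not quantified in the
recipe), labelled in 3-D with 26-connectivity, and labels with no
overlap with the neuromast mask are dropped (partial overlaps kept
whole by default, clipped with `clip_to_neuromast=True`). Touching
vesicles may share a label; no splitting is attempted. The cytoplasm
mask is the exact set difference, and the partition invariant
(cytoplasm ∪ vesicles = neuromast, cytoplasm ∩ vesicles = ∅) is
asserted voxelwise on every pipeline run.

Manual steps are replayed from files: seeds as (z, y, x) CSV, mask
corrections as an edits table (merge/delete). Seeds outside the
foreground are flagged and omitted; two seeds on one voxel raise an
error.

## Quantification (`quantification`)

Per-vesicle records (volume, centroid, per-channel mean/total intensity)
come from `regionprops_table` plus per-channel aggregation; a vesicle
straddling cells is assigned by majority overlap. Neuromast summaries
follow the figure conventions: vesicles, vesicle volume and vesicle
fluorescence **per hair cell** (totals divided by the cell count), with
per-vesicle means carried alongside. The compartment ratio is mean AG
intensity in the vesicle mask over mean AG intensity in the cytoplasm
mask — a concentration-style comparison insensitive to compartment
volume (total/total available by flag). Because vesicles occupy a small
volume fraction, this ratio is numerically large on punctate phantoms;
only its direction across regimes is interpreted. Two-group tests use
the exact Mann–Whitney null for groups of ≤ 12 and the normal
approximation above, plus unpaired/paired t-tests.

## Calcium analysis (`calcium`)

Traces are mean projected intensity per hand-drawn ROI per 30-s frame,
with a 5-frame (2.5-min) pre-exposure baseline. F/F₀ divides by the
baseline mean (baseline mean on the F/F₀ scale is exactly 1); the
baseline SD is the sample SD over the same frames on the F/F₀ scale.
A cell is a **responder** if its F/F₀ exceeds baseline mean + 2 SD
within its response window — baseline end to fragmentation for dying
cells, to the last frame for living cells. Classification takes the
maximum of a 3-frame running mean so single-frame shot-noise spikes do
not count as transients (real transients span several frames); reported
maxima are raw. Even so, with a 5-frame baseline the 2-SD rule retains
a non-trivial false-positive rate on noisy null traces (~20 % at noise
SD 0.05 over ~30 frames) — an intrinsic property of the rule, not a
bug; the trace generator's ground-truth labels agree with the rule
applied to the noiseless trace.

Endpoint alignment re-indexes dying traces so fragmentation sits at
index 0, padding shorter histories with NaN; missing frames are excluded
from windows, never imputed. Condition statistics: Pearson chi-square
(no continuity correction) on the responders-by-condition table —
the published dying-cell triples 16/16, 2/11, 10/14 give χ² = 20.25,
df = 2 — and Kruskal–Wallis with tie correction plus Dunn's rank-based
post-hoc, Holm-adjusted (the multiplicity adjustment for Dunn is not
specified in the source workflow; Holm is the conservative default and
is adjustable).

The trace generator floors responder peaks at baseline + 5 noise-SD so
suprathreshold transients are guaranteed by construction; non-responder
dying cells get a sub-threshold wiggle (≤ 0.5 noise-SD) and living
cells are flat. Fragmentation is a truncation index; no morphological
fragmentation is simulated.

## Dose–response (`dose_response`)

Counts are hair cells summed over 4 neuromasts per fish; survival is
100 × count / mean control count within the batch. The dose–response
model is the four-parameter logistic
S(d) = bottom + (top − bottom) / (1 + (d/HC50)^h), fitted on log₁₀ dose
with top/bottom fixed at 100/0 (free by flag); dose-0 controls anchor
normalization but are excluded from the curve fit. Initialisation takes
the dose whose mean survival is nearest 50 %; HC50 is bounded within
1.5 decades of the dose range and the slope within [0.2, 10]. HC50
uncertainty comes from fish-level bootstrap resampling within dose
(seeded; off by default in replicate studies for speed). When no dose
brings mean survival below 60 % (maximal kill < 40 %), the fit returns
**"HC50 not determined"** rather than an extrapolated number — the
behaviour the shallow 1-h gentamicin curve requires.

The count generator draws each fish's survival probability from a beta
distribution around the Hill curve (overdispersion ρ, default 0.05) and
the count as binomial out of the control capacity (default 60, i.e.
~15 cells/neuromast). Defaults mirror the published design scale:
doses up to 400 µM, 10 fish per dose. Recovery of the five published
HC50s (44/25/94 µM neomycin; 10/19 µM gentamicin) is unbiased to within
~2 % at this scale — well inside the ±15 % acceptance band chosen
because the source reports no uncertainty for its HC50 values.

Time-course and protection analyses are deliberately thin wrappers over
standard statistics: type-II two-way ANOVA (dose × time, dose × arm) via
OLS, with per-dose two-sample t-tests Sidak-corrected across doses for
the protection contrasts (an approximation to the original software's
post-hoc; the family is the set of doses). Single-level factors are
dropped from the model so one-dose designs remain analysable. The
time-course generator uses a sigmoid loss in time with dose-dependent
midpoint t50(d) = 7 h × (100 µM / d)^0.7 toward a 5 % floor — chosen
once to reproduce the qualitative design (higher initial dose, faster
delayed loss; similar final loss); the protection generator offsets the
protectant arm's survival fraction (default +0.30).

## Problem sizes and determinism

Every generator is bit-reproducible given its seed. Study-scale runs
used throughout tests and the acceptance script: 50 replicate studies
per HC50 target (70–80 fish each); 200 replicate sets of 16 dying cells
for the calcium maxima; one 40 × 128 × 128 phantom (and groups of 5)
for segmentation scores; 100 seeded phantom pairs for the
compartment-ratio direction. These sizes keep the full suite under a
few minutes while leaving the Monte-Carlo standard errors far inside
the acceptance tolerances.

## Known limitations

* The vesicle detectors are strictly 2-D slice-wise (as in the source
  workflow); strongly anisotropic vesicles spanning many slices are
  fragmented or merged by the 3-D labelling step, not re-segmented.
* The Sauvola/watershed hair-cell route needs a usable background mask;
  on images whose background straddles the lowest multi-Otsu class the
  inverted-neuromast route should be used instead.
* The 2-SD responder rule is sensitive to baseline length; with 5
  baseline frames its false-positive rate on pure noise is material
  (see above) and should be kept in mind when interpreting small
  responder fractions.
* The Hill fit fixes top = 100 % by default; designs with substantial
  regeneration during washout can exceed 100 % survival locally, which
  the constrained fit absorbs into the slope.
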