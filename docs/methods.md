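# Methods

This note documents the models, algorithms and numerical choices behind
`rootmosaic`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where genuinely open
design decisions were resolved.

## 1. The synthetic root meristem

The generator (`rootmosaic.synthetic`) produces multi-channel z-stacks that
emulate the statistical structure the analysis relies on, not root
morphology. A meristem is an idealized rectangular grid:

* **In plane**: `n_files` longitudinal files × `cells_per_file` cells,
  each cell a rectangle of `cell_length_px × cell_width_px` (default
  48 × 32 px ≈ 12 × 8 µm at the calibration of 2048 px ≙ 510 µm,
  i.e. ≈ 4.016 px/µm). Cells are bounded by 2-px bright walls rendered in
  the wall channel (emulating a propidium-iodide stain), lightly blurred
  (σ = 1 px) and overlaid with Gaussian detector noise clipped at zero.
* **In depth**: `n_layers` cell layers (default 4) of `cell_depth_um`
  (9 µm), separated by 3 µm transverse walls. Optical sections are sampled
  every `z_step_um` (3 µm) at a random phase relative to the tissue, so
  each layer is crossed by 3 cell sections plus one transverse-wall
  section (rendered fully bright across the tissue footprint).
* **Nuclei**: one sphere per cell (radius 3.5 µm, jittered within the
  cell). A 7 µm sphere sampled at a 3 µm step intersects 2 or 3 sections
  whatever the phase — matching the observation that each nucleus appears
  in 2–3 consecutive sections — and the in-plane disk radius follows the
  sphere's cross-section. Reporter channels show the nucleus at the ON or
  OFF intensity (defaults 200 / 20 a.u.) on a cytoplasmic background
  (10 a.u.).
* **Expression states** are drawn **per file** (clonal inheritance):
  a file is ON with probability `p_on`. With two reporters, `trans` mode
  draws one state per file shared by both reporters; `cis` mode draws the
  two reporters independently, producing mixed files with probability
  2·p_on·(1−p_on). A `switch_noise` parameter (default 0) flips individual
  cells for robustness studies. `p_on_from_cold_weeks` maps cold duration
  to `p_on` through a logistic (midpoint 6.5 weeks, scale 1.4 weeks),
  calibrated so non-vernalized files are nearly all ON, intermediate cold
  yields a bimodal population and ≥10 weeks silences almost everything.
* **Depth decay**: every reporter section is attenuated by
  `(1 − bleach_rate)^plane_index` (default 3 %/plane), reproducing the
  confound of top-to-bottom acquisition: depth and acquisition time are
  one variable. Bleaching is deliberately applied per acquisition index,
  not per physical depth.
* **Ground truth** records, per cell: file membership, plane span, voxel
  mask (label volume), per-reporter state and the noise-free mean
  intensity over the cell's voxels *after* blur and bleaching — exactly
  the quantity the measurement stage estimates.

Randomness uses one master seed split into sub-streams (geometry, states,
noise), so states are reproducible independently of the noise realisation,
and identical seeds give bit-identical stacks.

**What the phantom does not emulate:** realistic optics (no PSF
convolution or anisotropic blur), curved files and non-rectangular cell
shapes, cell growth/division dynamics, elongation-zone endoreduplication,
autofluorescence gradients, and registration drift (stacks are generated
pre-aligned; `align_stack` exists for real data). Tests passing on the
phantom therefore validate the pipeline's logic and its statistical
behaviour under the stated generative assumptions, not its performance on
arbitrary real microscopy.

Two fast sampling paths (`simulate_state_table`, `simulate_cell_means`)
draw states and per-cell means directly from the same generative model
without rendering pixels; `simulate_cell_means` models a cell's mean as
background + (nuclear volume fraction) × (nuclear excess intensity) with
the fraction drawn from the range induced by 2-vs-3-plane nucleus
sampling (0.18–0.30), plus a small measurement error. These paths power
the statistical studies (recovery, bimodality, cis/trans power) at
hundreds of replicates.

## 2. Segmentation

**Tissue mask** — Gaussian smooth (σ = 2 px), global Otsu, binary closing
(disk r = 5 px), keep the largest connected component, fill holes. The
bright wall network is one connected component whose holes are the cell
interiors, so the filled result covers walls and interiors. Otsu always
splits something, so a contrast guard rejects planes whose foreground—
background separation is below 5× the background SD (sections above or
below the tissue return an empty mask instead of noise speckle).

**2D cell regions** — Gaussian filter (σ = 2 px), then a median-based
local threshold: a pixel is wall if it exceeds the median within a 40-px
disk by more than 2 % of the dynamic range. The rank-median runs on an
8-bit quantisation of the smoothed image (sliding-histogram filter); the
offset is expressed on the same scale. The offset matters: the bare
median rule marks ~half of any flat interior as wall. The thresholded
wall is skeletonized to 1-px ridges (kept for QC), and regions are
produced by a watershed of the smoothed wall topography seeded by the
connected components of the non-wall space, with 1-px boundary lines.

Bounding regions by ridge lines rather than the thresholded wall mask is
a load-bearing choice: a bright wall blurs into a halo many pixels wide,
and regions clipped to the halo complement lose ~45 % of their area, which
inflates the measured mean of nucleus-bearing cells by ~50 % (the nucleus
occupies a larger fraction of the eroded region). With ridge-bounded
watershed regions the per-cell error drops to a few percent. Only ridge
pixels belong to no cell; distinct regions are never 4-connected.

Regions smaller than 50 px² are dropped (noise slivers); regions touching
the image border are kept but flagged, and flagged cells are excluded from
state calling.

## 3. 3D reconstruction

Regions in sections with consecutive indices are linked when centroids are
within 20 px **and** the relative area difference |a₁−a₂|/max(a₁,a₂) is at
most 0.5. The symmetric max-denominator form avoids order dependence; both
bounds are inclusive. Chains are cut after 6 sections (18 µm at the 3 µm
step) — the cap and the micrometre limit are validated for consistency
against the stack's z-step. No section skipping: only neighbouring
sections are compared.

Within a section pair, matching is a maximum-cardinality, minimum-total-
centroid-distance one-to-one assignment over criterion-respecting pairs
(Hungarian algorithm with a large penalty for infeasible pairs), not
first-come greedy matching: the result is deterministic and independent of
label order. Exact ties resolve by smaller area difference, then lower
labels, folded into the scalar cost as
`dist + 1e-6·rel_area + 1e-9·label_a + 1e-12·label_b`. The test suite pins
this behaviour against an exhaustive brute-force oracle on hundreds of
random instances.

Cells must span ≥ 2 sections by default (`min_planes`): nuclei span 2–3
sections, and single-section fragments are mostly segmentation noise —
cross-section corroboration is what makes a region a *bona fide* cell.
This also discards the single giant region produced by each fully-bright
transverse-wall section. A post-hoc audit (`audit_cells`) re-checks every
adjacent pair inside every reconstructed cell against the criteria,
independently of the matching code path.

## 4. Quantification and the depth filter

A cell's mean intensity is the reporter intensity summed over the exact
labelled pixels of its member regions across all its sections, divided by
the total reconstructed area (the volume proxy; sections have equal
weight). No background subtraction or flat-field correction anywhere —
raw means are reported, and Σ(mean × area) over cells equals the total
in-cell intensity to floating-point precision.

Cell depth is the mean of (section index × z-step): the mean distance of
the cell from the top focal plane. The **plateau rule** operationalizes
"restrict analysis to depths of approximately constant intensity": bin
cells by nearest section, compute the per-bin mean of cell means, and cut
at the deepest bin whose running (cumulative) mean is still ≥ (1 − tol) ×
the shallowest bin's mean, tol = 0.15. Cells deeper than the cut (plus
half a bin of slack) are flagged excluded. A manual cut is supported.
With fewer than 3 distinct depths the filter warns and keeps everything,
which also makes the filter idempotent. Note that with a mixed ON/OFF
population the per-bin mean carries composition noise (~√(p(1−p)/files)
relative); on small fields the plateau cut is accordingly conservative.

## 5. State classification

Per-cell mean intensities of a vernalizing population are bimodal on a
log scale (states differ severalfold; within-state spread is tens of
percent). States are called by a two-component Gaussian mixture on log
intensities, assigning each cell to the component with the higher
posterior; the upper component is ON.

A population is accepted as bimodal only if (i) the two-component model
beats the one-component model by BIC, (ii) the component means are at
least one pooled SD apart, and (iii) the modes are at least 0.5 log-units
(≈1.65-fold) apart. Guards (i) and (iii) are both necessary: a
two-component ML fit to genuinely unimodal data still splits it into two
overlapping components 1–2 SD apart, and for non-Gaussian unimodal shapes
BIC alone can also prefer two components — but no within-state
substructure approaches the severalfold ON/OFF contrast, which is what
(iii) encodes. If the population is judged unimodal, every cell receives
the single state given by comparing the population median with an
absolute fallback threshold (default 25 a.u., which sits between the
typical OFF ≈ 12 and ON ≈ 50 a.u. per-cell means at the default
calibration; it must be re-set for other instruments).

## 6. File coherence and the cis/trans test

**Coherence** summarises run-length structure along files: per file, the
run lengths of consecutive same-state calls and the majority-agreement
fraction; the score is the mean majority fraction over files of length
≥ 2. Under file-level true states with per-cell call error e the expected
score is E[max(k, L−k)]/L with k ~ Bin(L, 1−e) ≈ 1 − e; for shuffled
(i.i.d.) states it is the same formula with p the ON fraction — note this
exceeds max(p, 1−p) noticeably for short files.

**cis/trans test** (a formalisation constructed for this package — the
original argument was qualitative): file-level states are the per-reporter
majority call. Under the trans null every file is ON/ON or OFF/OFF and
mixed files arise only from call error. The error rate is estimated from
pooled within-file discordance, the ON/ON probability from the observed
file states (mixed files split evenly), and the null distribution of the
mixed-file fraction comes from a parametric bootstrap (default 999
replicates: draw file states, apply i.i.d. cell-level errors, re-derive
majorities); the p-value uses the (1 + #{sim ≥ obs})/(B + 1) convention.
Ties in the majority (even file lengths) resolve to ON identically in the
observed and simulated data. A two-sided exact binomial test on
(n_ON/OFF, n_OFF/ON) checks the symmetry expected under cis memory —
under cis, neither copy should be preferentially silenced. Simulation at
the default conditions (100 files of 8 cells, p_on = 0.5, 200 replicate
seeds) gives power ≈ 1.0 against cis-generated data, type-I error ≈ 0 on
trans data with 5 % call error, and a calibrated symmetry test.

## 7. Validation

Automated cells are paired to the true cell owning the strict majority
(> 50 %) of their pixels; each true cell may be claimed by at most one
automated cell (largest overlap wins). The accuracy audit draws a seeded
random sample (default 50) of reconstructed, depth-included cells across
roots; a cell is accurate when its automated mean is within 20 % relative
error of the reference (ground truth here; a manual-measurement table for
real data). Unpaired automated cells — incorrect segmentations — are
sampled in proportion and always count as inaccurate. The 20 % tolerance
is a package choice: an accuracy criterion must be numeric to be testable.

## 8. Registration

`align_stack` estimates a per-section translation of the wall channel by
phase correlation against the previous section, accumulates the shifts
and applies them to all channels. Per-pair estimates larger than 30 px
are treated as content change rather than stage drift and zeroed —
consecutive optical sections differ in content, and drift between them is
small. Registration is off by default in the pipeline (the phantom is
pre-aligned; whether registration belongs before quantification on real
data is left to the caller).

## 9. Problem sizes and tolerances used in the checks

The accuracy benchmark runs 8 default-geometry roots (288 true cells
each; 2304 total) and samples 50 cells — a desk-scale analogue of a
multi-root validation, chosen to keep a full run in tens of seconds while
exceeding 1000 cells. Statistical checks use 200 replicate seeds
(cis/trans), 10 seeds × 640 cells (recovery, ±0.05 band), 20 seeds
(bimodality, 95 % flag rate) and 500 random instances (linking oracle).
Conservation is exact to 1e-6 relative; all remaining tolerances are
stated inline where they are asserted.

## Known limitations

* The phantom's rectangular geometry makes segmentation easier than real
  tissue; the ~95–100 % audit accuracy on synthetic data is an upper
  bound, not a field estimate.
* File assignment for real images (tracking files through label maps) is
  out of scope; coherence and the cis/trans test consume file-grouped
  calls (synthetic truth provides them; for real data they must be
  supplied).
* The depth filter assumes state composition is independent of depth;
  a depth-stratified population would confound the plateau rule.
* The fallback threshold for unimodal populations is calibration-specific
  and has no meaning across instruments without re-calibration.
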