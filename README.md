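# rootmosaic

Quantification of clonal ON/OFF reporter expression in plant root-meristem
confocal z-stacks — and a two-reporter test for *cis*- vs *trans*-encoded
epigenetic memory.

## The problem

Vernalization epigenetically silences the *Arabidopsis* floral repressor
*FLC*: after prolonged cold, each meristematic cell holds the gene stably ON
or stably OFF, and the silenced fraction grows with cold duration. Because
root meristem cells divide anticlinally, clonal lineages are visible as
longitudinal **cell files**, so the mitotic heritability of an expression
state can be read directly from images: heritable states form long
single-state runs along files. With two fluorescent reporter copies of the
gene in one plant (e.g. Venus and mCherry fusions), memory stored in
diffusible factors (*trans*) allows only ON/ON and OFF/OFF files, whereas
memory stored locally at each gene copy (*cis*) also allows the mixed ON/OFF
and OFF/ON files.

Turning such images into per-cell statistics requires: segmenting cells
from a cell-wall stain in every optical section, reconstructing cells in
3D across sections, measuring mean reporter fluorescence per cell,
discarding depth ranges degraded by acquisition bleaching, classifying
cells ON/OFF, and testing file-level state combinations. `rootmosaic`
implements that pipeline as a tested, reusable library, together with a
synthetic root-meristem generator with complete per-cell ground truth, so
every stage can be validated quantitatively.

## Method summary

* **Tissue mask** (per section): Gaussian smooth, Otsu threshold, closing,
  largest connected component, fill holes.
* **2D segmentation**: Gaussian filter (σ = 2 px) → median-based local
  threshold (disk radius 40 px, small positive offset) → skeletonize →
  watershed of the wall topography seeded by the non-wall components, with
  1-px ridge lines that belong to no cell.
* **3D reconstruction**: regions in neighbouring sections are the same cell
  when centroids are ≤ 20 px apart **and** relative areas
  |a₁−a₂|/max(a₁,a₂) differ ≤ 50 %; cells are capped at 18 µm (6 sections
  at the 3 µm step). Within each section pair, regions are matched by a
  minimum-total-centroid-distance optimal assignment (verified against a
  brute-force oracle).
* **Quantification**: mean intensity = Σ reporter intensity over the cell's
  pixels across sections ÷ total reconstructed area; no background
  subtraction. A plateau rule excludes depths where the per-depth mean
  falls more than 15 % below the shallow reference (depth/bleach confound).
* **State calling**: two-component Gaussian mixture on log intensities with
  a unimodality guard (BIC + mode separation).
* **cis/trans test**: observed fraction of mixed-state files vs a
  parametric bootstrap of the trans null (call-error rate estimated from
  within-file discordance), plus an exact binomial test of ON/OFF vs OFF/ON
  symmetry.

## Worked example

```bash
python examples/simulate_and_quantify.py
```

```
stack: 17 planes of (704, 320) px, channels ['wall', 'reporter_1']
stage counts: {'planes': 17, 'regions_2d': 868, 'cells_3d': 286, 'cells_included': 143, 'cells_classified': 143}
depth cut: 18.0 um (deepest plateau depth with stable mean intensity)
accuracy audit: 50/50 sampled cells within 20% of their true mean intensity
OFF cells: n=  48, mean intensity   10.8 a.u.
 ON cells: n=  95, mean intensity   46.3 a.u.
```

A 288-cell synthetic meristem is rendered, 286 cells are reconstructed,
the depth filter keeps the stable-intensity range, and the per-cell means
split into the two expression states. `examples/cis_trans_test.py` runs the
two-reporter test on cis- and trans-generated data:

```
cis-generated data (100 files):
  ON/ON 24  ON/OFF 28  OFF/ON 27  OFF/OFF 21
  mixed-state fraction 0.55, p = 0.0010 vs the trans null (estimated call error 0.016)
  ON/OFF vs OFF/ON symmetry: p = 1.000
```

Other examples: `cold_duration_response.py` (ON fraction vs weeks of cold),
`file_coherence.py` (run-length structure along clonal files).

A thin CLI wraps the same library for shell use:

```bash
rootmosaic simulate --seed 1 --out sim/
rootmosaic run sim/stack.tif --truth sim/ --out out/
```

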