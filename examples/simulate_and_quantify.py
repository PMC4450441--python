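"""Simulate one root-meristem z-stack and run the full quantification pipeline.

Generates a two-channel stack (cell-wall stain + nuclear reporter) for a
half-vernalized meristem (p_on = 0.5), reconstructs cells in 3D, measures
per-cell mean reporter intensity, applies the depth filter, and audits the
result against the generator's ground truth.
"""

import warnings

import rootmosaic as rm

warnings.simplefilter("ignore")

geometry = rm.RootGeometry()  # 6 files x 12 cells x 4 layers = 288 cells
expression = rm.ExpressionModel(p_on=0.5)

stack, truth = rm.generate_root(geometry, expression, seed=42)
result = rm.run_pipeline(stack, truth=truth)

print(f"stack: {stack.n_planes} planes of {stack.frame_shape} px, "
      f"channels {stack.channels}")
print(f"stage counts: {result.stage_counts}")
print(f"depth cut: {result.depth_profile.d_cut_um:.1f} um "
      f"(deepest plateau depth with stable mean intensity)")
rep = result.validation_report
print(f"accuracy audit: {rep.n_accurate}/{rep.n_cells_checked} sampled cells "
      f"within {rep.tolerance:.0%} of their true mean intensity")

# Per-cell means separate into the two expression states
table = result.cell_table
called = table.dropna(subset=["state_reporter_1"])
for state, grp in called.groupby("state_reporter_1"):
    print(f"{state:>3} cells: n={len(grp):4d}, "
          f"mean intensity {grp['mean_reporter_1'].mean():6.1f} a.u.")
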