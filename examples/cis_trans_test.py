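"""The two-reporter test for cis- vs trans-encoded epigenetic memory.

With two independently integrated reporter copies of the same gene, memory
carried by diffusible (trans) factors forces both copies of a cell file
into one shared state (ON/ON or OFF/OFF), while memory stored locally at
each copy (cis) lets mixed ON/OFF and OFF/ON files arise.  The test
compares the observed fraction of mixed-state files against a parametric
bootstrap of the trans null, and checks the ON/OFF vs OFF/ON symmetry
expected under cis memory.
"""

import rootmosaic as rm

for mode in ("trans", "cis"):
    expr = rm.ExpressionModel(p_on=0.5, n_reporters=2, memory_mode=mode,
                              switch_noise=0.02)
    table = rm.simulate_state_table(expr, n_files=100, cells_per_file=10, seed=8)
    res = rm.cis_trans_test(table, seed=1)
    print(f"{mode}-generated data ({res.n_files} files):")
    print(f"  ON/ON {res.n_onon}  ON/OFF {res.n_onoff}  "
          f"OFF/ON {res.n_offon}  OFF/OFF {res.n_offoff}")
    print(f"  mixed-state fraction {res.mixed_fraction:.2f}, "
          f"p = {res.p_value:.4f} vs the trans null "
          f"(estimated call error {res.error_rate:.3f})")
    print(f"  ON/OFF vs OFF/ON symmetry: p = {res.p_symmetry:.3f}\n")

print("Mixed-state files in the cis run reject the trans null outright;")
print("their symmetric split shows neither copy is preferentially silenced.")
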