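#!/usr/bin/env python
"""Band-resolved point-dipole couplings on the study fixture.

Computes the full Q- and B-band coupling matrices and the class-pair
averages, and reports the Soret-vs-Q enhancement that follows from the
roughly doubled Soret transition dipoles.
"""

from forsternet.core import Band
from forsternet.workbench import RunConfig, run_couplings

cfg = RunConfig(output_dir="results")
out = run_couplings(cfg)

q = out["averages"][Band.Q].set_index(["class_i", "class_j"])
b = out["averages"][Band.B].set_index(["class_i", "class_j"])

print("class-pair mean |V| (cm^-1), multimer order", cfg.multimer_order)
print(f"{'pair':<18}{'Q':>10}{'B':>10}{'B/Q':>8}")
for idx in q.index:
    vq = q.loc[idx, "mean_V_cm-1"]
    vb = b.loc[idx, "mean_V_cm-1"] if idx in b.index else float("nan")
    print(f"{idx[0]}-{idx[1]:<12}{vq:>10.2f}{vb:>10.2f}{vb / vq:>8.2f}")

chl = [i for i in q.index if "crt" not in i]
ratios = [b.loc[i, "mean_V_cm-1"] / q.loc[i, "mean_V_cm-1"] for i in chl]
print(f"\nchlorophyll-pair Soret enhancement: {min(ratios):.1f}-{max(ratios):.1f}x "
      "(doubled dipoles -> ~4x couplings)")
print("matrices and averages written to results/couplings_*.tsv, "
      "results/class_pair_averages_*.tsv")
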