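"""PWM scoring and exact p-values for RSS motifs.

Scores are log2 odds against the A/T 0.3, C/G 0.2 background; p-values are
exact tail probabilities from a dynamic program over discretised
per-position contributions (the probability a background window scores at
least as high).
"""
import numpy as np

from ragdel.pwm import (
    compose_full_rss, default_heptamer, default_nonamer, revcomp,
    scan_flank, score_pvalue_table, score_window,
)

hep = default_heptamer()
table = score_pvalue_table(hep)
s = score_window(hep, "CACAGTG")
print(f"consensus heptamer CACAGTG: score {s:.2f} bits, exact p = {table.pvalue(s):.3g}")
s1 = score_window(hep, "CACTGTG")
print(f"one mismatch   CACTGTG: score {s1:.2f} bits, exact p = {table.pvalue(s1):.3g}"
      "  (fails the 1e-4 scan threshold)")

full = compose_full_rss(hep, default_nonamer(), 23)
print(f"full RSS with 23-nt spacer: width {full.width}; the spacer columns "
      "equal the background, so only heptamer+nonamer bases contribute")

# plant a heptamer 5 bp interior to a breakpoint and scan both strands
rng = np.random.default_rng(0)
flank = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=101))
flank = flank[:54] + "CACAGTG" + flank[61:]
for h in scan_flank(flank, [hep], breakpoint_offset=50):
    print(f"hit: {h.motif_name} strand {h.strand} offset {h.start_offset:+d} "
          f"(positive = interior to the deletion), p = {h.pvalue:.3g}")
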