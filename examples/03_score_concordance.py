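"""Concordance of a DNA copy-number score with an RNA expression score.

The DNA-based score has an established cutoff (0.63); the RNA-based score
has none, so it is dichotomized at the percentile the DNA cutoff occupies in
the data (marginal matching).  The synthetic pairs are built with exactly 81
of 103 concordant calls, the 22 disagreements split equally.
"""

import brcalike as bl
from brcalike import study

pairs = study.reference_concordance_pairs(seed=1)
res = bl.concordance(pairs, cutoff_a=0.63)

print(f"paired samples: {res.n}")
print(f"DNA cutoff 0.63 sits at the {res.percentile_used:.1f}th percentile")
print(f"matched RNA cutoff: {res.cutoff_b:.2f}")
print("\n2x2 table (rows: DNA call, cols: RNA call):")
print(f"             RNA-high  RNA-low")
print(f"  DNA-high   {res.both_high:8d} {res.a_high_b_low:8d}")
print(f"  DNA-low    {res.a_low_b_high:8d} {res.both_low:8d}")
print(f"\nconcordant: {res.both_high + res.both_low}/{res.n} "
      f"({100 * res.concordant_fraction:.1f}%); disagreement is "
      f"{res.a_high_b_low}/{res.a_low_b_high} in the two directions")
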