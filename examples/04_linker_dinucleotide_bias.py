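"""Dinucleotide sequence preference of linker DNA via dinucleosome midpoints.

Computes, for all 16 dinucleotides, the closest-dinucleotide distance
profile around highly positioned (>= 5 piles) dinucleosome midpoints,
normalized to the all-genome-positions background and scaled so that no
enrichment = 100. Dinucleosome midpoints sit in linker DNA, so values
above 100 near offset 0 mark linker-enriched dinucleotides.
"""

import numpy as np

import dinucmap as dm

result = dm.simulate_all(dm.SimConfig(seed=11))
mids = dm.midpoints_dict(dm.count_piles(result.di), min_pile=5)
print(f"di midpoints with >= 5 piles: {sum(len(m) for m in mids.values()):,}")

profiles = dm.run_all_dinucs(result.genome, mids, statistic="closest", window=500)
print(f"profiles computed: {len(profiles)}")
print("\nnormalized value near the midpoint (mean over |offset| <= 3):")
for dinuc in dm.DINUCLEOTIDES:
    p = profiles[dinuc]
    sel = (np.abs(p.offsets) <= 3) & ~p.masked
    val = float(np.nanmean(p.normalized[sel]))
    tag = "enriched" if val > 110 else ("depleted" if val < 90 else "")
    print(f"  {dinuc}: {val:6.1f}  {tag}")
print("\nThe simulator plants CC/CG/GC/GG into linkers at twice the")
print("background rate; those four sit above 100 at the midpoint while")
print("AT/TA (and A/T-rich pairs generally) fall below it — the linker")
print("sequence preference read directly from dinucleosome midpoints.")
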