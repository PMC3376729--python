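"""Fragment-length distributions stratified by pile level.

Counts piles (identical mapped fragment intervals), extracts the
fragment-length multiset at pile thresholds 1/2/3/5/10 with equal-n
subsampling, locates the distribution modes, and runs pairwise
Mann-Whitney tests between pile levels — the size-by-pile convergence
analysis.
"""

import dinucmap as dm
from dinucmap.lengths import pairwise_mw, pile_level_lengths

result = dm.simulate_all(dm.SimConfig(seed=11))

piles = dm.count_piles(result.mono)
print(f"{len(result.mono):,} mono fragments -> {len(piles):,} distinct intervals; "
      f"{int((piles['pile'] >= 5).sum()):,} piled >= 5x")

hists = dm.length_histogram_by_pile(piles, levels=[1, 2, 3, 5, 10], seed=7)
for level, hist in sorted(hists.items()):
    modes = dm.find_modes(hist, max_modes=2)
    print(f"  pile >= {level:>2}: n={hist.n:,} subsampled, modes at {modes} nt")

subsets = {lv: pile_level_lengths(piles, lv) for lv in (1, 5, 10)}
mw = pairwise_mw(subsets)
print("\nMann-Whitney between pile levels (two-sided):")
for row in mw.itertuples(index=False):
    print(f"  >= {row.level_a} vs >= {row.level_b}: U={row.U:.3g}, p={row.p:.3g}")
print("\nThe bimodal 132/150 nt mixture is visible at every pile level. The")
print("pile subsets are nested, so a small Mann-Whitney p would flag a")
print("length shift between loosely and well-positioned nucleosomes; at")
print("the default tight-positioning settings most fragments reach high")
print("piles and the subsets stay statistically indistinguishable.")
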