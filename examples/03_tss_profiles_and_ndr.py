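"""TSS-anchored midpoint profiles and the promoter depletion chi-square.

Quantifies expression (RPKM), splits genes into low/medium/high tertiles,
calls each TSS from 5'-end reads, builds strand-oriented dinucleosome
midpoint profiles around the TSSs, and tests dinucleosome depletion in
the [-200, -1] promoter window between expression groups.
"""

import dinucmap as dm

result = dm.simulate_all(dm.SimConfig(seed=11))
genes = result.genes

# expression layer: RPKM -> groups -> TSS calls
total = int(result.exon_counts["count"].sum())
count_of = dict(zip(result.exon_counts["id"], result.exon_counts["count"]))
for g in genes:
    g.rpkm = dm.compute_rpkm(count_of[g.id], total, g.mature_length)
dm.assign_groups(genes, scheme="thirds")
report = dm.call_all_tss(result.five_prime, genes)
print(f"TSS called for {report['called']} genes, {report['skipped']} skipped")

di_piles = dm.count_piles(result.di)
profiles = {}
for group in ("low", "medium", "high"):
    prof = dm.build_profile(di_piles, genes, anchor_kind="tss", group=group,
                            window=1000, min_pile=5)
    profiles[group] = prof
    upstream = prof.window_count(-200, -1)
    print(f"  {group:>6}: {prof.n_anchors} genes, "
          f"{int(prof.counts.sum())} di midpoints in +/-1 kb, "
          f"{int(upstream)} in [-200, -1]")

for ga, gb in (("low", "medium"), ("low", "high"), ("medium", "high")):
    chi2, df, p = dm.ndr_depletion_chisq(profiles[ga], profiles[gb])
    print(f"chi2 {ga} vs {gb}: {chi2:.1f} (df={df}, p={p:.3g})")
print("\nDinucleosome midpoints fall in linker DNA, so their loss in the")
print("promoter window reads out the nucleosome-depleted region; the")
print("depletion strengthens with expression, hence the chi-square grows")
print("with the expression contrast.")
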