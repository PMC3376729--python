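"""Simulator contracts: determinism, truth geometry, bias planting, noise knobs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dinucmap as dm
from dinucmap.genomes import dinuc_start_indicator, encode


def _tiny_cfg(**kw):
    base = dict(seed=7, n_contigs=1, contig_length=40_000, n_genes=6,
                n_mono_fragments=20_000, n_di_fragments=20_000)
    base.update(kw)
    return dm.SimConfig(**base)


class TestGenerate:
    def test_same_seed_byte_identical(self):
        a = dm.simulate_all(_tiny_cfg())
        b = dm.simulate_all(_tiny_cfg())
        assert a.genome == b.genome
        assert a.mono.equals(b.mono) and a.di.equals(b.di)
        assert a.exon_counts.equals(b.exon_counts) and a.five_prime.equals(b.five_prime)
        assert a.truth.gene_truth.equals(b.truth.gene_truth)
        for c in a.truth.dyads:
            assert np.array_equal(a.truth.dyads[c], b.truth.dyads[c])

    def test_no_genes_tiled_chromatin_no_ndrs(self):
        cfg = dm.SimConfig(seed=1, n_contigs=1, contig_length=10_000, n_genes=0)
        genome, genes, truth = dm.generate_genome_and_genes(cfg)
        assert genes == [] and truth.ndr_intervals == {}
        assert len(truth.dyads["contig1"]) > 0

    def test_dyad_tiling_arithmetic(self):
        # core 147 + fixed linker 20 => period 167; hand count on one contig
        cfg = dm.SimConfig(seed=1, n_contigs=1, contig_length=10_000, n_genes=0,
                           core_length=147, linker_length_mean=20, linker_length_sd=0)
        _, _, truth = dm.generate_genome_and_genes(cfg)
        assert len(truth.dyads["contig1"]) == (10_000 + 20) // 167

    def test_sizing_error_when_genes_do_not_fit(self):
        with pytest.raises(ValueError, match="sizing"):
            dm.generate_genome_and_genes(
                dm.SimConfig(seed=1, n_contigs=1, contig_length=10_000, n_genes=20))

    def test_cores_do_not_overlap_and_linkers_between(self):
        _, _, truth = dm.generate_genome_and_genes(_tiny_cfg())
        core = 147
        for c, d in truth.dyads.items():
            starts = d - core // 2
            assert np.all(np.diff(starts) >= core)
            lk = truth.linkers[c]
            assert np.all(lk[:, 0] == starts[:-1] + core)
            assert np.all(lk[:, 1] == starts[1:])
            assert np.all(lk[:, 1] > lk[:, 0])

    def test_truth_groups_near_equal_thirds(self):
        _, genes, truth = dm.generate_genome_and_genes(_tiny_cfg(n_genes=6))
        counts = truth.gene_truth["group"].value_counts()
        assert sorted(counts) == [2, 2, 2]


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"mono_mode_weights": (0.7, 0.2)},
        {"mono_modes": (70, 150)},
        {"di_mode": 450},
        {"linker_dinuc_enrichment": 0.0},
        {"contig_length": -5},
        {"ndr_di_depletion_by_group": {"low": 1.5, "medium": 0.5, "high": 0.5}},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            dm.SimConfig(**kw).validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = _tiny_cfg(positioning_jitter_sd=2.5)
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = dm.SimConfig.from_yaml(tmp_path / "sim.yaml")
        assert back == cfg


class TestSequenceBias:
    def test_enrichment_one_is_identity(self):
        cfg = _tiny_cfg(linker_dinuc_enrichment=1.0)
        genome, _, truth = dm.generate_genome_and_genes(cfg)
        assert dm.plant_sequence_bias(genome, truth, cfg) == genome

    def test_length_conserved_and_cores_untouched(self):
        cfg = _tiny_cfg()
        genome, _, truth = dm.generate_genome_and_genes(cfg)
        biased = dm.plant_sequence_bias(genome, truth, cfg)
        for c in genome:
            assert len(biased[c]) == len(genome[c])
            for d in truth.dyads[c][:50]:
                a = d - 147 // 2
                assert biased[c][a:a + 147] == genome[c][a:a + 147]

    def test_linker_gc_class_enrichment_factor(self):
        # independent k-mer count over truth linkers vs truth cores
        cfg = _tiny_cfg(n_contigs=2, contig_length=100_000, linker_dinuc_enrichment=2.0)
        genome, _, truth = dm.generate_genome_and_genes(cfg)
        biased = dm.plant_sequence_bias(genome, truth, cfg)

        def pooled(regions):
            hit = tot = 0
            for c, ivs in regions.items():
                codes = encode(biased[c])
                ind = sum(dinuc_start_indicator(codes, d).astype(int)
                          for d in ("CC", "CG", "GC", "GG"))
                for a, b in ivs:
                    if b - a >= 2:
                        hit += int(ind[a:b - 1].sum())
                        tot += b - a - 1
            return hit / tot

        linker_f = pooled(truth.linkers)
        core_f = pooled({c: [(d - 73, d - 73 + 147) for d in dd]
                         for c, dd in truth.dyads.items()})
        assert linker_f / core_f == pytest.approx(2.0, rel=0.15)


class TestFragments:
    def test_zero_noise_collapse(self):
        cfg = _tiny_cfg(positioning_jitter_sd=0.0, mono_length_sd=0.0,
                        mono_mode_weights=(1.0, 0.0))
        res = dm.simulate_all(cfg)
        piles = dm.count_piles(res.mono)
        # every fragment covering a dyad has identical coordinates
        assert set(piles["length"]) == {132}
        mids = set(piles["midpoint"])
        assert mids <= set(np.concatenate(list(res.truth.dyads.values())).tolist())
        assert int(piles["pile"].sum()) == len(res.mono)

    def test_truth_midpoints_in_linkers_and_at_dyads(self):
        cfg = _tiny_cfg(positioning_jitter_sd=0.0, ndr_di_depletion_by_group={
            "low": 0.0, "medium": 0.0, "high": 0.0}, orf_end_di_depletion=0.0)
        res = dm.simulate_all(cfg)
        for c, grp in dm.count_piles(res.di).groupby("contig"):
            lk = res.truth.linkers[c]
            mids = grp["midpoint"].to_numpy()
            idx = np.searchsorted(lk[:, 0], mids, side="right") - 1
            assert np.all((mids >= lk[idx, 0]) & (mids < lk[idx, 1]))
        for c, grp in dm.count_piles(res.mono).groupby("contig"):
            d = res.truth.dyads[c]
            mids = grp["midpoint"].to_numpy()
            near = d[np.clip(np.searchsorted(d, mids), 0, len(d) - 1)]
            near_lo = d[np.clip(np.searchsorted(d, mids) - 1, 0, len(d) - 1)]
            dist = np.minimum(np.abs(mids - near), np.abs(mids - near_lo))
            assert np.all(dist <= 147 // 2)

    def test_full_ndr_suppression_removes_di_from_ndr_linkers(self):
        cfg = _tiny_cfg(ndr_di_depletion_by_group={"low": 1.0, "medium": 1.0, "high": 1.0},
                        positioning_jitter_sd=0.0)
        res = dm.simulate_all(cfg)
        for c, grp in dm.count_piles(res.di).groupby("contig"):
            lk = res.truth.linkers[c]
            hot = lk[res.truth.linker_ndr_prob[c] > 0]
            mids = grp["midpoint"].to_numpy()
            for a, b in hot:
                assert not np.any((mids >= a) & (mids < b))

    def test_length_ranges_mostly_in_acceptance_windows(self, small_sim):
        mono_len = (small_sim.mono["end"] - small_sim.mono["start"]).to_numpy()
        di_len = (small_sim.di["end"] - small_sim.di["start"]).to_numpy()
        assert ((mono_len >= 80) & (mono_len <= 230)).mean() >= 0.99
        assert ((di_len >= 200) & (di_len <= 400)).mean() >= 0.99

    def test_pile_tightness_follows_jitter(self):
        # the spread of the >=5-pile length subset is non-increasing as jitter drops
        sds = []
        for jitter in (4.0, 2.0, 1.0):
            cfg = _tiny_cfg(positioning_jitter_sd=jitter, mono_length_sd=0.0,
                            mono_mode_weights=(1.0, 0.0), n_mono_fragments=60_000)
            res = dm.simulate_all(cfg)
            lens = dm.pile_level_lengths(dm.count_piles(res.mono), 5)
            sds.append(float(np.std(lens)))
        assert sds[0] >= sds[1] >= sds[2]


class TestExpressionReads:
    def test_group_separation_in_rpkm(self, small_sim):
        total = int(small_sim.exon_counts["count"].sum())
        count_of = dict(zip(small_sim.exon_counts["id"], small_sim.exon_counts["count"]))
        rpkm = {g.id: dm.compute_rpkm(count_of[g.id], total, g.mature_length)
                for g in small_sim.genes}
        by_group = {grp: [rpkm[r.gene_id] for r in small_sim.truth.gene_truth.itertuples()
                          if r.group == grp] for grp in ("low", "medium", "high")}
        assert max(by_group["low"]) < min(by_group["medium"]) < max(by_group["medium"]) \
            < min(by_group["high"])

    def test_noise_free_reads_sit_on_truth_tss(self):
        cfg = _tiny_cfg(tss_read_noise_sd=0.0)
        res = dm.simulate_all(cfg)
        tss_of = dict(zip(res.truth.gene_truth["gene_id"], res.truth.gene_truth["tss"]))
        for r in res.five_prime.itertuples():
            assert r.pos == tss_of[r.gene_id]

    def test_five_prime_depth_tracks_rpkm(self, small_sim):
        totals = small_sim.five_prime.groupby("gene_id").size()
        total = int(small_sim.exon_counts["count"].sum())
        count_of = dict(zip(small_sim.exon_counts["id"], small_sim.exon_counts["count"]))
        ids = [g.id for g in small_sim.genes]
        rpkm = [dm.compute_rpkm(count_of[i], total,
                                next(g for g in small_sim.genes if g.id == i).mature_length)
                for i in ids]
        rho = stats.spearmanr([totals.get(i, 0) for i in ids], rpkm).statistic
        assert rho > 0.9


def test_written_outputs_roundtrip(tmp_path):
    res = dm.simulate_all(_tiny_cfg(), outdir=tmp_path)
    genome = dm.read_fasta(tmp_path / "genome.fa")
    assert genome == res.genome
    genes = dm.read_genes_gff3(tmp_path / "genes.gff3")
    assert len(genes) == len(res.genes)
    for got, exp in zip(sorted(genes, key=lambda g: g.id),
                        sorted(res.genes, key=lambda g: g.id)):
        assert (got.strand, got.trs, got.cds_end3, got.exons) == \
            (exp.strand, exp.trs, exp.cds_end3, exp.exons)
    mono = dm.read_fragments(tmp_path / "mono.bed", "mono")
    pd.testing.assert_frame_equal(mono, res.mono)
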