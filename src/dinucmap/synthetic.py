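"""Synthetic chromatin and MNase fragment simulator.

Generates a toy genome, gene models, a truth nucleosome architecture and
simulated mono-/dinucleosomal fragment libraries plus expression counts
and 5'-end (oligo-cap) reads, so that every downstream analysis stage is
testable without any sequencing download.

The simulator emulates the statistical structure the analyses assume:

* positioned nucleosome arrays (147 nt cores) separated by short linkers;
* a bimodal mononucleosomal fragment-length mixture (modes near 132 and
  150 nt) and a unimodal dinucleosomal distribution (mode near 300 nt);
* pile structure — redundant identical fragment intervals — whose
  tightness is controlled by ``positioning_jitter_sd``. Jitter is applied
  as independent integer displacements of the two fragment ends (MNase
  trimming and positioning uncertainty act on fragment ends), so tighter
  positioning yields both higher piles and sharper length distributions,
  and loosening it degrades both together;
* an expression-dependent nucleosome-depleted region (NDR) carved
  upstream of each TSS, with dinucleosomes of the NDR-adjacent linker
  suppressed with a per-expression-group probability;
* dinucleosome depletion immediately downstream of ORF 3' ends;
* a dinucleotide composition bias between core and linker DNA
  (CC/CG/GC/GG enriched in linkers, AT/TA depleted).

All randomness flows from ``SimConfig.seed``; the same config produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import GROUPS, GeneModel, write_genes_gff3
from .fragments import fragments_frame, write_fragments
from .genomes import random_genome, write_fasta

# stage tags for per-operation random streams derived from the one seed
_STAGE_GENOME, _STAGE_GENES, _STAGE_CHROMATIN, _STAGE_BIAS, _STAGE_FRAGS, _STAGE_EXPR = range(6)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


@dataclass
class SimConfig:
    """All simulator knobs. Defaults are the package's study conditions."""

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 100_000
    n_genes: int = 30
    core_length: int = 147
    linker_length_mean: float = 20.0
    linker_length_sd: float = 2.0
    mono_modes: tuple[int, int] = (132, 150)
    mono_mode_weights: tuple[float, float] = (0.5, 0.5)
    mono_length_sd: float = 2.0
    di_mode: int = 300
    di_length_sd: float = 2.0
    positioning_jitter_sd: float = 1.0
    ndr_width_by_group: dict[str, int] = field(
        default_factory=lambda: {"low": 80, "medium": 140, "high": 200})
    ndr_di_depletion_by_group: dict[str, float] = field(
        default_factory=lambda: {"low": 0.2, "medium": 0.6, "high": 0.95})
    orf_end_di_depletion: float = 0.8
    orf_end_window: int = 200
    linker_dinuc_enrichment: float = 2.0
    n_mono_fragments: int = 400_000
    n_di_fragments: int = 400_000
    # expression / 5'-read layer
    total_mapped_reads: int = 2_000_000
    rpkm_range_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (0.5, 14.6), "medium": (41.3, 63.9),
                                 "high": (199.0, 2400.0)})
    five_prime_depth_scale: float = 6.0
    tss_read_noise_sd: float = 5.0
    tss_point_mass: float = 0.6
    # gene geometry
    utr_length_range: tuple[int, int] = (50, 200)
    cds_length_range: tuple[int, int] = (800, 1600)
    min_gene_flank: int = 2000

    def validate(self) -> None:
        for name in ("n_contigs", "contig_length", "core_length", "di_mode",
                     "n_mono_fragments", "n_di_fragments", "total_mapped_reads",
                     "orf_end_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("linker_length_mean", "linker_length_sd", "mono_length_sd",
                     "di_length_sd", "positioning_jitter_sd", "tss_read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for p in (self.orf_end_di_depletion, self.tss_point_mass,
                  *self.ndr_di_depletion_by_group.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.mono_mode_weights) - 1.0) > 1e-9:
            raise ValueError("mono_mode_weights must sum to 1")
        if any(w < 0 for w in self.mono_mode_weights):
            raise ValueError("mono_mode_weights must be non-negative")
        if not all(80 <= m <= 230 for m in self.mono_modes):
            raise ValueError("mono_modes must lie inside the mono acceptance range [80, 230]")
        if not 200 <= self.di_mode <= 400:
            raise ValueError("di_mode must lie inside the di acceptance range [200, 400]")
        if not 0.0 < self.linker_dinuc_enrichment <= 4.0:
            raise ValueError("linker_dinuc_enrichment must be in (0, 4]")
        for g in GROUPS:
            if g not in self.ndr_width_by_group or g not in self.ndr_di_depletion_by_group:
                raise ValueError(f"missing expression group {g!r} in NDR maps")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulator config keys: {sorted(unknown)}")
        for key in ("mono_modes", "mono_mode_weights", "utr_length_range", "cds_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "rpkm_range_by_group" in raw:
            raw["rpkm_range_by_group"] = {k: tuple(v) for k, v in raw["rpkm_range_by_group"].items()}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class TruthChromatin:
    """Ground-truth nucleosome architecture of a simulated genome.

    ``dyads`` are sorted per-contig dyad positions of the remaining cores
    (after NDR carving); ``linkers`` the half-open intervals strictly
    between adjacent cores; ``linker_ndr_prob`` the per-linker probability
    of suppressing a dinucleosome whose midpoint linker it is (non-zero
    only for NDR-adjacent linkers); ``ndr_intervals`` the carved window
    per gene; ``gene_truth`` the per-gene truth table (tss, strand,
    group, ...).
    """

    dyads: dict[str, np.ndarray]
    linkers: dict[str, np.ndarray]
    linker_ndr_prob: dict[str, np.ndarray]
    ndr_intervals: dict[str, tuple[str, int, int]]
    gene_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# genome + genes + truth chromatin


def _build_gene(gene_id: str, contig: str, start: int, span: int, strand: str,
                utr: int, cds_len: int, exon_chunks: list[int]) -> GeneModel:
    """Assemble a gene on a local transcript axis, then mirror for '-' strand."""
    # local axis: 0 = TSS; exons on the local axis, introns of 60 nt inside the CDS
    intron = 60
    local_exons = []
    cursor = 0
    first_len = utr + exon_chunks[0]
    local_exons.append((cursor, cursor + first_len))
    cursor += first_len
    for chunk in exon_chunks[1:]:
        cursor += intron
        local_exons.append((cursor, cursor + chunk))
        cursor += chunk
    assert cursor == span
    local_trs, local_cds_end3 = utr, span - 1
    if strand == "+":
        exons = [(start + a, start + b) for a, b in local_exons]
        trs = start + local_trs
        cds_end3 = start + local_cds_end3
    else:
        end = start + span
        exons = [(end - b, end - a) for a, b in local_exons]
        trs = end - 1 - local_trs
        cds_end3 = end - 1 - local_cds_end3
    return GeneModel(id=gene_id, contig=contig, strand=strand, trs=trs,
                     cds_end3=cds_end3, exons=exons)


def generate_genome_and_genes(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], TruthChromatin]:
    """Generate genome, gene models and the truth nucleosome architecture.

    The genome has i.i.d. uniform base composition. Genes are placed
    non-overlapping with >= ``min_gene_flank`` nt between them (sizing
    error if they do not fit), each with a truth TSS (= transcript start)
    and a truth expression group (near-equal thirds). Nucleosome cores
    are tiled over each contig with linkers drawn from
    N(linker_length_mean, linker_length_sd), then the cores overlapping
    the configured NDR window upstream of each TSS are deleted.
    Deterministic given ``config.seed``.
    """
    config.validate()
    genome = random_genome(_rng(config.seed, _STAGE_GENOME), config.n_contigs,
                           config.contig_length)
    contigs = list(genome)
    L = config.contig_length
    rng = _rng(config.seed, _STAGE_GENES)

    # --- genes, round-robin over contigs, evenly spaced with >= flank gaps
    genes: list[GeneModel] = []
    per_contig: dict[str, list[int]] = {c: [] for c in contigs}
    for i in range(config.n_genes):
        per_contig[contigs[i % len(contigs)]].append(i)
    specs = {}
    for i in range(config.n_genes):
        utr = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        cds_len = int(rng.integers(config.cds_length_range[0], config.cds_length_range[1] + 1))
        n_ex = int(rng.integers(1, 4))
        chunks = [cds_len // n_ex] * n_ex
        chunks[-1] += cds_len - sum(chunks)
        strand = "+" if rng.random() < 0.5 else "-"
        span = utr + cds_len + 60 * (n_ex - 1)
        specs[i] = (utr, cds_len, chunks, strand, span)
    for contig, idxs in per_contig.items():
        if not idxs:
            continue
        total_span = sum(specs[i][4] for i in idxs)
        gap = (L - total_span) / (len(idxs) + 1)
        if gap < config.min_gene_flank:
            raise ValueError(
                f"sizing error: {len(idxs)} genes (total span {total_span} nt) do not fit "
                f"contig of {L} nt with {config.min_gene_flank} nt flanks")
        cursor = gap
        for i in idxs:
            utr, cds_len, chunks, strand, span = specs[i]
            start = int(round(cursor))
            genes.append(_build_gene(f"gene{i + 1:04d}", contig, start, span,
                                     strand, utr, cds_len, chunks))
            cursor += span + gap
    genes.sort(key=lambda g: g.id)

    # truth expression groups: near-equal thirds over a random permutation
    truth_group = {}
    if genes:
        perm = rng.permutation(len(genes))
        for gi, part in zip(np.array_split(perm, 3), GROUPS):
            for idx in gi:
                truth_group[genes[idx].id] = part
        for g in genes:
            g.group = truth_group[g.id]

    # --- nucleosome tiling
    rng_chrom = _rng(config.seed, _STAGE_CHROMATIN)
    core = config.core_length
    c_left = core // 2  # dyad - c_left is the core start
    dyads: dict[str, np.ndarray] = {}
    for contig in contigs:
        pos, dl = 0, []
        while pos + core <= L:
            dl.append(pos + c_left)
            linker = max(1, int(round(rng_chrom.normal(config.linker_length_mean,
                                                       config.linker_length_sd))))
            pos += core + linker
        dyads[contig] = np.asarray(dl, dtype=np.int64)

    # --- carve NDRs: delete cores overlapping the upstream window of each TSS
    ndr_intervals: dict[str, tuple[str, int, int]] = {}
    truth_rows = []
    for g in genes:
        # truth TSS = transcript start (5'-most exon base in transcript orientation)
        tss = g.span[0] if g.strand == "+" else g.span[1] - 1
        g.tss = tss
        width = int(config.ndr_width_by_group[g.group])
        if g.strand == "+":
            a, b = max(0, tss - width), tss
        else:
            a, b = tss + 1, min(L, tss + 1 + width)
        ndr_intervals[g.id] = (g.contig, a, b)
        d = dyads[g.contig]
        core_start = d - c_left
        keep = ~((core_start < b) & (core_start + core > a))
        dyads[g.contig] = d[keep]
        truth_rows.append((g.id, g.contig, g.strand, tss, g.trs, g.cds_end3,
                           g.mature_length, g.group))
    gene_truth = pd.DataFrame(truth_rows, columns=["gene_id", "contig", "strand", "tss",
                                                   "trs", "cds_end3", "mature_length",
                                                   "group"])

    # --- linkers between adjacent remaining cores, with NDR-adjacency probs
    linkers: dict[str, np.ndarray] = {}
    linker_prob: dict[str, np.ndarray] = {}
    for contig in contigs:
        d = dyads[contig]
        if len(d) < 2:
            linkers[contig] = np.empty((0, 2), dtype=np.int64)
            linker_prob[contig] = np.empty(0)
            continue
        starts = d[:-1] - c_left + core
        ends = d[1:] - c_left
        linkers[contig] = np.stack([starts, ends], axis=1)
        linker_prob[contig] = np.zeros(len(starts))
    for g in genes:
        contig, a, b = ndr_intervals[g.id]
        lk = linkers[contig]
        if len(lk) == 0:
            continue
        overlap = (lk[:, 0] < b) & (lk[:, 1] > a)
        p = float(config.ndr_di_depletion_by_group[g.group])
        linker_prob[contig][overlap] = np.maximum(linker_prob[contig][overlap], p)

    truth = TruthChromatin(dyads=dyads, linkers=linkers, linker_ndr_prob=linker_prob,
                           ndr_intervals=ndr_intervals, gene_truth=gene_truth)
    return genome, genes, truth


# ---------------------------------------------------------------------------
# linker sequence bias


def plant_sequence_bias(genome: dict[str, str], truth: TruthChromatin,
                        config: SimConfig) -> dict[str, str]:
    """Resample linker sequences from a G/C-enriched base model.

    Linker bases are redrawn i.i.d. with p(C) = p(G) = sqrt(f)/4 where
    f = ``linker_dinuc_enrichment``, which sets the expected frequency of
    each of CC/CG/GC/GG inside linkers to f/16 — f times the uniform
    background that core DNA keeps — while AT and TA drop to
    ((1 - sqrt(f)/2)/2)^2. Core intervals are untouched and the genome
    length is conserved. ``f = 1`` returns an identical copy.
    """
    f = config.linker_dinuc_enrichment
    if f <= 0:
        raise ValueError("linker_dinuc_enrichment must be > 0")
    if f == 1.0:
        return dict(genome)
    p_gc = np.sqrt(f) / 4.0
    probs = np.array([(1 - 2 * p_gc) / 2, p_gc, p_gc, (1 - 2 * p_gc) / 2])
    rng = _rng(config.seed, _STAGE_BIAS)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for contig, seq in genome.items():
        arr = bytearray(seq.encode("ascii"))
        for a, b in truth.linkers.get(contig, ()):
            if not (0 <= a <= b <= len(arr)):
                raise ValueError(f"linker [{a}, {b}) outside contig {contig}")
            draw = rng.choice(4, size=b - a, p=probs)
            arr[a:b] = lut[draw].tobytes()
        out[contig] = arr.decode("ascii")
    return out


# ---------------------------------------------------------------------------
# fragment simulation


def _round_normal(rng: np.random.Generator, mean, sd: float, size: int) -> np.ndarray:
    return np.round(rng.normal(mean, sd, size=size)).astype(np.int64)


def sample_mono_lengths(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    """Draw n lengths from the two-mode mononucleosome mixture, rounded."""
    comp = rng.choice(2, size=n, p=np.asarray(config.mono_mode_weights, dtype=float))
    modes = np.asarray(config.mono_modes)[comp]
    return _round_normal(rng, modes, config.mono_length_sd, n)


def simulate_fragments(genome: dict[str, str], truth: TruthChromatin,
                       config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate mono- and dinucleosomal fragment libraries.

    Mononucleosomal fragments are centred on dyads with length drawn from
    the two-mode mixture; dinucleosomal fragments are centred on linker
    midpoints between adjacent cores with length ~ N(di_mode,
    di_length_sd). Positioning jitter displaces each fragment end by an
    independent round(N(0, positioning_jitter_sd)). Dinucleosome
    candidates are suppressed with the owning linker's NDR-adjacency
    probability, and with ``orf_end_di_depletion`` when their midpoint
    lies within ``orf_end_window`` nt downstream of an ORF 3' end.
    Fragments extending past a contig end are discarded, so the returned
    library can be smaller than the requested counts. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_FRAGS)
    contigs = list(genome)
    clen = {c: len(genome[c]) for c in contigs}

    def _emit(centers: np.ndarray, contig_idx: np.ndarray, lengths: np.ndarray,
              cls: str, keep_extra: np.ndarray | None = None) -> pd.DataFrame:
        j1 = _round_normal(rng, 0.0, config.positioning_jitter_sd, len(centers))
        j2 = _round_normal(rng, 0.0, config.positioning_jitter_sd, len(centers))
        start = centers - lengths // 2 + j1
        end = centers - lengths // 2 + lengths + j2
        lens = np.asarray([clen[contigs[i]] for i in range(len(contigs))])
        keep = (start >= 0) & (end <= lens[contig_idx]) & (end > start)
        if keep_extra is not None:
            keep &= keep_extra
        names = np.asarray(contigs, dtype=object)[contig_idx[keep]]
        return fragments_frame(names, start[keep], end[keep], cls)

    # mono: uniform with replacement over all dyads
    dyad_pos = np.concatenate([truth.dyads[c] for c in contigs]) if contigs else np.empty(0, np.int64)
    dyad_ctg = np.concatenate([np.full(len(truth.dyads[c]), i) for i, c in enumerate(contigs)]) \
        if contigs else np.empty(0, np.int64)
    if len(dyad_pos):
        pick = rng.integers(0, len(dyad_pos), size=config.n_mono_fragments)
        mono = _emit(dyad_pos[pick], dyad_ctg[pick].astype(np.int64),
                     sample_mono_lengths(rng, config, config.n_mono_fragments), "mono")
    else:
        mono = fragments_frame([], [], [], "mono")

    # di: uniform with replacement over linkers, with NDR / ORF-end suppression
    lk_center, lk_ctg, lk_prob = [], [], []
    for i, c in enumerate(contigs):
        lk = truth.linkers[c]
        if len(lk) == 0:
            continue
        lk_center.append((lk[:, 0] + lk[:, 1]) // 2)
        lk_ctg.append(np.full(len(lk), i))
        lk_prob.append(truth.linker_ndr_prob[c])
    if lk_center:
        lk_center = np.concatenate(lk_center)
        lk_ctg = np.concatenate(lk_ctg).astype(np.int64)
        lk_prob = np.concatenate(lk_prob)
        pick = rng.integers(0, len(lk_center), size=config.n_di_fragments)
        centers, ctg = lk_center[pick], lk_ctg[pick]
        keep = rng.random(config.n_di_fragments) >= lk_prob[pick]
        # ORF-end suppression by midpoint position (strand-oriented downstream window)
        orf_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
        for row in truth.gene_truth.itertuples():
            if row.strand == "+":
                w = (row.cds_end3 + 1, row.cds_end3 + 1 + config.orf_end_window)
            else:
                w = (max(0, row.cds_end3 - config.orf_end_window), row.cds_end3)
            orf_windows[row.contig].append(w)
        if config.orf_end_di_depletion > 0:
            in_orf = np.zeros(config.n_di_fragments, dtype=bool)
            for i, c in enumerate(contigs):
                mask_c = ctg == i
                for a, b in orf_windows[c]:
                    in_orf |= mask_c & (centers >= a) & (centers < b)
            keep &= ~(in_orf & (rng.random(config.n_di_fragments) < config.orf_end_di_depletion))
        lengths = _round_normal(rng, float(config.di_mode), config.di_length_sd,
                                config.n_di_fragments)
        di = _emit(centers, ctg, lengths, "di", keep_extra=keep)
    else:
        di = fragments_frame([], [], [], "di")
    return mono.reset_index(drop=True), di.reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression counts and 5'-end reads


def simulate_expression_and_tss_reads(
    genes: list[GeneModel], truth: TruthChromatin, config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-gene exon read counts and 5'-end read positions.

    Exon counts are derived from a per-group log-uniform target RPKM so
    that recomputed RPKM ranks reproduce the truth groups. 5'-end reads
    concentrate at the truth TSS: a ``tss_point_mass`` fraction sits
    exactly on it, the rest is displaced by round(N(0,
    tss_read_noise_sd)) clipped into the 1 kb upstream window of the TRS.
    Read depth is proportional to RPKM. Deterministic given seed.
    """
    rng = _rng(config.seed, _STAGE_EXPR)
    group_of = dict(zip(truth.gene_truth["gene_id"], truth.gene_truth["group"]))
    count_rows, read_rows = [], []
    for g in genes:
        lo, hi = config.rpkm_range_by_group[group_of[g.id]]
        rpkm = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
        count = max(1, int(round(rpkm * config.total_mapped_reads * g.mature_length / 1e9)))
        count_rows.append((g.id, count))
        depth = max(1, int(round(config.five_prime_depth_scale * rpkm)))
        at_tss = rng.random(depth) < config.tss_point_mass
        offsets = np.where(at_tss, 0,
                           _round_normal(rng, 0.0, config.tss_read_noise_sd, depth))
        pos = g.tss + offsets
        if g.strand == "+":
            pos = np.clip(pos, max(0, g.trs - 1000), g.trs)
        else:
            pos = np.clip(pos, g.trs, g.trs + 1000)
        for p in pos:
            read_rows.append((g.contig, int(p), g.strand, g.id))
    exon_counts = pd.DataFrame(count_rows, columns=["id", "count"])
    five_prime = pd.DataFrame(read_rows, columns=["contig", "pos", "strand", "gene_id"])
    return exon_counts, five_prime


# ---------------------------------------------------------------------------
# one-call convenience + file output


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: TruthChromatin
    mono: pd.DataFrame
    di: pd.DataFrame
    exon_counts: pd.DataFrame
    five_prime: pd.DataFrame


def simulate_all(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Run the full simulator; optionally write all outputs to ``outdir``."""
    genome, genes, truth = generate_genome_and_genes(config)
    genome = plant_sequence_bias(genome, truth, config)
    mono, di = simulate_fragments(genome, truth, config)
    exon_counts, five_prime = simulate_expression_and_tss_reads(genes, truth, config)
    result = SimResult(config, genome, genes, truth, mono, di, exon_counts, five_prime)
    if outdir is not None:
        write_simulation(result, outdir)
    return result


def write_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA / GFF3 / BED / TSV outputs plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": outdir / "genome.fa", "genes": outdir / "genes.gff3",
             "mono": outdir / "mono.bed", "di": outdir / "di.bed",
             "five_prime": outdir / "five_prime.bed",
             "exon_counts": outdir / "exon_counts.tsv",
             "dyads": outdir / "truth_dyads.tsv", "linkers": outdir / "truth_linkers.tsv",
             "ndrs": outdir / "truth_ndrs.tsv", "gene_truth": outdir / "truth_genes.tsv",
             "config": outdir / "sim_config.yaml"}
    write_fasta(result.genome, paths["genome"])
    write_genes_gff3(result.genes, paths["genes"])
    write_fragments(result.mono, paths["mono"])
    write_fragments(result.di, paths["di"])
    fp = result.five_prime
    pd.DataFrame({"contig": fp["contig"], "start": fp["pos"], "end": fp["pos"] + 1,
                  "name": fp["gene_id"], "score": 0, "strand": fp["strand"]}
                 ).to_csv(paths["five_prime"], sep="\t", header=False, index=False)
    result.exon_counts.to_csv(paths["exon_counts"], sep="\t", index=False)
    pd.concat([pd.DataFrame({"contig": c, "dyad": d})
               for c, d in result.truth.dyads.items()]
              ).to_csv(paths["dyads"], sep="\t", index=False)
    pd.concat([pd.DataFrame({"contig": c, "start": lk[:, 0], "end": lk[:, 1],
                             "ndr_prob": result.truth.linker_ndr_prob[c]})
               for c, lk in result.truth.linkers.items() if len(lk)]
              ).to_csv(paths["linkers"], sep="\t", index=False)
    pd.DataFrame([(gid, c, a, b) for gid, (c, a, b) in result.truth.ndr_intervals.items()],
                 columns=["gene_id", "contig", "start", "end"]
                 ).to_csv(paths["ndrs"], sep="\t", index=False)
    result.truth.gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    result.config.to_yaml(paths["config"])
    return paths
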