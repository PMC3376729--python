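"""End-to-end orchestration: simulate/load -> piles -> expression -> profiles -> dinuc.

One ``RunConfig`` drives all stages in dependency order and a JSON
manifest records every output file (with content hash), the parameters
and the seeds, so a rerun with the same config is byte-identical. All
interchange goes through plain FASTA / GFF3 / BED / TSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dinuc as dinuc_mod
from . import expression as expr_mod
from . import fragments as frag_mod
from . import lengths as len_mod
from . import profiles as prof_mod
from .genomes import read_fasta
from .synthetic import SimConfig, simulate_all

log = logging.getLogger("dinucmap")

REAL_INPUT_KEYS = ("genome", "genes", "mono", "di", "five_prime", "exon_counts")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``sim`` (simulator config) and ``inputs`` (paths to
    real genome/genes/fragment/5'-read/exon-count files) must be set.
    """

    outdir: str = "dinucmap_out"
    sim: SimConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    min_pile: int = 5
    profile_window: int = 1000
    chisq_window: tuple[int, int] = (-200, -1)
    closest_window: int = 500
    frequency_window: int = 150
    levels: tuple[int, ...] = len_mod.DEFAULT_PILE_LEVELS
    seed: int = 0
    scheme: str = "thirds"
    tss_window: int = 1000

    def validate(self) -> None:
        if (self.sim is None) == (not self.inputs):
            raise ValueError("exactly one of simulator config and real inputs must be set")
        if self.inputs:
            missing = [k for k in REAL_INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ValueError(f"missing input paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = SimConfig(**raw["sim"])
            sim.validate()
            raw["sim"] = sim
        for key in ("chisq_window", "levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _save(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = str(path)
        return path

    # --- stage: inputs
    if config.sim is not None:
        log.info("[simulate] seed=%d", config.sim.seed)
        sim = simulate_all(config.sim, outdir=outdir / "sim")
        genome, genes = sim.genome, sim.genes
        mono_raw, di_raw = sim.mono, sim.di
        exon_counts, five_prime = sim.exon_counts, sim.five_prime
        for p in sorted((outdir / "sim").iterdir()):
            outputs[f"sim/{p.name}"] = str(p)
    else:
        for key in REAL_INPUT_KEYS:
            if not Path(config.inputs[key]).exists():
                raise FileNotFoundError(
                    f"stage 'inputs': missing {key} file {config.inputs[key]}")
        log.info("[inputs] loading real data")
        genome = read_fasta(config.inputs["genome"])
        genes = expr_mod.read_genes_gff3(config.inputs["genes"])
        mono_raw = frag_mod.read_fragments(config.inputs["mono"], "mono")
        di_raw = frag_mod.read_fragments(config.inputs["di"], "di")
        exon_counts = pd.read_csv(config.inputs["exon_counts"], sep="\t")
        fp = frag_mod.read_fragments(config.inputs["five_prime"], "mono")
        strands = pd.read_csv(config.inputs["five_prime"], sep="\t", header=None).iloc[:, 5]
        five_prime = pd.DataFrame({"contig": fp["contig"], "pos": fp["start"],
                                   "strand": strands.values})

    # --- stage: piles
    log.info("[piles] filtering by class length range and counting piles")
    mono_f, mono_report = frag_mod.filter_by_length(mono_raw)
    di_f, di_report = frag_mod.filter_by_length(di_raw)
    mono_piles = frag_mod.count_piles(mono_f)
    di_piles = frag_mod.count_piles(di_f)
    _save(mono_piles, "piles_mono.tsv")
    _save(di_piles, "piles_di.tsv")

    # --- stage: expression
    log.info("[expression] RPKM, %s grouping, TSS calling", config.scheme)
    total_reads = int(exon_counts["count"].sum())
    count_of = dict(zip(exon_counts["id"], exon_counts["count"]))
    for g in genes:
        g.rpkm = expr_mod.compute_rpkm(count_of.get(g.id, 0), total_reads, g.mature_length)
    expr_mod.assign_groups(genes, scheme=config.scheme)
    tss_report = expr_mod.call_all_tss(five_prime, genes, window=config.tss_window)
    log.info("[expression] TSS called for %d genes, %d skipped",
             tss_report["called"], tss_report["skipped"])
    _save(expr_mod.genes_table(genes), "genes.tsv")

    # --- stage: lengths
    log.info("[lengths] pile-level histograms at levels %s", list(config.levels))
    for cls, piles in (("mono", mono_piles), ("di", di_piles)):
        usable = [lv for lv in config.levels
                  if len(len_mod.pile_level_lengths(piles, lv))]
        hists = len_mod.length_histogram_by_pile(piles, usable, seed=config.seed)
        len_mod.write_length_tsv(hists, outdir / f"lengths_{cls}.tsv")
        outputs[f"lengths_{cls}.tsv"] = str(outdir / f"lengths_{cls}.tsv")

    # --- stage: profiles + NDR chi-square
    log.info("[profiles] anchored profiles, min_pile=%d, W=%d",
             config.min_pile, config.profile_window)
    all_profiles = []
    by_key = {}
    for anchor in ("tss", "orf3"):
        for cls, piles in (("mono", mono_piles), ("di", di_piles)):
            for group in ("low", "medium", "high", "all"):
                try:
                    prof = prof_mod.build_profile(
                        piles, genes, anchor_kind=anchor, group=group,
                        window=config.profile_window, min_pile=config.min_pile)
                except ValueError as exc:
                    log.warning("[profiles] %s/%s/%s skipped: %s", anchor, cls, group, exc)
                    continue
                all_profiles.append(prof)
                by_key[(anchor, cls, group)] = prof
    _save(prof_mod.profiles_table(all_profiles), "profiles.tsv")
    chisq_rows = []
    for ga, gb in (("low", "medium"), ("low", "high"), ("medium", "high")):
        pa = by_key.get(("tss", "di", ga))
        pb = by_key.get(("tss", "di", gb))
        if pa is None or pb is None:
            continue
        try:
            chi2, df, p = prof_mod.ndr_depletion_chisq(pa, pb, window=config.chisq_window)
            chisq_rows.append((ga, gb, config.chisq_window[0], config.chisq_window[1],
                               chi2, df, p))
        except ValueError as exc:
            log.warning("[profiles] chi-square %s vs %s not computable: %s", ga, gb, exc)
    _save(pd.DataFrame(chisq_rows, columns=["group_a", "group_b", "win_lo", "win_hi",
                                            "chi2", "df", "p"]), "ndr_chisq.tsv")

    # --- stage: dinucleotide bias
    log.info("[dinuc] 16-dinucleotide profiles (closest W=%d, frequency W=%d)",
             config.closest_window, config.frequency_window)
    for cls, piles in (("mono", mono_piles), ("di", di_piles)):
        mids = dinuc_mod.midpoints_dict(piles, min_pile=config.min_pile)
        for statistic, W in (("closest", config.closest_window),
                             ("frequency", config.frequency_window)):
            profs = dinuc_mod.run_all_dinucs(genome, mids, statistic=statistic, window=W)
            _save(dinuc_mod.dinuc_table(profs), f"dinuc_{statistic}_{cls}.tsv")

    # --- manifest
    manifest = {
        "parameters": {
            "min_pile": config.min_pile, "profile_window": config.profile_window,
            "chisq_window": list(config.chisq_window),
            "closest_window": config.closest_window,
            "frequency_window": config.frequency_window,
            "levels": list(config.levels), "scheme": config.scheme,
            "tss_window": config.tss_window},
        "seeds": {"pipeline": config.seed,
                  "simulator": None if config.sim is None else config.sim.seed},
        "mode": "simulate" if config.sim is not None else "real",
        "filter_report": {"mono": mono_report["mono"], "di": di_report["di"]},
        "tss_report": tss_report,
        "outputs": {name: _sha256(Path(path)) for name, path in sorted(outputs.items())},
    }
    if config.sim is not None:
        manifest["parameters"]["sim"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config.sim).items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("[done] %d outputs in %s", len(outputs), outdir)
    return manifest


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(stream=sys.stderr, format="%(name)s %(levelname)s %(message)s",
                        level=logging.DEBUG if verbose else logging.INFO)
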