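"""Gene models, RPKM quantification, expression grouping and TSS calling.

The expression layer feeds the anchored-profile analyses: every gene gets
an RPKM (reads per kilobase of mature transcript per million mapped
reads), genes are split into low/medium/high groups by RPKM rank, and a
TSS is called per gene as the position most intensely mapped by 5'-end
(oligo-cap) reads within the 1 kb window upstream of the translation
start (TRS).

Coordinates are 0-based half-open internally; GFF3 (1-based, closed) is
converted on read/write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

GROUPS = ("low", "medium", "high")


@dataclass
class GeneModel:
    """A protein-coding gene with strand, TRS, exon structure and expression.

    ``trs`` is the 0-based position of the first CDS base in transcript
    orientation; ``cds_end3`` the 0-based position of the 3'-most CDS base
    (translational termination end, not transcript end). ``exons`` are
    0-based half-open genomic intervals, sorted and non-overlapping.
    """

    id: str
    contig: str
    strand: str
    trs: int
    cds_end3: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    tss: int | None = None
    rpkm: float | None = None
    group: str = "ungrouped"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(f"gene {self.id}: overlapping exons")
        if self.exons and self.mature_length <= 0:
            raise ValueError(f"gene {self.id}: mature length must be positive")

    @property
    def mature_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces inside the genomic CDS span."""
        lo, hi = (self.trs, self.cds_end3 + 1) if self.strand == "+" else (self.cds_end3, self.trs + 1)
        out = []
        for a, b in self.exons:
            s, e = max(a, lo), min(b, hi)
            if e > s:
                out.append((s, e))
        return out


# ---------------------------------------------------------------------------
# GFF3 I/O


def write_genes_gff3(genes: list[GeneModel], path: str | Path, source: str = "dinucmap") -> None:
    """Write gene/mRNA/exon/CDS features, 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            row = f"{g.contig}\t{source}\t%s\t%d\t%d\t.\t{g.strand}\t%s\t%s\n"
            fh.write(row % ("gene", lo + 1, hi, ".", f"ID={g.id}"))
            fh.write(row % ("mRNA", lo + 1, hi, ".", f"ID={g.id}.t1;Parent={g.id}"))
            for a, b in g.exons:
                fh.write(row % ("exon", a + 1, b, ".", f"Parent={g.id}.t1"))
            for a, b in g.cds_intervals():
                fh.write(row % ("CDS", a + 1, b, "0", f"Parent={g.id}.t1"))


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models through gffutils (in-memory db)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = [(f.start - 1, f.end) for f in db.children(g, featuretype="exon", order_by="start")]
        cds = [(f.start - 1, f.end) for f in db.children(g, featuretype="CDS", order_by="start")]
        if not exons:
            exons = [(g.start - 1, g.end)]
        if cds:
            lo = min(a for a, _ in cds)
            hi = max(b for _, b in cds) - 1
        else:
            lo, hi = exons[0][0], exons[-1][1] - 1
        trs, cds_end3 = (lo, hi) if g.strand == "+" else (hi, lo)
        genes.append(GeneModel(id=g.id, contig=g.seqid, strand=g.strand,
                               trs=trs, cds_end3=cds_end3, exons=exons))
    return genes


# ---------------------------------------------------------------------------
# RPKM and grouping


def compute_rpkm(exon_reads: int, total_mapped: int, mature_length: int) -> float:
    """RPKM = exon_reads * 1e9 / (total_mapped * mature_length)."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if mature_length <= 0:
        raise ValueError("mature_length must be positive")
    return exon_reads * 1e9 / (total_mapped * mature_length)


def assign_groups(genes: list[GeneModel], scheme: str = "thirds",
                  group_size: int | None = None) -> pd.DataFrame:
    """Rank genes ascending by RPKM and assign low/medium/high groups.

    ``scheme="thirds"`` partitions all N genes into three rank tertiles.
    ``scheme="rank-windows"`` uses three windows of ``group_size`` genes
    (default min(1000, N//3)): ranks [1, g], a middle window centered on
    ceil(N/2), and [N-g+1, N]; genes outside the windows stay
    "ungrouped". Rank 1 is the LOWEST RPKM; ties are broken by gene id so
    grouping is deterministic. Mutates ``gene.group`` and returns a
    summary table (id, rpkm, rank, group).
    """
    n = len(genes)
    if n < 3:
        raise ValueError(f"need at least 3 genes to form groups, got {n}")
    if any(g.rpkm is None for g in genes):
        raise ValueError("all genes need an rpkm before grouping")
    order = sorted(genes, key=lambda g: (g.rpkm, g.id))
    for g in genes:
        g.group = "ungrouped"
    if scheme == "thirds":
        bounds = [round(n / 3), round(2 * n / 3)]
        for rank0, g in enumerate(order):
            g.group = "low" if rank0 < bounds[0] else ("medium" if rank0 < bounds[1] else "high")
    elif scheme == "rank-windows":
        gsz = group_size if group_size is not None else min(1000, n // 3)
        if gsz < 1 or 3 * gsz > n:
            raise ValueError(f"group size {gsz} does not fit {n} genes")
        mid = math.ceil(n / 2)
        windows = {"low": (1, gsz),
                   "medium": (mid - gsz // 2 + 1, mid - gsz // 2 + gsz),
                   "high": (n - gsz + 1, n)}
        for name, (lo, hi) in windows.items():
            for rank in range(lo, hi + 1):
                order[rank - 1].group = name
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return pd.DataFrame({"id": [g.id for g in order],
                         "rpkm": [g.rpkm for g in order],
                         "rank": np.arange(1, n + 1),
                         "group": [g.group for g in order]})


# ---------------------------------------------------------------------------
# TSS calling


def call_tss(five_prime: pd.DataFrame, gene: GeneModel, window: int = 1000) -> int | None:
    """Call the TSS as the modal 5'-end read position upstream of the TRS.

    ``five_prime`` has one row per read: columns contig, pos, strand.
    Only strand-matched reads within the strand-oriented ``window`` nt
    upstream of the TRS (TRS base included) count. Ties break toward the
    position closest to the TRS. Returns None when no read falls in the
    window (the gene is then excluded from TSS-anchored analyses).
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    sel = (five_prime["contig"] == gene.contig) & (five_prime["strand"] == gene.strand)
    pos = five_prime.loc[sel, "pos"].to_numpy()
    if gene.strand == "+":
        pos = pos[(pos >= gene.trs - window) & (pos <= gene.trs)]
    else:
        pos = pos[(pos >= gene.trs) & (pos <= gene.trs + window)]
    if len(pos) == 0:
        return None
    vals, counts = np.unique(pos, return_counts=True)
    best = counts == counts.max()
    cand = vals[best]
    return int(cand[np.argmin(np.abs(cand - gene.trs))])


def call_all_tss(five_prime: pd.DataFrame, genes: list[GeneModel],
                 window: int = 1000) -> dict[str, int]:
    """Call every gene's TSS in place; returns a skip report."""
    n_called = 0
    for g in genes:
        g.tss = call_tss(five_prime, g, window=window)
        n_called += g.tss is not None
    return {"called": n_called, "skipped": len(genes) - n_called}


def count_reads_in_exons(reads: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Count reads overlapping each gene's exons (any-overlap rule).

    A read overlapping two genes counts for both; a read is counted once
    per gene even if it spans several of that gene's exons.
    """
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, sub in reads.groupby("contig"):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        order = np.argsort(s, kind="stable")
        by_contig[contig] = (s[order], e[order])
    rows = []
    for g in genes:
        if g.contig not in by_contig:
            rows.append((g.id, 0))
            continue
        starts, ends = by_contig[g.contig]
        max_len = int((ends - starts).max()) if len(starts) else 0
        hit: set[int] = set()
        for a, b in g.exons:
            lo = np.searchsorted(starts, a - max_len, side="left")
            hi = np.searchsorted(starts, b, side="left")
            idx = np.arange(lo, hi)
            idx = idx[ends[idx] > a]
            hit.update(idx.tolist())
        rows.append((g.id, len(hit)))
    return pd.DataFrame(rows, columns=["id", "count"])


def genes_table(genes: list[GeneModel]) -> pd.DataFrame:
    """Flat per-gene table (id, contig, strand, trs, cds_end3, tss, rpkm, group)."""
    return pd.DataFrame({
        "id": [g.id for g in genes], "contig": [g.contig for g in genes],
        "strand": [g.strand for g in genes], "trs": [g.trs for g in genes],
        "cds_end3": [g.cds_end3 for g in genes],
        "mature_length": [g.mature_length for g in genes],
        "tss": [-1 if g.tss is None else g.tss for g in genes],
        "rpkm": [np.nan if g.rpkm is None else g.rpkm for g in genes],
        "group": [g.group for g in genes]})
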