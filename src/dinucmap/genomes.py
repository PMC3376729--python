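"""Genome container helpers.

A genome is a plain ``dict`` mapping contig name to an upper-case DNA
string. Everything downstream works in 0-based, half-open coordinates on
these strings. FASTA round-tripping goes through Biopython; the integer
encoding used by the dinucleotide scanners maps A/C/G/T to 0..3 and any
other character (ambiguity codes included) to 4, which never matches a
dinucleotide.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: The 16 dinucleotides in lexicographic order (AA, AC, ..., TT).
DINUCLEOTIDES = [a + b for a in BASES for b in BASES]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a ``{contig: sequence}`` dict (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def random_genome(
    rng: np.random.Generator, n_contigs: int, contig_length: int, prefix: str = "contig"
) -> dict[str, str]:
    """i.i.d. uniform A/C/G/T genome — the neutral canvas for bias planting."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for i in range(n_contigs):
        codes = rng.integers(0, 4, size=contig_length)
        genome[f"{prefix}{i + 1}"] = lut[codes].tobytes().decode("ascii")
    return genome


def dinuc_codes(dinuc: str) -> tuple[int, int]:
    """Validate a 2-mer over {A,C,G,T} and return its two base codes."""
    if len(dinuc) != 2 or any(b not in BASES for b in dinuc.upper()):
        raise ValueError(f"not a dinucleotide over ACGT: {dinuc!r}")
    d = dinuc.upper()
    return BASES.index(d[0]), BASES.index(d[1])


def dinuc_start_indicator(codes: np.ndarray, dinuc: str) -> np.ndarray:
    """Boolean array of length L-1: True where ``dinuc`` starts (overlaps count)."""
    a, b = dinuc_codes(dinuc)
    return (codes[:-1] == a) & (codes[1:] == b)


def occurrence_positions(codes: np.ndarray, dinuc: str) -> np.ndarray:
    """Sorted start indices of every (possibly overlapping) occurrence."""
    return np.flatnonzero(dinuc_start_indicator(codes, dinuc))
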