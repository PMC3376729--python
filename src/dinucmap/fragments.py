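"""Fragment I/O, length filtering, midpoints and pile counting.

A "fragment" is one sequenced nucleosomal DNA fragment mapped to the
genome: contig, 0-based half-open interval, and a class tag (``mono`` or
``di``). Duplicates are positioning evidence and are never collapsed
silently: the number of fragments mapping to the identical interval is
the *pile* count, and midpoints of high-pile intervals are what the
anchored-profile and sequence-bias analyses consume.

Note this inverts standard ChIP-seq practice: PCR/optical duplicates are
NOT removed. Redundantly mapped identical fragment pairs are exactly the
evidence that a nucleosome is well positioned.

Fragment collections are pandas DataFrames with columns
``contig, start, end, cls`` (one row per fragment, input order preserved);
piled-midpoint tables add ``midpoint, length, pile``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: Inclusive fragment-length acceptance ranges per class (nt).
MONO_LENGTH_RANGE = (80, 230)
DI_LENGTH_RANGE = (200, 400)
LENGTH_RANGES = {"mono": MONO_LENGTH_RANGE, "di": DI_LENGTH_RANGE}

FRAGMENT_COLUMNS = ["contig", "start", "end", "cls"]
PILE_COLUMNS = ["contig", "start", "end", "midpoint", "length", "pile", "cls"]


def _empty_fragments() -> pd.DataFrame:
    return pd.DataFrame({"contig": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64), "cls": pd.Series(dtype=str)})


def fragments_frame(contig, start, end, cls) -> pd.DataFrame:
    """Assemble a fragment table from per-fragment arrays."""
    return pd.DataFrame({"contig": np.asarray(contig, dtype=object),
                         "start": np.asarray(start, dtype=np.int64),
                         "end": np.asarray(end, dtype=np.int64),
                         "cls": cls if np.ndim(cls) else np.repeat(cls, len(start))})


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def read_fragments(path: str | Path, cls: str) -> pd.DataFrame:
    """Read fragments from BED (>=3 columns) or BEDPE.

    BEDPE records (detected by an integer sixth column, i.e. the second
    mate's end coordinate) collapse to the outer span of the read pair.
    Duplicates are preserved in input order. Malformed lines raise with
    the 1-based line number.
    """
    if cls not in ("mono", "di"):
        raise ValueError(f"cls must be 'mono' or 'di', got {cls!r}")
    contigs: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split("\t") if "\t" in line else line.split()
            try:
                if len(toks) >= 6 and _is_int(toks[4]) and _is_int(toks[5]) and not _is_int(toks[3]):
                    # BEDPE: chrom1 start1 end1 chrom2 start2 end2 ...
                    c1, s1, e1, c2, s2, e2 = toks[0], int(toks[1]), int(toks[2]), toks[3], int(toks[4]), int(toks[5])
                    if c1 != c2:
                        raise ValueError("mates on different contigs")
                    start, end = min(s1, s2), max(e1, e2)
                    contig = c1
                else:
                    contig, start, end = toks[0], int(toks[1]), int(toks[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed record at line {lineno}: {line!r} ({exc})") from None
            if end <= start:
                raise ValueError(f"{path}: end <= start at line {lineno}: {line!r}")
            contigs.append(contig)
            starts.append(start)
            ends.append(end)
    if not contigs:
        return _empty_fragments()
    return fragments_frame(contigs, starts, ends, cls)


def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    """Write fragments as BED6 (name = class tag, score = 0, strandless)."""
    out = frags[["contig", "start", "end"]].copy()
    out["name"] = frags["cls"].values
    out["score"] = 0
    out["strand"] = "."
    out.to_csv(path, sep="\t", header=False, index=False)


def filter_by_length(frags: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Keep fragments inside their class length range (bounds inclusive).

    Mono fragments must have length in [80, 230] nt and di fragments in
    [200, 400] nt. Returns the filtered table (input order preserved) and
    a per-class report of kept/dropped counts.
    """
    length = (frags["end"] - frags["start"]).to_numpy()
    keep = np.zeros(len(frags), dtype=bool)
    report: dict[str, dict[str, int]] = {}
    for cls, (lo, hi) in LENGTH_RANGES.items():
        in_cls = (frags["cls"] == cls).to_numpy()
        ok = in_cls & (length >= lo) & (length <= hi)
        keep |= ok
        report[cls] = {"kept": int(ok.sum()), "dropped": int(in_cls.sum() - ok.sum())}
    return frags[keep].reset_index(drop=True), report


def fragment_midpoint(start: int, end: int) -> int:
    """Midpoint of a fragment interval: floor((start + end) / 2).

    For even-length fragments this is the right-of-center base — a fixed,
    documented convention so every downstream profile is reproducible
    bit-exact. Empty intervals are an error.
    """
    if end <= start:
        raise ValueError(f"empty fragment interval [{start}, {end})")
    return (start + end) // 2


def count_piles(frags: pd.DataFrame, on: str = "interval") -> pd.DataFrame:
    """Group identical fragments into piled midpoints.

    ``on="interval"`` (default): a pile is the set of fragments sharing the
    identical (contig, start, end); this keeps within-pile lengths well
    defined, which the size-by-pile analysis needs. ``on="midpoint"`` is
    the documented alternative reading — fragments sharing (contig,
    midpoint) pile together and the reported length/interval are those of
    the pile's modal length (smallest length on ties).

    The sum of pile counts always equals the number of input fragments.
    """
    if len(frags) == 0:
        return pd.DataFrame({c: pd.Series(dtype=np.int64 if c not in ("contig", "cls") else str)
                             for c in PILE_COLUMNS})
    df = frags.copy()
    df["midpoint"] = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    df["length"] = df["end"] - df["start"]
    if on == "interval":
        grouped = (df.groupby(["contig", "start", "end", "cls"], sort=True, observed=True)
                     .agg(midpoint=("midpoint", "first"), length=("length", "first"),
                          pile=("start", "size"))
                     .reset_index())
    elif on == "midpoint":
        def _modal(sub: pd.DataFrame) -> pd.Series:
            counts = sub["length"].value_counts()
            best_len = counts[counts == counts.max()].index.min()
            rep = sub[sub["length"] == best_len].iloc[0]
            return pd.Series({"start": rep["start"], "end": rep["end"],
                              "length": best_len, "pile": len(sub)})
        grouped = (df.groupby(["contig", "midpoint", "cls"], sort=True, observed=True)
                     .apply(_modal, include_groups=False).reset_index())
    else:
        raise ValueError(f"on must be 'interval' or 'midpoint', got {on!r}")
    grouped["pile"] = grouped["pile"].astype(np.int64)
    return grouped[PILE_COLUMNS].reset_index(drop=True)


def select_piled(mids: pd.DataFrame, min_pile: int) -> pd.DataFrame:
    """Keep piled midpoints supported by at least ``min_pile`` fragments."""
    if min_pile < 1:
        raise ValueError(f"min_pile must be >= 1, got {min_pile}")
    return mids[mids["pile"] >= min_pile].reset_index(drop=True)


def write_piled_tsv(mids: pd.DataFrame, path: str | Path) -> None:
    mids[PILE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_piled_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"contig": str, "cls": str})


def write_piled_bed(mids: pd.DataFrame, path: str | Path) -> None:
    """Piled midpoints as BED6: 1-nt interval at the midpoint, score = pile."""
    out = pd.DataFrame({"contig": mids["contig"], "start": mids["midpoint"],
                        "end": mids["midpoint"] + 1, "name": mids["cls"],
                        "score": mids["pile"], "strand": "."})
    out.to_csv(path, sep="\t", header=False, index=False)
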