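"""Dinucleotide sequence preference around nucleosome fragment midpoints.

Two statistics, each computed for all 16 dinucleotides and normalized
against an all-genome-positions background so that "no enrichment" sits
at a baseline of 100:

* **closest-distance**: for every midpoint, the signed distance (positive
  downstream in genome coordinates) to the nearest occurrence of the
  dinucleotide within a search cap of W nt. A unique nearest occurrence
  contributes weight 1 at its distance; an exact two-sided tie
  contributes 0.5 to each side (any consistent tie rule cancels in the
  observed/background ratio); a midpoint with no occurrence within W
  contributes nothing. The background applies the identical rule with
  the midpoint set equal to every eligible genome position.
* **frequency**: the fraction of midpoints whose 2-mer starting at
  offset o equals the dinucleotide, against the genome-wide fraction of
  positions starting it (a scalar background).

Conventions: an occurrence's position is the start index of the 2-mer;
overlapping occurrences all count; ambiguity codes never match; and
positions within W of a contig edge are excluded from both the observed
and the background sets so the ratio stays unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genomes import DINUCLEOTIDES, dinuc_codes, dinuc_start_indicator, encode, occurrence_positions


@dataclass
class DinucProfile:
    """One dinucleotide's normalized profile around a midpoint set.

    ``normalized[o]`` = 100 x (observed rate / background rate) at offset
    o wherever the background is positive; offsets with zero background
    are masked (``normalized`` holds NaN there and ``masked`` is True).
    """

    dinuc: str
    statistic: str
    window: int
    observed: np.ndarray
    background: np.ndarray
    n_obs: int
    n_bg: int
    normalized: np.ndarray
    masked: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)


def eligible_positions(seq_len: int, window: int) -> np.ndarray:
    """Positions at least ``window`` nt from both contig edges.

    A position p is eligible when the full search window [p - W, p + W]
    of dinucleotide start indices fits inside the contig, i.e. W <= p <=
    L - 2 - W.
    """
    return np.arange(window, seq_len - 1 - window, dtype=np.int64)


def restrict_to_eligible(midpoints: dict[str, np.ndarray], genome: dict[str, str],
                         window: int) -> dict[str, np.ndarray]:
    out = {}
    for contig, mids in midpoints.items():
        m = np.asarray(mids, dtype=np.int64)
        L = len(genome[contig])
        out[contig] = m[(m >= window) & (m <= L - 2 - window)]
    return out


def midpoints_dict(mids: pd.DataFrame, min_pile: int = 1) -> dict[str, np.ndarray]:
    """Per-contig sorted midpoint positions from a piled-midpoint table."""
    sub = mids[mids["pile"] >= min_pile]
    return {contig: np.sort(grp["midpoint"].to_numpy(np.int64))
            for contig, grp in sub.groupby("contig")}


def _closest_one_contig(occ: np.ndarray, mids: np.ndarray, window: int,
                        hist: np.ndarray) -> None:
    """Accumulate closest-occurrence weights for one contig into ``hist``."""
    if len(occ) == 0 or len(mids) == 0:
        return
    sentinel = window + 1
    idx = np.searchsorted(occ, mids, side="left")
    has_right = idx < len(occ)
    has_left = idx > 0
    d_right = np.where(has_right, occ[np.minimum(idx, len(occ) - 1)] - mids, sentinel)
    d_left = np.where(has_left, mids - occ[np.maximum(idx - 1, 0)], sentinel)
    d_right = np.where(d_right <= window, d_right, sentinel)
    d_left = np.where(d_left <= window, d_left, sentinel)
    tie = (d_left == d_right) & (d_left <= window)
    right_wins = (d_right < d_left) & (d_right <= window)
    left_wins = (d_left < d_right) & (d_left <= window)
    nbins = 2 * window + 1
    hist += np.bincount(window + d_right[right_wins], minlength=nbins).astype(float)
    hist += np.bincount(window - d_left[left_wins], minlength=nbins).astype(float)
    if tie.any():
        hist += 0.5 * np.bincount(window + d_right[tie], minlength=nbins).astype(float)
        hist += 0.5 * np.bincount(window - d_left[tie], minlength=nbins).astype(float)


def closest_distance_histogram(genome: dict[str, str], midpoints: dict[str, np.ndarray],
                               dinuc: str, window: int = 500,
                               _codes: dict[str, np.ndarray] | None = None,
                               ) -> tuple[np.ndarray, int]:
    """Histogram of signed distances to the closest dinucleotide occurrence.

    Returns (per-offset weight over [-W, +W], number of eligible
    midpoints used). Midpoints within W of a contig edge are excluded
    (and counted out of n); each remaining midpoint contributes total
    weight 1 (0.5 + 0.5 on an exact tie) or 0 when no occurrence lies
    within the cap.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    dinuc_codes(dinuc)  # validate
    hist = np.zeros(2 * window + 1)
    n_used = 0
    for contig, mids in midpoints.items():
        codes = _codes[contig] if _codes is not None else encode(genome[contig])
        m = np.asarray(mids, dtype=np.int64)
        L = len(codes)
        m = m[(m >= window) & (m <= L - 2 - window)]
        n_used += len(m)
        occ = occurrence_positions(codes, dinuc)
        _closest_one_contig(occ, np.sort(m), window, hist)
    return hist, n_used


def background_closest_distance(genome: dict[str, str], dinuc: str, window: int = 500,
                                _codes: dict[str, np.ndarray] | None = None,
                                ) -> tuple[np.ndarray, int]:
    """Closest-distance histogram with every eligible position as a midpoint."""
    all_positions = {contig: eligible_positions(len(seq), window)
                     for contig, seq in genome.items()}
    return closest_distance_histogram(genome, all_positions, dinuc, window, _codes=_codes)


def frequency_histogram(genome: dict[str, str], midpoints: dict[str, np.ndarray],
                        dinuc: str, window: int = 150,
                        _codes: dict[str, np.ndarray] | None = None,
                        ) -> tuple[np.ndarray, float, int]:
    """Per-offset dinucleotide start frequency around midpoints.

    Returns (fraction of midpoints whose 2-mer at offset o equals
    ``dinuc`` for o in [-W, +W], genome-wide background fraction, number
    of eligible midpoints).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    dinuc_codes(dinuc)
    hits = np.zeros(2 * window + 1)
    n_used = 0
    total_occ = 0
    total_pos = 0
    for contig, mids in midpoints.items():
        codes = _codes[contig] if _codes is not None else encode(genome[contig])
        ind = dinuc_start_indicator(codes, dinuc)
        total_occ += int(ind.sum())
        total_pos += len(ind)
        m = np.asarray(mids, dtype=np.int64)
        L = len(codes)
        m = m[(m >= window) & (m <= L - 2 - window)]
        n_used += len(m)
        if len(m) == 0:
            continue
        for j, o in enumerate(range(-window, window + 1)):
            hits[j] += ind[m + o].sum()
    if total_pos == 0:
        raise ValueError("empty genome")
    fractions = hits / n_used if n_used else np.zeros_like(hits)
    return fractions, total_occ / total_pos, n_used


def normalize_to_baseline(observed: np.ndarray, background: np.ndarray,
                          n_obs: int, n_bg: int) -> tuple[np.ndarray, np.ndarray]:
    """Scale an observed profile to the no-enrichment baseline of 100.

    value(o) = 100 x (observed(o)/n_obs) / (background(o)/n_bg) wherever
    background(o) > 0; offsets with zero background are masked (NaN).
    Returns (normalized values, masked flags).
    """
    if n_obs <= 0 or n_bg <= 0:
        raise ValueError("n_obs and n_bg must be positive")
    observed = np.asarray(observed, dtype=float)
    background = np.broadcast_to(np.asarray(background, dtype=float), observed.shape)
    masked = background <= 0
    normalized = np.full_like(observed, np.nan)
    np.divide(observed / n_obs, background / n_bg, out=normalized, where=~masked)
    normalized[~masked] *= 100.0
    return normalized, masked


def run_all_dinucs(genome: dict[str, str], midpoints: dict[str, np.ndarray],
                   statistic: str = "closest", window: int | None = None,
                   ) -> dict[str, DinucProfile]:
    """Compute all 16 dinucleotide profiles for one midpoint set.

    ``statistic`` is "closest" (search cap default 500 nt) or
    "frequency" (window default 150 nt). Returns a dict keyed AA..TT
    with exactly 16 profiles, deterministic in input order.
    """
    if statistic not in ("closest", "frequency"):
        raise ValueError(f"statistic must be 'closest' or 'frequency', got {statistic!r}")
    if window is None:
        window = 500 if statistic == "closest" else 150
    codes = {contig: encode(seq) for contig, seq in genome.items()}
    profiles: dict[str, DinucProfile] = {}
    for dinuc in DINUCLEOTIDES:
        if statistic == "closest":
            obs, n_obs = closest_distance_histogram(genome, midpoints, dinuc, window,
                                                    _codes=codes)
            bg, n_bg = background_closest_distance(genome, dinuc, window, _codes=codes)
            norm, masked = normalize_to_baseline(obs, bg, n_obs, n_bg)
            background = bg
        else:
            obs, bg_scalar, n_obs = frequency_histogram(genome, midpoints, dinuc, window,
                                                        _codes=codes)
            n_bg = 1
            norm, masked = normalize_to_baseline(obs, np.full_like(obs, bg_scalar), 1, 1)
            background = np.full_like(obs, bg_scalar)
        profiles[dinuc] = DinucProfile(dinuc=dinuc, statistic=statistic, window=window,
                                       observed=obs, background=background,
                                       n_obs=n_obs, n_bg=n_bg,
                                       normalized=norm, masked=masked)
    return profiles


def dinuc_table(profiles: dict[str, DinucProfile]) -> pd.DataFrame:
    """Long-format table: dinuc, offset, observed, background, normalized, masked."""
    rows = []
    for dinuc in DINUCLEOTIDES:
        p = profiles[dinuc]
        for o, ob, bg, nm, mk in zip(p.offsets, p.observed, p.background,
                                     p.normalized, p.masked):
            rows.append((dinuc, int(o), ob, bg, nm, bool(mk)))
    return pd.DataFrame(rows, columns=["dinuc", "offset", "observed", "background",
                                       "normalized", "masked"])


def plot_dinuc_profiles(profiles: dict[str, DinucProfile], path: str | Path,
                        title: str = "") -> None:
    """16-panel plot of normalized profiles (baseline 100 dashed)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 4, figsize=(12, 9), sharex=True)
    for ax, dinuc in zip(axes.flat, DINUCLEOTIDES):
        p = profiles[dinuc]
        ax.plot(p.offsets, p.normalized, lw=0.8)
        ax.axhline(100, color="grey", lw=0.5, ls="--")
        ax.set_title(dinuc, fontsize=9)
    for ax in axes[-1]:
        ax.set_xlabel("offset (nt)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
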