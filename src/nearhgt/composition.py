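"""Genomic-signature composition scan: word spectra and atypical windows.

A sequence's l_w-spectrum is the 4^l_w vector of relative frequencies of all
overlapping l_w-mers (l_w = 2, 3, 4), or, in GC mode, the 2-vector of G+C vs
A+T content.  A sliding window (default 2000 bp, step 10 bp) is compared to
the whole-genome spectrum by Euclidean distance; a window is delta-atypical
if its distance exceeds the empirical (1 - delta) quantile of all window
distances (strict >).  A gene is delta-atypical if any (or, optionally, a
majority of) overlapping windows are atypical.  Composition methods lose
power on transfers between closely related genomes, whose signatures are
nearly identical -- this scan is the comparator for that claim.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "WindowCall",
    "spectrum",
    "window_scan",
    "atypical_threshold",
    "atypical_genes",
]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _BASE_CODE[b] = i
for i, b in enumerate(b"acgt"):
    _BASE_CODE[b] = i


@dataclass(frozen=True)
class Spectrum:
    """Relative word frequencies of a sequence segment."""

    word_length: int  # 0 denotes GC mode
    frequencies: np.ndarray

    def __post_init__(self):
        total = float(self.frequencies.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"spectrum frequencies sum to {total}, not 1")


def _encode(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def _word_counts(codes: np.ndarray, word_length: int) -> np.ndarray:
    """Counts of overlapping words (step 1); words containing a non-ACGT
    character are skipped."""
    n_words = len(codes) - word_length + 1
    if n_words < 1:
        raise ValueError("sequence shorter than word length")
    idx = np.zeros(n_words, dtype=np.int64)
    valid = np.ones(n_words, dtype=bool)
    for j in range(word_length):
        part = codes[j : j + n_words]
        idx = idx * 4 + np.where(part >= 0, part, 0)
        valid &= part >= 0
    return np.bincount(idx[valid], minlength=4**word_length).astype(float)


def spectrum(sequence: str, word_length: int | Literal["gc"]) -> Spectrum:
    """The l_w-spectrum of a sequence, or its (G+C, A+T) split in GC mode."""
    codes = _encode(sequence)
    if word_length == "gc":
        valid = codes >= 0
        if not valid.any():
            raise ValueError("no unambiguous bases in sequence")
        gc = float(np.isin(codes[valid], (1, 2)).sum())
        total = float(valid.sum())
        return Spectrum(0, np.array([gc / total, 1.0 - gc / total]))
    if word_length < 1:
        raise ValueError("word_length must be >= 1 or 'gc'")
    counts = _word_counts(codes, int(word_length))
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid words in sequence")
    return Spectrum(int(word_length), counts / total)


@dataclass(frozen=True)
class WindowCall:
    """One window of the sliding scan (0-based half-open coordinates)."""

    start: int
    end: int
    distance: float
    atypical: bool = False


def window_scan(
    genome_sequence: str,
    word_length: int | Literal["gc"] = 4,
    window_size: int = 2000,
    step: int = 10,
) -> pd.DataFrame:
    """Euclidean distance of each sliding window's spectrum to the genome's.

    Windows are taken on the linearized sequence (no wrap-around).  Returns
    a DataFrame with columns start, end, distance.
    """
    n = len(genome_sequence)
    if n < window_size:
        raise ValueError(f"genome ({n} bp) shorter than window ({window_size} bp)")
    genome_freq = spectrum(genome_sequence, word_length).frequencies
    codes = _encode(genome_sequence)

    starts = list(range(0, n - window_size + 1, step))
    if word_length == "gc":
        valid = codes >= 0
        gc = np.isin(codes, (1, 2)) & valid
        cum_gc = np.concatenate([[0], np.cumsum(gc)])
        cum_valid = np.concatenate([[0], np.cumsum(valid)])
        rows = []
        for s in starts:
            tot = cum_valid[s + window_size] - cum_valid[s]
            g = (cum_gc[s + window_size] - cum_gc[s]) / tot
            freq = np.array([g, 1.0 - g])
            rows.append((s, s + window_size, float(np.linalg.norm(freq - genome_freq))))
        return pd.DataFrame(rows, columns=["start", "end", "distance"])

    w = int(word_length)
    n_words_per_window = window_size - w + 1
    # rolling counts: slide by `step`, removing/adding `step` words per move
    idx = np.zeros(n - w + 1, dtype=np.int64)
    valid = np.ones(n - w + 1, dtype=bool)
    for j in range(w):
        part = codes[j : j + n - w + 1]
        idx = idx * 4 + np.where(part >= 0, part, 0)
        valid &= part >= 0
    counts = np.bincount(idx[:n_words_per_window][valid[:n_words_per_window]],
                         minlength=4**w).astype(float)
    rows = []
    prev = 0
    for s in starts:
        if s > prev:
            drop = slice(prev, s)
            add = slice(prev + n_words_per_window, s + n_words_per_window)
            np.subtract.at(counts, idx[drop][valid[drop]], 1.0)
            np.add.at(counts, idx[add][valid[add]], 1.0)
            prev = s
        total = counts.sum()
        freq = counts / total if total else counts
        rows.append((s, s + window_size, float(np.linalg.norm(freq - genome_freq))))
    return pd.DataFrame(rows, columns=["start", "end", "distance"])


def atypical_threshold(distances: Sequence[float], delta: float) -> float:
    """Empirical upper (1-delta) quantile of the window distances; windows
    strictly above it are delta-atypical."""
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    return float(np.quantile(np.asarray(distances, dtype=float), 1.0 - delta))


def atypical_genes(
    calls: pd.DataFrame,
    gene_coordinates: Mapping[str, tuple[int, int]],
    delta: float = 0.05,
    rule: Literal["any", "majority"] = "any",
) -> tuple[set[str], set[str]]:
    """Gene-level atypicality calls from window distances.

    ``gene_coordinates`` maps gene id -> (start, end), 0-based half-open on
    the scanned sequence.  Under ``rule="any"`` a gene is delta-atypical if
    at least one overlapping window exceeds the genome-wide threshold;
    ``"majority"`` requires more than half.  Returns (atypical, uncovered)
    where uncovered genes overlap no window.
    """
    thr = atypical_threshold(calls["distance"].to_numpy(), delta)
    starts = calls["start"].to_numpy()
    ends = calls["end"].to_numpy()
    above = calls["distance"].to_numpy() > thr
    atypical: set[str] = set()
    uncovered: set[str] = set()
    for gene, (gs, ge) in gene_coordinates.items():
        overlap = (starts < ge) & (ends > gs)
        if not overlap.any():
            uncovered.add(gene)
            continue
        hits = above[overlap]
        if rule == "any":
            flagged = bool(hits.any())
        elif rule == "majority":
            flagged = hits.sum() > hits.size / 2
        else:
            raise ValueError("rule must be 'any' or 'majority'")
        if flagged:
            atypical.add(gene)
    return atypical, uncovered
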