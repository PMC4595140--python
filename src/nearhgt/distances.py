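"""Pairwise sequence distances over aligned orthologs.

Normalized Hamming distance with pairwise gap deletion, the Jukes-Cantor
correction d = -(3/4) ln(1 - (4/3) h), and its inverse
h = (3/4)(1 - e^(-(4/3) d)).  JC is the substitution model used throughout
the CRM test; the correct/convert pair isolates the model so another
time-reversible model could be slotted in.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio import SeqIO

from .errors import NoComparableSitesError, SaturatedDistanceError

__all__ = [
    "OrthologAlignment",
    "PairwiseDistance",
    "hamming_distance",
    "jc_correct",
    "jc_to_hamming",
    "gene_distance",
]

_VALID = set("ACGTN-")
_ACGT = np.frombuffer(b"ACGT", dtype="S1")


def _encode(seq: str) -> np.ndarray:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return np.frombuffer(s.encode(), dtype="S1")


@dataclass(frozen=True)
class OrthologAlignment:
    """One gene's aligned nucleotide sequences across organisms."""

    gene_id: str
    sequences: Mapping[str, str]  # organism_id -> aligned sequence

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if not self.sequences:
            raise ValueError("alignment has no sequences")
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in {self.gene_id}: {lengths}")
        if lengths == {0}:
            raise ValueError("alignment length is zero")
        for s in self.sequences.values():
            _encode(s)  # validates the alphabet

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def organisms(self) -> frozenset[str]:
        return frozenset(self.sequences)

    @classmethod
    def from_fasta(cls, path, gene_id: str | None = None) -> "OrthologAlignment":
        """Read a per-gene aligned FASTA; record ids are organism ids."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        if gene_id is None:
            import os

            gene_id = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(gene_id=gene_id, sequences={r.id: str(r.seq) for r in records})


def hamming_distance(a: str, b: str) -> tuple[float, int]:
    """Normalized Hamming distance and the number of sites it used.

    Only columns where both characters are unambiguous bases (A/C/G/T)
    count; gap or N columns are excluded pairwise.
    """
    ea, eb = _encode(a), _encode(b)
    if ea.size != eb.size:
        raise ValueError(f"length mismatch: {ea.size} vs {eb.size}")
    usable = np.isin(ea, _ACGT) & np.isin(eb, _ACGT)
    sites_used = int(usable.sum())
    if sites_used == 0:
        raise NoComparableSitesError("no comparable sites")
    mismatches = int((ea[usable] != eb[usable]).sum())
    return mismatches / sites_used, sites_used


def jc_correct(h: float) -> float:
    """Jukes-Cantor evolutionary distance from a Hamming fraction."""
    if h < 0:
        raise ValueError("hamming fraction must be >= 0")
    if h >= 0.75:
        raise SaturatedDistanceError(f"saturated distance: hamming {h} >= 0.75")
    return -0.75 * math.log1p(-(4.0 / 3.0) * h)


def jc_to_hamming(d: float) -> float:
    """Expected Hamming fraction at JC distance d: (3/4)(1 - e^(-4d/3))."""
    if d < 0:
        raise ValueError("JC distance must be >= 0")
    return 0.75 * -math.expm1(-(4.0 / 3.0) * d)


@dataclass(frozen=True)
class PairwiseDistance:
    """Distances between one gene's copies in two organisms.

    ``jc`` is +inf when the Hamming fraction is saturated (>= 3/4); the CRM
    driver skips such tests with a logged reason.
    """

    gene_id: str
    pair: tuple[str, str]
    hamming: float
    jc: float
    sites_used: int

    @property
    def saturated(self) -> bool:
        return not math.isfinite(self.jc)


def gene_distance(
    alignment: OrthologAlignment, x: str, y: str
) -> PairwiseDistance:
    """Hamming + JC distance bundle for one organism pair of one gene."""
    for org in (x, y):
        if org not in alignment.sequences:
            raise KeyError(f"organism {org!r} missing from alignment {alignment.gene_id!r}")
    h, n = hamming_distance(alignment.sequences[x], alignment.sequences[y])
    try:
        d = jc_correct(h)
    except SaturatedDistanceError:
        d = math.inf
    return PairwiseDistance(
        gene_id=alignment.gene_id, pair=(x, y), hamming=h, jc=d, sites_used=n
    )
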