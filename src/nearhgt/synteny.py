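"""Gene-order genomes, k-neighborhoods and the synteny index (SI).

The synteny index of a gene shared by two genomes counts how many genes the
two k-neighborhoods of that gene (up to k genes upstream plus k downstream,
wrapping around a circular chromosome) have in common.  A gene that was
recently inserted at a random position -- the signature of horizontal
transfer -- lands in a new neighborhood and its SI drops to 0 with high
probability, while vertically inherited genes of closely related strains
keep SI near the maximum 2k.  Genes in the low tail of the SI distribution
of a genome pair are the SI-based HGT candidates that the CRM stage then
validates.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

from .errors import GeneNotInGenomeError, NoSharedGenesError

__all__ = [
    "Genome",
    "SIProfile",
    "CandidateSet",
    "neighborhood",
    "synteny_index",
    "si_profile",
    "average_si",
    "si_cutoff",
    "si_candidates",
    "si_histogram",
    "infer_recipient",
]


@dataclass(frozen=True)
class Genome:
    """An ordered sequence of gene identifiers for one organism.

    Duplicate identifiers (paralogs) are canonicalized by keeping the first
    occurrence in genome order; the dropped copies are recorded in
    ``dropped_duplicates``.  Neighborhoods and SI operate on identifier sets,
    so a genome behaves as a (circular) permutation of distinct genes.
    """

    organism_id: str
    genes: tuple[str, ...]
    topology: str = "circular"  # or "linear"
    dropped_duplicates: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not self.genes:
            raise ValueError("gene list is empty")
        seen: dict[str, None] = {}
        dropped = []
        for g in self.genes:
            if g in seen:
                dropped.append(g)
            else:
                seen[g] = None
        if dropped:
            object.__setattr__(self, "genes", tuple(seen))
            object.__setattr__(self, "dropped_duplicates", tuple(dropped))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.positions

    @property
    def positions(self) -> Mapping[str, int]:
        # cached gene -> index map (frozen dataclass, so stash on __dict__)
        cache = self.__dict__.get("_positions")
        if cache is None:
            cache = {g: i for i, g in enumerate(self.genes)}
            self.__dict__["_positions"] = cache
        return cache

    @property
    def gene_set(self) -> frozenset[str]:
        cache = self.__dict__.get("_gene_set")
        if cache is None:
            cache = frozenset(self.genes)
            self.__dict__["_gene_set"] = cache
        return cache


def neighborhood(genome: Genome, gene: str, k: int) -> frozenset[str]:
    """Set of up to 2k genes at gene-order distance <= k from ``gene``.

    The focal gene itself is excluded.  Circular genomes wrap around (so on a
    genome of n genes the neighborhood holds min(2k, n-1) genes); linear
    genomes truncate at the ends.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pos = genome.positions.get(gene)
    if pos is None:
        raise GeneNotInGenomeError(f"gene {gene!r} not in genome {genome.organism_id!r}")
    n = len(genome)
    if genome.topology == "circular":
        idx = {(pos + off) % n for off in range(-k, k + 1)}
    else:
        idx = set(range(max(0, pos - k), min(n, pos + k + 1)))
    idx.discard(pos)
    return frozenset(genome.genes[i] for i in idx)


def synteny_index(gene: str, g1: Genome, g2: Genome, k: int) -> int:
    """SI of ``gene`` between two genomes: |N_k(G1,gene) & N_k(G2,gene)|.

    Defined as 0 for a gene absent from either genome.  Symmetric in the two
    genomes and bounded by [0, 2k].
    """
    if gene not in g1 or gene not in g2:
        return 0
    return len(neighborhood(g1, gene, k) & neighborhood(g2, gene, k))


@dataclass(frozen=True)
class SIProfile:
    """Per-gene SI values for one genome pair."""

    genome_pair: tuple[str, str]
    k: int
    si: Mapping[str, int]  # every gene in the union of both genomes
    core_genes: frozenset[str]  # genes present in both genomes

    def involves(self, organism_id: str) -> bool:
        return organism_id in self.genome_pair


def si_profile(g1: Genome, g2: Genome, k: int) -> SIProfile:
    """Compute SI for every gene in the union of the two gene sets."""
    core = g1.gene_set & g2.gene_set
    si = {g: 0 for g in g1.gene_set | g2.gene_set}
    for g in core:
        si[g] = synteny_index(g, g1, g2, k)
    return SIProfile(
        genome_pair=(g1.organism_id, g2.organism_id),
        k=k,
        si=si,
        core_genes=frozenset(core),
    )


def average_si(g1: Genome, g2: Genome, k: int) -> float:
    """Average SI: mean of SI/2k over the union of the two gene sets.

    Equals 1 for identical genomes and 0 for disjoint gene sets; a
    genome-level similarity in [0, 1].
    """
    prof = si_profile(g1, g2, k)
    union = prof.si
    return sum(union.values()) / (2 * k * len(union))


def si_cutoff(profile: SIProfile, delta_si: float) -> int:
    """SI cutoff C(delta): largest observed SI value c such that the fraction
    of core genes with SI <= c stays below ``delta_si``.

    Returns -1 when even the lowest observed SI value already captures a
    fraction >= delta_si (no gene qualifies).
    """
    if not 0 < delta_si < 1:
        raise ValueError("delta_si must lie in (0, 1)")
    if not profile.core_genes:
        raise NoSharedGenesError(
            "no shared genes between %s and %s" % profile.genome_pair
        )
    n_core = len(profile.core_genes)
    counts = Counter(profile.si[g] for g in profile.core_genes)
    cutoff = -1
    running = 0
    for value in sorted(counts):
        running += counts[value]
        if running / n_core < delta_si:
            cutoff = value
        else:
            break
    return cutoff


@dataclass(frozen=True)
class CandidateSet:
    """SI-based HGT candidates for one genome pair."""

    genome_pair: tuple[str, str]
    threshold_fraction: float
    cutoff: int
    candidates: tuple[str, ...]  # sorted by (si, gene_id)


def si_candidates(
    profile: SIProfile, delta_si: float, strict: bool = False
) -> CandidateSet:
    """Core genes whose SI falls at or below the cutoff C(delta_si).

    ``strict=True`` uses SI < C instead of SI <= C (an alternative reading of
    the selection rule; the default follows the cutoff's own definition).
    """
    cutoff = si_cutoff(profile, delta_si)
    if strict:
        picked = [g for g in profile.core_genes if profile.si[g] < cutoff]
    else:
        picked = [g for g in profile.core_genes if profile.si[g] <= cutoff]
    picked.sort(key=lambda g: (profile.si[g], g))
    return CandidateSet(
        genome_pair=profile.genome_pair,
        threshold_fraction=delta_si,
        cutoff=cutoff,
        candidates=tuple(picked),
    )


def si_histogram(profile: SIProfile, over: str = "union") -> dict[int, int]:
    """Counts of genes per SI value 0..2k.

    ``over="union"`` tallies every gene in the union of the two genomes
    (genes private to one genome sit at SI=0); ``over="core"`` restricts to
    shared genes.
    """
    if over == "union":
        genes: Iterable[str] = profile.si
    elif over == "core":
        genes = profile.core_genes
    else:
        raise ValueError("over must be 'union' or 'core'")
    hist = {v: 0 for v in range(2 * profile.k + 1)}
    for g in genes:
        hist[profile.si[g]] += 1
    return hist


def infer_recipient(
    candidate_gene: str,
    profiles: Sequence[SIProfile],
    delta_si: float,
) -> Optional[str]:
    """Guess the recipient organism of a transferred gene from pairwise SI.

    A transferred gene shows low SI between the recipient and *every* other
    organism carrying it, but high SI among the remaining organisms.  If the
    gene is an SI candidate in >= 2 pairs whose intersection is a single
    organism, and is not a candidate in any pair avoiding that organism,
    that organism is returned; otherwise ``None`` (undetermined).
    """
    low_pairs: list[tuple[str, str]] = []
    for prof in profiles:
        if candidate_gene not in prof.core_genes:
            continue
        try:
            cand = si_candidates(prof, delta_si)
        except NoSharedGenesError:
            continue
        if candidate_gene in cand.candidates:
            low_pairs.append(prof.genome_pair)
    if len(low_pairs) < 2:
        return None
    common = set(low_pairs[0])
    for pair in low_pairs[1:]:
        common &= set(pair)
    if len(common) != 1:
        return None
    recipient = common.pop()
    # the gene must look native (not a candidate) among the other organisms
    for prof in profiles:
        if prof.involves(recipient) or candidate_gene not in prof.core_genes:
            continue
        try:
            cand = si_candidates(prof, delta_si)
        except NoSharedGenesError:
            continue
        if candidate_gene in cand.candidates:
            return None
    return recipient


def all_pairwise_profiles(genomes: Sequence[Genome], k: int) -> list[SIProfile]:
    """SI profiles for every unordered pair of genomes."""
    return [si_profile(a, b, k) for a, b in combinations(genomes, 2)]
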