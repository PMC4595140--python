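"""Constant-relative-mutability (CRM) validation and the Near HGT driver.

The CRM property (a consequence of the universal-pacemaker view of genome
evolution) says that any two genes keep an approximately constant ratio
between their evolutionary rates across all lineages.  For a candidate gene
g_h flagged by the synteny screen between strains s1, s2, a witness gene g_w
and a reference organism pair r1, r2 give the expected rate ratio

    rho = d_gh(r1,r2) / d_gw(r1,r2)          (divergence time cancels)

and hence the expected strain distance d' = rho * d_gw(s1,s2).  The observed
d_gh(s1,s2) is tested against d' with a two-cell chi-square on the Hamming
scale, 1 degree of freedom, over the gene length.  A recent transfer between
the strains shortens the observed distance; a transfer from outside the
analyzed set lengthens it -- both directions are reported, labeled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

from scipy.stats import chi2 as _chi2_dist

from .distances import OrthologAlignment, gene_distance, jc_to_hamming
from .errors import CRMTestSkipped, NoComparableSitesError, NoSharedGenesError
from .synteny import (
    Genome,
    SIProfile,
    all_pairwise_profiles,
    infer_recipient,
    si_candidates,
)

__all__ = [
    "CRMTestRecord",
    "GeneSummary",
    "HGTReport",
    "expected_ratio",
    "expected_distance",
    "chi_square_stat",
    "chi_square_two_cell",
    "chi_square_pvalue",
    "crm_from_distances",
    "crm_single_test",
    "near_hgt",
]

DEFAULT_DELTA_SI = 0.05
DEFAULT_DELTA_RHO = 0.01
DEFAULT_K = 10


def expected_ratio(d_h_ref: float, d_w_ref: float) -> float:
    """Expected rate ratio rho = d_gh(r1,r2)/d_gw(r1,r2).

    Both distances are JC distances between the two reference organisms; the
    shared divergence time cancels.  A zero or non-finite witness distance
    carries no rate information, so the test is skipped.
    """
    if not (math.isfinite(d_h_ref) and math.isfinite(d_w_ref)) or d_w_ref <= 0 or d_h_ref <= 0:
        raise CRMTestSkipped(
            f"uninformative witness: reference distances {d_h_ref}, {d_w_ref}"
        )
    return d_h_ref / d_w_ref


def expected_distance(rho: float, d_w_strain: float) -> float:
    """Expected strain-pair JC distance of the candidate: d' = rho * d_gw(s1,s2)."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    if d_w_strain < 0:
        raise ValueError("witness strain distance must be >= 0")
    return rho * d_w_strain


def chi_square_two_cell(length: int, h_obs: float, h_exp: float) -> float:
    """Sum of (O-E)^2/E over the mismatch and match cells of the gene."""
    o1, e1 = length * h_obs, length * h_exp
    o2, e2 = length * (1 - h_obs), length * (1 - h_exp)
    return (o1 - e1) ** 2 / e1 + (o2 - e2) ** 2 / e2


def chi_square_stat(length: int, h_obs: float, h_exp: float) -> float:
    """Goodness-of-fit statistic l (h_obs - h_exp)^2 / (h_exp (1 - h_exp)).

    ``h_obs`` and ``h_exp`` are Hamming-scale distances (convert JC distances
    first).  The closed form and the explicit two-cell sum are algebraically
    identical; both are evaluated and cross-checked.
    """
    if length < 1:
        raise ValueError("gene length must be >= 1")
    if not 0 <= h_obs < 1:
        raise ValueError("observed hamming fraction must lie in [0, 1)")
    if not 0 < h_exp < 1:
        raise ValueError(f"degenerate expectation: h_exp={h_exp}")
    stat = length * (h_obs - h_exp) ** 2 / (h_exp * (1 - h_exp))
    cells = chi_square_two_cell(length, h_obs, h_exp)
    if not math.isclose(stat, cells, rel_tol=1e-9, abs_tol=1e-12):
        raise AssertionError(f"chi-square forms disagree: {stat} vs {cells}")
    return stat


def chi_square_pvalue(stat: float) -> float:
    """Upper-tail probability of chi-square with 1 degree of freedom."""
    if stat < 0:
        raise ValueError("chi-square statistic must be >= 0")
    return float(_chi2_dist.sf(stat, df=1))


@dataclass(frozen=True)
class CRMTestRecord:
    """One (candidate gene, strain pair, witness, reference pair) CRM test."""

    gene: str
    strain_pair: tuple[str, str]
    witness: str
    reference_pair: tuple[str, str]
    rho: float
    d_obs: float  # observed JC distance d_gh(s1,s2)
    d_exp: float  # expected JC distance d'
    h_obs: float
    h_exp: float
    length: int
    chi2: float
    p: float
    direction: str  # "shorter" | "longer"
    p_corrected: float = float("nan")  # filled by the driver (Bonferroni)

    def corrected(self, n_tests: int) -> "CRMTestRecord":
        from dataclasses import replace

        return replace(self, p_corrected=min(1.0, self.p * n_tests))


def crm_from_distances(
    d_h_strain: float,
    d_w_strain: float,
    d_h_ref: float,
    d_w_ref: float,
    length: int,
    gene: str = "g_h",
    witness: str = "g_w",
    strain_pair: tuple[str, str] = ("s1", "s2"),
    reference_pair: tuple[str, str] = ("r1", "r2"),
    scale: str = "hamming",
) -> CRMTestRecord:
    """Assemble the full CRM test from four JC distances and a gene length.

    This is the computational core: rho from the reference pair, expected
    strain distance, then the 1-DoF chi-square on observed vs expected.

    ``scale`` selects what is fed to the chi-square.  ``"hamming"`` (the
    worked-example procedure, default for real-data screening) converts the
    observed and expected JC distances to Hamming fractions first, so the
    two cells are genuine site counts.  ``"jc"`` plugs the JC distances in
    directly, the closed form the method's pseudocode states; it treats the
    corrected distance as a per-site "probability", which inflates both
    signal and noise at larger distances and is the variant the simulation
    study exercises.
    """
    if not math.isfinite(d_h_strain):
        raise CRMTestSkipped("saturated observed strain distance")
    if not math.isfinite(d_w_strain):
        raise CRMTestSkipped("saturated witness strain distance")
    rho = expected_ratio(d_h_ref, d_w_ref)
    d_exp = expected_distance(rho, d_w_strain)
    h_obs = jc_to_hamming(d_h_strain)
    h_exp = jc_to_hamming(d_exp)
    if h_exp >= 0.75 - 1e-12 or h_exp <= 0.0:
        raise CRMTestSkipped(f"expected distance degenerate or saturated: d'={d_exp}")
    if scale == "hamming":
        stat = chi_square_stat(length, h_obs, h_exp)
    elif scale == "jc":
        if d_exp >= 1.0 or d_h_strain >= 1.0:
            raise CRMTestSkipped(
                f"JC-scale statistic undefined: d={d_h_strain}, d'={d_exp}"
            )
        stat = chi_square_stat(length, d_h_strain, d_exp)
    else:
        raise ValueError("scale must be 'hamming' or 'jc'")
    return CRMTestRecord(
        gene=gene,
        strain_pair=strain_pair,
        witness=witness,
        reference_pair=reference_pair,
        rho=rho,
        d_obs=d_h_strain,
        d_exp=d_exp,
        h_obs=h_obs,
        h_exp=h_exp,
        length=length,
        chi2=stat,
        p=chi_square_pvalue(stat),
        direction="shorter" if d_h_strain <= d_exp else "longer",
    )


def crm_single_test(
    g_h: OrthologAlignment,
    g_w: OrthologAlignment,
    s1: str,
    s2: str,
    r1: str,
    r2: str,
) -> CRMTestRecord:
    """Run one CRM test from per-gene alignments.

    Distances are estimated from the alignments; the gene length is the
    candidate gene's alignment length.  Saturated or degenerate distances
    raise :class:`CRMTestSkipped` with the reason.
    """
    for aln, orgs in ((g_h, (s1, s2, r1, r2)), (g_w, (s1, s2, r1, r2))):
        missing = [o for o in orgs if o not in aln.sequences]
        if missing:
            raise CRMTestSkipped(f"{aln.gene_id}: missing organisms {missing}")
    try:
        d_h_s = gene_distance(g_h, s1, s2)
        d_w_s = gene_distance(g_w, s1, s2)
        d_h_r = gene_distance(g_h, r1, r2)
        d_w_r = gene_distance(g_w, r1, r2)
    except NoComparableSitesError as exc:
        raise CRMTestSkipped(str(exc)) from exc
    for pd in (d_h_r, d_w_r):
        if pd.saturated:
            raise CRMTestSkipped(
                f"saturated reference distance for {pd.gene_id} ({pd.pair})"
            )
    return crm_from_distances(
        d_h_s.jc,
        d_w_s.jc,
        d_h_r.jc,
        d_w_r.jc,
        length=g_h.length,
        gene=g_h.gene_id,
        witness=g_w.gene_id,
        strain_pair=(s1, s2),
        reference_pair=(r1, r2),
    )


@dataclass(frozen=True)
class GeneSummary:
    """Per (strain pair, gene) outcome of the driver."""

    strain_pair: tuple[str, str]
    gene: str
    si: int
    n_tests: int
    n_significant_witnesses: int  # witnesses with >=1 corrected p <= delta_rho
    best_p_corrected: float
    direction: str
    putative_hgt: bool
    recipient: Optional[str]


@dataclass
class HGTReport:
    """Full output of the Near HGT driver."""

    k: int
    delta_si: float
    delta_rho: float
    summaries: list[GeneSummary] = field(default_factory=list)
    records: list[CRMTestRecord] = field(default_factory=list)
    skips: list[tuple[str, str]] = field(default_factory=list)  # (context, reason)
    profiles: list[SIProfile] = field(default_factory=list)
    pairs_without_shared_genes: list[tuple[str, str]] = field(default_factory=list)

    @property
    def putative_genes(self) -> set[str]:
        return {s.gene for s in self.summaries if s.putative_hgt}


def near_hgt(
    strains: Sequence[Genome],
    references: Sequence[str],
    alignments: Mapping[str, OrthologAlignment],
    delta_si: float = DEFAULT_DELTA_SI,
    delta_rho: float = DEFAULT_DELTA_RHO,
    k: int = DEFAULT_K,
    strict_cutoff: bool = False,
) -> HGTReport:
    """The complete two-stage screen over a set of strains.

    For every unordered strain pair: compute the SI profile, select SI
    candidates, then for each candidate iterate over reference pairs and
    witness genes, running the CRM chi-square.  Raw p-values are Bonferroni
    corrected per (gene, strain pair) by the number of completed tests; a
    gene is putative HGT if any corrected p <= ``delta_rho``.  Witness genes
    that are themselves SI candidates for the pair are ineligible.
    """
    report = HGTReport(k=k, delta_si=delta_si, delta_rho=delta_rho)
    profiles = all_pairwise_profiles(list(strains), k)
    report.profiles = profiles
    prof_by_pair = {frozenset(p.genome_pair): p for p in profiles}

    for s1g, s2g in combinations(strains, 2):
        s1, s2 = s1g.organism_id, s2g.organism_id
        prof = prof_by_pair[frozenset((s1, s2))]
        try:
            cand = si_candidates(prof, delta_si, strict=strict_cutoff)
        except NoSharedGenesError:
            report.pairs_without_shared_genes.append((s1, s2))
            continue
        candidate_set = set(cand.candidates)
        for gene in cand.candidates:
            g_h = alignments.get(gene)
            if g_h is None or not {s1, s2} <= g_h.organisms:
                report.skips.append(
                    ((f"{s1}|{s2}|{gene}"), "candidate alignment missing for strains")
                )
                continue
            records: list[CRMTestRecord] = []
            for r1, r2 in combinations(references, 2):
                if not {r1, r2} <= g_h.organisms:
                    report.skips.append(
                        (f"{s1}|{s2}|{gene}|{r1},{r2}", "candidate absent from reference pair")
                    )
                    continue
                for w, g_w in alignments.items():
                    if w == gene or w in candidate_set:
                        continue
                    if not {s1, s2, r1, r2} <= g_w.organisms:
                        continue
                    try:
                        rec = crm_single_test(g_h, g_w, s1, s2, r1, r2)
                    except CRMTestSkipped as exc:
                        report.skips.append(
                            (f"{s1}|{s2}|{gene}|{r1},{r2}|{w}", exc.reason)
                        )
                        continue
                    records.append(rec)
            n_tests = len(records)
            records = [r.corrected(n_tests) for r in records]
            report.records.extend(records)
            sig = [r for r in records if r.p_corrected <= delta_rho]
            sig_witnesses = {r.witness for r in sig}
            best = min((r.p_corrected for r in records), default=math.nan)
            best_rec = min(records, key=lambda r: r.p_corrected, default=None)
            recipient = infer_recipient(gene, profiles, delta_si) if sig else None
            report.summaries.append(
                GeneSummary(
                    strain_pair=(s1, s2),
                    gene=gene,
                    si=prof.si[gene],
                    n_tests=n_tests,
                    n_significant_witnesses=len(sig_witnesses),
                    best_p_corrected=best,
                    direction=best_rec.direction if best_rec else "",
                    putative_hgt=bool(sig),
                    recipient=recipient,
                )
            )
    return report
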