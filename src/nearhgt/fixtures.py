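"""Synthetic strain fixtures with known, implanted transfers.

The generator emulates the setting the detector targets: a handful of
closely related strains (pairwise distances of a few percent, conserved gene
order) plus two distant reference organisms (pairwise distance ~0.5, the
scale of the worked example's reference pair).  Every gene gets its own
rate multiplier that is constant across lineages, so the
constant-relative-mutability assumption holds by construction.  A transfer
implants two signals at once: the recipient's copy of the gene is evolved on
a grafted gene tree (coalescing with the donor at a recent fractional
height), and the gene is relocated in the recipient's gene order.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import dendropy
import numpy as np

from .distances import OrthologAlignment
from .simulate import evolve_jc, graft_hgt, tree_height, yule_tree
from .synteny import Genome

__all__ = ["Fixture", "Transfer", "make_fixture"]


@dataclass(frozen=True)
class Transfer:
    gene: str
    donor: str
    recipient: str
    height: float  # fraction of the recipient-to-LCA path


@dataclass
class Fixture:
    """Synthetic genomes + alignments + ground truth."""

    strains: list[Genome]
    references: list[str]
    alignments: dict[str, OrthologAlignment]
    transfers: list[Transfer]
    species_tree_newick: str
    seed: int

    def write(self, out_dir) -> None:
        """Materialize the fixture as the pipeline's input files."""
        from .io import write_gene_order

        out = Path(out_dir)
        (out / "gene_orders").mkdir(parents=True, exist_ok=True)
        (out / "alignments").mkdir(exist_ok=True)
        for genome in self.strains:
            write_gene_order(genome, out / "gene_orders" / f"{genome.organism_id}.tsv")
        for gene, aln in sorted(self.alignments.items()):
            with open(out / "alignments" / f"{gene}.fa", "w") as fh:
                for org in sorted(aln.sequences):
                    fh.write(f">{org}\n{aln.sequences[org]}\n")
        with open(out / "roles.tsv", "w") as fh:
            for genome in self.strains:
                fh.write(f"{genome.organism_id}\tstrain\n")
            for ref in self.references:
                fh.write(f"{ref}\treference\n")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("gene\tdonor\trecipient\theight\n")
            for t in self.transfers:
                fh.write(f"{t.gene}\t{t.donor}\t{t.recipient}\t{t.height}\n")
        (out / "species_tree.nwk").write_text(self.species_tree_newick)


def _scale_edges(tree: dendropy.Tree, factor: float) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor


def _species_tree(
    n_strains: int,
    strain_height: float,
    ref_split_age: float,
    root_age: float,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Ultrametric tree: a shallow Yule clade of strains and a deep
    reference cherry, joined at the root."""
    sub = yule_tree(n_strains, birth_rate=1.0, rng=rng)
    _scale_edges(sub, strain_height / tree_height(sub))
    # relabel tips t1..tn -> S1..Sn
    for taxon in sub.taxon_namespace:
        taxon.label = "S" + taxon.label[1:]
    sub_newick = sub.as_string(schema="newick", suppress_rooting=True).strip().rstrip(";")
    ref_pendant = ref_split_age
    newick = (
        f"({sub_newick}:{root_age - strain_height},"
        f"(R1:{ref_pendant},R2:{ref_pendant}):{root_age - ref_split_age});"
    )
    return dendropy.Tree.get(data=newick, schema="newick")


def make_fixture(
    n_strains: int = 4,
    n_genes: int = 60,
    n_transfers: int = 1,
    divergence: float = 0.01,
    gene_length: int = 1500,
    transfer_height: float = 0.05,
    rate_sigma: float = 0.3,
    min_displacement: int | None = None,
    ref_split_age: float = 0.25,
    root_age: float = 0.5,
    seed: int = 0,
) -> Fixture:
    """Generate a deterministic fixture with ``n_transfers`` implanted HGTs.

    ``divergence`` is the height of the strain clade (pairwise strain
    distances up to 2x this, matching the percent-scale distances of real
    congeneric strains); references sit at pairwise distance
    2*``ref_split_age``.  ``min_displacement`` is the minimum circular
    gene-order distance between a transferred gene's old and new slots; the
    default (21 = 2k+1 at the default neighborhood radius) mimics the
    large-genome regime, where a uniformly random insertion lands outside
    the old neighborhood with high probability.  Set 0 for fully uniform
    placement.
    """
    if n_strains < 2:
        raise ValueError("need at least two strains")
    if n_transfers < 0 or n_transfers > n_genes:
        raise ValueError("invalid n_transfers")
    if min_displacement is None:
        min_displacement = min(21, max(1, n_genes // 2 - 2))
    if min_displacement >= n_genes // 2 and n_transfers > 0:
        raise ValueError("min_displacement too large for this many genes")
    rng = np.random.default_rng(seed)
    tree = _species_tree(n_strains, divergence, ref_split_age, root_age, rng)
    strain_ids = [f"S{i+1}" for i in range(n_strains)]
    references = ["R1", "R2"]
    gene_ids = [f"g{i+1:04d}" for i in range(n_genes)]

    # choose transfers: distinct genes, random donor/recipient strain pairs
    transferred = rng.choice(n_genes, size=n_transfers, replace=False)
    transfers = []
    for gi in transferred:
        donor, recipient = rng.choice(n_strains, size=2, replace=False)
        transfers.append(
            Transfer(
                gene=gene_ids[int(gi)],
                donor=strain_ids[int(donor)],
                recipient=strain_ids[int(recipient)],
                height=transfer_height,
            )
        )
    by_gene = {t.gene: t for t in transfers}

    # evolve every gene on the (per-gene rate-scaled) species tree;
    # transferred genes evolve on the grafted gene tree instead
    rates = np.exp(rng.normal(0.0, rate_sigma, size=n_genes))
    alignments = {}
    for gene, rate in zip(gene_ids, rates):
        gtree = tree.clone(depth=1)
        _scale_edges(gtree, float(rate))
        t = by_gene.get(gene)
        if t is not None:
            gtree = graft_hgt(gtree, t.recipient, t.donor, t.height)
        seqs = evolve_jc(gtree, gene_length, rng)
        alignments[gene] = OrthologAlignment(gene_id=gene, sequences=seqs)

    # gene orders: one shared circular order; relocate transferred genes
    # in their recipients
    base_order = list(gene_ids)
    orders = {s: list(base_order) for s in strain_ids}
    for t in transfers:
        order = orders[t.recipient]
        old = order.index(t.gene)
        order.pop(old)
        n = len(order)
        slots = []
        for slot in range(n + 1):
            # circular distance between old position and insertion slot
            d = min(abs(slot - old), n + 1 - abs(slot - old))
            if d > min_displacement:
                slots.append(slot)
        new = int(rng.choice(slots if slots else list(range(n + 1))))
        order.insert(new, t.gene)
    strains = [
        Genome(organism_id=s, genes=tuple(orders[s]), topology="circular")
        for s in strain_ids
    ]
    return Fixture(
        strains=strains,
        references=references,
        alignments=alignments,
        transfers=transfers,
        species_tree_newick=tree.as_string(schema="newick"),
        seed=seed,
    )
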