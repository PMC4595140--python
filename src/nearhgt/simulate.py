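"""Simulation study: Yule species trees, HGT grafting, JC sequence evolution.

The power of the CRM test is probed by evolving a witness gene on an
ultrametric Yule species tree and a "transferred" gene on the same tree with
one surgery: the recipient tip s1 is re-attached on the path of s2 at age
tau = height * t(s1, LCA(s1,s2)), so the two strains coalesce at tau instead
of at their LCA (height 0 = transfer at the very leaves, height 1 = at the
LCA, i.e. no detectable event).  Four Jukes-Cantor distances are estimated
from the simulated sequences -- candidate and witness genes between the
strain pair and between a reference pair -- and fed to the CRM chi-square.

As in the published study, each sweep draws one species tree and one
(s1,s2)/(r1,r2) choice and holds them fixed; replicates vary only the
stochastic sequence evolution.  The chi-square is the pseudocode's JC-scale
form, which is defined only for distances below 1 substitution/site;
the default birth rate 4.0 keeps the 20-taxon tree's deepest tip pairs
just under that bound, with typical pair distances 0.3-0.9 -- the scale of
the worked example's reference organisms.  By default the sweep drivers pick
the deepest disjoint tip pairs within the validity bound, exercising the
regime the power study describes.

The power sweeps vary the length of the transferred fragment only; the
witness is a full-length calibration gene (default 1472 bp, the length of
the worked example's witness) whose distances are estimated with
correspondingly less noise.  Set ``witness_length=None`` to give both genes
the same length, as the false-positive studies do.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .crm import crm_from_distances
from .distances import jc_correct
from .errors import CRMTestSkipped, SaturatedDistanceError

__all__ = [
    "SimScenario",
    "ReplicateResult",
    "yule_tree",
    "yule_expected_height",
    "graft_hgt",
    "evolve_jc",
    "quartet_tree",
    "run_replicate",
    "sweep_height",
    "sweep_length",
    "sweep_fp_length",
    "sweep_fp_distance",
]

DEFAULT_BIRTH_RATE = 4.0
MAX_PAIR_DISTANCE = 0.95  # validity margin for the JC-scale statistic
DEFAULT_WITNESS_LENGTH = 1472  # full-length calibration witness (worked-example gene)
_MAX_REDRAWS = 500


# ---------------------------------------------------------------------------
# tree generation and manipulation
# ---------------------------------------------------------------------------

def yule_tree(
    n_taxa: int,
    birth_rate: float = DEFAULT_BIRTH_RATE,
    rng: np.random.Generator | int | None = None,
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree over ``n_taxa`` tips.

    Waiting times between successive speciations are exponential with rate
    (number of extant lineages) x ``birth_rate``; the lineage that splits is
    uniform among those extant.  All tips end at the present, so the tree is
    ultrametric with expected root height sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(rng)

    taxa = dendropy.TaxonNamespace([f"t{i+1}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    # active lineages: (node to grow from, depth at which its edge started)
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0), (root, 0.0)]
    depth = 0.0
    while len(active) < n_taxa:
        k = len(active)
        depth += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        parent, born = active.pop(idx)
        node = parent.new_child(edge_length=depth - born)
        active.append((node, depth))
        active.append((node, depth))
    depth += rng.exponential(1.0 / (n_taxa * birth_rate))
    for i, (parent, born) in enumerate(active):
        leaf = parent.new_child(edge_length=depth - born)
        leaf.taxon = taxa.get_taxon(f"t{i+1}")
    return tree


def yule_expected_height(n_taxa: int, birth_rate: float = DEFAULT_BIRTH_RATE) -> float:
    """Analytic expected root height of the Yule tree: sum_{k=2..n} 1/(k*lambda)."""
    return sum(1.0 / (k * birth_rate) for k in range(2, n_taxa + 1))


def _node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Time-before-present of every node (requires an ultrametric tree)."""
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    tip_depths = [depths[l] for l in tree.leaf_node_iter()]
    height = max(tip_depths)
    if height - min(tip_depths) > 1e-9 * max(height, 1.0):
        raise ValueError("tree is not ultrametric")
    return {n: height - d for n, d in depths.items()}


def tree_height(tree: dendropy.Tree) -> float:
    return _node_ages(tree)[tree.seed_node]


def tip_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Patristic (path-length) distance between two tip labels."""
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    return pdm.patristic_distance(tax[a], tax[b])


def _leaf_by_label(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == label:
            return leaf
    raise KeyError(f"tip {label!r} not in tree")


def graft_hgt(
    tree: dendropy.Tree, s1: str, s2: str, height: float
) -> dendropy.Tree:
    """Gene tree of a transferred gene: s1 re-coalesces with s2 at a
    fraction ``height`` of the s1-to-LCA path.

    The input species tree must be ultrametric and is not modified; on the
    returned tree d(s1, s2) = 2 * height * t(s1, LCA) while every tip-pair
    distance involving neither s1 nor s2 is untouched, and ultrametricity is
    preserved.
    """
    if not 0.0 <= height <= 1.0:
        raise ValueError("height must lie in [0, 1]")
    if s1 == s2:
        raise ValueError("s1 and s2 must differ")
    gene = tree.clone(depth=1)
    ages = _node_ages(gene)  # validates ultrametricity
    leaf1 = _leaf_by_label(gene, s1)
    leaf2 = _leaf_by_label(gene, s2)
    ancestors1 = set()
    node = leaf1
    while node is not None:
        ancestors1.add(node)
        node = node.parent_node
    mrca = leaf2
    while mrca not in ancestors1:
        mrca = mrca.parent_node
    tau = height * ages[mrca]

    # prune s1, suppressing the resulting unifurcation
    parent = leaf1.parent_node
    parent.remove_child(leaf1)
    if parent.num_child_nodes() == 1:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        if grand is None:
            only.parent_node = None
            only.edge.length = None
            gene.seed_node = only
        else:
            extra = parent.edge.length or 0.0
            grand.remove_child(parent)
            grand.add_child(only)
            only.edge.length = (only.edge.length or 0.0) + extra

    # find the edge on the s2 -> root path spanning age tau and attach there
    node = leaf2
    while node.parent_node is not None and ages[node.parent_node] < tau:
        node = node.parent_node
    attach_parent = node.parent_node
    junction = dendropy.Node()
    if attach_parent is None:  # tau reaches the (new) root
        junction.add_child(node)
        node.edge.length = tau - ages[node]
        gene.seed_node = junction
    else:
        attach_parent.remove_child(node)
        attach_parent.add_child(junction)
        junction.edge.length = ages[attach_parent] - tau
        junction.add_child(node)
        node.edge.length = tau - ages[node]
    leaf1.edge.length = tau
    junction.add_child(leaf1)
    return gene


def quartet_tree(pair_distance: float, root_age: float | None = None) -> dendropy.Tree:
    """Symmetric ultrametric quartet ((s1,s2),(r1,r2)) with both within-pair
    distances equal to ``pair_distance``.

    Used for the false-positive studies, where "organism distance" is the
    path length between the two tested organisms; only the within-pair
    distances enter the chi-square, so the root depth is immaterial (default
    age max(1, pair_distance)).
    """
    if pair_distance <= 0:
        raise ValueError("pair_distance must be > 0")
    half = pair_distance / 2.0
    if root_age is None:
        root_age = max(1.0, pair_distance)
    if root_age < half:
        raise ValueError("root_age must be >= pair_distance / 2")
    taxa = dendropy.TaxonNamespace(["s1", "s2", "r1", "r2"])
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    for pair in (("s1", "s2"), ("r1", "r2")):
        anc = root.new_child(edge_length=root_age - half)
        for label in pair:
            leaf = anc.new_child(edge_length=half)
            leaf.taxon = taxa.get_taxon(label)
    return tree


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")


def evolve_jc(
    tree: dendropy.Tree,
    length: int,
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """Evolve one gene of ``length`` sites down the tree under Jukes-Cantor.

    The root sequence is uniform over {A,C,G,T}^length; along a branch of
    length d each site substitutes with probability (3/4)(1 - e^(-4d/3)),
    uniformly to one of the three other bases (the exact JC transition).
    Returns tip label -> sequence.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(rng)
    states: dict[dendropy.Node, np.ndarray] = {}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = rng.integers(0, 4, size=length, dtype=np.int8)
        else:
            bl = node.edge.length or 0.0
            p_change = 0.75 * -math.expm1(-(4.0 / 3.0) * bl)
            seq = states[node.parent_node].copy()
            mask = rng.random(length) < p_change
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_mut, dtype=np.int8)) % 4
        if node.is_leaf():
            out[node.taxon.label] = _ALPHABET[seq].tobytes().decode()
        else:
            states[node] = seq
    return out


def _seq_jc(a: str, b: str) -> float:
    """JC distance between two gap-free simulated sequences (may raise
    SaturatedDistanceError)."""
    ea = np.frombuffer(a.encode(), dtype="S1")
    eb = np.frombuffer(b.encode(), dtype="S1")
    return jc_correct(float((ea != eb).mean()))


# ---------------------------------------------------------------------------
# replicates and sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimScenario:
    """One point of a power/FP sweep."""

    n_taxa: int = 20
    hgt_height: float = 0.5
    gene_length: int = 70
    n_replicates: int = 20
    delta_rho: float = 0.01
    birth_rate: float = DEFAULT_BIRTH_RATE
    s_pair: Optional[tuple[str, str]] = None
    r_pair: Optional[tuple[str, str]] = None
    graft: bool = True  # False: null model, both genes on the species tree
    test_scale: str = "jc"  # chi-square scale; the pseudocode (JC) form
    witness_length: Optional[int] = None  # None: same length as the gene

    def __post_init__(self):
        if not 0.0 <= self.hgt_height <= 1.0:
            raise ValueError("hgt_height must lie in [0, 1]")
        if self.s_pair and self.r_pair and set(self.s_pair) & set(self.r_pair):
            raise ValueError("strain and reference pairs must be disjoint")


@dataclass(frozen=True)
class ReplicateResult:
    reject: bool
    d_gw_r: float
    d_gh_r: float
    d_gw_s: float
    d_gh_s: float
    redraws: int


def _choose_pairs(
    scenario: SimScenario, labels: Sequence[str], rng: np.random.Generator
) -> tuple[tuple[str, str], tuple[str, str]]:
    if scenario.s_pair is not None and scenario.r_pair is not None:
        return scenario.s_pair, scenario.r_pair
    picked = rng.choice(np.asarray(labels, dtype=object), size=4, replace=False)
    s_pair = scenario.s_pair or (picked[0], picked[1])
    r_pair = scenario.r_pair or tuple(l for l in picked if l not in s_pair)[:2]
    return tuple(s_pair), tuple(r_pair)


def choose_pairs_deep(
    tree: dendropy.Tree, max_distance: float = MAX_PAIR_DISTANCE
) -> tuple[tuple[str, str], tuple[str, str]]:
    """Deepest disjoint tip pairs whose distances stay below the JC-scale
    validity bound: the strain pair first, then the deepest disjoint
    reference pair."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    pairs = []
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            d = pdm.patristic_distance(a, b)
            if d < max_distance:
                pairs.append((d, a.label, b.label))
    pairs.sort(reverse=True)
    if not pairs:
        raise ValueError("no tip pair below the distance bound")
    _, s1, s2 = pairs[0]
    for d, a, b in pairs[1:]:
        if not {a, b} & {s1, s2}:
            return (s1, s2), (a, b)
    raise ValueError("no disjoint reference pair below the distance bound")


def run_replicate(
    scenario: SimScenario,
    seed: int | np.random.Generator,
    species_tree: dendropy.Tree | None = None,
) -> ReplicateResult:
    """One simulation replicate: trees, sequences, four distances, CRM test.

    Replicates whose estimated distances are saturated or degenerate (an
    artifact of short genes on deep trees) are redrawn from the same stream;
    the redraw count is returned.
    """
    rng = np.random.default_rng(seed)
    for redraws in range(_MAX_REDRAWS):
        if species_tree is None:
            tree = yule_tree(scenario.n_taxa, scenario.birth_rate, rng)
        else:
            tree = species_tree
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        (s1, s2), (r1, r2) = _choose_pairs(scenario, labels, rng)
        if scenario.graft:
            gene_tree = graft_hgt(tree, s1, s2, scenario.hgt_height)
        else:
            gene_tree = tree
        wlen = scenario.witness_length or scenario.gene_length
        seq_w = evolve_jc(tree, wlen, rng)
        seq_h = evolve_jc(gene_tree, scenario.gene_length, rng)
        try:
            d_gw_s = _seq_jc(seq_w[s1], seq_w[s2])
            d_gh_s = _seq_jc(seq_h[s1], seq_h[s2])
            d_gw_r = _seq_jc(seq_w[r1], seq_w[r2])
            d_gh_r = _seq_jc(seq_h[r1], seq_h[r2])
            rec = crm_from_distances(
                d_gh_s, d_gw_s, d_gh_r, d_gw_r,
                length=scenario.gene_length, scale=scenario.test_scale,
            )
        except (SaturatedDistanceError, CRMTestSkipped):
            continue
        return ReplicateResult(
            reject=rec.p <= scenario.delta_rho,
            d_gw_r=d_gw_r,
            d_gh_r=d_gh_r,
            d_gw_s=d_gw_s,
            d_gh_s=d_gh_s,
            redraws=redraws,
        )
    raise RuntimeError("replicate redraw limit exceeded")


def _sweep(
    scenarios: Sequence[SimScenario],
    values: Sequence,
    value_name: str,
    seed: int,
    species_tree: dendropy.Tree | None = None,
) -> pd.DataFrame:
    """Shared sweep driver: one species tree and one pair choice per sweep
    (drawn from ``seed`` unless supplied), replicates vary the sequences."""
    master = np.random.default_rng(seed)
    if species_tree is None:
        species_tree = yule_tree(
            scenarios[0].n_taxa, scenarios[0].birth_rate, master
        )
    base = scenarios[0]
    if base.s_pair is None or base.r_pair is None:
        s_pair, r_pair = choose_pairs_deep(species_tree)
        scenarios = [replace(sc, s_pair=s_pair, r_pair=r_pair) for sc in scenarios]
    rows = []
    for value, scenario in zip(values, scenarios):
        results = [
            run_replicate(scenario, int(master.integers(2**31)), species_tree)
            for _ in range(scenario.n_replicates)
        ]
        rows.append(
            {
                value_name: value,
                "rate": float(np.mean([r.reject for r in results])),
                "d_gw_r": float(np.mean([r.d_gw_r for r in results])),
                "d_gh_r": float(np.mean([r.d_gh_r for r in results])),
                "d_gw_s": float(np.mean([r.d_gw_s for r in results])),
                "d_gh_s": float(np.mean([r.d_gh_s for r in results])),
                "n_replicates": scenario.n_replicates,
                "redraws": int(np.sum([r.redraws for r in results])),
            }
        )
    return pd.DataFrame(rows)


def sweep_height(
    heights: Sequence[float],
    base: SimScenario | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """HGT identification rate as a function of event height (recentness)."""
    base = base or SimScenario(gene_length=70, witness_length=DEFAULT_WITNESS_LENGTH)
    scenarios = [replace(base, hgt_height=h, graft=True) for h in heights]
    return _sweep(scenarios, list(heights), "height", seed)


def sweep_length(
    lengths: Sequence[int],
    base: SimScenario | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """HGT identification rate as a function of transferred-gene length."""
    base = base or SimScenario(hgt_height=0.7, witness_length=DEFAULT_WITNESS_LENGTH)
    scenarios = [replace(base, gene_length=int(l), graft=True) for l in lengths]
    return _sweep(scenarios, list(lengths), "length", seed)


def sweep_fp_length(
    lengths: Sequence[int],
    pair_distance: float = 0.2,
    n_replicates: int = 20,
    delta_rho: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """False-positive rate vs gene length at fixed organism distance.

    Both genes evolve on the same quartet species tree (no transfer); a
    rejection is a false alarm.  The FP studies probe the calibration of the
    screen as applied to real data, so they use the worked-example
    (hamming-scale) statistic.
    """
    tree = quartet_tree(pair_distance)
    base = SimScenario(
        n_taxa=4,
        gene_length=0,
        n_replicates=n_replicates,
        delta_rho=delta_rho,
        s_pair=("s1", "s2"),
        r_pair=("r1", "r2"),
        graft=False,
        hgt_height=0.0,
        test_scale="hamming",
    )
    scenarios = [replace(base, gene_length=int(l)) for l in lengths]
    return _sweep(scenarios, list(lengths), "length", seed, species_tree=tree)


def sweep_fp_distance(
    distances: Sequence[float],
    gene_length: int = 640,
    n_replicates: int = 20,
    delta_rho: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """False-positive rate vs organism (within-pair) distance at fixed length."""
    master = np.random.default_rng(seed)
    frames = []
    for d in distances:
        tree = quartet_tree(d)
        scen = SimScenario(
            n_taxa=4,
            gene_length=gene_length,
            n_replicates=n_replicates,
            delta_rho=delta_rho,
            s_pair=("s1", "s2"),
            r_pair=("r1", "r2"),
            graft=False,
            hgt_height=0.0,
            test_scale="hamming",
        )
        df = _sweep([scen], [d], "distance", int(master.integers(2**31)), species_tree=tree)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
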