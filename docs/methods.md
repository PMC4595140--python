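# Methods

## The problem

Horizontal gene transfer (HGT) between closely related bacterial strains is
nearly invisible to the two classical detector families: gene trees of
congeneric strains carry almost no phylogenetic signal, and the nucleotide
composition of donor and recipient is practically identical. `nearhgt`
implements a two-stage screen that works precisely in this regime:

1. **Synteny screen.** A gene recently inserted at a random genomic position
   sits in a new neighborhood. For a gene g shared by genomes G1, G2, the
   synteny index SI(g) = |N_k(G1,g) ∩ N_k(G2,g)| counts the genes common to
   its k-neighborhoods (k genes upstream + k downstream, wrapping around the
   circular chromosome), so SI ∈ [0, 2k]. Between closely related strains
   almost all genes have SI near 2k; genes in the extreme low tail are HGT
   candidates. The cutoff C(δ_SI) is the largest observed SI value whose
   cumulative fraction of core genes stays below δ_SI (default 0.05);
   candidates satisfy SI ≤ C. Low SI alone cannot distinguish transfer from
   translocation or duplication, hence stage two.

2. **Rate-ratio (CRM) validation.** Under the universal-pacemaker view of
   genome evolution, two genes keep an approximately constant ratio between
   their evolutionary rates along every lineage (constant relative
   mutability). For candidate gene g_h between strains s1, s2, a witness
   gene g_w and a reference organism pair r1, r2 yield the expected ratio
   ρ = d_gh(r1,r2)/d_gw(r1,r2) (divergence time cancels) and the expected
   strain distance d' = ρ·d_gw(s1,s2). The observed d_gh(s1,s2) is compared
   to d' with a two-cell goodness-of-fit statistic at one degree of freedom,

       χ² = ℓ (d_obs − d')² / (d'(1 − d')),

   over the gene length ℓ. Distances are Jukes-Cantor (JC) corrected
   Hamming fractions, d = −(3/4)ln(1 − (4/3)h). In the screening procedure
   the observed and expected distances are converted back to the Hamming
   scale before the χ² (so the two cells are genuine site counts); the
   statistic can also be evaluated directly on the JC scale, the closed form
   the method's pseudocode states (see "Two statistic scales" below). A
   transfer between the strains *shortens* d_obs; a transfer into one strain
   from outside the analyzed set *lengthens* it. Both directions are
   reported, labeled.

The driver iterates over all unordered strain pairs, all reference pairs
containing the candidate, and all eligible witness genes. Witnesses that are
themselves SI candidates for the pair are excluded (a transferred witness
masks detection). Raw p-values are Bonferroni-corrected per (gene, strain
pair) by the number of completed tests; skipped tests (saturated distances,
missing orthologs, uninformative witnesses) are logged with reasons and
excluded from the correction denominator. A gene is putative HGT when any
corrected p ≤ δ_ρ (default 0.01).

**Recipient inference.** A transferred gene shows low SI between the
recipient and every other carrier, but high SI among the rest. When the gene
is a candidate in ≥ 2 pairs whose intersection is a single organism, and is
not a candidate in any pair avoiding that organism, that organism is called
the recipient; otherwise the call is undetermined.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 10 | neighborhood radius (genes); SI histograms span 0..20 |
| δ_SI | 0.05 | maximal low-tail fraction defining the SI cutoff |
| δ_ρ | 0.01 | significance level of the corrected χ² test |
| topology | circular | bacterial chromosomes; linear mode for contigs |

Gap handling is pairwise deletion: a column counts only when both sequences
show an unambiguous base. Duplicate identifiers within a genome (paralogs)
are canonicalized to the first occurrence in genome order; neighborhoods
operate on identifier sets. Candidate selection uses SI ≤ C(δ_SI); a strict
(<) variant is available behind a flag.

## Two statistic scales

The χ² form above is algebraically identical to the explicit two-cell sum
Σ(O−E)²/E and the package asserts this at runtime. What varies is the scale
of its operands. On the **Hamming scale** (default for real-data screening,
and the worked-example procedure) the cells are site counts and the test is
calibrated against binomial sampling noise — with exactly known
expectations its null rejection rate matches the nominal level (tested).
On the **JC scale** the corrected distance is treated as a per-site
"probability"; beyond ~0.3 substitutions/site the correction inflates both
the deviation and its fluctuations, making the test markedly
anticonservative but far more sensitive to distance shortening at deep
divergences. The simulation study exercises the JC-scale form, which is the
only variant that reproduces the published power levels; the false-positive
studies probe the calibration of the screen as used on real data and run on
the Hamming scale.

## Simulation study

`simulate` reproduces the power and false-positive studies at configurable
scale. Each sweep draws **one** ultrametric Yule species tree over 20 taxa
and **one** strain/reference pair choice, then replicates vary only the
stochastic sequence evolution. A transfer at fractional height η is
implanted by re-attaching the recipient tip on the partner's lineage at age
η·t(s1, LCA(s1,s2)): the gene-tree distance of the pair becomes η times the
species-tree distance, all tip pairs not involving the two strains keep
their distances exactly, and ultrametricity is preserved. Sequences evolve
site-independently under JC (uniform root, exact per-branch transition
probabilities), and all four distances are re-estimated from the simulated
sequences.

Numerical/design choices, made once:

- **Branch-length scale.** Branch lengths are expected substitutions per
  site (rate × time at rate 1; only rate ratios enter the test). The birth
  rate defaults to 4.0 so that a 20-taxon tree's deepest tip pairs fall just
  below 1 substitution/site — the JC-scale statistic requires d' < 1, and
  the regime matches the reference-organism distances of the worked example
  (~0.55).
- **Pair choice.** By default the sweep drivers pick the deepest disjoint
  tip pairs under a 0.95 distance cap, the regime in which the power study
  operates (shallow pairs carry almost no signal at two-digit gene lengths).
- **Witness length.** Power sweeps vary the length of the transferred
  fragment only; the witness is a fixed full-length calibration gene
  (1472 bp, the worked example's witness length). The FP studies give both
  genes the same length.
- **Degenerate replicates.** Draws with a saturated Hamming fraction
  (≥ 3/4) or an out-of-range expectation (d' ≥ 1) are redrawn from the same
  stream and counted.
- **FP geometry.** "Organism distance" is the within-pair path length on a
  symmetric ultrametric quartet ((s1,s2),(r1,r2)); only the two within-pair
  distances enter the statistic, so the root depth is immaterial.

With these conditions (200-400 replicates per point) the height sweep at
70 bp identifies essentially every transfer up to height ~0.3-0.4 and
~0.45-0.5 at height 0.9; the length sweep at height 0.7 yields ~0.4 at
20 bp, ~0.7 at 80 bp and ~1.0 at 640 bp; FP rates are flat in sequence
length at fixed distance and non-increasing in distance at fixed length.
Identification at 80 bp cannot reach 1.0 under sequence-estimated
distances: the binomial noise of an 80-bp distance estimate is of the same
order as the 30% distance reduction the event leaves at height 0.7, capping
the rejection rate near 0.7 regardless of tree scale — a genuine limit of
the test in this regime.

## Synthetic fixtures

`make_fixture` generates the end-to-end test bed: a shallow Yule clade of
strains (pairwise distances ≤ 2× `divergence`, default 1%, the scale of
congeneric strains) plus a deep reference cherry (pairwise 0.5). Every gene
carries its own lognormal rate multiplier applied to *all* branches, so the
constant-ratio assumption holds by construction. A transfer implants both
signals: the recipient's copy evolves on a grafted gene tree (recent
coalescence with the donor) and the gene is relocated in the recipient's
gene order. The relocation slot is drawn among slots farther than 2k+1
genes from the origin (shrunk for small gene sets): at real-genome scale a
uniformly random insertion lands outside the old neighborhood with high
probability, and this default mimics that regime at fixture scale;
`min_displacement=0` restores fully uniform placement.

What the fixtures do *not* emulate: gene gain/loss, rearrangements other
than the implanted relocation, alignment error, paralogy, amelioration, or
rate variation across sites. Passing the recovery tests therefore shows the
pipeline's logic is sound under its own model assumptions, not that real
strain data will be as clean.

## Composition scan

The comparator for composition-based detection: the ℓ_w-spectrum of a
segment is the 4^ℓ_w vector of overlapping word frequencies (ℓ_w = 2, 3, 4,
or G+C content as a 2-vector). A sliding window (2000 bp, step 10 bp by
default) is compared to the whole-genome spectrum by Euclidean distance; a
window is δ-atypical when its distance strictly exceeds the empirical
(1−δ) quantile of all window distances, so at most ⌈δN⌉ windows are ever
flagged. A gene is δ-atypical when any overlapping window is (a stricter
majority rule is available). Words are counted on the given strand only;
windows run over the linearized sequence. Between closely related strains
the donor and recipient signatures nearly coincide, so this scan is
expected to miss intra-clade transfers — which is the point of the
comparison.

## Known limitations

- Reference-organism choice is a user input; the method cannot detect a
  transfer that also occurred between the references, or a transferred
  witness, and its sensitivity depends on reference depth.
- The JC model has no rate heterogeneity or base-composition bias; the
  architecture isolates the correction behind a convert/correct pair so
  another time-reversible model can be slotted in.
- The published power levels at two-digit gene lengths are partly driven by
  the anticonservatism of the JC-scale statistic; the package reproduces
  the curve shapes and most levels but reports honest rates (see the
  simulation section).
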