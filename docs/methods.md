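# Methods

This note documents the models and procedures orthokit implements, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that make runs bit-reproducible.

## Ortholog delineation

**Homology scores.** The built-in scorer is Smith–Waterman local alignment
with affine gaps: a gap of length *k* costs `gap_open + k·gap_extend`
(defaults 11 and 1, the common protein-search convention), substitution
scores from BLOSUM62, and the ambiguity residue `X` scoring 0 against
everything so masked positions neither reward nor punish an alignment.
Scores are raw matrix units, not bit scores: they are only ever compared
within one hit table, so internal consistency is all that is required, and
imported BLAST bit scores (column 12 of the 12-column tabular format) are
used as-is for the same reason. The alignment itself is delegated to
Biopython's pairwise aligner; an independently coded quadratic Gotoh dynamic
program in the test suite checks exact agreement on random pairs.

All-vs-all search applies an exact k-mer prefilter first: a pair is aligned
only if the two sequences share at least 2 distinct 4-mers. At desk scale
this is permissive — the tests verify that every prefilter-passing pair
scores identically to exhaustive scoring — while making the quadratic DP
affordable. Hits below `min_score` (default 30, roughly the level of chance
local similarity between unrelated ~300-residue proteins) are discarded.
Within-species pairs are scored by default because the in-paralog rule needs
them; `cross_species_only` disables this.

**Best-reciprocal hits.** For species pair (S, T), gene x of S and y of T
form a BRH iff y is x's highest-scoring hit in T and x is y's highest in S.
Ties are broken toward the lexicographically smallest gene id — here and
everywhere else in the package — so identical inputs give byte-identical
outputs regardless of iteration order.

**In-paralog attachment.** An unplaced gene g is attached to a same-species
BRH participant m iff `score(g, m) ≥ max_p score(m, p)` over m's BRH
partners p: g is closer to m than m's nearest cross-species ortholog, the
standard evidence that g duplicated after the relevant speciation. Each gene
attaches to at most one anchor (best score, then smallest id). The rule is a
design choice — co-ortholog handling admits several reasonable definitions —
and is flag-controlled (on by default).

**Clustering.** At one level of orthology, OGs are the connected components
of the graph whose vertices are the genes of the level's species and whose
edges are the BRH pairs within the level plus in-paralog attachments.
Components are the simplest faithful reading of "cluster the candidates" and
have the advantage of being oracle-testable against breadth-first search.
Components touching a single species are not orthologous groups (an OG
represents a gene of the last common ancestor of *several* species); their
genes are reported in an unassigned sidecar with reason codes. OG ids are
`og{n}at{level}`, numbered by descending size then smallest member id.

**Tree mode.** Walking the species tree post-order, each internal node
inherits its children's clusters (leaves contribute single genes) and merges
clusters joined by at least `min_crossing_edges` (default 1) BRH edges whose
two species lie in *different* child subtrees; the node's in-paralog
attachments are then applied as further merges. Because every BRH edge is
used exactly at the species pair's last common ancestor and clusters are
only ever merged on the way up, child OGs nest inside exactly one parent OG
by construction, and the root-level partition with attachments disabled
equals the flat root-level clustering (both are components of the same edge
set) — an invariant the tests assert. `min_crossing_edges > 1` reserves room
for stricter merging; with it, merging proceeds to a fixpoint over cluster
pairs with sufficient edge support.

## Mapping novel proteomes

Mapping links a new genome to precomputed OGs without re-running
delineation, so a fragmented or incomplete input cannot perturb the existing
orthology. Each novel gene is scored (same scorer and prefilter) against all
OG member sequences; it is assigned to the OG of its best-scoring anchor iff
`score ≥ accept_ratio × reference(OG)`, where the reference is the median
pairwise member–member score of that OG (a seeded random subsample of 50
pairs when the OG has more). The ratio form makes acceptance scale-free with
respect to sequence length; 0.5 is deliberately lenient — a member-length
sequence half as similar as a typical member pair still maps — and raising
it can only shrink the assigned set (a tested monotonicity). The acceptance
rule is this package's own design; mapping thresholds are not standardised
across orthology tools.

## Phyloprofiles

For an OG at a level with N species, of which n are present (≥ 1 member),
s single-copy and m = n − s multi-copy: universality = n/N, duplicability =
m/n, single-copy fraction = s/N. The duplicability denominator is *present*
species on purpose — it measures the propensity to duplicate where the gene
exists; users wanting m/N can recompute it from the counts, which are all in
the profiles TSV. Filters use strict inequality (">90%" excludes exactly
90%), a documented choice where convention varies. The marker-gene FASTA
export writes one file per selected OG with `gene_id species_id og_id`
headers; if a relaxed filter lets a multi-copy species through, the longest
member is exported and a warning recorded.

## Genome sampling

Sketches are bottom-s MinHash: the s smallest distinct 64-bit hashes of
canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement; k-mers containing N are skipped). Defaults k = 21, s = 1000
follow common sketching practice for genome-scale identity. The hash is a
seeded splitmix64 mix of the 2-bit-packed canonical k-mer; any stable 64-bit
hash would do, and the seed is stored in the sketch so incompatible sketches
are rejected rather than silently compared. The Jaccard index j is estimated
from the s smallest hashes of the merged union; distance
d = −(1/k)·ln(2j/(1+j)), capped at 1 (identity 0) when j = 0; identity
= 100·(1 − d).

Genomes are clustered at identity > 96% with single linkage by default:
"every pair above threshold" reads like complete linkage, but well-sampled
clades form chains of near-identical assemblies, and single linkage keeps a
chain together; complete linkage is available as a flag. Representatives are
chosen by completeness percentage first, then annotation count, then
smallest id — the ordering of the first two criteria is genuinely open, so
it is configurable (`priority="annotation"`).

## Benchmarking

Per reference OG (refOG), the *best combination* is the subset of
overlapping predicted OGs whose union maximises F1 against the refOG —
exhaustive over all nonempty subsets up to 15 candidates, greedy beyond
(seeded with the single OG of highest F1, then adding candidates in
descending-overlap order while F1 improves; the seed guarantees the greedy
result is never worse than any single OG). Ties prefer fewer OGs, then
smaller id tuples.

Categories: *exact* — a single predicted OG identical to the refOG; *akin* —
a single OG with F1 ≥ 0.9 (configurable; "nearly identical" has no standard
definition, so the threshold is explicit in the output header); *other* —
everything else, including multi-OG combinations however good. A refOG is
*split* when ≥ 2 predicted OGs overlap it by at least `min_overlap` genes
(default 2, so single-gene strays do not count as splits); each contributing
OG beyond the first is one split event.

The Variation of Information VI = H(X) + H(Y) − 2I(X;Y) is computed from the
contingency table with natural logarithms (0·ln 0 ≡ 0), restricted to the
genes covered by both partitions — predictions cover many genes outside the
benchmark set, and the metric should compare classifications of the
benchmarked genes. VI is a true metric (zero iff equal, symmetric, triangle
inequality), which the tests verify numerically.

Cumulative curves report, for a grid of thresholds x, the number of refOGs
whose metric exceeds x — more informative than a single average when family
difficulty varies by orders of magnitude. The summary row counts refOGs with
F1/precision/recall ≥ 85% (configurable; a tiny epsilon guards the
floating-point comparison at the printed threshold).

## The simulator

Gene content evolves along a rooted species tree with branch lengths by a
per-gene birth–death process. On a branch of length t each gene is first
lost with probability 1 − exp(−λt); a survivor duplicates (exactly one extra
copy) with probability 1 − exp(−δt). Loss is drawn before duplication so a
copy cannot duplicate and vanish within one branch — the resurrect-then-lose
ambiguity would make truth bookkeeping ill-defined. Sequences start as iid
uniform draws over the 20 residues (length Normal(300, 50) truncated at 50)
and diverge by per-site substitution with probability 1 − exp(−μt), uniform
over the 19 other residues. The substitution model is deliberately *not* an
empirical exchangeability matrix: recovery tests would be circular if the
generator shared the scorer's BLOSUM62 assumptions.

Truth is recorded at every internal node: each gene copy present at the node
founds one truth OG containing its extant descendants, so truth blocks are
disjoint and complete per level by construction (asserted after every run).
The mean extant copy number per family approximately follows the branching
process exp((δ−λ)·path length); the exact per-branch factor is
e^{−λt}(2 − e^{−δt}), which differs from e^{(δ−λ)t} only at second order in
the rates — negligible at the rates used here, and the Monte-Carlo test
allows 3 standard errors.

Two regimes anchor the tests: *strict* (δ = λ = μ = 0; identical single-copy
families, which the pipeline must recover exactly — 100/100 exact, VI = 0)
and *easy* (all rates 0.05 on a 5-species tree of depth ≈ 0.3; mean
per-family F1 ≥ 0.9 required, ≈ 0.995 observed). What passing these shows —
and does not show: the simulator produces clean, complete proteomes with
uniform composition, no domain shuffling, no fragments, no rate
heterogeneity across sites or lineages, and no horizontal transfer, so
recovery here demonstrates the correctness of the machinery, not
state-of-the-art accuracy on real, messy proteomes.

## Numerical and reproducibility conventions

- All tie-breaks are lexicographic (target ids, anchor ids, OG ordering by
  descending size then smallest member, cluster representatives), making
  every output byte-deterministic under input reordering.
- One seeded NumPy generator drives each simulation; the species tree is
  traversed in a fixed order. Fixture writing is checksum-stable.
- Problem sizes in the shipped tests and the acceptance script (100 families,
  5 species, ~500 genes; 30 families for the repeated-run check) keep a full
  run around a minute on one CPU while leaving clear statistical margins.
- Degenerate inputs are errors, not silent results: empty sequences, empty
  OG sets, levels with fewer than two species, sketches with mismatched k or
  seed, empty common universes in VI.

## Known limitations

- The BRH graph uses a single score per pair; no E-values, compositional
  adjustment, or profile models. Imported bit scores must come from one
  consistent search run.
- Connected components can chain distinct families through a single spurious
  BRH edge; `min_crossing_edges` mitigates this in tree mode only.
- The mapping rule is heuristic and per-level; it does not model multi-domain
  proteins mapping partially to several OGs.
- MinHash identity is a point estimate; no significance model is attached.
- The simulator's duplication events copy one gene at a time; bursts, segmental
  duplications and gene conversion are out of scope.
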