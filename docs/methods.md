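# Methods

This note records the models implemented in `tandemfill`, the parameter
choices that matter, what the synthetic benchmark does and does not
emulate, and the places where the design was genuinely open.

## Read recall

A read is a candidate for the target area of interest (TOI) as soon as it
partially aligns to the reference TOI. The false-positive filter models
the number `X` of rare k-mers (k = 21, genome-wide count ≤ 3, canonical
form) shared between the aligned reference region and the aligned read
region as `X ~ Normal(δy, σ²)`, where `y` is the rare-k-mer count of the
reference region. `δ ∈ [0, 1)` absorbs the reference–query divergence;
`σ²` the sequencing-error dispersion. Maximizing the normal log-likelihood
gives `δ = Σyᵢxᵢ / Σyᵢ²` and `σ² = Σ(xᵢ − δyᵢ)²/N`. Note the variance is
the mean *squared* residual — the unsquared form is dimensionally not a
variance and can be negative. A two-sided test at level α (default 0.05)
accepts an alignment when `x ∈ δy ± Z_{α/2}·σ`, and one accepted alignment
recalls the read. Presence of a rare k-mer in the read region is tested by
canonical set membership, not position, because HiFi indels shift
coordinates. Training observations should come from a homologous region
with a trusted assembly; without them a logged, deliberately permissive
fallback (δ = 0.85, σ = 250) is used — at the rare-k-mer counts carried by
HiFi-scale alignments (y in the thousands) this accepts roughly ±10%
around the expected sharing while still rejecting strongly diverged
off-target reads. A tight constant σ cannot serve as a universal default
because the acceptance band does not scale with y.

With `y` in the thousands (typical for 10–20 kb HiFi reads over a
diverged satellite array) the test separates same-repeat reads from reads
of a 15%-diverged off-target array by two orders of magnitude in `x/y`;
the binding assumption is that σ² is constant across alignments, which
holds approximately when read lengths are homogeneous.

## Contig generation

The unitig graph is bidirected (every edge implies its reverse-complement
mirror); read paths contribute +1 support to each oriented adjacency they
traverse. Simplification and traversal:

* **Transitive edges.** A direct edge `v→w` is removed when a path
  `v→o→…→w` of ≥ 2 edges exists whose edges all have support ≥
  `min_support` and the direct edge is itself supported; the search is
  capped at 5 hops. `min_support` defaults to 2.
* **Modified BFS.** Starting from zero-indegree oriented nodes (leftover
  nodes are re-seeded, longest first), each node may be visited
  `⌊(id+od)/2⌋` times (floor 1). At a branching node, successors reachable
  by a longer sibling path are deferred (a legitimate detour may not pass
  through the branching node itself); among the rest, the single
  best-supported successor with support ≥ `min_support` is taken, or all
  of them when none qualifies. Deferred successors get later visits.
  Support ties break by (support, node length, node id) descending.
* **DFS and cuts.** Walks follow traversal edges toward the earliest BFS
  timestamp within visit budgets. Branching nodes of the *traversal*
  graph get cut flags (1-in/many-out cuts outgoing; many-in/1-out cuts
  incoming; many/many cuts all); a revisit that closes a loop inside one
  walk clears the node's flag, which is what lets a two-copy repeat come
  out as a single contig. After severing, each maximal unsevered path is
  a contig; mirror-orientation duplicates are deduplicated and walks
  whose every node-visit is already consumed by longer walks are dropped
  (the forward and mirror traversals of the same component need not
  decompose it identically).

## Placement

Contigs are filtered (TOI-aligned bases ≥ 10% of length and ≥ 2× off-TOI
bases), then each contig's fragmented alignments become elements. A
candidate window of the contig's length is anchored at every element's
projected start (windows overlapping > 50% are merged, top 7 kept). The
window score is the longest non-decreasing subsequence of contig-order
indices read in reference order — computed both forward and reversed, the
better orientation becoming the window strand. The exact O(NM) longest
matching subsequence DP is retained as a test oracle; on one-to-one
matchings the two agree.

The genetic algorithm operates on assignments (contig → window or
unplaced): 500 random individuals; fitness-proportional selection of 60
(fitness shifted so the minimum maps to weight 1); one-locus allele
switching between random parent pairs until 300 offspring; 5% per-offspring
mutation (drop a placed contig or place an unplaced one); the population is
refilled to 500 with fresh randoms. Termination: 200 generations, or when
the ten best *distinct* assignments share one fitness — distinct matters,
because offspring frequently duplicate a parent and ten copies of one
individual signal takeover, not convergence. The objective books the TOI
into depth classes (`l_t`), with uncovered stretches flanked on both sides
by contigs of one assembly-graph component penalized 2.5× (they should not
exist), and adds half the sum of pairwise placement-midpoint distances to
discourage stacking.

## Phasing

Signals, on the placed contigs and the two haplotypes' shores:

* `HIC[s, c]`: Hi-C pairs whose ends are each anchored by 31-mers unique
  across all contigs and shores; an end hitting unique k-mers of more than
  one sequence is ambiguous and drops the pair.
* `HIFI[i, j]`: recalled reads aligning to both contigs (+1 per read per
  pair). Read-to-contig mapping keeps secondary alignments at a relaxed
  score ratio (minimap2 `-p 0.3`): the alignments to the *other*
  haplotype's homologous contig are exactly the links the homology
  penalty needs.
* `h_ij`: shared distinct canonical 31-mers over the smaller set;
  `H̄` = mean of the non-zero off-diagonal values.
* `D[s, c]`: |shore inner boundary − placement midpoint| + 1 kb, on
  reference-TOI coordinates.

The objective is
`C₁·Σ HIC/(L·L·D) + C₂·Σ (H̄−h)·HIFI/(L·L) − C₃·|ΣL_mat − ΣL_pat|/L_TOI`,
summing the first term over same-haplotype shore–contig pairs and the
second over same-haplotype contig pairs; collapsed contigs count in both
haplotypes. The raw per-entry terms are ~10⁻¹¹ at these length scales
while the balance term is O(1), so each component matrix is normalized to
unit total absolute mass before weighting; with that normalization the
default weights C₁ = C₂ = C₃ = 1 are meaningful across region sizes and
depths, and remain user-configurable.

The search is hill climbing over single-contig state changes (accept only
improvements; local optimum after 100 non-improving proposals) with 1000
restarts, each perturbing half the contigs. One extension proved
necessary: a homologous pair assigned to *swapped* haplotypes cannot be
repaired one contig at a time — the intermediate state puts two homologs
on one haplotype and pays the homology penalty, so every single move is
rejected and the climber stalls at ~50% assignment accuracy regardless of
restart count. At each plateau the search therefore scans all coordinated
two-contig changes (vectorized batch evaluation) before declaring a local
optimum; with the pair neighborhood the planted diploid truth is the
optimum actually reached.

Haploid mode skips phasing entirely. Scaffolds join contigs in reference
order with 100 N's (configurable); prefix/suffix blocks aligning to the
shores at ≥ 90% identity within 100 bp of a scaffold end are trimmed.

## Evaluation

Completeness = union of truth-side alignment blocks / truth length;
correctness = union of assembly-side blocks / assembly length. The LIS
identity score chains k-mers unique within *both* sequences, ordered by
assembly position, and divides the longest non-decreasing run of truth
positions by the assembly's unique-k-mer count; both assembly orientations
are tried and the better is reported. The strictly/loosely-improved
classifiers are pure decision rules over externally computed R_AQI/S_AQI
quality indices and read coverages (strict: R_new > 1.1·R_ori; loose:
R_new > R_ori, or R_new > R_ori/1.6 with S improving and coverage moving
toward the genome-wide mean).

## Satellite analysis

Monomers are annotated by a greedy scan: at each position the consensus
and its reverse complement are aligned against a window of ≤ 1.2 unit
lengths with end-gaps free on the window side (edlib, prefix mode); a hit
within 25% edit budget is emitted and the scan jumps past it. The
consensus is a per-column majority vote (seeded from the modal-length
monomers, refined by one realignment pass; ties break to the
lexicographically smaller base) and the variant profile is 1 − max base
frequency per column. An HOR is a tandem duplication of ≥ 3 consecutive
monomers, each copy within 5 edits of its counterpart one period earlier
(Levenshtein, preceding-block comparison); maximal repeats per (start,
period) are reported, skipping starts whose run extends left. A monomer's
HOR score is the number of reported HORs containing it divided by the
region's monomer count. Monomer-set similarity is the Jaccard index over
distinct strand-canonicalized sequences; the similarity experiment draws
random region pairs (whole regions for genome/chromosome level, disjoint
tenths for the within-region case).

## Synthetic data

The generator emulates the validation design the pipeline targets: a
monomeric array (181 bp units, period-3 higher-order block) between unique
shores; one or two haplotypes derived by independent mutation; HiFi-like
reads; Hi-C pairs; and a planted unitig graph with read paths that stands
in for an assembler's output, so the graph stage is testable in isolation.
Defaults, chosen once as the study conditions:

* monomer-to-monomer diversity 5% (satellite arrays typically show 5–20%;
  this is also what makes rare 21-mers informative and 31-mers unique);
* haplotype divergence 1% (SNP:ins:del = 2:1:1);
* HiFi 30×, mean 12 kb (Normal, σ = 10%, floor 1 kb), 0.1% error;
* Hi-C 60× of 150 bp ends, contact distance ~ (d+1)^(−1.1) (genome-wide
  decay is ≈ d^(−1.08)), 10% inter-haplotype swap noise by default
  (1/6 for the 5:1 enrichment scenarios);
* 4 unitigs per haplotype with one severed junction (a coverage dropout),
  optional decoy transitive edges and block-level SVs.

Everything is byte-reproducible from (config, seed). What the generator
does **not** emulate: HiFi chemistry error profiles, restriction-site
placement and ligation artifacts in Hi-C, assembler-specific unitig
topology (bubbles, tips), segmental duplications outside the TOI, and
reference bias in alignment. Passing tests therefore demonstrate the
algorithms' correctness under the stated model, not performance on real
centromeres.

## Numerical and problem-size choices

Acceptance-style checks run at desk scale: ~50 kb arrays, ≤ 16 contigs for
phasing (exhaustive 4ⁿ oracles up to n = 10, vectorized), 20-seed
replicates for stochastic equivalences, 200 random instances for chain
-score oracles. σ² is floored at 10⁻⁹; fitted δ ≥ 1 is clamped just below
1 with a warning; GA fitness evaluations are cached per assignment;
coordinate ties break lexicographically throughout so identical inputs
give identical outputs. minimap2 is used wherever the pipeline genuinely
needs a general aligner at run time (reads/contigs vs reference, scaffold
vs shores or truth); the package's own contributions never call it.

## Known limitations

* The recall model assumes one global (δ, σ²); per-region estimation is
  not attempted.
* The GA and phasing searches are heuristics; equivalence with exhaustive
  search is demonstrated at small n only.
* The placement objective can legitimately prefer dropping a contig whose
  only windows double-cover in haploid mode — genuinely collapsed repeats
  are then under-represented.
* Shore trimming relies on the aligner reporting terminal blocks; a
  scaffold whose shore overlap is heavily mutated (> 10% divergence) will
  not be trimmed.
* The satellite scanner is greedy left-to-right; a long insertion inside
  a monomer can shift the frame for one unit before it re-anchors.
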