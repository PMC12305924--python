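# tandemfill

Reference-guided local reassembly of long tandem-repeat regions —
centromeric satellite arrays, subtelomeric repeats — from PacBio HiFi and
Illumina Hi-C data, plus the evaluation metrics and population-level
repeat-unit analyses that go with it.

## The problem

Standard HiFi assembly pipelines leave gaps exactly where genomes are most
repetitive. When a high-quality assembly of *another* individual of the
same species exists, it can guide a local reassembly: recruit the reads
that belong to the repeat region, assemble them de novo, and use the
reference only to order, orient and phase the result. `tandemfill`
implements that strategy for a *target area of interest* (TOI) flanked by
assembled unique sequence (*shores*):

1. **Read recall.** Reads partially aligned to the reference TOI are
   candidates; a rare-k-mer hypothesis test removes reads from other
   repeats. For an alignment with `y` rare 21-mers (genome-wide count < 4)
   in the reference region and `x` of them shared by the read region, the
   model is `X ~ N(δy, σ²)`; `δ, σ²` have closed-form maximum-likelihood
   estimates (`δ = Σyᵢxᵢ/Σyᵢ²`, `σ² = Σ(xᵢ−δyᵢ)²/N`) fitted on a trusted
   homologous region, and a read is recalled when some alignment satisfies
   `x ∈ [δy − Z_{α/2}σ, δy + Z_{α/2}σ]`.
2. **Contig generation.** A unitig graph plus read paths is simplified —
   per-edge read support, removal of transitive edges shadowed by a
   supported longer path — then traversed by a modified BFS (visit budget
   `⌊(id+od)/2⌋` per node) and a timestamp-guided DFS whose cut flags are
   cleared when a revisit closes a loop, so repeat loops come out as one
   contig instead of fragments.
3. **Placement.** Fragmented contig-to-reference alignments become
   *elements*; each candidate window of the TOI is scored by the longest
   non-decreasing subsequence (LIS) of contig indices in reference order
   (fast stand-in for the exact longest-matching-subsequence DP, which is
   kept as an oracle). A genetic algorithm picks one window (or none) per
   contig, maximizing a coverage-plus-spread objective
   (`f_hap = 2(l₁−l₀−l₍>2₎)+l₂−2.5·l₍<0₎+½Σdᵢⱼ`, diploid analog with
   `l₍≥2₎`).
4. **Phasing.** Hi-C pairs anchored by unique 31-mers link contigs to the
   maternal/paternal shores; HiFi links weighted by `(H̄−hᵢⱼ)` penalize
   placing homologous contigs on one haplotype; a length-balance term
   keeps the two reconstructions comparable. Restart hill climbing over
   per-contig states {discarded, maternal, paternal, collapsed} optimizes
   the weighted sum, and the chosen contigs are joined with N-gaps and
   trimmed against the shores.

The package also ships the evaluation metrics (completeness, correctness,
LIS identity score, strictly/loosely-improved classifiers over CRAQ-style
quality indices), a population-level satellite toolkit (monomer
annotation, consensus and variant profile, higher-order-repeat detection
and scoring, monomer-set similarity experiments), and a fully seeded
synthetic-data generator so everything runs at desk scale with no
downloads.

## Worked example

```bash
python examples/04_fill_haploid.py
```

builds a ~50 kb planted satellite array with shores, samples 30× HiFi
reads, and runs recall → contigs → placement → scaffolding:

```
recalled 142 reads, assembled 2 contigs, placed 2 (adaptivity 112,396)
completeness 1.000 (truth covered), correctness 1.000 (scaffold aligned)
```

Completeness is the fraction of the planted truth covered by alignment
blocks of the reconstructed scaffold; correctness is the aligned fraction
of the scaffold itself. `adaptivity` is the genetic algorithm's objective
(≈ 2× TOI length plus the contig-spread bonus when the tiling is exact).
The other examples cover simulation (`01`), read recall (`02`), contig
generation from a loop graph (`03`), diploid phasing (`05`) and the
satellite monomer/HOR analysis (`06`). A thin CLI exposes the same steps
(`tandemfill simulate|recall|contigs|place|fill|evaluate|classify|satellite`).

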