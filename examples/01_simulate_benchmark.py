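"""Build a small synthetic tandem-repeat benchmark and describe it.

The generator plants a ~50 kb satellite array (181 bp monomers with a
period-3 higher-order structure) between two unique 8 kb shores, derives
two haplotypes at 1% divergence, and samples HiFi reads and Hi-C pairs.
"""

from tandemfill.simdata import (SimConfig, simulate_hic, simulate_hifi,
                                simulate_region)

cfg = SimConfig(ploidy=2)
sim = simulate_region(cfg, seed=7)
reads, truth = simulate_hifi(sim, seed=8)
pairs = simulate_hic(sim, seed=9)

chrom, s, e = sim.ref_toi
print(f"reference: {len(sim.reference.seq):,} bp; TOI [{s:,}, {e:,}) "
      f"= {e - s:,} bp of satellite array")
for h in sim.haplotypes:
    print(f"haplotype {h.index}: array {len(h.array):,} bp")
print(f"{len(reads)} HiFi reads "
      f"(~{sum(len(r.seq) for r in reads) / (e - s + 2 * cfg.shore_len):.0f}x)"
      f", {len(pairs):,} Hi-C pairs")
# The arrays differ from the reference by ~1%: close enough to recall
# reads against the reference, far enough to phase with unique 31-mers.
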