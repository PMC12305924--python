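"""Recall the reads belonging to a repeat region with the rare-k-mer test.

The recall model (delta, sigma^2) is fitted on observations from an
independent homologous region, then each candidate alignment is tested:
a read is kept when its shared-rare-21-mer count x falls inside
delta*y +/- z*sigma.
"""

from tandemfill.io import count_kmer_codes
from tandemfill.recall import (extract_rare_kmers, fit_recall_model,
                               recall_reads)
from tandemfill.simdata import (SimConfig, candidate_alignments,
                                simulate_decoys, simulate_hifi,
                                simulate_region, training_observations)

cfg = SimConfig(ploidy=2)
sim = simulate_region(cfg, seed=1)
reads, truth = simulate_hifi(sim, seed=2)
alns = candidate_alignments(sim, reads, truth)
decoy_reads, decoy_alns = simulate_decoys(sim, 100, divergence=0.15, seed=3)

model = fit_recall_model(training_observations(cfg, seed=1))
print(f"fitted model: delta={model.delta:.3f} sigma={model.sigma2 ** 0.5:.1f}")

codes, counts = count_kmer_codes([sim.reference], model.k)
rare = extract_rare_kmers(codes, counts)
toi_ids = {a.query_id for a in alns}
kept = recall_reads(alns, [r for r in reads if r.id in toi_ids],
                    sim.reference.seq, model, rare)
rejected = recall_reads(decoy_alns, decoy_reads, sim.reference.seq, model, rare)
print(f"sensitivity: {len(kept) / len(toi_ids):.3f} "
      f"({len(kept)}/{len(toi_ids)} true region reads kept)")
print(f"decoy rejection: {1 - len(rejected) / 100:.3f} "
      f"(reads from a 15%-diverged off-target array discarded)")
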