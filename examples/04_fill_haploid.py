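"""End-to-end gap filling of a haploid satellite array, then evaluation.

Pipeline: recall reads -> assemble contigs from the unitig graph ->
score candidate positions on the reference TOI (LIS chaining) -> pick a
consistent placement set with the genetic algorithm -> join into a
scaffold -> compare against the planted truth.
"""

from tandemfill import external
from tandemfill.evaluation import completeness_correctness
from tandemfill.io import SequenceRecord
from tandemfill.pipeline import fill_region
from tandemfill.recall import fit_recall_model
from tandemfill.simdata import (SimConfig, build_truth_graph, simulate_hifi,
                                simulate_region, training_observations)

cfg = SimConfig(ploidy=1, n_unitigs=6, contig_breaks=1)
sim = simulate_region(cfg, seed=41)
reads, truth = simulate_hifi(sim, seed=42)
graph, paths, _ = build_truth_graph(sim, reads, truth)
model = fit_recall_model(training_observations(cfg, seed=41))

res = fill_region(
    sim.reference, sim.ref_toi, reads, graph, paths, ploidy=1,
    model=model, seed=1,
    shores_mat=[SequenceRecord("shore_left", sim.haplotypes[0].shore_left),
                SequenceRecord("shore_right", sim.haplotypes[0].shore_right)])

scaffold = res.scaffolds["haplotype"]
print(f"recalled {len(res.recalled)} reads, assembled "
      f"{len(res.contigs)} contigs, placed {len(res.placements)} "
      f"(adaptivity {res.adaptivity:,.0f})")

truth_rec = SequenceRecord("truth", sim.haplotypes[0].array)
alns = [a for a in external.minimap2([truth_rec], [scaffold])
        if a.query_id == scaffold.id]
rep = completeness_correctness(alns, len(truth_rec.seq), len(scaffold.seq))
print(f"completeness {rep.completeness:.3f} (truth covered), "
      f"correctness {rep.correctness:.3f} (scaffold aligned)")
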