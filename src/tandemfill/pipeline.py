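"""End-to-end gap filling: recall -> contigs -> placement -> phasing ->
scaffolds, on in-memory objects. The CLI and the examples are thin layers
over :func:`fill_region`."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import external, graph as graphmod, phasing, placement, recall
from .io import (AlignmentRecord, ReadPath, SequenceRecord, UnitigGraph,
                 count_kmer_codes)

logger = logging.getLogger("tandemfill")


@dataclass
class FillResult:
    recalled: set[str]
    contigs: list
    placements: dict[str, placement.CandidatePlacement]
    states: dict[str, int]
    scaffolds: dict[str, SequenceRecord]
    adaptivity: float = 0.0
    phasing_objective: float = 0.0
    details: dict = field(default_factory=dict)


def _base_read_id(path_id: str) -> str:
    return path_id.split("/")[0]


def recall_stage(reference: SequenceRecord, toi: tuple[str, int, int],
                 reads: list[SequenceRecord],
                 read_alignments: list[AlignmentRecord] | None,
                 model: recall.RecallModel) -> set[str]:
    """Restrict candidate alignments to the TOI and run the rare-k-mer
    test. When no alignments are supplied, reads are mapped to the
    reference with minimap2 first."""
    chrom, toi_s, toi_e = toi
    if read_alignments is None:
        read_alignments = external.minimap2([reference], reads,
                                            preset="map-hifi")
    toi_alns = [
        a for a in read_alignments
        if a.target_id == chrom
        and min(a.target_end, toi_e) - max(a.target_start, toi_s) > 0
    ]
    codes, counts = count_kmer_codes([reference], model.k)
    rare = recall.extract_rare_kmers(codes, counts, model.rare_max_count)
    return recall.recall_reads(toi_alns, reads, reference.seq, model, rare)


def place_stage(contigs, reference: SequenceRecord,
                toi: tuple[str, int, int], ploidy: int, seed: int,
                components: dict[str, int],
                ga_config: placement.GAConfig | None = None
                ) -> tuple[dict[str, placement.CandidatePlacement], float]:
    """Map contigs to the reference, filter spurious ones, enumerate
    candidate windows and run the genetic algorithm."""
    chrom, toi_s, toi_e = toi
    contig_records = [SequenceRecord(c.id, c.seq) for c in contigs]
    alns = external.minimap2([reference], contig_records, preset="map-hifi")
    lengths = {c.id: len(c.seq) for c in contigs}
    kept = placement.filter_contigs(lengths, alns, (chrom, toi_s, toi_e))
    if not kept:
        return {}, 0.0
    toi_len = toi_e - toi_s
    candidates = {}
    for cid in kept:
        els = placement.elements_from_alignments(
            [a for a in alns if a.query_id == cid and a.target_id == chrom],
            toi_start=toi_s, toi_end=toi_e,
        )
        cands = placement.enumerate_candidates(cid, lengths[cid], els, toi_len)
        if cands:
            candidates[cid] = cands
    if not candidates:
        return {}, 0.0
    best = placement.run_ga(candidates, toi_len, ploidy,
                            components=components, config=ga_config,
                            seed=seed)
    placements = {cid: candidates[cid][k] for cid, k in best.assignment.items()}
    return placements, best.adaptivity


def _trim(scaffold: SequenceRecord, shores: list[SequenceRecord]
          ) -> SequenceRecord:
    if not scaffold.seq or not shores:
        return scaffold
    alns = external.minimap2(shores, [scaffold], preset="map-hifi")
    return phasing.trim_shores(scaffold, alns)


def fill_region(reference: SequenceRecord, toi: tuple[str, int, int],
                reads: list[SequenceRecord],
                unitig_graph: UnitigGraph, read_paths: list[ReadPath],
                ploidy: int = 2,
                read_alignments: list[AlignmentRecord] | None = None,
                model: recall.RecallModel | None = None,
                shores_mat: list[SequenceRecord] | None = None,
                shores_pat: list[SequenceRecord] | None = None,
                hic_pairs: list[tuple[str, str, str]] | None = None,
                min_support: int = graphmod.DEFAULT_MIN_SUPPORT,
                gap_n: int = 100,
                seed: int = 0,
                ga_config: placement.GAConfig | None = None,
                annealing_restarts: int = 200,
                trim: bool = True) -> FillResult:
    """Run the full pipeline for one TOI.

    Haploid mode (ploidy=1) skips phasing and joins the placed contigs in
    reference order; diploid mode phases contigs against the maternal and
    paternal shores using Hi-C, HiFi and homology signals.
    """
    model = model or recall.default_model()
    recalled = recall_stage(reference, toi, reads, read_alignments, model)
    logger.info("recalled %d / %d reads", len(recalled), len(reads))

    paths = [p for p in read_paths if _base_read_id(p.read_id) in recalled]
    contigs = graphmod.assemble_contigs(unitig_graph, paths, min_support)
    logger.info("assembled %d contigs", len(contigs))
    components = {c.id: c.component for c in contigs}

    placements, adapt = place_stage(contigs, reference, toi, ploidy, seed,
                                    components, ga_config)
    placed_contigs = [c for c in contigs if c.id in placements]
    seqs = {c.id: c.seq for c in placed_contigs}

    states: dict[str, int] = {}
    phase_obj = 0.0
    if ploidy == 1 or not placed_contigs:
        states = {cid: phasing.MATERNAL for cid in placements}
        haps = ("maternal",) if ploidy == 1 else ("maternal", "paternal")
        scaffolds = phasing.build_scaffolds(placements, states, seqs, gap_n,
                                            haplotypes=haps)
        if ploidy == 1:
            scaffolds = {"haplotype": scaffolds["maternal"]}
    else:
        shores_mat = shores_mat or []
        shores_pat = shores_pat or []
        contig_records = [SequenceRecord(c.id, c.seq) for c in placed_contigs]
        hic_counts = phasing.unique_kmer_hic_signals(
            contig_records, shores_mat + shores_pat, hic_pairs or [])
        recalled_reads = [r for r in reads if r.id in recalled]
        read_alns = external.minimap2(contig_records, recalled_reads,
                                      preset="map-hifi",
                                      extra=external.READ_TO_CONTIG_EXTRA)
        hifi_counts = phasing.hifi_link_signals(read_alns)
        chrom, toi_s, toi_e = toi
        boundaries = {s.id: 0.0 for s in shores_mat + shores_pat}
        for s in shores_mat + shores_pat:
            boundaries[s.id] = 0.0 if "left" in s.id else float(toi_e - toi_s)
        mids = {cid: p.midpoint for cid, p in placements.items()}
        M = phasing.build_signal_matrices(
            contig_records, shores_mat, shores_pat, hic_counts, hifi_counts,
            mids, boundaries, l_toi_ref=float(toi_e - toi_s))
        state_vec, phase_obj = phasing.run_annealing(
            M, n_restarts=annealing_restarts, seed=seed)
        states = {cid: int(s) for cid, s in zip(M.contigs, state_vec)}
        scaffolds = phasing.build_scaffolds(placements, states, seqs, gap_n)

    if trim:
        all_shores = (shores_mat or []) + (shores_pat or [])
        scaffolds = {k: _trim(v, all_shores) for k, v in scaffolds.items()}
    return FillResult(recalled, contigs, placements, states, scaffolds,
                      adaptivity=adapt, phasing_objective=phase_obj)
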