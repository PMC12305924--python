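"""Seeded synthetic tandem-repeat benchmarks.

The generator emulates the study design the pipeline is built for: a
reference chromosome whose centre is a monomeric satellite array with
higher-order structure, flanked by unique shores; one or two query
haplotypes derived from the reference array by independent point mutation
(plus optional structural events); HiFi-like long reads with low error;
Hi-C pairs with intra-haplotype contact enrichment and power-law distance
decay; and truth files (candidate alignments, a unitig graph with read
paths, monomer coordinates) so every pipeline stage runs with no external
data. Identical config + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (AlignmentRecord, ReadPath, SequenceRecord, UnitigGraph,
                 revcomp)
from .recall import AlignmentObservation, observe_alignment

BASES = np.array(list("ACGT"))


@dataclass
class SvEvent:
    """Deletion or tandem insertion of a monomer block in one haplotype."""

    haplotype: int        # 0-based haplotype index
    kind: str             # 'del' | 'ins'
    start_monomer: int
    n_monomers: int


@dataclass
class SimConfig:
    """Study conditions for one synthetic region."""

    monomer_len: int = 181
    n_monomers: int = 275           # ~50 kb array at 181 bp units
    hor_period: int = 3
    monomer_mut_rate: float = 0.05  # per-base divergence between array copies
    ploidy: int = 2
    haplotype_divergence: float = 0.01
    sv_events: list[SvEvent] = field(default_factory=list)
    shore_len: int = 8000
    hifi_depth: float = 30.0
    hifi_len_mean: int = 12000
    hifi_err: float = 0.001
    hic_depth: float = 60.0
    hic_read_len: int = 150
    hic_decay_exponent: float = 1.1  # genome-wide contact decay ~ d^-1.08
    inter_hap_noise: float = 0.1
    n_unitigs: int = 4              # unitigs per haplotype array
    contig_breaks: int = 1          # severed junctions per haplotype
    decoy_transitive_edges: int = 0


@dataclass
class Haplotype:
    index: int
    array: str
    shore_left: str
    shore_right: str

    @property
    def seq(self) -> str:
        return self.shore_left + self.array + self.shore_right

    @property
    def toi_start(self) -> int:
        return len(self.shore_left)

    @property
    def toi_end(self) -> int:
        return len(self.shore_left) + len(self.array)


@dataclass
class SimRegion:
    cfg: SimConfig
    ref_array: str
    ref_shore_left: str
    ref_shore_right: str
    haplotypes: list[Haplotype]
    monomer_starts: list[int]       # on the reference array
    consensus_monomer: str

    @property
    def reference(self) -> SequenceRecord:
        return SequenceRecord(
            "reference", self.ref_shore_left + self.ref_array + self.ref_shore_right
        )

    @property
    def ref_toi(self) -> tuple[str, int, int]:
        s = len(self.ref_shore_left)
        return ("reference", s, s + len(self.ref_array))


def _rand_seq(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def mutate(seq: str, rate: float, rng,
           sub_frac: float = 0.5, ins_frac: float = 0.25,
           del_frac: float = 0.25) -> str:
    """Point-mutate a sequence; event mix defaults to sub:ins:del = 2:1:1."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    hit = np.nonzero(rng.random(n) < rate)[0]
    if hit.size == 0:
        return seq
    kinds = rng.choice(3, size=hit.size, p=[sub_frac, ins_frac, del_frac])
    out = []
    prev = 0
    lookup = {0: "A", 1: "C", 2: "G", 3: "T"}
    for pos, kind in zip(hit.tolist(), kinds.tolist()):
        out.append(seq[prev:pos])
        base = seq[pos]
        if kind == 0:  # substitution to a different base
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(0, 3)])
            prev = pos + 1
        elif kind == 1:  # insertion before the base
            out.append(lookup[int(rng.integers(0, 4))])
            out.append(base)
            prev = pos + 1
        else:  # deletion
            prev = pos + 1
    out.append(seq[prev:])
    return "".join(out)


def simulate_region(cfg: SimConfig, seed: int = 0) -> SimRegion:
    """Build the reference array (HOR-structured monomers between unique
    shores) and the diverged haplotypes with optional block SVs."""
    rng = np.random.default_rng(seed)
    base = _rand_seq(rng, cfg.monomer_len)
    block = [mutate(base, cfg.monomer_mut_rate, rng)
             for _ in range(cfg.hor_period)]
    monomers = [
        mutate(block[i % cfg.hor_period], cfg.monomer_mut_rate, rng)
        for i in range(cfg.n_monomers)
    ]
    starts, pos = [], 0
    for m in monomers:
        starts.append(pos)
        pos += len(m)
    ref_array = "".join(monomers)
    shore_l = _rand_seq(rng, cfg.shore_len)
    shore_r = _rand_seq(rng, cfg.shore_len)

    haps = []
    for h in range(cfg.ploidy):
        hap_monomers = list(monomers)
        for ev in cfg.sv_events:
            if ev.haplotype != h:
                continue
            if ev.kind == "del":
                del hap_monomers[ev.start_monomer : ev.start_monomer + ev.n_monomers]
            elif ev.kind == "ins":
                blockcopy = hap_monomers[ev.start_monomer : ev.start_monomer + ev.n_monomers]
                hap_monomers[ev.start_monomer : ev.start_monomer] = blockcopy
        arr = mutate("".join(hap_monomers), cfg.haplotype_divergence, rng)
        haps.append(Haplotype(
            index=h,
            array=arr,
            shore_left=mutate(shore_l, cfg.haplotype_divergence, rng),
            shore_right=mutate(shore_r, cfg.haplotype_divergence, rng),
        ))
    return SimRegion(cfg, ref_array, shore_l, shore_r, haps, starts, base)


# ---------------------------------------------------------------------------
# HiFi reads


@dataclass
class ReadTruth:
    read_id: str
    haplotype: int
    start: int    # on the haplotype full sequence
    end: int
    strand: str


def simulate_hifi(sim: SimRegion, seed: int = 0,
                  prefix: str = "read") -> tuple[list[SequenceRecord], list[ReadTruth]]:
    """Sample reads per haplotype at depth/ploidy each, lengths
    Normal(mean, 0.1*mean) floored at 1 kb, random strand, with per-base
    errors at the configured rate (sub:ins:del = 2:1:1)."""
    cfg = sim.cfg
    rng = np.random.default_rng(seed)
    reads, truth = [], []
    for hap in sim.haplotypes:
        L = len(hap.seq)
        target_bases = cfg.hifi_depth / cfg.ploidy * L
        total = 0
        while total < target_bases:
            ln = max(1000, int(rng.normal(cfg.hifi_len_mean,
                                          0.1 * cfg.hifi_len_mean)))
            ln = min(ln, L)
            start = int(rng.integers(0, L - ln + 1))
            frag = hap.seq[start : start + ln]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            frag = mutate(frag, cfg.hifi_err, rng)
            rid = f"{prefix}_{len(reads)}"
            reads.append(SequenceRecord(rid, frag))
            truth.append(ReadTruth(rid, hap.index, start, start + ln, strand))
            total += ln
    return reads, truth


def candidate_alignments(sim: SimRegion, reads: list[SequenceRecord],
                         truth: list[ReadTruth], min_overlap: int = 1000,
                         extra_offset_blocks: int = 1
                         ) -> list[AlignmentRecord]:
    """Project each read's true haplotype interval onto the reference TOI
    (identity projection — haplotypes are colinear with the reference) to
    emulate the candidate set a partial aligner would return. Reads also
    receive a second candidate shifted by one HOR block, the typical
    multi-mapping inside a tandem array."""
    cfg = sim.cfg
    chrom, toi_s, toi_e = sim.ref_toi
    ref_len = len(sim.reference.seq)
    by_id = {r.id: len(r.seq) for r in reads}
    out = []
    period_bp = cfg.hor_period * cfg.monomer_len
    for t in truth:
        ov_s, ov_e = max(t.start, toi_s), min(t.end, toi_e)
        if ov_e - ov_s < min_overlap:
            continue
        qlen = by_id[t.read_id]
        offsets = [0]
        if extra_offset_blocks:
            offsets.append(extra_offset_blocks * period_bp)
        for off in offsets:
            ts = ov_s + off
            te = ov_e + off
            if te > toi_e:
                ts, te = ov_s - off, ov_e - off
                if ts < toi_s:
                    continue
            qs = max(0, ov_s - t.start)
            qe = min(qlen, qs + (te - ts))
            if qe - qs < min_overlap:
                continue
            if t.strand == "-":
                qs, qe = qlen - qe, qlen - qs
            out.append(AlignmentRecord(
                query_id=t.read_id, query_len=qlen, query_start=qs,
                query_end=qe, strand=t.strand, target_id=chrom,
                target_len=ref_len, target_start=ts, target_end=te,
                n_match=te - ts, block_len=te - ts, mapq=60,
            ))
    return out


def simulate_decoys(sim: SimRegion, n_reads: int, divergence: float = 0.15,
                    seed: int = 0, prefix: str = "decoy"
                    ) -> tuple[list[SequenceRecord], list[AlignmentRecord]]:
    """Reads from an off-target repeat diverged from the reference array,
    each given a random candidate alignment on the reference TOI (the
    false positives partial alignment lets through)."""
    cfg = sim.cfg
    rng = np.random.default_rng(seed)
    decoy_array = mutate(sim.ref_array, divergence, rng)
    chrom, toi_s, toi_e = sim.ref_toi
    ref_len = len(sim.reference.seq)
    reads, alns = [], []
    for i in range(n_reads):
        ln = max(1000, int(rng.normal(cfg.hifi_len_mean,
                                      0.1 * cfg.hifi_len_mean)))
        ln = min(ln, len(decoy_array))
        start = int(rng.integers(0, len(decoy_array) - ln + 1))
        frag = mutate(decoy_array[start : start + ln], cfg.hifi_err, rng)
        rid = f"{prefix}_{i}"
        reads.append(SequenceRecord(rid, frag))
        span = min(ln, toi_e - toi_s)
        ts = int(rng.integers(toi_s, toi_e - span + 1))
        alns.append(AlignmentRecord(
            query_id=rid, query_len=len(frag), query_start=0,
            query_end=min(span, len(frag)), strand="+", target_id=chrom,
            target_len=ref_len, target_start=ts, target_end=ts + span,
            n_match=span, block_len=span, mapq=60,
        ))
    return reads, alns


def training_observations(cfg: SimConfig, seed: int = 0,
                          n_reads: int = 300) -> list[AlignmentObservation]:
    """Rare-k-mer observations from an independent homologous region pair
    at the configured haplotype divergence — the trusted training set the
    recall model is fitted from."""
    from .io import count_kmer_codes
    from .recall import extract_rare_kmers

    train_cfg = SimConfig(**{**cfg.__dict__, "ploidy": 1,
                             "sv_events": []})
    sim = simulate_region(train_cfg, seed=seed + 104729)
    reads, truth = simulate_hifi(sim, seed=seed + 224737, prefix="train")
    alns = candidate_alignments(sim, reads, truth, extra_offset_blocks=0)
    codes, counts = count_kmer_codes([sim.reference], 21)
    rare = extract_rare_kmers(codes, counts)
    by_id = {r.id: r for r in reads}
    obs = []
    for a in alns[:n_reads]:
        o = observe_alignment(a, sim.reference.seq, by_id[a.query_id].seq, rare)
        if o.y > 0:
            obs.append(o)
    return obs


# ---------------------------------------------------------------------------
# Hi-C pairs


def simulate_hic(sim: SimRegion, seed: int = 0
                 ) -> list[tuple[str, str, str]]:
    """Hi-C pairs with P(distance d) ~ (d+1)^(-decay) within a haplotype;
    a pair's second end is swapped to the other haplotype (same position)
    with probability inter_hap_noise."""
    cfg = sim.cfg
    rng = np.random.default_rng(seed)
    rl = cfg.hic_read_len
    pairs = []
    total_len = sum(len(h.seq) for h in sim.haplotypes)
    n_pairs = int(cfg.hic_depth * total_len / (2 * rl))
    a = cfg.hic_decay_exponent
    for i in range(n_pairs):
        hap = sim.haplotypes[int(rng.integers(0, len(sim.haplotypes)))]
        L = len(hap.seq)
        p1 = int(rng.integers(0, L - rl))
        u = rng.random()
        d = int((1 - u) ** (-1.0 / (a - 1.0)) - 1) if a > 1 else int(u * L)
        d = min(d + rl, L - rl)
        p2 = p1 + d if rng.random() < 0.5 else p1 - d
        p2 = min(max(p2, 0), L - rl)
        hap2 = hap
        if len(sim.haplotypes) > 1 and rng.random() < cfg.inter_hap_noise:
            others = [h for h in sim.haplotypes if h.index != hap.index]
            hap2 = others[int(rng.integers(0, len(others)))]
            p2 = min(p2, len(hap2.seq) - rl)
        s1 = hap.seq[p1 : p1 + rl]
        s2 = revcomp(hap2.seq[p2 : p2 + rl])
        pairs.append((f"hic_{i}", s1, s2))
    return pairs


# ---------------------------------------------------------------------------
# truth unitig graph


@dataclass
class NodeTruth:
    node_id: str
    haplotype: int
    start: int   # on the haplotype array
    end: int


def build_truth_graph(sim: SimRegion, reads: list[SequenceRecord],
                      truth: list[ReadTruth]
                      ) -> tuple[UnitigGraph, list[ReadPath], list[NodeTruth]]:
    """Chop each haplotype array into unitigs at planted junctions, sever
    `contig_breaks` evenly spaced junctions (emulating coverage dropouts),
    optionally add decoy transitive edges, and thread every read through
    the nodes its true interval overlaps."""
    cfg = sim.cfg
    graph = UnitigGraph()
    node_truth: list[NodeTruth] = []
    bounds_by_hap = {}
    for hap in sim.haplotypes:
        n = len(hap.array)
        cuts = [round(i * n / cfg.n_unitigs) for i in range(cfg.n_unitigs + 1)]
        nodes = []
        for i in range(cfg.n_unitigs):
            nid = f"h{hap.index}u{i}"
            graph.add_node(nid, hap.array[cuts[i] : cuts[i + 1]])
            node_truth.append(NodeTruth(nid, hap.index, cuts[i], cuts[i + 1]))
            nodes.append(nid)
        n_junctions = cfg.n_unitigs - 1
        severed = set()
        if cfg.contig_breaks and n_junctions > 0:
            step = (n_junctions + 1) / (cfg.contig_breaks + 1)
            severed = {min(n_junctions - 1, int(step * (b + 1)))
                       for b in range(min(cfg.contig_breaks, n_junctions))}
        for i in range(n_junctions):
            if i in severed:
                continue
            graph.add_edge(nodes[i], "+", nodes[i + 1], "+", 0)
        for i in range(cfg.decoy_transitive_edges):
            if i + 2 < len(nodes) and i not in severed and i + 1 not in severed:
                graph.add_edge(nodes[i], "+", nodes[i + 2], "+", 0)
        bounds_by_hap[hap.index] = (cuts, nodes, severed)

    paths: list[ReadPath] = []
    for t in truth:
        hap = sim.haplotypes[t.haplotype]
        cuts, nodes, severed = bounds_by_hap[t.haplotype]
        a_s = max(0, t.start - hap.toi_start)
        a_e = min(len(hap.array), t.end - hap.toi_start)
        if a_e <= a_s:
            continue
        steps: list[tuple[str, str]] = []
        for i in range(cfg.n_unitigs):
            if cuts[i + 1] > a_s and cuts[i] < a_e:
                steps.append((nodes[i], "+"))
        # split the walk at severed junctions
        pieces: list[list[tuple[str, str]]] = [[]]
        for s in steps:
            if pieces[-1] and not graph.has_edge(pieces[-1][-1], s):
                pieces.append([])
            pieces[-1].append(s)
        for k, piece in enumerate(p for p in pieces if p):
            suffix = f"/{k}" if k else ""
            if t.strand == "-":
                piece = [(n, "-") for n, _ in reversed(piece)]
            paths.append(ReadPath(t.read_id + suffix, piece))
    return graph, paths, node_truth
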