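"""Population-level repeat-unit analysis.

A satellite array is a run of ~171-181 bp monomers. The scanner walks a
region left to right matching the consensus (either strand) with banded
edit distance; the consensus itself is a per-column majority over aligned
monomers. Higher-order repeats (HORs) are tandem duplications of at least
three consecutive monomers, each copy within a small edit budget of its
counterpart one period earlier. Monomer-set similarity between regions is
the Jaccard index over distinct strand-canonicalized monomer sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np

from .io import revcomp

DEFAULT_MAX_EDIT_FRAC = 0.25
HOR_MIN_PERIOD = 3
HOR_MAX_EDIT = 5


@dataclass
class MonomerAnnotation:
    """One repeat unit: coordinates on its region, detection strand, the
    monomer sequence oriented to the consensus strand, and its edit
    distance to the consensus."""

    region_id: str
    index: int
    start: int
    end: int
    strand: str
    seq: str
    edit_to_consensus: int


@dataclass
class HOR:
    """A detected higher-order repeat: `repeats` tandem copies of a block
    of `period` consecutive monomers starting at monomer `start_index`."""

    region_id: str
    start_index: int
    period: int
    repeats: int
    span_bp: int

    @property
    def monomer_indices(self) -> range:
        return range(self.start_index,
                     self.start_index + self.period * self.repeats)


def edit_distance(a: str, b: str, limit: int = -1) -> int:
    res = edlib.align(a, b, mode="NW", k=limit)
    d = res["editDistance"]
    return d if d >= 0 else limit + 1 if limit >= 0 else d


# ---------------------------------------------------------------------------
# monomer annotation


def annotate_monomers(seq: str, consensus: str, region_id: str = "region",
                      max_edit_frac: float = DEFAULT_MAX_EDIT_FRAC
                      ) -> list[MonomerAnnotation]:
    """Greedy left-to-right scan: at each position align the consensus (and
    its reverse complement) against a window of up to 1.2x the unit length
    with end-gaps free on the window side, emit the better strand when the
    edit distance is within budget, and advance past the emitted monomer.
    """
    u = len(consensus)
    if u < 20:
        raise ValueError("consensus must be >= 20 bp")
    max_edit = int(max_edit_frac * u)
    lo, hi = int(math.floor(0.8 * u)), int(math.ceil(1.2 * u))
    rc = revcomp(consensus)
    out: list[MonomerAnnotation] = []
    pos = 0
    n = len(seq)
    while pos + lo <= n:
        window = seq[pos : pos + hi]
        best = None  # (edit, end, strand)
        for query, strand in ((consensus, "+"), (rc, "-")):
            res = edlib.align(query, window, mode="SHW", task="locations",
                              k=max_edit)
            if res["editDistance"] < 0:
                continue
            end = res["locations"][0][1] + 1
            if end < lo:
                continue
            cand = (res["editDistance"], end, strand)
            if best is None or cand < best:
                best = cand
        if best is None:
            pos += 1
            continue
        edit, end, strand = best
        mono = seq[pos : pos + end]
        out.append(MonomerAnnotation(
            region_id=region_id, index=len(out), start=pos, end=pos + end,
            strand=strand, seq=mono if strand == "+" else revcomp(mono),
            edit_to_consensus=edit,
        ))
        pos += end
    return out


# ---------------------------------------------------------------------------
# consensus and variant profile


def _majority_columns(columns: list[dict[str, int]]) -> str:
    # lexicographic tie-break on equally frequent bases
    return "".join(
        max(sorted(col), key=lambda b: col[b]) for col in columns if col
    )


def build_consensus(monomer_seqs: list[str], refine: bool = True) -> str:
    """Majority-vote consensus: seeded from the monomers of the most common
    length, then refined once by aligning every monomer back to the seed
    and re-voting per column."""
    if len(monomer_seqs) < 2:
        raise ValueError("need >= 2 monomers")
    lengths = [len(s) for s in monomer_seqs]
    modal = max(sorted(set(lengths)), key=lengths.count)
    same = [s for s in monomer_seqs if len(s) == modal]
    columns = [dict() for _ in range(modal)]
    for s in same:
        for i, b in enumerate(s):
            columns[i][b] = columns[i].get(b, 0) + 1
    seed = _majority_columns(columns)
    if not refine:
        return seed
    columns = _aligned_columns(monomer_seqs, seed)
    return _majority_columns(columns)


def _aligned_columns(monomer_seqs: list[str], consensus: str
                     ) -> list[dict[str, int]]:
    """Per-consensus-column base counts from pairwise alignments; inserted
    monomer bases are skipped, deleted columns receive no vote."""
    u = len(consensus)
    columns: list[dict[str, int]] = [dict() for _ in range(u)]
    for s in monomer_seqs:
        res = edlib.align(s, consensus, mode="NW", task="path")
        ci = si = 0
        for op in _cigar_ops(res["cigar"]):
            kind, ln = op
            if kind in ("=", "X", "M"):
                for _ in range(ln):
                    columns[ci][s[si]] = columns[ci].get(s[si], 0) + 1
                    ci += 1
                    si += 1
            elif kind == "I":  # insertion in monomer relative to consensus
                si += ln
            elif kind == "D":  # consensus column deleted in monomer
                ci += ln
    return columns


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield ch, int(num)
            num = ""


def variant_profile(monomer_seqs: list[str], consensus: str) -> np.ndarray:
    """Per-consensus-position variant frequency: 1 - frequency of the most
    frequent base among the monomer bases aligned to that column."""
    columns = _aligned_columns(monomer_seqs, consensus)
    out = np.zeros(len(consensus))
    for i, col in enumerate(columns):
        total = sum(col.values())
        if total:
            out[i] = 1.0 - max(col.values()) / total
    return out


# ---------------------------------------------------------------------------
# HOR detection


def detect_hors(monomers: list[MonomerAnnotation],
                min_period: int = HOR_MIN_PERIOD,
                max_edit: int = HOR_MAX_EDIT) -> list[HOR]:
    """Find maximal tandem duplications: monomer i+j+p must be within
    max_edit of monomer i+j (its counterpart one period earlier) for every
    j in the duplicated span. Reported HORs are maximal per (start, period):
    not left-extendable and with the largest repeat count."""
    n = len(monomers)
    seqs = [m.seq for m in monomers]
    cache: dict[tuple[int, int], bool] = {}

    def ok(i: int, p: int) -> bool:
        key = (i, p)
        if key not in cache:
            cache[key] = edit_distance(seqs[i], seqs[i + p], max_edit) <= max_edit
        return cache[key]

    out: list[HOR] = []
    for p in range(min_period, n // 2 + 1):
        i = 0
        while i + 2 * p <= n:
            if (i > 0 and ok(i - 1, p)) or not all(ok(i + j, p) for j in range(p)):
                i += 1
                continue
            # extend: repeats r while every pair one period apart matches
            run = p
            while i + run + p < n and ok(i + run, p):
                run += 1
            r = 1 + run // p
            out.append(HOR(
                region_id=monomers[i].region_id, start_index=i, period=p,
                repeats=r,
                span_bp=monomers[i + p * r - 1].end - monomers[i].start,
            ))
            i += 1
    out.sort(key=lambda h: (h.start_index, h.period))
    return out


def hor_scores(monomers: list[MonomerAnnotation],
               hors: list[HOR]) -> np.ndarray:
    """Per-monomer score: number of HORs the monomer belongs to, divided by
    the total monomer count of its region."""
    n = len(monomers)
    counts = np.zeros(n)
    for h in hors:
        for i in h.monomer_indices:
            counts[i] += 1
    return counts / n if n else counts


def strand_bias(monomers: list[MonomerAnnotation]) -> tuple[float, float]:
    if not monomers:
        return 0.0, 0.0
    plus = sum(1 for m in monomers if m.strand == "+") / len(monomers)
    return plus, 1.0 - plus


# ---------------------------------------------------------------------------
# monomer-set similarity


def _canon(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def monomer_set_similarity(A, B) -> float:
    """Jaccard index over distinct strand-canonicalized monomer sequences;
    0 on an empty union."""
    sa = {_canon(s) for s in A}
    sb = {_canon(s) for s in B}
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


@dataclass
class Region:
    """A repeat region with its population labels."""

    genome: str
    chromosome: str
    region_id: str
    monomer_seqs: list[str]


def similarity_experiment(regions: list[Region], mode: str,
                          n_trials: int = 200, seed: int = 0
                          ) -> dict[str, np.ndarray]:
    """Random-pair similarity trials, intra vs inter at the requested level.

    mode 'genome'/'chromosome': each set is all monomers of a randomly
    chosen region; intra pairs share the genome/chromosome, inter pairs do
    not. mode 'subtelomere': each set is a random tenth of a region's
    monomers; intra draws two disjoint tenths of the same region, inter
    draws tenths of two different regions.
    """
    rng = np.random.default_rng(seed)
    intra, inter = [], []

    def label(r: Region):
        if mode == "genome":
            return r.genome
        if mode == "chromosome":
            return (r.genome, r.chromosome)
        if mode == "subtelomere":
            return (r.genome, r.chromosome, r.region_id)
        raise ValueError(f"unknown mode {mode!r}")

    idx = np.arange(len(regions))
    for _ in range(n_trials):
        if mode == "subtelomere":
            r = regions[rng.choice(idx)]
            tenth = max(1, len(r.monomer_seqs) // 10)
            perm = rng.permutation(len(r.monomer_seqs))
            a = [r.monomer_seqs[i] for i in perm[:tenth]]
            b = [r.monomer_seqs[i] for i in perm[tenth : 2 * tenth]]
            intra.append(monomer_set_similarity(a, b))
            r1, r2 = (regions[i] for i in rng.choice(idx, 2, replace=False))
            a = [r1.monomer_seqs[i] for i in
                 rng.choice(len(r1.monomer_seqs),
                            max(1, len(r1.monomer_seqs) // 10), replace=False)]
            b = [r2.monomer_seqs[i] for i in
                 rng.choice(len(r2.monomer_seqs),
                            max(1, len(r2.monomer_seqs) // 10), replace=False)]
            inter.append(monomer_set_similarity(a, b))
        else:
            r1, r2 = (regions[i] for i in rng.choice(idx, 2, replace=False))
            sim = monomer_set_similarity(r1.monomer_seqs, r2.monomer_seqs)
            (intra if label(r1) == label(r2) else inter).append(sim)
    return {"intra": np.array(intra), "inter": np.array(inter)}
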