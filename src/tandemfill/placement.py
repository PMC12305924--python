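"""Placing contigs on the reference TOI.

Fragmented contig-to-reference alignments are treated as *elements*
(aligned pairs of a reference interval and a contig interval). For each
candidate window of the TOI with the contig's length, the elements falling
inside the window are chained: the chain score is the length of the longest
non-decreasing subsequence (LIS) of contig indices when elements are read
in reference order — a fast approximation of the exact longest matching
subsequence (LMS) dynamic program, which is kept as the oracle. A genetic
algorithm then picks one candidate window (or none) per contig so that the
TOI is covered once (haploid) or twice (diploid), with a penalty for gaps
flanked by contigs from the same assembly-graph component and a reward for
spreading contigs out.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

DEFAULT_MAX_CANDIDATES = 7
MERGE_OVERLAP_FRAC = 0.5
SAME_COMPONENT_GAP_PENALTY = 2.5


@dataclass
class Element:
    """An aligned pair: a reference-TOI interval matched to a contig
    interval, with the alignment strand."""

    ref_start: int
    ref_end: int
    ctg_start: int
    ctg_end: int
    strand: str = "+"


@dataclass
class CandidatePlacement:
    """A scored window of the reference TOI where a contig may belong."""

    contig_id: str
    start: int
    end: int
    strand: str
    score: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def elements_from_alignments(alignments, toi_start: int = 0,
                             toi_end: int | None = None) -> list[Element]:
    """Convert PAF records of one contig vs the reference into TOI-local
    elements (alignments whose target midpoint is outside the TOI are
    skipped)."""
    out = []
    for a in alignments:
        mid = (a.target_start + a.target_end) / 2
        if mid < toi_start or (toi_end is not None and mid >= toi_end):
            continue
        out.append(
            Element(a.target_start - toi_start, a.target_end - toi_start,
                    a.query_start, a.query_end, a.strand)
        )
    return out


# ---------------------------------------------------------------------------
# contig filtering


def filter_contigs(contig_lengths: dict[str, int], alignments,
                   toi: tuple[str, int, int],
                   min_toi_frac: float = 0.10,
                   min_toi_ratio: float = 2.0) -> list[str]:
    """Keep a contig iff its TOI-aligned bases cover >= 10% of its length
    and are at least twice its off-TOI aligned bases."""
    chrom, start, end = toi
    toi_bp: dict[str, int] = {c: 0 for c in contig_lengths}
    off_bp: dict[str, int] = {c: 0 for c in contig_lengths}
    for a in alignments:
        if a.query_id not in contig_lengths:
            continue
        span = a.query_end - a.query_start
        mid = (a.target_start + a.target_end) / 2
        if a.target_id == chrom and start <= mid < end:
            toi_bp[a.query_id] += span
        else:
            off_bp[a.query_id] += span
    kept = []
    for c, ln in contig_lengths.items():
        if toi_bp[c] >= min_toi_frac * ln and toi_bp[c] >= min_toi_ratio * off_bp[c]:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# chain scores


def lms_score(A, B, match_fn) -> int:
    """Exact longest matching subsequence by O(N*M) dynamic programming
    (oracle; use lis_score on coordinate sequences in production)."""
    n, m = len(A), len(B)
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(dp[i - 1][j], dp[i][j - 1])
            if match_fn(A[i - 1], B[j - 1]):
                best = max(best, dp[i - 1][j - 1] + 1)
            dp[i][j] = best
    return int(dp[n][m])


def lis_score(L) -> int:
    """Length of the longest non-decreasing subsequence, O(M log M) via
    patience sorting with binary search."""
    tails: list = []
    for v in L:
        i = bisect_right(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)


# ---------------------------------------------------------------------------
# candidate enumeration


def _window_score(window_start: int, window_end: int, order: list[int],
                  mids: list[float]) -> tuple[int, str]:
    """Chain score of the elements whose reference midpoint lies in the
    window; contig indices read in reference order, non-decreasing for a
    plus-strand chain, non-increasing for minus."""
    L = [order[j] for j in range(len(order))
         if window_start <= mids[j] < window_end]
    if not L:
        return 0, "+"
    plus = lis_score(L)
    minus = lis_score([-v for v in L])
    return (plus, "+") if plus >= minus else (minus, "-")


def enumerate_candidates(contig_id: str, contig_len: int,
                         elements: list[Element], toi_len: int,
                         max_candidates: int = DEFAULT_MAX_CANDIDATES
                         ) -> list[CandidatePlacement]:
    """Anchor a window of the contig's length at every element's projected
    contig start, score each window by LIS chaining, merge windows that
    overlap by more than half, and keep the top windows by score."""
    if not elements:
        return []
    win_len = min(contig_len, toi_len)
    # elements in reference order; L values are contig-order indices
    by_ctg = sorted(range(len(elements)), key=lambda i: (elements[i].ctg_start,
                                                         elements[i].ctg_end))
    ctg_rank = {idx: r for r, idx in enumerate(by_ctg)}
    by_ref = sorted(range(len(elements)), key=lambda i: (elements[i].ref_start,
                                                         elements[i].ref_end))
    order = [ctg_rank[i] for i in by_ref]
    mids = [(elements[i].ref_start + elements[i].ref_end) / 2 for i in by_ref]

    starts = set()
    for e in elements:
        if e.strand == "+":
            ws = e.ref_start - e.ctg_start
        else:
            ws = e.ref_start - (contig_len - e.ctg_end)
        starts.add(int(min(max(ws, 0), toi_len - win_len)))

    scored = []
    for ws in sorted(starts):
        score, strand = _window_score(ws, ws + win_len, order, mids)
        if score > 0:
            scored.append(CandidatePlacement(contig_id, ws, ws + win_len,
                                             strand, score))
    scored.sort(key=lambda c: (-c.score, c.start))
    kept: list[CandidatePlacement] = []
    for cand in scored:
        overlaps = any(
            min(cand.end, k.end) - max(cand.start, k.start)
            > MERGE_OVERLAP_FRAC * win_len
            for k in kept
        )
        if not overlaps:
            kept.append(cand)
        if len(kept) == max_candidates:
            break
    return kept


# ---------------------------------------------------------------------------
# coverage objective


@dataclass
class CoverageProfile:
    """Depth bookkeeping over the reference TOI for one placement set."""

    toi_len: int
    l_by_depth: dict[int, int]  # depth t >= 1 -> total bp at depth t
    l0: int                     # uncovered bp with no same-component flanks
    l_neg: int                  # uncovered bp flanked by one component
    d_sum: float                # sum of pairwise midpoint distances
    n_placed: int

    def l_at(self, t: int) -> int:
        return self.l_by_depth.get(t, 0)

    @property
    def l_gt2(self) -> int:
        return sum(v for t, v in self.l_by_depth.items() if t > 2)

    @property
    def l_ge2(self) -> int:
        return sum(v for t, v in self.l_by_depth.items() if t >= 2)


def coverage_profile(placements: dict[str, CandidatePlacement], toi_len: int,
                     components: dict[str, int] | None = None) -> CoverageProfile:
    """Sweep the placed windows into a piecewise-constant depth profile.

    Zero-depth stretches whose nearest placed neighbours on both sides come
    from the same assembly-graph component are booked separately (they
    should not exist in a correct placement); stretches at the TOI ends or
    between different components count as plain uncovered sequence.
    """
    components = components or {}
    placed = sorted(placements.items())
    if not placed:
        return CoverageProfile(toi_len, {}, toi_len, 0, 0.0, 0)
    points = {0, toi_len}
    for _, p in placed:
        points.add(max(0, p.start))
        points.add(min(toi_len, p.end))
    cuts = sorted(points)
    l_by_depth: dict[int, int] = {}
    l0 = l_neg = 0
    for a, b in zip(cuts, cuts[1:]):
        depth = sum(1 for _, p in placed if p.start <= a and p.end >= b)
        if depth > 0:
            l_by_depth[depth] = l_by_depth.get(depth, 0) + (b - a)
            continue
        left = [(cid, p) for cid, p in placed if p.end <= a]
        right = [(cid, p) for cid, p in placed if p.start >= b]
        if left and right:
            lc = max(left, key=lambda t: t[1].end)[0]
            rc = min(right, key=lambda t: t[1].start)[0]
            if components.get(lc, -1) == components.get(rc, -2):
                l_neg += b - a
                continue
        l0 += b - a
    mids = [p.midpoint for _, p in placed]
    d_sum = float(sum(abs(mids[i] - mids[j])
                      for i in range(len(mids)) for j in range(i + 1, len(mids))))
    return CoverageProfile(toi_len, l_by_depth, l0, l_neg, d_sum, len(placed))


def adaptivity(profile: CoverageProfile, ploidy: int) -> float:
    """Fitness of a placement set: coverage terms push the TOI towards depth
    equal to the ploidy, same-component gaps are penalised harder, and the
    half-sum of pairwise midpoint distances discourages piling contigs up."""
    p = profile
    if ploidy == 1:
        return (2 * (p.l_at(1) - p.l0 - p.l_gt2) + p.l_at(2)
                - SAME_COMPONENT_GAP_PENALTY * p.l_neg + 0.5 * p.d_sum)
    if ploidy == 2:
        return (2 * (p.l_ge2 - p.l0) - p.l_at(1)
                - SAME_COMPONENT_GAP_PENALTY * p.l_neg + 0.5 * p.d_sum)
    raise ValueError("ploidy must be 1 or 2")


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass
class GAConfig:
    pop_size: int = 500
    n_select: int = 60
    n_offspring: int = 300
    mutation_prob: float = 0.05
    max_iter: int = 200
    top_equal: int = 10


@dataclass
class Individual:
    """One placement choice per retained contig; a missing contig is left
    unplaced."""

    assignment: dict[str, int]  # contig id -> candidate index
    adaptivity: float = 0.0


def _evaluate(assignment: dict[str, int], candidates, toi_len, ploidy,
              components, cache) -> float:
    key = tuple(sorted(assignment.items()))
    if key in cache:
        return cache[key]
    placements = {cid: candidates[cid][idx] for cid, idx in assignment.items()}
    fit = adaptivity(coverage_profile(placements, toi_len, components), ploidy)
    cache[key] = fit
    return fit


def run_ga(candidates: dict[str, list[CandidatePlacement]], toi_len: int,
           ploidy: int, components: dict[str, int] | None = None,
           config: GAConfig | None = None, seed: int = 0) -> Individual:
    """Evolve placement sets: 500 random individuals, fitness-proportional
    selection of 60, allele switching at one shared locus until 300
    offspring exist, 5% per-offspring mutation (drop a placed contig or
    place an unplaced one), the population refilled to 500 with fresh
    randoms; stops when the top 10 agree on fitness or after 200
    generations. Fully reproducible from the seed."""
    candidates = {c: v for c, v in candidates.items() if v}
    if not candidates:
        raise ValueError("no contig has any candidate placement")
    cfg = config or GAConfig()
    rng = np.random.default_rng(seed)
    contigs = sorted(candidates)
    cache: dict = {}

    def random_assignment() -> dict[str, int]:
        a = {}
        for c in contigs:
            choice = rng.integers(0, len(candidates[c]) + 1)
            if choice < len(candidates[c]):
                a[c] = int(choice)
        return a

    def fit(a) -> float:
        return _evaluate(a, candidates, toi_len, ploidy, components, cache)

    population = [random_assignment() for _ in range(cfg.pop_size)]
    best: Individual | None = None

    for _ in range(cfg.max_iter):
        fits = np.array([fit(a) for a in population])
        order = np.argsort(-fits, kind="stable")
        if best is None or fits[order[0]] > best.adaptivity:
            best = Individual(dict(population[order[0]]), float(fits[order[0]]))
        # convergence: the ten best *distinct* placement sets agree on
        # fitness (duplicates of one individual are takeover, not consensus)
        seen, top = set(), []
        for idx in order:
            key = tuple(sorted(population[idx].items()))
            if key not in seen:
                seen.add(key)
                top.append(fits[idx])
            if len(top) == cfg.top_equal:
                break
        if len(top) >= cfg.top_equal and top[0] == top[-1]:
            break
        # natural selection: probability proportional to shifted fitness
        weights = fits - fits.min() + 1.0
        probs = weights / weights.sum()
        chosen = rng.choice(len(population), size=min(cfg.n_select, len(population)),
                            replace=False, p=probs)
        parents = [population[i] for i in chosen]
        offspring: list[dict[str, int]] = []
        while len(offspring) < cfg.n_offspring:
            i, j = rng.integers(0, len(parents), size=2)
            a = dict(parents[i])
            b = dict(parents[j])
            locus = contigs[rng.integers(0, len(contigs))]
            a_val, b_val = a.pop(locus, None), b.pop(locus, None)
            if b_val is not None:
                a[locus] = b_val
            if a_val is not None:
                b[locus] = a_val
            for child in (a, b):
                if rng.random() < cfg.mutation_prob:
                    placed = [c for c in contigs if c in child]
                    unplaced = [c for c in contigs if c not in child]
                    moves = (["del"] if placed else []) + (["ins"] if unplaced else [])
                    if moves:
                        move = moves[rng.integers(0, len(moves))]
                        if move == "del":
                            child.pop(placed[rng.integers(0, len(placed))])
                        else:
                            c = unplaced[rng.integers(0, len(unplaced))]
                            child[c] = int(rng.integers(0, len(candidates[c])))
                if len(offspring) < cfg.n_offspring:
                    offspring.append(child)
        fresh = [random_assignment()
                 for _ in range(cfg.pop_size - len(parents) - len(offspring))]
        population = parents + offspring + fresh

    fits = np.array([fit(a) for a in population])
    i = int(np.argmax(fits))
    if best is None or fits[i] > best.adaptivity:
        best = Individual(dict(population[i]), float(fits[i]))
    return best


def brute_force_best(candidates: dict[str, list[CandidatePlacement]],
                     toi_len: int, ploidy: int,
                     components: dict[str, int] | None = None) -> Individual:
    """Exhaustive search over every assignment (oracle for small instances)."""
    contigs = sorted(c for c in candidates if candidates[c])
    best: Individual | None = None

    def rec(i: int, current: dict[str, int]):
        nonlocal best
        if i == len(contigs):
            placements = {c: candidates[c][k] for c, k in current.items()}
            f = adaptivity(coverage_profile(placements, toi_len, components), ploidy)
            if best is None or f > best.adaptivity:
                best = Individual(dict(current), f)
            return
        c = contigs[i]
        rec(i + 1, current)
        for k in range(len(candidates[c])):
            current[c] = k
            rec(i + 1, current)
        del current[c]

    rec(0, {})
    assert best is not None
    return best
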