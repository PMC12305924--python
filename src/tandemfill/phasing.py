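"""Haplotype phasing of placed contigs and scaffold emission.

Each contig takes one of four states — discarded, maternal, paternal, or
collapsed (present in both haplotypes). The objective rewards Hi-C pairs
(anchored by 31-mers unique across contigs and shores) linking contigs to
the shores of the same haplotype, rewards HiFi reads linking low-homology
contig pairs inside a haplotype while penalising links between
high-homology pairs (which are almost surely the two haplotypes of the
same locus), and penalises maternal/paternal length imbalance. The search
is hill-climbing over single-contig state changes with random restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import SequenceRecord, kmer_codes, kmer_set, revcomp

logger = logging.getLogger("tandemfill")

DISCARDED, MATERNAL, PATERNAL, COLLAPSED = 0, 1, 2, 3
STATES = (DISCARDED, MATERNAL, PATERNAL, COLLAPSED)

PHASING_K = 31
SHORE_PSEUDO_DISTANCE = 1000.0


@dataclass
class SignalMatrices:
    """Everything the phasing objective needs, on a fixed contig order."""

    contigs: list[str]
    shores_mat: list[str]
    shores_pat: list[str]
    hic: np.ndarray       # (n_shores, n_contigs) unique-k-mer Hi-C counts
    hifi: np.ndarray      # (n_contigs, n_contigs) HiFi link counts
    H: np.ndarray         # (n_contigs, n_contigs) homology coefficients
    D: np.ndarray         # (n_shores, n_contigs) shore-contig distances, bp > 0
    L_contig: np.ndarray  # contig lengths
    L_shore: np.ndarray   # shore lengths
    h_bar: float          # global homology coefficient
    l_toi_ref: float      # reference-TOI length
    c1: float = 1.0
    c2: float = 1.0
    c3: float = 1.0
    hic_scale: float = 1.0   # rescales the shore-contig Hi-C component
    pair_scale: float = 1.0  # rescales the contig-pair HiFi component

    @property
    def shores(self) -> list[str]:
        return self.shores_mat + self.shores_pat


# ---------------------------------------------------------------------------
# signals


def homology_coefficients(contigs: list[SequenceRecord],
                          k: int = PHASING_K) -> tuple[np.ndarray, float]:
    """h_ij = |S_i & S_j| / min(|S_i|, |S_j|) over distinct canonical
    k-mer sets; the global coefficient is the mean of the non-zero
    off-diagonal values (0 if none). Contigs shorter than k get an empty
    set and h = 0 by convention."""
    if len(contigs) < 2:
        raise ValueError("need >= 2 contigs")
    sets = [kmer_set(c.seq, k) for c in contigs]
    n = len(contigs)
    H = np.zeros((n, n))
    for i in range(n):
        H[i, i] = 1.0 if sets[i].size else 0.0
        for j in range(i + 1, n):
            denom = min(sets[i].size, sets[j].size)
            if denom == 0:
                continue
            inter = np.intersect1d(sets[i], sets[j], assume_unique=True).size
            H[i, j] = H[j, i] = inter / denom
    off = H[~np.eye(n, dtype=bool)]
    nonzero = off[off > 0]
    h_bar = float(nonzero.mean()) if nonzero.size else 0.0
    return H, h_bar


def unique_kmer_index(seqs: dict[str, str], k: int = PHASING_K) -> dict[int, str]:
    """Map each k-mer occurring exactly once across all sequences to the
    sequence carrying it."""
    owner: dict[int, str] = {}
    repeated: set[int] = set()
    for name, seq in seqs.items():
        codes, _ = kmer_codes(seq, k)
        uniq, counts = np.unique(codes, return_counts=True)
        for code, cnt in zip(uniq.tolist(), counts.tolist()):
            if code in repeated:
                continue
            if cnt > 1 or code in owner:
                repeated.add(code)
                owner.pop(code, None)
            else:
                owner[code] = name
    return owner


def _locate_end(seq: str, owner: dict[int, str], k: int) -> str | None:
    """Place one Hi-C read end by its unique k-mers; None if no unique
    k-mer hits or if hits point at more than one sequence (ambiguous)."""
    codes, _ = kmer_codes(seq, k)
    hits = {owner[c] for c in set(codes.tolist()) if c in owner}
    if len(hits) == 1:
        return hits.pop()
    return None


def unique_kmer_hic_signals(contigs: list[SequenceRecord],
                            shores: list[SequenceRecord],
                            hic_pairs: list[tuple[str, str, str]],
                            k: int = PHASING_K) -> dict[tuple[str, str], int]:
    """Count Hi-C pairs whose two ends are each anchored by unique k-mers
    to a single sequence; ambiguous or unlocatable ends drop the pair.
    Returns symmetric counts keyed by sorted (name_a, name_b)."""
    seqs = {r.id: r.seq for r in list(contigs) + list(shores)}
    if len(seqs) < len(contigs) + len(shores):
        raise ValueError("contig and shore names must be distinct")
    owner = unique_kmer_index(seqs, k)
    counts: dict[tuple[str, str], int] = {}
    for _, s1, s2 in hic_pairs:
        a = _locate_end(s1, owner, k) or _locate_end(revcomp(s1), owner, k)
        b = _locate_end(s2, owner, k) or _locate_end(revcomp(s2), owner, k)
        if a is None or b is None:
            continue
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    return counts


def hifi_link_signals(read_alignments) -> dict[tuple[str, str], int]:
    """A read aligning to contigs i and j adds one link to each pair it
    touches (once per read per pair); single-contig reads contribute
    nothing."""
    targets: dict[str, set[str]] = {}
    for a in read_alignments:
        targets.setdefault(a.query_id, set()).add(a.target_id)
    counts: dict[tuple[str, str], int] = {}
    for tset in targets.values():
        names = sorted(tset)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                key = (names[i], names[j])
                counts[key] = counts.get(key, 0) + 1
    return counts


def build_signal_matrices(contigs: list[SequenceRecord],
                          shores_mat: list[SequenceRecord],
                          shores_pat: list[SequenceRecord],
                          hic_counts: dict[tuple[str, str], int],
                          hifi_counts: dict[tuple[str, str], int],
                          contig_midpoints: dict[str, float],
                          shore_boundaries: dict[str, float],
                          l_toi_ref: float,
                          c1: float = 1.0, c2: float = 1.0, c3: float = 1.0,
                          k: int = PHASING_K,
                          normalize: bool = True) -> SignalMatrices:
    """Assemble the matrices for the phasing objective. Shore-contig
    distance is |shore inner boundary - contig placement midpoint| plus a
    1 kb pseudo-distance, on reference-TOI coordinates.

    With `normalize` (the default) the Hi-C and HiFi component matrices are
    each rescaled to unit total absolute mass, so the three components of
    the objective live on comparable scales and the unit default weights
    are meaningful regardless of region size, read depth or contig count.
    Raw per-entry terms span many orders of magnitude (counts divided by
    length and distance products), which would otherwise let the length
    -balance term dominate everything.
    """
    cnames = [c.id for c in contigs]
    snames = [s.id for s in shores_mat] + [s.id for s in shores_pat]
    nc, ns = len(cnames), len(snames)
    H, h_bar = homology_coefficients(contigs, k)
    hic = np.zeros((ns, nc))
    for si, s in enumerate(snames):
        for ci, c in enumerate(cnames):
            key = (s, c) if s <= c else (c, s)
            hic[si, ci] = hic_counts.get(key, 0)
    hifi = np.zeros((nc, nc))
    for i in range(nc):
        for j in range(i + 1, nc):
            hifi[i, j] = hifi[j, i] = hifi_counts.get(
                (min(cnames[i], cnames[j]), max(cnames[i], cnames[j])), 0)
    D = np.zeros((ns, nc))
    for si, s in enumerate(snames):
        for ci, c in enumerate(cnames):
            D[si, ci] = abs(shore_boundaries[s] - contig_midpoints[c]) \
                + SHORE_PSEUDO_DISTANCE
    hic_scale = pair_scale = 1.0
    if normalize:
        L_c = np.array([len(c.seq) for c in contigs], dtype=float)
        L_s = np.array([len(s.seq) for s in shores_mat + shores_pat],
                       dtype=float)
        shore_mass = float(np.abs(hic / (L_s[:, None] * L_c[None, :] * D)).sum())
        pair_mass = float(np.abs(
            np.triu((h_bar - H) * hifi / np.outer(L_c, L_c), k=1)
        ).sum())
        hic_scale = 1.0 / shore_mass if shore_mass > 0 else 1.0
        pair_scale = 1.0 / pair_mass if pair_mass > 0 else 1.0
    return SignalMatrices(
        contigs=cnames,
        shores_mat=[s.id for s in shores_mat],
        shores_pat=[s.id for s in shores_pat],
        hic=hic, hifi=hifi, H=H, D=D,
        L_contig=np.array([len(c.seq) for c in contigs], dtype=float),
        L_shore=np.array([len(s.seq) for s in shores_mat + shores_pat],
                         dtype=float),
        h_bar=h_bar, l_toi_ref=float(l_toi_ref), c1=c1, c2=c2, c3=c3,
        hic_scale=hic_scale, pair_scale=pair_scale,
    )


# ---------------------------------------------------------------------------
# objective


def _membership(state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mat = (state == MATERNAL) | (state == COLLAPSED)
    pat = (state == PATERNAL) | (state == COLLAPSED)
    return mat, pat


def _precompute(M: SignalMatrices):
    """Per-contig shore rewards and pairwise contig terms, so that the
    objective is a few dot products per state vector."""
    ns_mat = len(M.shores_mat)
    shore_term = M.hic_scale * M.hic / (
        M.L_shore[:, None] * M.L_contig[None, :] * M.D)
    w_mat = M.c1 * shore_term[:ns_mat].sum(axis=0)
    w_pat = M.c1 * shore_term[ns_mat:].sum(axis=0)
    pair = M.c2 * M.pair_scale * (M.h_bar - M.H) * M.hifi \
        / np.outer(M.L_contig, M.L_contig)
    pair = np.triu(pair, k=1)
    return w_mat, w_pat, pair


def phasing_objective(state, M: SignalMatrices) -> float:
    """Evaluate the three-component objective for one state vector."""
    state = np.asarray(state)
    if state.shape != (len(M.contigs),):
        raise ValueError("state vector length mismatch")
    mat, pat = _membership(state)
    w_mat, w_pat, pair = _precompute(M)
    f = float(w_mat @ mat + w_pat @ pat)
    f += float(mat @ pair @ mat + pat @ pair @ pat)
    diff = abs(float(M.L_contig @ mat) - float(M.L_contig @ pat))
    f -= M.c3 * diff / M.l_toi_ref
    return f


def _objective_batch(states: np.ndarray, M: SignalMatrices,
                     pre=None) -> np.ndarray:
    """Vectorised objective over an (n_states, n_contigs) state matrix."""
    w_mat, w_pat, pair = pre if pre is not None else _precompute(M)
    mat = (states == MATERNAL) | (states == COLLAPSED)
    pat = (states == PATERNAL) | (states == COLLAPSED)
    f = mat @ w_mat + pat @ w_pat
    f = f + np.einsum("si,ij,sj->s", mat, pair, mat)
    f = f + np.einsum("si,ij,sj->s", pat, pair, pat)
    diff = np.abs(mat @ M.L_contig - pat @ M.L_contig)
    return f - M.c3 * diff / M.l_toi_ref


def brute_force_phasing(M: SignalMatrices,
                        chunk: int = 1 << 16) -> tuple[np.ndarray, float]:
    """Exhaustive 4^n search (oracle for small n)."""
    n = len(M.contigs)
    pre = _precompute(M)
    best_state, best_f = None, -np.inf
    total = 4 ** n
    base = 4 ** np.arange(n)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        states = (idx[:, None] // base[None, :]) % 4
        f = _objective_batch(states, M, pre)
        i = int(np.argmax(f))
        if f[i] > best_f:
            best_f = float(f[i])
            best_state = states[i].copy()
    return best_state, best_f


# ---------------------------------------------------------------------------
# search


def run_annealing(M: SignalMatrices, n_restarts: int = 1000,
                  plateau: int = 100, perturb_frac: float = 0.5,
                  seed: int = 0,
                  pair_moves: bool = True) -> tuple[np.ndarray, float]:
    """Hill-climbing with restarts: single-contig state changes accepted
    only when they improve the objective; a local optimum is declared after
    `plateau` consecutive non-improving proposals; between the `n_restarts`
    outer rounds half the contigs are randomised. Returns the best state
    seen and its objective.

    When single-contig proposals plateau, all coordinated two-contig
    changes are scanned once (vectorised) before declaring a local
    optimum. This wider neighbourhood is essential for diploid phasing: a
    homologous contig pair assigned to swapped haplotypes cannot be
    repaired one contig at a time, because the intermediate state places
    two homologs on one haplotype and pays the homology penalty, so every
    single move out of the swap is rejected.
    """
    n = len(M.contigs)
    if n == 0:
        raise ValueError("need >= 1 contig")
    rng = np.random.default_rng(seed)
    w_mat, w_pat, pair = _precompute(M)
    psym = pair + pair.T  # row i = pair terms touching contig i
    L = M.L_contig

    def full_f(state) -> float:
        mat, pat = _membership(state)
        f = float(w_mat @ mat + w_pat @ pat)
        f += 0.5 * float(mat @ psym @ mat + pat @ psym @ pat)
        return f - M.c3 * abs(float(L @ mat) - float(L @ pat)) / M.l_toi_ref

    def proposal_delta(state, mat, pat, sum_m, sum_p, i, new) -> float:
        """Objective change from setting contig i to `new`, in O(n)."""
        m_old, p_old = mat[i], pat[i]
        m_new = new in (MATERNAL, COLLAPSED)
        p_new = new in (PATERNAL, COLLAPSED)
        d = 0.0
        row = psym[i]
        if m_new != m_old:
            sgn = 1.0 if m_new else -1.0
            d += sgn * (w_mat[i] + float(row @ mat) - row[i] * m_old)
        if p_new != p_old:
            sgn = 1.0 if p_new else -1.0
            d += sgn * (w_pat[i] + float(row @ pat) - row[i] * p_old)
        nm = sum_m + (m_new - m_old) * L[i]
        np_ = sum_p + (p_new - p_old) * L[i]
        d += M.c3 * (abs(sum_m - sum_p) - abs(nm - np_)) / M.l_toi_ref
        return d

    pre = (w_mat, w_pat, pair)
    if pair_moves and n >= 2:
        ii, jj = np.triu_indices(n, 1)
        combos = [(a, b) for a in range(4) for b in range(4)]

    def best_pair_move(state):
        """Best coordinated two-contig change, or None."""
        trials = np.repeat(state[None, :], len(ii) * len(combos), axis=0)
        row = 0
        for a, b in combos:
            block = slice(row, row + len(ii))
            trials[block][np.arange(len(ii)), ii] = a
            trials[block][np.arange(len(ii)), jj] = b
            row += len(ii)
        fs = _objective_batch(trials, M, pre)
        k = int(np.argmax(fs))
        return trials[k], float(fs[k])

    state = rng.integers(0, 4, size=n)
    best_state, best_f = state.copy(), full_f(state)
    for _ in range(n_restarts):
        mat, pat = _membership(state)
        mat, pat = mat.astype(float), pat.astype(float)
        sum_m, sum_p = float(L @ mat), float(L @ pat)
        cur_f = full_f(state)
        while True:
            stale = 0
            while stale < plateau:
                i = int(rng.integers(0, n))
                new = int(rng.integers(0, 4))
                if new == state[i]:
                    stale += 1
                    continue
                d = proposal_delta(state, mat, pat, sum_m, sum_p, i, new)
                if d > 0:
                    m_new = 1.0 if new in (MATERNAL, COLLAPSED) else 0.0
                    p_new = 1.0 if new in (PATERNAL, COLLAPSED) else 0.0
                    sum_m += (m_new - mat[i]) * L[i]
                    sum_p += (p_new - pat[i]) * L[i]
                    mat[i], pat[i] = m_new, p_new
                    state[i] = new
                    cur_f += d
                    stale = 0
                else:
                    stale += 1
            if not (pair_moves and n >= 2):
                break
            cand, f_cand = best_pair_move(state)
            if f_cand <= cur_f + 1e-12:
                break
            state = cand.copy()
            cur_f = f_cand
            mat, pat = _membership(state)
            mat, pat = mat.astype(float), pat.astype(float)
            sum_m, sum_p = float(L @ mat), float(L @ pat)
        if cur_f > best_f:
            best_f = cur_f
            best_state = state.copy()
        flip = rng.random(n) < perturb_frac
        state[flip] = rng.integers(0, 4, size=int(flip.sum()))
    return best_state, best_f


# ---------------------------------------------------------------------------
# scaffolds


def build_scaffolds(placements, state: dict[str, int],
                    contig_seqs: dict[str, str],
                    gap_n: int = 100,
                    haplotypes: tuple[str, ...] = ("maternal", "paternal")
                    ) -> dict[str, SequenceRecord]:
    """Join contigs into per-haplotype scaffolds in reference order,
    reverse-complementing minus-strand placements and separating contigs
    with a fixed run of N; collapsed contigs go to both haplotypes."""
    out = {}
    for hap, label in (("maternal", MATERNAL), ("paternal", PATERNAL)):
        if hap not in haplotypes:
            continue
        chosen = [
            (p.start, cid, p) for cid, p in sorted(placements.items())
            if state.get(cid, DISCARDED) in (label, COLLAPSED)
        ]
        chosen.sort()
        parts = []
        for _, cid, p in chosen:
            seq = contig_seqs[cid]
            parts.append(seq if p.strand == "+" else revcomp(seq))
        if not parts:
            logger.warning("no contigs assigned to %s haplotype", hap)
            out[hap] = SequenceRecord(hap, "")
        else:
            out[hap] = SequenceRecord(hap, ("N" * gap_n).join(parts))
    return out


def trim_shores(scaffold: SequenceRecord, shore_alignments,
                min_identity: float = 0.9,
                end_slack: int = 100) -> SequenceRecord:
    """Remove the scaffold prefix aligned to the left shore and the suffix
    aligned to the right shore (longest terminal block at >= 90% identity
    touching within 100 bp of the scaffold end). Internal-only shore
    alignments leave the scaffold unchanged, with a warning."""
    n = len(scaffold.seq)
    cut_left, cut_right = 0, n
    saw_internal = False
    for a in shore_alignments:
        if a.query_id != scaffold.id or a.identity < min_identity:
            continue
        if a.query_start <= end_slack:
            cut_left = max(cut_left, a.query_end)
        elif a.query_end >= n - end_slack:
            cut_right = min(cut_right, a.query_start)
        else:
            saw_internal = True
    if saw_internal and cut_left == 0 and cut_right == n:
        logger.warning(
            "scaffold %s has only internal shore alignments; not trimming",
            scaffold.id,
        )
    if cut_left >= cut_right:
        return SequenceRecord(scaffold.id, "")
    return SequenceRecord(scaffold.id, scaffold.seq[cut_left:cut_right])
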