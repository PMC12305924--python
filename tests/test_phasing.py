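"""Phasing signals, the three-component objective, search and scaffolds."""

import numpy as np
import pytest

from tandemfill.io import AlignmentRecord, SequenceRecord, revcomp
from tandemfill.phasing import (COLLAPSED, DISCARDED, MATERNAL, PATERNAL,
                                SignalMatrices, brute_force_phasing,
                                build_scaffolds,
                                hifi_link_signals, homology_coefficients,
                                phasing_objective, run_annealing, trim_shores,
                                unique_kmer_hic_signals)

from .conftest import random_dna


class TestHomology:
    def test_identical_contigs(self, rng):
        s = random_dna(rng, 300)
        H, h_bar = homology_coefficients(
            [SequenceRecord("a", s), SequenceRecord("b", s)])
        assert H[0, 1] == 1.0 and h_bar == 1.0

    def test_disjoint_contigs(self, rng):
        H, _ = homology_coefficients(
            [SequenceRecord("a", "A" * 100), SequenceRecord("b", "C" * 100)])
        assert H[0, 1] == 0.0

    def test_half_containment(self, rng):
        s = random_dna(rng, 400)
        H, _ = homology_coefficients(
            [SequenceRecord("a", s), SequenceRecord("b", s[:200])])
        assert H[0, 1] == 1.0  # S_b subset of S_a, denominator |S_b|

    def test_short_contig_zero_by_convention(self, rng):
        s = random_dna(rng, 300)
        H, _ = homology_coefficients(
            [SequenceRecord("a", s), SequenceRecord("b", "ACGT")])
        assert H[0, 1] == 0.0


class TestHicSignals:
    def _setup(self, rng):
        contig = SequenceRecord("ctg", random_dna(rng, 400))
        shore = SequenceRecord("shore", random_dna(rng, 400))
        return contig, shore

    def test_pair_anchored_to_two_sequences(self, rng):
        contig, shore = self._setup(rng)
        pairs = [("p1", shore.seq[50:110], contig.seq[100:160])]
        counts = unique_kmer_hic_signals([contig], [shore], pairs)
        assert counts == {("ctg", "shore"): 1}

    def test_repeat_only_end_dropped(self, rng):
        contig, shore = self._setup(rng)
        # an end made of k-mers occurring twice (in both contig and a copy)
        twin = SequenceRecord("twin", contig.seq)
        pairs = [("p1", shore.seq[50:110], contig.seq[100:160])]
        counts = unique_kmer_hic_signals([contig, twin], [shore], pairs)
        assert counts == {}

    def test_ambiguous_end_dropped(self, rng):
        contig, shore = self._setup(rng)
        other = SequenceRecord("other", random_dna(rng, 400))
        chimera = contig.seq[100:140] + other.seq[100:140]
        pairs = [("p1", shore.seq[50:110], chimera)]
        counts = unique_kmer_hic_signals([contig, other], [shore], pairs)
        assert counts == {}

    def test_duplicate_names_rejected(self, rng):
        contig, _ = self._setup(rng)
        with pytest.raises(ValueError):
            unique_kmer_hic_signals([contig], [SequenceRecord("ctg", "ACGT" * 20)], [])


class TestHifiSignals:
    def _aln(self, rid, tid):
        return AlignmentRecord(rid, 100, 0, 50, "+", tid, 1000, 0, 50, 50, 50)

    def test_read_spanning_two_contigs(self):
        counts = hifi_link_signals([self._aln("r", "c1"), self._aln("r", "c2")])
        assert counts == {("c1", "c2"): 1}

    def test_single_contig_read_no_link(self):
        assert hifi_link_signals([self._aln("r", "c1")]) == {}

    def test_three_contigs_three_pairs(self):
        alns = [self._aln("r", c) for c in ("c1", "c2", "c3")]
        counts = hifi_link_signals(alns)
        assert counts == {("c1", "c2"): 1, ("c1", "c3"): 1, ("c2", "c3"): 1}

    def test_once_per_read_per_pair(self):
        alns = [self._aln("r", "c1"), self._aln("r", "c1"),
                self._aln("r", "c2")]
        assert hifi_link_signals(alns) == {("c1", "c2"): 1}


def toy_matrices(n=3, seed=5, **kw):
    rng = np.random.default_rng(seed)
    H = rng.random((n, n))
    H = (H + H.T) / 2
    np.fill_diagonal(H, 1.0)
    hifi = rng.integers(0, 10, (n, n)).astype(float)
    hifi = (hifi + hifi.T) / 2
    np.fill_diagonal(hifi, 0)
    hic = rng.integers(0, 30, (2, n)).astype(float)
    D = rng.integers(1000, 30000, (2, n)).astype(float)
    L = rng.integers(2000, 9000, n).astype(float)
    off = H[np.triu_indices(n, 1)]
    h_bar = float(off[off > 0].mean()) if (off > 0).any() else 0.0
    return SignalMatrices([f"c{i}" for i in range(n)], ["sm"], ["sp"],
                          hic, hifi, H, D, L, np.array([5000.0, 5000.0]),
                          h_bar, 30000.0, **kw)


def literal_objective(state, M):
    """Independent, literal re-implementation of the printed objective."""
    mat_c = [i for i, s in enumerate(state) if s in (MATERNAL, COLLAPSED)]
    pat_c = [i for i, s in enumerate(state) if s in (PATERNAL, COLLAPSED)]
    ns_mat = len(M.shores_mat)
    f = 0.0
    for si in range(len(M.shores_mat + M.shores_pat)):
        side = mat_c if si < ns_mat else pat_c
        for j in side:
            f += M.c1 * M.hic_scale * M.hic[si, j] / (
                M.L_shore[si] * M.L_contig[j] * M.D[si, j])
    for side in (mat_c, pat_c):
        for a in range(len(side)):
            for b in range(a + 1, len(side)):
                i, j = min(side[a], side[b]), max(side[a], side[b])
                f += M.c2 * M.pair_scale * (M.h_bar - M.H[i, j]) * \
                    M.hifi[i, j] / (M.L_contig[i] * M.L_contig[j])
    lm = sum(M.L_contig[i] for i in mat_c)
    lp = sum(M.L_contig[i] for i in pat_c)
    return f - M.c3 * abs(lm - lp) / M.l_toi_ref


class TestObjective:
    def test_all_discarded_is_zero(self):
        M = toy_matrices()
        assert phasing_objective([DISCARDED] * 3, M) == 0.0

    def test_single_maternal_pays_only_balance(self):
        M = toy_matrices()
        M.hic[:] = 0
        M.hifi[:] = 0
        f = phasing_objective([MATERNAL, DISCARDED, DISCARDED], M)
        assert f == pytest.approx(-M.c3 * M.L_contig[0] / M.l_toi_ref)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_reimplementation(self, seed):
        M = toy_matrices(seed=seed)
        rng = np.random.default_rng(seed + 100)
        for _ in range(10):
            state = rng.integers(0, 4, size=3)
            assert phasing_objective(state, M) == pytest.approx(
                literal_objective(state, M), abs=1e-12)

    def test_swap_invariance(self):
        """Swapping maternal/paternal on all contigs AND all shores leaves
        the objective unchanged."""
        M = toy_matrices(n=4, seed=8)
        swapped = SignalMatrices(
            M.contigs, ["sp"], ["sm"],
            M.hic[::-1].copy(), M.hifi, M.H, M.D[::-1].copy(),
            M.L_contig, M.L_shore[::-1].copy(), M.h_bar, M.l_toi_ref)
        rng = np.random.default_rng(0)
        flip = {MATERNAL: PATERNAL, PATERNAL: MATERNAL,
                DISCARDED: DISCARDED, COLLAPSED: COLLAPSED}
        for _ in range(10):
            state = rng.integers(0, 4, size=4)
            mirror = np.array([flip[s] for s in state])
            assert phasing_objective(state, M) == pytest.approx(
                phasing_objective(mirror, swapped), abs=1e-12)

    def test_state_length_mismatch(self):
        with pytest.raises(ValueError):
            phasing_objective([0, 1], toy_matrices())


class TestAnnealing:
    def test_single_contig_enumerates_states(self):
        M = toy_matrices(n=1, seed=2)
        # make maternal clearly best
        M.hic[0, 0], M.hic[1, 0] = 50.0, 0.0
        state, f = run_annealing(M, n_restarts=20, seed=0)
        best = max(range(4), key=lambda s: phasing_objective([s], M))
        assert state[0] == best
        assert f == pytest.approx(phasing_objective([best], M))

    def test_matches_brute_force(self):
        ok = 0
        for seed in range(5):
            M = toy_matrices(n=6, seed=seed)
            _, bf = brute_force_phasing(M)
            _, f = run_annealing(M, n_restarts=100, seed=seed)
            ok += abs(f - bf) < 1e-9
        assert ok >= 4

    def test_reproducible(self):
        M = toy_matrices(n=6, seed=3)
        a = run_annealing(M, n_restarts=50, seed=7)
        b = run_annealing(M, n_restarts=50, seed=7)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]


class TestScaffolds:
    def test_join_with_gap(self):
        pl = {"a": _cand("a", 0, 4), "b": _cand("b", 10, 14)}
        out = build_scaffolds(pl, {"a": MATERNAL, "b": MATERNAL},
                              {"a": "AAAA", "b": "CCCC"}, gap_n=2)
        assert out["maternal"].seq == "AAAANNCCCC"
        assert out["paternal"].seq == ""

    def test_single_contig(self):
        pl = {"a": _cand("a", 0, 4)}
        out = build_scaffolds(pl, {"a": PATERNAL}, {"a": "AAAA"})
        assert out["paternal"].seq == "AAAA"

    def test_minus_strand_reverse_complemented(self):
        pl = {"a": _cand("a", 0, 4, "-")}
        out = build_scaffolds(pl, {"a": MATERNAL}, {"a": "AACG"})
        assert out["maternal"].seq == revcomp("AACG")

    def test_collapsed_in_both(self):
        pl = {"a": _cand("a", 0, 4)}
        out = build_scaffolds(pl, {"a": COLLAPSED}, {"a": "AAAA"})
        assert out["maternal"].seq == out["paternal"].seq == "AAAA"

    def test_reference_order(self):
        pl = {"late": _cand("late", 100, 104), "early": _cand("early", 0, 4)}
        out = build_scaffolds(pl, {"late": MATERNAL, "early": MATERNAL},
                              {"late": "TTTT", "early": "AAAA"}, gap_n=1)
        assert out["maternal"].seq == "AAAANTTTT"


def _cand(cid, s, e, strand="+"):
    from tandemfill.placement import CandidatePlacement

    return CandidatePlacement(cid, s, e, strand, 1)


class TestTrim:
    def _aln(self, scaffold_id, n, qs, qe, target="left_shore", ident=1.0):
        span = qe - qs
        return AlignmentRecord(scaffold_id, n, qs, qe, "+", target, 10_000,
                               0, span, int(span * ident), span, 60)

    def test_left_prefix_removed(self, rng):
        seq = random_dna(rng, 3000)
        sc = SequenceRecord("s", seq)
        out = trim_shores(sc, [self._aln("s", 3000, 0, 1000)])
        assert out.seq == seq[1000:]

    def test_no_alignment_unchanged(self, rng):
        sc = SequenceRecord("s", random_dna(rng, 500))
        assert trim_shores(sc, []).seq == sc.seq

    def test_both_ends_trimmed_middle_kept(self, rng):
        left, mid, right = (random_dna(rng, 800), random_dna(rng, 1000),
                            random_dna(rng, 700))
        sc = SequenceRecord("s", left + mid + right)
        alns = [self._aln("s", 2500, 0, 800),
                self._aln("s", 2500, 1800, 2500, target="right_shore")]
        assert trim_shores(sc, alns).seq == mid

    def test_internal_only_alignment_ignored(self, rng):
        seq = random_dna(rng, 3000)
        sc = SequenceRecord("s", seq)
        out = trim_shores(sc, [self._aln("s", 3000, 1200, 1500)])
        assert out.seq == seq

    def test_low_identity_ignored(self, rng):
        seq = random_dna(rng, 3000)
        sc = SequenceRecord("s", seq)
        out = trim_shores(sc, [self._aln("s", 3000, 0, 1000, ident=0.5)])
        assert out.seq == seq
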