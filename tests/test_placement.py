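"""Contig filtering, LMS/LIS chaining, coverage objective and the GA."""

import itertools

import numpy as np
import pytest

from tandemfill.io import AlignmentRecord
from tandemfill.placement import (CandidatePlacement, Element,
                                  adaptivity, brute_force_best,
                                  coverage_profile, elements_from_alignments,
                                  enumerate_candidates, filter_contigs,
                                  lis_score, lms_score, run_ga)


def brute_force_lis(L):
    """Longest non-decreasing subsequence by subset enumeration."""
    best = 0
    for r in range(len(L), 0, -1):
        for combo in itertools.combinations(L, r):
            if all(a <= b for a, b in zip(combo, combo[1:])):
                return r
    return best


class TestFilter:
    def _aln(self, cid, clen, tstart, tend, tid="ref"):
        span = tend - tstart
        return AlignmentRecord(cid, clen, 0, span, "+", tid, 100_000,
                               tstart, tend, span, span, 60)

    def test_short_toi_alignment_discarded(self):
        alns = [self._aln("c", 10_000, 50_000, 50_500)]
        assert filter_contigs({"c": 10_000}, alns, ("ref", 40_000, 90_000)) == []

    def test_off_target_ratio_discards(self):
        # 3 kb on the TOI vs 2 kb elsewhere: 3 < 2*2
        alns = [self._aln("c", 10_000, 50_000, 53_000),
                self._aln("c", 10_000, 5_000, 7_000)]
        assert filter_contigs({"c": 10_000}, alns, ("ref", 40_000, 90_000)) == []

    def test_passing_ratio_keeps(self):
        alns = [self._aln("c", 10_000, 50_000, 53_000),
                self._aln("c", 10_000, 5_000, 6_000)]
        assert filter_contigs({"c": 10_000}, alns, ("ref", 40_000, 90_000)) == ["c"]


class TestLmsLis:
    def test_lms_identity_and_disjoint(self):
        A = ["e1", "e2", "e3"]
        assert lms_score(A, A, lambda x, y: x == y) == 3
        assert lms_score(A, ["z1", "z2"], lambda x, y: x == y) == 0

    def test_lms_permuted(self):
        assert lms_score(["e1", "e2", "e3"], ["e2", "e1", "e3"],
                         lambda x, y: x == y) == 2

    @pytest.mark.parametrize("L,expected", [([3, 1, 2, 5, 4], 3),
                                            ([1, 2, 3, 4], 4),
                                            ([2, 2, 2], 3),
                                            ([], 0)])
    def test_lis_examples(self, L, expected):
        assert lis_score(L) == expected

    def test_lis_vs_brute_force(self):
        for seed in range(50):
            r = np.random.default_rng(seed)
            L = r.integers(0, 8, size=int(r.integers(1, 9))).tolist()
            assert lis_score(L) == brute_force_lis(L)

    def test_lis_bounded_by_lms(self):
        """On random one-to-one element matchings, LIS on the coordinate
        sequence equals the exact LMS chain; in general it never exceeds."""
        for seed in range(200):
            r = np.random.default_rng(seed)
            n = int(r.integers(1, 13))
            perm = r.permutation(n).tolist()  # L: contig indices in ref order
            A = list(range(n))       # contig-side elements (sorted)
            B = perm                 # ref-side order
            lms = lms_score(B, A, lambda x, y: x == y)
            lis = lis_score(perm)
            assert lis <= lms
            # one-to-one matching: the two are the same chain length
            assert lis == lms


class TestCandidates:
    def test_single_full_length_alignment(self):
        els = [Element(100, 600, 0, 500, "+")]
        cands = enumerate_candidates("c", 500, els, 10_000)
        assert len(cands) == 1
        assert (cands[0].start, cands[0].end) == (100, 600)
        assert cands[0].score == 1

    def test_multi_anchor_windows_capped(self):
        els = [Element(s, s + 100, 0, 100, "+") for s in (0, 3000, 6000)]
        cands = enumerate_candidates("c", 1000, els, 10_000)
        assert 1 <= len(cands) <= 3

    def test_top7_and_merging(self):
        els = [Element(s, s + 50, 0, 50, "+") for s in range(0, 9000, 200)]
        cands = enumerate_candidates("c", 400, els, 10_000)
        assert len(cands) <= 7
        for a, b in itertools.combinations(cands, 2):
            ov = min(a.end, b.end) - max(a.start, b.start)
            assert ov <= 0.5 * 400

    def test_no_elements_empty(self):
        assert enumerate_candidates("c", 500, [], 10_000) == []

    def test_window_score_matches_lms_oracle(self):
        """Colinear fragmented alignments: window LIS score = exact LMS."""
        for seed in range(30):
            r = np.random.default_rng(seed)
            n = int(r.integers(2, 12))
            starts = np.sort(r.choice(900, size=n, replace=False))
            els = [Element(int(100 + s), int(100 + s + 20), int(s),
                           int(s + 20), "+") for s in starts]
            cands = enumerate_candidates("c", 1000, els, 5000)
            lms = lms_score(list(range(n)), list(range(n)),
                            lambda x, y: x == y)
            assert cands[0].score == lms == n


class TestCoverage:
    def test_single_cover(self):
        p = {"c": CandidatePlacement("c", 0, 1000, "+", 1)}
        prof = coverage_profile(p, 1000)
        assert prof.l_at(1) == 1000 and prof.l0 == 0 and prof.l_neg == 0

    def test_same_component_gap(self):
        p = {"a": CandidatePlacement("a", 0, 400, "+", 1),
             "b": CandidatePlacement("b", 500, 1000, "+", 1)}
        prof = coverage_profile(p, 1000, components={"a": 0, "b": 0})
        assert prof.l_neg == 100 and prof.l0 == 0
        prof2 = coverage_profile(p, 1000, components={"a": 0, "b": 1})
        assert prof2.l_neg == 0 and prof2.l0 == 100

    def test_overlap_depth(self):
        p = {"a": CandidatePlacement("a", 0, 600, "+", 1),
             "b": CandidatePlacement("b", 400, 1000, "+", 1)}
        prof = coverage_profile(p, 1000)
        assert prof.l_at(2) == 200 and prof.l_at(1) == 800

    def test_end_gaps_are_plain_uncovered(self):
        p = {"a": CandidatePlacement("a", 200, 800, "+", 1)}
        prof = coverage_profile(p, 1000, components={"a": 0})
        assert prof.l0 == 400 and prof.l_neg == 0


class TestAdaptivity:
    def test_haploid_exact_tiling(self):
        p = {"c": CandidatePlacement("c", 0, 5000, "+", 1)}
        assert adaptivity(coverage_profile(p, 5000), 1) == 2 * 5000

    def test_haploid_empty(self):
        assert adaptivity(coverage_profile({}, 5000), 1) == -2 * 5000

    def test_diploid_two_disjoint_single_copies(self):
        # l_1 = L gives -L, plus half the pairwise midpoint distance
        p = {"a": CandidatePlacement("a", 0, 500, "+", 1),
             "b": CandidatePlacement("b", 500, 1000, "+", 1)}
        d12 = abs(250 - 750)
        f = adaptivity(coverage_profile(p, 1000), 2)
        assert f == -1000 + 0.5 * d12

    def test_invalid_ploidy(self):
        with pytest.raises(ValueError):
            adaptivity(coverage_profile({}, 100), 3)

    def test_relabeling_invariance(self):
        p1 = {"a": CandidatePlacement("a", 0, 400, "+", 1),
              "b": CandidatePlacement("b", 300, 900, "+", 1)}
        p2 = {"x": CandidatePlacement("x", 0, 400, "+", 1),
              "y": CandidatePlacement("y", 300, 900, "+", 1)}
        assert adaptivity(coverage_profile(p1, 1000), 1) == \
            adaptivity(coverage_profile(p2, 1000), 1)


class TestGa:
    def test_single_perfect_candidate(self):
        cands = {"c": [CandidatePlacement("c", 0, 1000, "+", 5)]}
        best = run_ga(cands, 1000, 1, seed=3)
        assert best.assignment == {"c": 0}
        assert best.adaptivity == 2000

    def test_no_candidates_raises(self):
        with pytest.raises(ValueError):
            run_ga({"c": []}, 1000, 1, seed=0)

    def test_reproducible(self):
        cands = {f"c{i}": [CandidatePlacement(f"c{i}", s, s + 300, "+", 1)
                           for s in (0, 400, 800)] for i in range(3)}
        a = run_ga(cands, 1200, 1, seed=9)
        b = run_ga(cands, 1200, 1, seed=9)
        assert a.assignment == b.assignment and a.adaptivity == b.adaptivity

    def test_double_covering_contig_dropped_in_haploid(self):
        """A contig whose every candidate doubles coverage is left out."""
        cands = {
            "good": [CandidatePlacement("good", 0, 1000, "+", 9)],
            "dup": [CandidatePlacement("dup", 0, 1000, "+", 1),
                    CandidatePlacement("dup", 0, 1000, "-", 1)],
        }
        best = run_ga(cands, 1000, 1, seed=4)
        assert "dup" not in best.assignment

    def test_matches_brute_force_small(self):
        ok = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            cands = {}
            for ci in range(int(r.integers(2, 5))):
                lst = []
                for _ in range(int(r.integers(1, 4))):
                    clen = int(r.integers(500, 3000))
                    s = int(r.integers(0, 8000 - clen))
                    lst.append(CandidatePlacement(f"c{ci}", s, s + clen, "+", 1))
                cands[f"c{ci}"] = lst
            ploidy = 1 + seed % 2
            bf = brute_force_best(cands, 8000, ploidy)
            ga = run_ga(cands, 8000, ploidy, seed=seed)
            ok += ga.adaptivity == pytest.approx(bf.adaptivity)
        assert ok == 5


def test_elements_from_alignments_toi_local():
    a = AlignmentRecord("c", 1000, 10, 200, "+", "ref", 9000, 4010, 4200,
                        190, 190, 60)
    off = AlignmentRecord("c", 1000, 10, 200, "+", "ref", 9000, 100, 290,
                          190, 190, 60)
    els = elements_from_alignments([a, off], toi_start=4000, toi_end=9000)
    assert len(els) == 1
    assert (els[0].ref_start, els[0].ref_end) == (10, 200)
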