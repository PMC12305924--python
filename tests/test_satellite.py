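"""Monomer annotation, consensus/variants, HOR detection, similarity."""

import numpy as np
import pytest

from tandemfill.io import revcomp
from tandemfill.satellite import (HOR, MonomerAnnotation, Region,
                                  annotate_monomers, build_consensus,
                                  detect_hors, edit_distance, hor_scores,
                                  monomer_set_similarity,
                                  similarity_experiment, strand_bias,
                                  variant_profile)

from .conftest import random_dna


def make_monomers(seqs, region="r"):
    out, pos = [], 0
    for i, s in enumerate(seqs):
        out.append(MonomerAnnotation(region, i, pos, pos + len(s), "+", s, 0))
        pos += len(s)
    return out


def brute_force_hors(monomers, min_period=3, max_edit=5):
    """Independent oracle: enumerate every (i, p, r) directly from the
    duplication definition, keeping the triples with maximal repeat count
    that are not a phase-shifted continuation of the same periodic run
    (i.e. the run cannot be extended one monomer to the left)."""
    seqs = [m.seq for m in monomers]
    n = len(seqs)
    keep = []
    for p in range(min_period, n):
        for i in range(n):
            r = 1
            while i + (r + 1) * p <= n and all(
                edit_distance(seqs[i + j], seqs[i + j + p]) <= max_edit
                for j in range((r - 1) * p, r * p)
            ):
                r += 1
            if r < 2:
                continue
            if i > 0 and edit_distance(seqs[i - 1], seqs[i - 1 + p]) <= max_edit:
                continue
            keep.append((i, p, r))
    return sorted(keep)


class TestAnnotate:
    def test_exact_repeats(self, rng):
        cons = random_dna(rng, 60)
        monomers = annotate_monomers(cons * 5, cons)
        assert len(monomers) == 5
        assert all(m.edit_to_consensus == 0 and m.strand == "+"
                   for m in monomers)
        assert [m.start for m in monomers] == [0, 60, 120, 180, 240]

    def test_reverse_strand(self, rng):
        cons = random_dna(rng, 60)
        monomers = annotate_monomers(revcomp(cons) * 3, cons)
        assert len(monomers) == 3
        assert all(m.strand == "-" for m in monomers)
        assert all(m.seq == cons for m in monomers)  # oriented to consensus

    def test_random_sequence_yields_nothing(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            cons = random_dna(r, 181)
            noise = random_dna(r, 2000)
            assert annotate_monomers(noise, cons) == []

    def test_mutated_copies_found(self, rng):
        from tandemfill.simdata import mutate

        cons = random_dna(rng, 100)
        arr = "".join(mutate(cons, 0.05, rng) for _ in range(6))
        monomers = annotate_monomers(arr, cons)
        assert len(monomers) == 6

    def test_short_consensus_rejected(self):
        with pytest.raises(ValueError):
            annotate_monomers("ACGT" * 100, "ACGTACGT")


class TestConsensus:
    def test_identical_monomers(self, rng):
        m = random_dna(rng, 80)
        cons = build_consensus([m] * 5)
        assert cons == m
        assert variant_profile([m] * 5, cons).max() == 0.0

    def test_single_substitution_column(self, rng):
        m = random_dna(rng, 80)
        alt = m[:5] + ("A" if m[5] != "A" else "C") + m[6:]
        seqs = [m] * 9 + [alt]
        cons = build_consensus(seqs)
        assert cons == m
        prof = variant_profile(seqs, cons)
        assert prof[5] == pytest.approx(0.1)
        assert prof.sum() == pytest.approx(0.1)

    def test_majority_tie_lexicographic(self):
        seqs = ["AAAAAAAAAAAAAAAAAAAAA", "AAAAAAAAAACAAAAAAAAAA"]
        cons = build_consensus(seqs)
        # column 10 ties A vs C -> lexicographically smaller base wins
        assert cons[10] == "A"
        prof = variant_profile(seqs, cons)
        assert prof[10] == pytest.approx(0.5)


class TestHors:
    def test_six_identical_monomers(self, rng):
        ms = make_monomers([random_dna(rng, 60)] * 6)
        hors = detect_hors(ms)
        assert any((h.start_index, h.period, h.repeats) == (0, 3, 2)
                   for h in hors)

    def test_five_monomers_no_hor(self, rng):
        ms = make_monomers([random_dna(rng, 60)] * 5)
        assert all(h.period > 3 or h.repeats < 2 for h in detect_hors(ms)) \
            or detect_hors(ms) == []

    def test_excess_edits_break_period(self, rng):
        m = random_dna(rng, 60)
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        bad = "".join(sub[b] if i % 5 == 0 else b for i, b in enumerate(m))
        assert edit_distance(m, bad) > 5
        ms = make_monomers([m, m, m, bad, m, m])
        assert not any(h.start_index == 0 and h.period == 3
                       for h in detect_hors(ms))

    def test_planted_abc_block_detected(self, rng):
        from tandemfill.simdata import mutate

        a, b, c = (random_dna(rng, 60) for _ in range(3))
        seqs = []
        for _ in range(4):  # (ABC) x 4, each copy with <= 2 light edits
            for base in (a, b, c):
                seqs.append(mutate(base, 0.02, rng))
        hors = detect_hors(make_monomers(seqs))
        spanning = [h for h in hors if h.period == 3
                    and h.start_index == 0 and h.repeats == 4]
        assert spanning

    def test_matches_brute_force_enumeration(self):
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = int(r.integers(6, 31))
            alphabet = [random_dna(r, 40) for _ in range(int(r.integers(1, 4)))]
            from tandemfill.simdata import mutate

            seqs = [mutate(alphabet[int(r.integers(0, len(alphabet)))],
                           0.04, r) for _ in range(n)]
            ms = make_monomers(seqs)
            got = sorted((h.start_index, h.period, h.repeats)
                         for h in detect_hors(ms))
            assert got == brute_force_hors(ms)


class TestScores:
    def test_hor_score_formula(self, rng):
        ms = make_monomers([random_dna(rng, 60)] * 10)
        hors = [HOR("r", 0, 3, 2, 360), HOR("r", 1, 3, 2, 360)]
        scores = hor_scores(ms, hors)
        # monomer 3 sits in both HOR spans [0,6) and [1,7)
        assert scores[3] == pytest.approx(0.2)
        assert scores[9] == 0.0

    def test_strand_bias(self, rng):
        ms = make_monomers([random_dna(rng, 60)] * 4)
        assert strand_bias(ms) == (1.0, 0.0)
        ms[0].strand = "-"
        plus, minus = strand_bias(ms)
        assert plus == 0.75 and minus == 0.25


class TestSimilarity:
    def test_identical_sets(self):
        A = ["ACGTACGTAC", "TTTTGGGGCC"]
        assert monomer_set_similarity(A, A) == 1.0

    def test_disjoint(self):
        assert monomer_set_similarity(["AAAAACCCCC"], ["AAAAAGGGGG"]) == 0.0

    def test_jaccard_arithmetic(self, rng):
        seqs = [random_dna(rng, 30) for _ in range(8)]
        A, B = seqs[:5], seqs[3:]  # intersection 2, union 8
        assert monomer_set_similarity(A, B) == pytest.approx(2 / 8)

    def test_strand_canonicalization(self, rng):
        s = random_dna(rng, 30)
        assert monomer_set_similarity([s], [revcomp(s)]) == 1.0

    def test_empty_union(self):
        assert monomer_set_similarity([], []) == 0.0

    def test_genome_mode_partitions_pairs(self, rng):
        from tandemfill.simdata import mutate

        regions = []
        for g in ("g1", "g2"):
            for k in range(2):
                base = random_dna(rng, 40)
                regions.append(Region(g, "chr1", f"{g}r{k}",
                                      [mutate(base, 0.02, rng)
                                       for _ in range(20)]))
        out = similarity_experiment(regions, "genome", n_trials=60, seed=1)
        assert len(out["intra"]) + len(out["inter"]) == 60
        assert len(out["intra"]) > 0 and len(out["inter"]) > 0

    def test_local_drift_law(self, rng):
        """Regions with region-local monomer drift: intra-region tenths are
        much more similar than cross-region tenths."""
        from scipy.stats import mannwhitneyu

        from tandemfill.simdata import mutate

        regions = []
        for g in range(5):
            base = random_dna(rng, 60)
            seqs = [mutate(base, 0.03, rng) for _ in range(120)]
            # duplications within the region create shared monomers
            seqs += [s for s in seqs[:60]]
            regions.append(Region("g", "chr1", f"reg{g}", seqs))
        out = similarity_experiment(regions, "subtelomere", n_trials=100,
                                    seed=5)
        assert np.median(out["intra"]) > np.median(out["inter"])
        p = mannwhitneyu(out["intra"], out["inter"],
                         alternative="greater").pvalue
        assert p < 0.01
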