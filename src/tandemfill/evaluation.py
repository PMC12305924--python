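"""Assembly-quality metrics against a ground truth.

Completeness is the truth-side fraction covered by continuous alignment
blocks; correctness is the assembly-side fraction; the LIS identity score
chains k-mers unique in both sequences and measures how colinear the
assembly is with the truth. The strictly/loosely-improved classifiers are
pure rules over externally computed reference-free quality indices (R_AQI,
S_AQI) and read coverages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import kmer_codes, revcomp
from .placement import lis_score

EVAL_K = 31


@dataclass
class QualityReport:
    completeness: float
    correctness: float
    lis_score: float
    correct_bp_truth: int
    correct_bp_asm: int
    truth_len: int
    asm_len: int


@dataclass
class ImprovementInputs:
    r_aqi_ori: float
    s_aqi_ori: float
    r_aqi_new: float
    s_aqi_new: float
    cov_ori: float
    cov_new: float
    cov_whole: float


def _union_len(intervals) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def completeness_correctness(asm_vs_truth, truth_len: int, asm_len: int,
                             lis: float = 0.0) -> QualityReport:
    """Union of aligned blocks on each side (no double counting), divided by
    the respective total lengths."""
    if truth_len <= 0 or asm_len <= 0:
        raise ValueError("truth and assembly lengths must be positive")
    truth_iv = [(a.target_start, a.target_end) for a in asm_vs_truth]
    asm_iv = [(a.query_start, a.query_end) for a in asm_vs_truth]
    bp_truth = _union_len(truth_iv)
    bp_asm = _union_len(asm_iv)
    return QualityReport(
        completeness=bp_truth / truth_len,
        correctness=bp_asm / asm_len,
        lis_score=lis,
        correct_bp_truth=bp_truth,
        correct_bp_asm=bp_asm,
        truth_len=truth_len,
        asm_len=asm_len,
    )


def _unique_positions(seq: str, k: int) -> dict[int, int]:
    """canonical code -> position, for k-mers occurring exactly once."""
    codes, starts = kmer_codes(seq, k)
    uniq, idx, counts = np.unique(codes, return_index=True, return_counts=True)
    keep = counts == 1
    return {int(c): int(starts[i]) for c, i in zip(uniq[keep], idx[keep])}


def lis_identity_score(truth_seq: str, asm_seq: str, k: int = EVAL_K) -> float:
    """Chain the k-mers unique within BOTH sequences: order them by assembly
    position, take their truth positions, and divide the longest
    non-decreasing subsequence length by the number of unique k-mers in the
    assembly. Both orientations of the assembly are tried (canonical k-mers
    make matching strand-blind; colinearity is not) and the better score is
    returned. 0 when the assembly has no unique k-mers."""
    best = 0.0
    for asm in (asm_seq, revcomp(asm_seq)):
        asm_pos = _unique_positions(asm, k)
        if not asm_pos:
            continue
        truth_pos = _unique_positions(truth_seq, k)
        shared = [(p, truth_pos[c]) for c, p in asm_pos.items() if c in truth_pos]
        shared.sort()
        L = [t for _, t in shared]
        best = max(best, lis_score(L) / len(asm_pos))
    return best


def classify_improvement(inp: ImprovementInputs) -> str:
    """'strict' when the repair quality index rises by more than 10%;
    'loose' when it rises at all, or drops by less than the 1.6 factor
    while the structural index improves and the read coverage moves towards
    the genome-wide average; 'none' otherwise. A strict call implies the
    loose condition also holds."""
    strict = inp.r_aqi_new > inp.r_aqi_ori * 1.1
    loose = inp.r_aqi_new > inp.r_aqi_ori or (
        inp.r_aqi_new > inp.r_aqi_ori / 1.6
        and inp.s_aqi_new > inp.s_aqi_ori
        and abs(inp.cov_whole - inp.cov_new) < abs(inp.cov_whole - inp.cov_ori)
    )
    if strict:
        return "strict"
    if loose:
        return "loose"
    return "none"
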