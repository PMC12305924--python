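"""Recruiting the HiFi reads that belong to a target repeat region.

Any read partially aligned to the reference TOI is a candidate; a rare-k-mer
hypothesis test then removes reads that originate from other repeats. For an
alignment between a reference region R and a read region Q, let y be the
number of distinct rare k-mers in R and x the number of those also present
in Q. Under homology, X ~ Normal(delta*y, sigma^2) with region-constant
delta (0 <= delta < 1) and technology-constant sigma^2; the read is recalled
when x falls inside the central 1-alpha interval of that normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import AlignmentRecord, kmer_codes, revcomp

logger = logging.getLogger("tandemfill")

_SIGMA2_EPS = 1e-9

#: fallback model parameters for zero-config runs, when no training
#: observations from a trusted homologous region are supplied. The
#: fallback is deliberately permissive: HiFi-scale alignments carry rare
#: k-mer counts y in the thousands, so sigma = 250 accepts roughly
#: +-10% around the expected sharing at y ~ 5000 while still rejecting
#: strongly diverged off-target reads. Fitting from training
#: observations is always preferable.
DEFAULT_DELTA = 0.85
DEFAULT_SIGMA2 = 62500.0


class ModelFitError(ValueError):
    pass


@dataclass
class AlignmentObservation:
    """Rare-k-mer counts for one candidate alignment: y in the reference
    region, x shared with the read region (0 <= x <= y)."""

    read_id: str
    x: int
    y: int

    def __post_init__(self):
        if not 0 <= self.x <= self.y:
            raise ValueError(f"observation {self.read_id}: need 0 <= x <= y")


@dataclass
class RecallModel:
    """Fitted (delta, sigma^2) plus the significance parameters of the
    two-sided recall test."""

    delta: float
    sigma2: float
    alpha: float = 0.05
    k: int = 21
    rare_max_count: int = 3

    def __post_init__(self):
        if not 0 <= self.delta < 1:
            raise ValueError("delta must be in [0, 1)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def z_half_alpha(self) -> float:
        return float(stats.norm.ppf(1 - self.alpha / 2))


def extract_rare_kmers(spectrum_codes: np.ndarray, counts: np.ndarray,
                       rare_max_count: int = 3) -> np.ndarray:
    """Canonical k-mer codes whose genome-wide count is <= rare_max_count
    (default 3, i.e. 'appearing less than 4 times')."""
    return spectrum_codes[counts <= rare_max_count]


def observe_alignment(aln: AlignmentRecord, ref_seq: str, read_seq: str,
                      rare_codes: np.ndarray, k: int = 21) -> AlignmentObservation:
    """Count distinct rare k-mers in the aligned reference substring (y) and
    how many of those also occur in the aligned read substring (x).

    Presence in Q is set membership of canonical k-mers, not positional
    correspondence, since HiFi indels shift positions. Minus-strand reads are
    reverse-complemented first (canonical codes make this a no-op for the
    counts, but Q is still sliced on read coordinates).
    """
    R = ref_seq[aln.target_start : aln.target_end]
    q = read_seq if aln.strand == "+" else revcomp(read_seq)
    Q = (
        q[aln.query_start : aln.query_end]
        if aln.strand == "+"
        else q[len(q) - aln.query_end : len(q) - aln.query_start]
    )
    if len(R) < k or len(Q) < k:
        return AlignmentObservation(aln.query_id, 0, 0)
    r_codes = np.unique(kmer_codes(R, k)[0])
    r_rare = r_codes[np.isin(r_codes, rare_codes, assume_unique=True)]
    y = int(r_rare.size)
    if y == 0:
        return AlignmentObservation(aln.query_id, 0, 0)
    q_codes = np.unique(kmer_codes(Q, k)[0])
    x = int(np.isin(r_rare, q_codes, assume_unique=True).sum())
    return AlignmentObservation(aln.query_id, x, y)


def fit_recall_model(observations, alpha: float = 0.05, k: int = 21,
                     rare_max_count: int = 3) -> RecallModel:
    """Maximum-likelihood fit of (delta, sigma^2) from training observations.

    delta = sum(y_i x_i) / sum(y_i^2); sigma^2 = mean squared residual
    (the MLE of the normal model; delta is clamped to [0, 1) and sigma^2
    floored at a small epsilon).
    """
    obs = list(observations)
    with_y = [o for o in obs if o.y > 0]
    if len(with_y) < 2:
        raise ModelFitError("need >= 2 observations with y > 0")
    x = np.array([o.x for o in obs], dtype=float)
    y = np.array([o.y for o in obs], dtype=float)
    delta = float((y * x).sum() / (y * y).sum())
    if delta >= 1.0:
        logger.warning("fitted delta %.4f clamped to just below 1", delta)
        delta = 1.0 - 1e-9
    delta = max(delta, 0.0)
    sigma2 = float(((x - delta * y) ** 2).mean())
    sigma2 = max(sigma2, _SIGMA2_EPS)
    return RecallModel(delta, sigma2, alpha=alpha, k=k, rare_max_count=rare_max_count)


def default_model(alpha: float = 0.05) -> RecallModel:
    logger.warning(
        "no training observations supplied; using packaged fallback "
        "delta=%.2f sigma2=%.1f", DEFAULT_DELTA, DEFAULT_SIGMA2,
    )
    return RecallModel(DEFAULT_DELTA, DEFAULT_SIGMA2, alpha=alpha)


def test_alignment(model: RecallModel, obs: AlignmentObservation) -> bool:
    """Two-sided test: accept iff delta*y - z*sigma <= x <= delta*y + z*sigma
    (boundary inclusive)."""
    sigma = model.sigma2 ** 0.5
    half = model.z_half_alpha * sigma
    center = model.delta * obs.y
    return center - half <= obs.x <= center + half


def recall_reads(alignments, reads, ref_seq: str, model: RecallModel,
                 rare_codes: np.ndarray) -> set[str]:
    """Recall every read with at least one TOI alignment passing the test.

    `alignments` must already be restricted to those overlapping the
    reference TOI (target coordinates on `ref_seq`). Reads with zero TOI
    alignments are never recalled.
    """
    by_id = {r.id: r for r in reads}
    missing = sorted({a.query_id for a in alignments} - set(by_id))
    if missing:
        raise KeyError(f"reads in alignments absent from read set: {missing}")
    recalled: set[str] = set()
    for aln in alignments:
        if aln.query_id in recalled:
            continue
        obs = observe_alignment(aln, ref_seq, by_id[aln.query_id].seq,
                                rare_codes, model.k)
        if test_alignment(model, obs):
            recalled.add(aln.query_id)
    return recalled
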