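"""Readers/writers for the external formats the pipeline touches, plus an
exact k-mer counter.

All coordinates are 0-based half-open internally (PAF/BED native). K-mers are
canonicalized (lexicographic min of a k-mer and its reverse complement)
everywhere, because tandem-repeat arrays mix strands freely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("tandemfill")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base encoding: A=0 C=1 G=2 T=3, anything else = 4 (invalid)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


class ParseError(ValueError):
    """Raised when an input file violates its format."""


class ValidationError(ValueError):
    """Raised when a syntactically valid record violates an invariant."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# sequence records


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N} (uppercase)."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path) -> list[SequenceRecord]:
    """Parse FASTA; lowercase input is uppercased, wrapped lines joined."""
    records: list[SequenceRecord] = []
    name = None
    chunks: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks).upper()))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                if name in seen:
                    raise ParseError(f"{path}: duplicate id {name!r} at line {lineno}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                chunks.append(line)
    if name is not None:
        records.append(SequenceRecord(name, "".join(chunks).upper()))
    return records


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    """Parse FASTQ (4-line records); qualities are discarded."""
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 not in (0,) and lines and lines[-1] == "":
        lines = lines[:-1]
    for i in range(0, len(lines) - 3, 4):
        head = lines[i]
        if not head.startswith("@"):
            raise ParseError(f"{path}: bad FASTQ header at line {i + 1}")
        records.append(SequenceRecord(head[1:].split()[0], lines[i + 1].upper()))
    return records


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")


# ---------------------------------------------------------------------------
# alignments (PAF)


@dataclass
class AlignmentRecord:
    """One PAF line: an alignment of a query interval onto a target interval.

    Coordinates are 0-based half-open on both sides.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int
    block_len: int
    mapq: int = 60

    def __post_init__(self):
        for side, s, e, ln in (
            ("query", self.query_start, self.query_end, self.query_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not (0 <= s < e <= ln):
                raise ValidationError(
                    f"alignment {self.query_id}->{self.target_id}: bad {side} "
                    f"interval [{s},{e}) on length {ln}"
                )
        if self.strand not in "+-":
            raise ValidationError(f"alignment {self.query_id}: bad strand")

    @property
    def identity(self) -> float:
        return self.n_match / self.block_len if self.block_len else 0.0


def parse_paf(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"{path}: line {lineno} has {len(cols)} < 12 columns")
            records.append(
                AlignmentRecord(
                    query_id=cols[0],
                    query_len=int(cols[1]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                    strand=cols[4],
                    target_id=cols[5],
                    target_len=int(cols[6]),
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    n_match=int(cols[9]),
                    block_len=int(cols[10]),
                    mapq=int(cols[11]),
                )
            )
    return records


def write_paf(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id,
                        r.query_len,
                        r.query_start,
                        r.query_end,
                        r.strand,
                        r.target_id,
                        r.target_len,
                        r.target_start,
                        r.target_end,
                        r.n_match,
                        r.block_len,
                        r.mapq,
                    )
                )
                + "\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED4; returns (chrom, start, end, name) with name possibly ''."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: BED needs >= 3 columns")
            start, end = int(cols[1]), int(cols[2])
            if end <= start:
                raise ValidationError(f"{path}: line {lineno}: end <= start")
            out.append((cols[0], start, end, cols[3] if len(cols) > 3 else ""))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


# ---------------------------------------------------------------------------
# unitig graph (GFA1) + read paths (GAF)

OrientedNode = tuple[str, str]  # (node id, '+'|'-')


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def _mirror(u: OrientedNode, v: OrientedNode) -> tuple[OrientedNode, OrientedNode]:
    return (v[0], _flip(v[1])), (u[0], _flip(u[1]))


def edge_key(u: OrientedNode, v: OrientedNode):
    """Canonical key identifying a bidirected edge (an edge and its mirror
    are the same physical join)."""
    m = _mirror(u, v)
    return min((u, v), m)


class UnitigGraph:
    """Bidirected sequence graph with per-edge read-support counts.

    Directed adjacency is kept over oriented nodes; adding an edge also adds
    its reverse-complement mirror, and support is shared between the two.
    """

    def __init__(self):
        self.nodes: dict[str, str] = {}  # id -> sequence
        self._adj: dict[OrientedNode, dict[OrientedNode, int]] = {}
        self.support: dict = {}  # edge_key -> int

    # -- construction -------------------------------------------------
    def add_node(self, node_id: str, seq: str) -> None:
        if node_id in self.nodes:
            raise ValidationError(f"duplicate segment {node_id!r}")
        self.nodes[node_id] = seq.upper()

    def add_edge(self, u: str, ou: str, v: str, ov: str, overlap: int = 0) -> None:
        for n in (u, v):
            if n not in self.nodes:
                raise ParseError(f"edge references unknown segment {n!r}")
        a, b = (u, ou), (v, ov)
        self._adj.setdefault(a, {})[b] = overlap
        ma, mb = _mirror(a, b)
        self._adj.setdefault(ma, {})[mb] = overlap
        self.support.setdefault(edge_key(a, b), 0)

    def remove_edge(self, u: OrientedNode, v: OrientedNode) -> None:
        self._adj.get(u, {}).pop(v, None)
        ma, mb = _mirror(u, v)
        self._adj.get(ma, {}).pop(mb, None)
        self.support.pop(edge_key(u, v), None)

    # -- queries ------------------------------------------------------
    def successors(self, u: OrientedNode) -> list[OrientedNode]:
        return sorted(self._adj.get(u, {}))

    def has_edge(self, u: OrientedNode, v: OrientedNode) -> bool:
        return v in self._adj.get(u, {})

    def overlap(self, u: OrientedNode, v: OrientedNode) -> int:
        return self._adj[u][v]

    def edges(self):
        """Iterate each bidirected edge once, as (u, v, overlap) with the
        canonical orientation."""
        seen = set()
        for u, nbrs in self._adj.items():
            for v, ov in nbrs.items():
                k = edge_key(u, v)
                if k not in seen:
                    seen.add(k)
                    yield k[0], k[1], ov

    def get_support(self, u: OrientedNode, v: OrientedNode) -> int:
        return self.support.get(edge_key(u, v), 0)

    def add_support(self, u: OrientedNode, v: OrientedNode, n: int = 1) -> None:
        k = edge_key(u, v)
        self.support[k] = self.support.get(k, 0) + n

    def node_len(self, node_id: str) -> int:
        return len(self.nodes[node_id])

    def in_degree(self, node_id: str) -> int:
        return sum(
            1
            for u, nbrs in self._adj.items()
            for v in nbrs
            if v == (node_id, "+")
        )

    def out_degree(self, node_id: str) -> int:
        return len(self._adj.get((node_id, "+"), {}))

    def copy(self) -> "UnitigGraph":
        g = UnitigGraph()
        g.nodes = dict(self.nodes)
        g._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        g.support = dict(self.support)
        return g


@dataclass
class ReadPath:
    """An ordered walk of a read through the unitig graph."""

    read_id: str
    steps: list[OrientedNode] = field(default_factory=list)


def parse_gfa(path) -> UnitigGraph:
    """Parse GFA1 S/L lines. The L-line overlap CIGAR contributes the overlap
    length (only match-only CIGARs like '55M' or '*' are supported)."""
    graph = UnitigGraph()
    links = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] not in "SL":
                continue
            cols = line.split("\t")
            if cols[0] == "S":
                if len(cols) < 3:
                    raise ParseError(f"{path}: line {lineno}: short S line")
                graph.add_node(cols[1], "" if cols[2] == "*" else cols[2])
            elif cols[0] == "L":
                if len(cols) < 6:
                    raise ParseError(f"{path}: line {lineno}: short L line")
                cig = cols[5]
                if cig in ("*", ""):
                    ov = 0
                elif cig.endswith("M") and cig[:-1].isdigit():
                    ov = int(cig[:-1])
                else:
                    raise ParseError(f"{path}: line {lineno}: unsupported CIGAR {cig}")
                links.append((cols[1], cols[2], cols[3], cols[4], ov, lineno))
    for u, ou, v, ov_, ovl, lineno in links:
        try:
            graph.add_edge(u, ou, v, ov_, ovl)
        except ParseError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return graph


def _parse_gaf_path(spec: str) -> list[OrientedNode]:
    steps: list[OrientedNode] = []
    token = ""
    orient = None
    for ch in spec:
        if ch in "><":
            if orient is not None:
                steps.append((token, orient))
            orient = "+" if ch == ">" else "-"
            token = ""
        else:
            token += ch
    if orient is not None:
        steps.append((token, orient))
    return steps


def parse_gaf(path, graph: UnitigGraph) -> list[ReadPath]:
    """Parse GAF read paths; a path stepping over a non-edge is excluded and
    logged rather than failing the whole file."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ParseError(f"{path}: line {lineno}: GAF needs >= 6 columns")
            steps = _parse_gaf_path(cols[5])
            ok = bool(steps) and all(s[0] in graph.nodes for s in steps)
            if ok:
                for a, b in zip(steps, steps[1:]):
                    if not graph.has_edge(a, b):
                        ok = False
                        break
            if not ok:
                logger.warning(
                    "GAF path for %s at line %d does not follow graph edges; excluded",
                    cols[0],
                    lineno,
                )
                continue
            out.append(ReadPath(cols[0], steps))
    return out


def write_gfa(graph: UnitigGraph, path) -> None:
    with open(path, "w") as fh:
        for node_id in sorted(graph.nodes):
            fh.write(f"S\t{node_id}\t{graph.nodes[node_id]}\n")
        for u, v, ov in sorted(graph.edges()):
            fh.write(f"L\t{u[0]}\t{u[1]}\t{v[0]}\t{v[1]}\t{ov}M\n")


def write_gaf(paths, path) -> None:
    with open(path, "w") as fh:
        for p in paths:
            spec = "".join((">" if o == "+" else "<") + n for n, o in p.steps)
            fh.write(f"{p.read_id}\t0\t0\t0\t+\t{spec}\t0\t0\t0\t0\t0\t60\n")


# ---------------------------------------------------------------------------
# Hi-C pairs


def read_hic_pairs(path) -> list[tuple[str, str, str]]:
    """Read Hi-C pairs from a TSV with columns (read_id, seq1, seq2); extra
    columns are ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: need >= 3 columns")
            out.append((cols[0], cols[1].upper(), cols[2].upper()))
    return out


def read_hic_fastq(path1, path2) -> list[tuple[str, str, str]]:
    r1 = read_fastq(path1)
    r2 = read_fastq(path2)
    if len(r1) != len(r2):
        raise ValidationError("paired FASTQ files have different record counts")
    return [(a.id, a.seq, b.seq) for a, b in zip(r1, r2)]


def write_hic_pairs(pairs, path) -> None:
    with open(path, "w") as fh:
        for rid, s1, s2 in pairs:
            fh.write(f"{rid}\t{s1}\t{s2}\n")


# ---------------------------------------------------------------------------
# k-mer counting


@dataclass
class KmerSpectrum:
    """Exact canonical k-mer counts."""

    k: int
    counts: dict[str, int]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer integer codes for every valid (N-free) window.

    Returns (codes, starts): uint64 codes (2 bits/base, canonical of forward
    and reverse complement) and the 0-based window start positions.
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    vals = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(vals, k).astype(np.uint64)
    valid = (win < 4).all(axis=1)
    starts = np.nonzero(valid)[0]
    win = win[valid]
    if win.size == 0:
        return np.empty(0, dtype=np.uint64), starts
    pw_f = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    pw_r = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
    fwd = win @ pw_f
    rev = (np.uint64(3) - win) @ pw_r
    return np.minimum(fwd, rev), starts


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def count_kmer_codes(records, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes and their exact counts over all records."""
    parts = [kmer_codes(rec.seq, k)[0] for rec in records]
    parts = [p for p in parts if p.size]
    if not parts:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    allc = np.concatenate(parts)
    return np.unique(allc, return_counts=True)


def count_kmers(records, k: int) -> KmerSpectrum:
    """Exact canonical k-mer counting (k odd, 3..31); k-mers spanning N are
    skipped. A k longer than every sequence yields an empty spectrum."""
    if k % 2 == 0 or not (3 <= k <= 31):
        raise ValueError("k must be odd and in [3, 31]")
    codes, counts = count_kmer_codes(records, k)
    return KmerSpectrum(k, {decode_kmer(int(c), k): int(n) for c, n in zip(codes, counts)})


def kmer_set(seq: str, k: int) -> np.ndarray:
    """Distinct canonical k-mer codes of one sequence (sorted)."""
    codes, _ = kmer_codes(seq, k)
    return np.unique(codes)
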