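"""Thin wrapper around the minimap2 command-line aligner.

The pipeline's own contributions (read recall, graph simplification,
placement, phasing) never depend on this module; it is only used where a
general-purpose aligner is genuinely needed at run time — mapping reads
and contigs to the reference and scaffolds to shores/truth.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .io import AlignmentRecord, parse_paf, write_fasta


class AlignerError(RuntimeError):
    pass


def minimap2_available() -> bool:
    return shutil.which("minimap2") is not None


#: flags for read-to-contig mapping: secondary alignments to the homologous
#: contig of the other haplotype carry the homology-penalty signal, so the
#: secondary-to-primary score ratio is relaxed well below the default
READ_TO_CONTIG_EXTRA = ("-N", "10", "--secondary=yes", "-p", "0.3")


def minimap2(targets, queries, preset: str = "map-hifi",
             extra: tuple[str, ...] = ("-N", "10", "--secondary=yes"),
             ) -> list[AlignmentRecord]:
    """Align query records against target records, returning PAF records.

    Secondary alignments are kept by default: inside tandem arrays the
    alternative placements are informative, not noise.
    """
    if not minimap2_available():
        raise AlignerError("minimap2 not found on PATH")
    with tempfile.TemporaryDirectory(prefix="tandemfill_mm2_") as tmp:
        t_fa = Path(tmp) / "target.fa"
        q_fa = Path(tmp) / "query.fa"
        out = Path(tmp) / "aln.paf"
        write_fasta(targets, t_fa)
        write_fasta(queries, q_fa)
        cmd = ["minimap2", "-x", preset, *extra, "-o", str(out),
               str(t_fa), str(q_fa)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AlignerError(f"minimap2 failed: {proc.stderr[-2000:]}")
        return parse_paf(out)
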