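"""Sequence file I/O and quality-score arithmetic.

FASTA goes through Biopython.  FASTQ is parsed strictly (4-line records,
Phred+33) so that malformed files fail with the offending line number, which
matters when ingesting converted nanopore output of uneven provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FastqRead",
    "FastqParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "q_to_error",
    "error_to_q",
    "mean_expected_error",
]

_PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """Raised on malformed FASTQ input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class FastqRead:
    """One FASTQ record with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=float)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality values"
            )

    @property
    def mean_expected_error(self) -> float:
        """Mean per-base error probability, averaged on the error scale."""
        return mean_expected_error(self.qualities)

    @property
    def mean_q(self) -> float:
        return float(np.mean(self.qualities))


def q_to_error(q: float) -> float:
    """Phred quality -> per-base error probability, ``10^(-Q/10)``."""
    return 10.0 ** (-q / 10.0)


def error_to_q(e: float) -> float:
    if not 0.0 < e <= 1.0:
        raise ValueError("error probability must be in (0, 1]")
    return -10.0 * math.log10(e)


def mean_expected_error(qualities: Sequence[float]) -> float:
    """Expected error rate of a read: mean of 10^(-Q/10) over its bases.

    Averaging on the error scale (not the Q scale) is what makes a mean
    Q of 13.2 correspond to ~5% expected errors.
    """
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("empty quality vector")
    return float(np.mean(10.0 ** (-q / 10.0)))


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as ``[(id, sequence), ...]`` (uppercased)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(recs, str(path), "fasta-2line")


# ---------------------------------------------------------------- FASTQ


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Strict 4-line FASTQ reader (Phred+33).

    Raises :class:`FastqParseError` with the 1-based line number on a
    truncated record, a malformed header/separator, or a sequence/quality
    length mismatch.
    """
    reads: list[FastqRead] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if lines[i] == "" and i == len(lines) - 1:
            break  # trailing newline
        if not lines[i].startswith("@"):
            raise FastqParseError("expected '@' header", i + 1)
        if i + 3 >= len(lines):
            raise FastqParseError("truncated record", len(lines))
        header = lines[i][1:].split()[0] if len(lines[i]) > 1 else ""
        if not header:
            raise FastqParseError("empty read id", i + 1)
        seq = lines[i + 1].upper()
        if not lines[i + 2].startswith("+"):
            raise FastqParseError("expected '+' separator", i + 3)
        qual = lines[i + 3]
        if len(qual) != len(seq):
            raise FastqParseError(
                f"quality length {len(qual)} != sequence length {len(seq)}", i + 4
            )
        quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float)
        quals -= _PHRED_OFFSET
        if np.any(quals < 0):
            raise FastqParseError("quality character below Phred+33 offset", i + 4)
        reads.append(FastqRead(header, seq, quals))
        i += 4
    return reads


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(
                chr(int(round(q)) + _PHRED_OFFSET) for q in np.asarray(r.qualities)
            )
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
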