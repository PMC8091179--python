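"""Sequencing-read input/output, quality/length filtering and read-set statistics.

Reads are held as lightweight :class:`SequencingRead` records. FASTQ parsing is
delegated to Biopython; the filter reproduces BBDuk-style ``maq`` semantics
(arithmetic mean of per-base Phred scores) combined with a minimum read length,
the selection applied to the nanopore read set before any repeat annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)


class ReadParseError(ValueError):
    """Raised when a sequence record cannot be parsed, naming the record index."""


@dataclass
class SequencingRead:
    """A single read: id, uppercase sequence, optional per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ReadParseError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values "
                f"for {len(self.sequence)} bases"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def mean_quality(self) -> float | None:
        """Arithmetic mean Phred score (BBDuk 'maq' semantics); None without qualities."""
        if self.qualities is None:
            return None
        if not self.qualities:
            return 0.0
        return float(np.mean(self.qualities))


@dataclass
class ReadSetStats:
    """Summary statistics of a read set."""

    n_reads: int
    total_bp: int
    max_length: int
    n50: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def load_reads(path: str | Path, fmt: str | None = None) -> Iterator[SequencingRead]:
    """Stream reads from a FASTA or FASTQ file in file order.

    Parameters
    ----------
    path
        Input file. Format is inferred from the extension unless ``fmt`` is
        given (``"fasta"`` or ``"fastq"``).

    Yields uppercased sequences; FASTA records carry ``qualities=None``.
    Malformed records raise :class:`ReadParseError` naming the record index.
    An empty file yields nothing.
    """
    path = Path(path)
    if fmt is None:
        fmt = _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    index = 0
    parser = SeqIO.parse(str(path), fmt)
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise ReadParseError(f"record {index} in {path}: {exc}") from exc
        quals = None
        if fmt == "fastq":
            quals = list(rec.letter_annotations["phred_quality"])
        yield SequencingRead(rec.id, str(rec.seq), quals)
        index += 1


def write_reads(reads: Iterable[SequencingRead], path: str | Path,
                fmt: str | None = None) -> int:
    """Write reads as FASTA or FASTQ (Phred+33). Returns the number written.

    Reads without qualities written as FASTQ get a uniform placeholder Q20.
    """
    path = Path(path)
    if fmt is None:
        fmt = _infer_format(path)
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            if fmt == "fasta":
                fh.write(f">{read.read_id}\n{read.sequence}\n")
            else:
                quals = read.qualities or [20] * read.length
                qstr = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qstr}\n")
            n += 1
    return n


def filter_reads(reads: Iterable[SequencingRead], min_mean_q: float = 8.0,
                 min_length: int = 30_000) -> Iterator[SequencingRead]:
    """Retain reads with length >= min_length and mean Phred >= min_mean_q.

    Reads shorter than ``min_length`` are discarded ("shorter than" —
    a read exactly at the threshold is kept). Reads without qualities pass
    the quality criterion unconditionally. Order is preserved and the
    operation is idempotent. Discard counts are logged, not raised.
    """
    if min_length < 0 or min_mean_q < 0:
        raise ValueError("thresholds must be non-negative")
    n_in = n_short = n_lowq = n_kept = 0
    for read in reads:
        n_in += 1
        if read.length < min_length:
            n_short += 1
            continue
        mq = read.mean_quality()
        if mq is not None and mq < min_mean_q:
            n_lowq += 1
            continue
        n_kept += 1
        yield read
    logger.info("filter_reads: kept %d/%d (%d short, %d low-quality)",
                n_kept, n_in, n_short, n_lowq)


def read_stats(reads: Iterable[SequencingRead | int]) -> ReadSetStats:
    """Compute read-set statistics (count, total bp, max length, N50).

    N50 is the largest length L present in the set such that reads of length
    >= L jointly cover at least half of the total bases. Accepts reads or
    raw lengths. Empty input gives all-zero stats.
    """
    lengths = np.array(
        [r if isinstance(r, (int, np.integer)) else r.length for r in reads],
        dtype=np.int64,
    )
    if lengths.size == 0:
        return ReadSetStats(0, 0, 0, 0)
    lengths[::-1].sort()  # descending
    total = int(lengths.sum())
    csum = np.cumsum(lengths)
    # first index whose cumulative sum reaches total/2; an exact boundary
    # resolves toward the larger length (searchsorted side='left')
    idx = int(np.searchsorted(csum, total / 2))
    return ReadSetStats(
        n_reads=int(lengths.size),
        total_bp=total,
        max_length=int(lengths[0]),
        n50=int(lengths[idx]),
    )


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path.name!r}")
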