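"""Sequence I/O, read filtering and subsampling.

The data plumbing of the pipeline: FASTA/FASTQ (Phred+33, optionally
gzipped) readers and writers, whole-read quality/length filters matching
the primary-processing rules (short reads kept at mean base quality >= 30,
long reads kept at length >= 1 kb), and deterministic base-count
subsampling.

Coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import gzip
import io
import logging
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger("hcbha")

LONG = "long"
SHORT = "short"

_NON_ACGT = re.compile(r"[^ACGT]")


class ParseError(ValueError):
    """Malformed FASTA/FASTQ input."""


@dataclass
class SequenceRead:
    """A single platform-tagged read.

    quals are Phred scores (integers); None for reads without qualities.
    mate is "R1"/"R2" for paired short reads, None otherwise.
    """

    id: str
    bases: str
    quals: list[int] | None = None
    platform: str = LONG
    mate: str | None = None

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.quals)} != "
                f"sequence length {len(self.bases)}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        if self.quals is None:
            raise ValueError(f"read {self.id!r} has no qualities")
        return sum(self.quals) / len(self.quals)


@dataclass
class ReadSet:
    """Ordered collection of reads with unique IDs."""

    reads: list[SequenceRead] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate read id {dup!r} in ReadSet")

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[SequenceRead]:
        return iter(self.reads)

    def ids(self) -> set[str]:
        return {r.id for r in self.reads}


@dataclass
class ContigSeq:
    """An assembled contig with its mean long-read depth."""

    id: str
    bases: str
    coverage: float = 0.0
    circular: bool = False

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        if self.coverage < 0:
            raise ValueError(f"contig {self.id!r}: negative coverage")

    def __len__(self) -> int:
        return len(self.bases)


# ---------------------------------------------------------------------------
# parsing


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def normalize_bases(seq: str) -> str:
    """Uppercase and map non-ACGT characters to N."""
    return _NON_ACGT.sub("N", seq.upper())


def parse_fasta(path) -> list[tuple[str, str]]:
    """Parse a (possibly gzipped) FASTA file into (id, sequence) pairs.

    IDs are the first whitespace-delimited header token; sequences are
    uppercased with non-ACGT characters mapped to N.
    """
    with _open_text(path) as fh:
        # locate the first non-blank line for a helpful error message
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: sequence before first "
                        f"'>' header")
                break
        else:
            return []
        fh.seek(0)
        return [(rec.id, normalize_bases(str(rec.seq)))
                for rec in SeqIO.parse(fh, "fasta")]


def parse_fastq(path, platform: str) -> ReadSet:
    """Parse a (possibly gzipped) 4-line FASTQ file (Phred+33)."""
    reads = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                reads.append(SequenceRead(
                    id=rec.id,
                    bases=normalize_bases(str(rec.seq)),
                    quals=list(rec.letter_annotations["phred_quality"]),
                    platform=platform,
                ))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return ReadSet(reads)


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    """Write FASTA with 80-column wrapped sequence lines."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(path, rs: ReadSet) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in rs:
            quals = r.quals if r.quals is not None else [2] * len(r)
            qstr = "".join(chr(min(q, 93) + 33) for q in quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# filtering and subsampling


def filter_short_reads(rs: ReadSet, min_mean_q: float = 30.0) -> ReadSet:
    """Keep short reads whose arithmetic mean Phred score is >= min_mean_q.

    Mates are filtered independently; orphaned mates survive (tracked by
    their mate tag).
    """
    kept = []
    for r in rs:
        if r.quals is None:
            raise ValueError(f"read {r.id!r} lacks qualities; cannot "
                             f"quality-filter")
        if r.mean_quality >= min_mean_q:
            kept.append(r)
    return ReadSet(kept)


def filter_long_reads(rs: ReadSet, min_len: int = 1000) -> ReadSet:
    """Keep long reads with length >= min_len (default 1 kb)."""
    return ReadSet([r for r in rs if len(r) >= min_len])


def subsample_to_bases(rs: ReadSet, target_bases: int, seed: int) -> ReadSet:
    """Uniform without-replacement subsample until >= target_bases.

    Reads are drawn in a seeded random order and accumulated until the
    cumulative base count first reaches the target. If the input holds
    fewer bases than the target the whole input is returned (warning
    logged). Output preserves the input read order.
    """
    if target_bases <= 0:
        raise ValueError("target_bases must be positive")
    if rs.total_bases <= target_bases:
        if rs.total_bases < target_bases:
            logger.warning(
                "subsample target %d bp exceeds input %d bp; returning all",
                target_bases, rs.total_bases)
        return ReadSet(list(rs.reads))
    rng = random.Random(seed)
    order = list(range(len(rs.reads)))
    rng.shuffle(order)
    picked: set[int] = set()
    acc = 0
    for idx in order:
        picked.add(idx)
        acc += len(rs.reads[idx])
        if acc >= target_bases:
            break
    return ReadSet([rs.reads[i] for i in sorted(picked)])
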