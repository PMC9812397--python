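"""Streaming segment extraction from co-indexed FASTQ tuples.

Input libraries arrive as one or more FASTQ (optionally gzipped) files
whose records are co-indexed: record *i* of every file describes the
same cluster/molecule (R1/R2/index reads).  Reads are paired
positionally; a strict mode additionally verifies that read IDs agree
up to the first whitespace.

Extraction applies the compiled matchers of every declared source
structure in configuration order; the first structure that fully
matches claims the read.  Segment quality is summarized as the
arithmetic mean and minimum of the per-base Phred scores, and a record
failing the quality policy on any governed segment is dropped whole.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .config import QualityPolicy, ReadMatcher

__all__ = [
    "FastqFormatError",
    "ReadTuple",
    "Segment",
    "SegmentedRecord",
    "SegmentTally",
    "stream_read_tuples",
    "extract_segments",
    "quality_filter",
    "tally_segments",
    "write_fastq",
]

PHRED_OFFSET = 33


class FastqFormatError(ValueError):
    """Malformed FASTQ input or co-indexing violation."""


@dataclass(frozen=True)
class ReadTuple:
    """One sequencing entry across all co-indexed files."""

    read_id: str
    seqs: tuple[str, ...]
    quals: tuple[str, ...]

    def __post_init__(self) -> None:
        for s, q in zip(self.seqs, self.quals):
            if len(s) != len(q):
                raise FastqFormatError(
                    f"read {self.read_id!r}: sequence and quality lengths differ"
                )


@dataclass(frozen=True)
class Segment:
    seq: str
    qual: str
    avg_q: float
    min_q: int


@dataclass
class SegmentedRecord:
    """Per-read extracted segments for the structure that claimed it."""

    read_id: str
    structure_index: int
    segments: dict[str, Segment]


@dataclass
class SegmentTally:
    """Per-segment sequence counts for one chunk (or a merge of chunks)."""

    counts: dict[str, Counter] = field(default_factory=dict)
    chunk_id: int = 0

    def add(self, record: SegmentedRecord) -> None:
        for name, seg in record.segments.items():
            self.counts.setdefault(name, Counter())[seg.seq] += 1

    def total(self, segment: str) -> int:
        return sum(self.counts.get(segment, Counter()).values())


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as fh:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title, seq.upper(), qual
                index += 1
        except ValueError as e:
            raise FastqFormatError(f"{path}: malformed FASTQ record {index}: {e}") from None


def stream_read_tuples(
    paths: Sequence, chunk_size: int, strict_ids: bool = False
) -> Iterator[list[ReadTuple]]:
    """Yield order-preserving chunks of <= `chunk_size` read tuples.

    gzip compression is handled transparently by file suffix.  A
    record-count mismatch between files raises naming the offending
    file; in strict mode, so does an ID disagreement (IDs compared up
    to the first whitespace).
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    iters = [_fastq_records(p) for p in paths]
    chunk: list[ReadTuple] = []
    index = 0
    sentinel = object()
    while True:
        entries = [next(it, sentinel) for it in iters]
        done = [e is sentinel for e in entries]
        if all(done):
            break
        if any(done):
            short = paths[done.index(True)]
            raise FastqFormatError(
                f"record-count mismatch across files: {short} ended at record {index}"
            )
        ids = [e[0].split()[0] for e in entries]
        if strict_ids and len(set(ids)) != 1:
            raise FastqFormatError(f"read ID mismatch at record {index}: {ids}")
        chunk.append(
            ReadTuple(ids[0], tuple(e[1] for e in entries), tuple(e[2] for e in entries))
        )
        index += 1
        if len(chunk) == chunk_size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def _segment(seq: str, qual: str) -> Segment:
    phreds = [ord(c) - PHRED_OFFSET for c in qual]
    return Segment(seq, qual, sum(phreds) / len(phreds), min(phreds))


def extract_segments(
    tup: ReadTuple, matchers: Sequence[ReadMatcher]
) -> SegmentedRecord | None:
    """Apply matchers in configuration order; the first full match
    claims the read.  Returns None when no structure matches."""
    for idx, matcher in enumerate(matchers):
        spans = matcher.match(list(tup.seqs))
        if spans is None:
            continue
        segments = {
            name: _segment(tup.seqs[ri][s:e], tup.quals[ri][s:e])
            for name, (ri, s, e) in spans.items()
        }
        return SegmentedRecord(tup.read_id, idx, segments)
    return None


def quality_filter(
    record: SegmentedRecord, policy: QualityPolicy
) -> tuple[bool, str | None]:
    """Whole-record verdict: fail when any governed segment's average Q
    is below `min_avg_q` or its minimum per-base Q is below
    `min_base_q` (equality passes)."""
    for name, seg in record.segments.items():
        if not policy.governs(name):
            continue
        if seg.avg_q < policy.min_avg_q or seg.min_q < policy.min_base_q:
            return False, "quality"
    return True, None


def tally_segments(records: Iterable[SegmentedRecord], chunk_id: int = 0) -> SegmentTally:
    tally = SegmentTally(chunk_id=chunk_id)
    for rec in records:
        tally.add(rec)
    return tally


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (id, seq, qual) triples as 4-line FASTQ; returns the count.
    gzip output is selected by the `.gz` suffix."""
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
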