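"""FASTQ streaming, segment extraction, quality filtering, tallies."""

from __future__ import annotations

import gzip
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import single_pass_tally
from readxlate.config import (
    FixedSpan,
    PipelineConfig,
    QualityPolicy,
    ReadStructure,
    SegmentSpec,
    VariableSpec,
    compile_matcher,
)
from readxlate.segmentation import (
    FastqFormatError,
    Segment,
    SegmentedRecord,
    extract_segments,
    quality_filter,
    stream_read_tuples,
    tally_segments,
    write_fastq,
)
from readxlate.correction import merge_tallies


def _write(tmp_path, name, records):
    p = tmp_path / name
    write_fastq(p, records)
    return p


def _records(n, length=8):
    return [(f"r{i}", "ACGTACGT"[:length], "I" * length) for i in range(n)]


def test_chunking_sizes_and_order(tmp_path):
    p1 = _write(tmp_path, "a.fastq", _records(10))
    p2 = _write(tmp_path, "b.fastq", _records(10))
    chunks = list(stream_read_tuples([p1, p2], chunk_size=4))
    assert [len(c) for c in chunks] == [4, 4, 2]
    ids = [t.read_id for c in chunks for t in c]
    assert ids == [f"r{i}" for i in range(10)]
    assert all(len(t.seqs) == 2 for c in chunks for t in c)


def test_record_count_mismatch_names_short_file(tmp_path):
    p1 = _write(tmp_path, "a.fastq", _records(10))
    p2 = _write(tmp_path, "b.fastq", _records(9))
    with pytest.raises(FastqFormatError, match="b.fastq"):
        list(stream_read_tuples([p1, p2], chunk_size=100))


def test_gzip_round_trips_identically(tmp_path):
    recs = _records(7)
    plain = _write(tmp_path, "a.fastq", recs)
    gz = tmp_path / "a.fastq.gz"
    with gzip.open(gz, "wt") as fh:
        for rid, seq, qual in recs:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    a = [t for c in stream_read_tuples([plain], 3) for t in c]
    b = [t for c in stream_read_tuples([gz], 3) for t in c]
    assert a == b


def test_malformed_fastq_reports_record_index(tmp_path):
    p = tmp_path / "bad.fastq"
    p.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n+\nIII\n")  # short quality
    with pytest.raises(FastqFormatError, match="bad.fastq"):
        list(stream_read_tuples([p], 10))


def test_strict_id_mode_flags_disagreement(tmp_path):
    p1 = _write(tmp_path, "a.fastq", [("x", "ACGT", "IIII")])
    p2 = _write(tmp_path, "b.fastq", [("y", "ACGT", "IIII")])
    assert len(list(stream_read_tuples([p1, p2], 10))[0]) == 1  # positional pairing
    with pytest.raises(FastqFormatError, match="ID mismatch"):
        list(stream_read_tuples([p1, p2], 10, strict_ids=True))


def _two_structure_matchers():
    make = lambda name, L: ReadStructure(name, (SegmentSpec("tag", 0, FixedSpan(0, L)),))
    return [compile_matcher(make("first", 8)), compile_matcher(make("second", 8))]


def test_first_matching_structure_claims_ambiguous_read(tmp_path):
    from readxlate.segmentation import ReadTuple

    tup = ReadTuple("r0", ("ACGTACGTAC",), ("I" * 10,))
    rec = extract_segments(tup, _two_structure_matchers())
    assert rec.structure_index == 0  # both match; first wins
    short = ReadTuple("r1", ("ACGT",), ("IIII",))
    assert extract_segments(short, _two_structure_matchers()) is None


@pytest.mark.parametrize(
    "avg_q, min_q, expect",
    [
        (19.9, 40, False),  # average just below threshold fails
        (20.0, 10, True),  # thresholds read "below X"; equality passes
        (40.0, 40, True),
        (25.0, 9, False),  # min per-base violation
    ],
)
def test_quality_filter_thresholds(avg_q, min_q, expect):
    policy = QualityPolicy(min_avg_q=20, min_base_q=10)
    rec = SegmentedRecord("r", 0, {"seg": Segment("ACGT", "IIII", avg_q, min_q)})
    ok, reason = quality_filter(rec, policy)
    assert ok is expect
    assert reason == (None if expect else "quality")


def test_quality_filter_only_governs_listed_segments():
    policy = QualityPolicy(min_avg_q=20, min_base_q=10, applies_to=("bc",))
    rec = SegmentedRecord(
        "r", 0,
        {"bc": Segment("AC", "II", 40, 40), "cdna": Segment("AC", "##", 2.0, 2)},
    )
    assert quality_filter(rec, policy) == (True, None)


def _rec(seqs_by_segment):
    return SegmentedRecord(
        "r", 0, {k: Segment(v, "I" * len(v), 40.0, 40) for k, v in seqs_by_segment.items()}
    )


def test_tally_counts_multiset():
    recs = [_rec({"bc": s}) for s in ["AA", "AA", "AC"]]
    tally = tally_segments(recs)
    assert tally.counts["bc"] == Counter({"AA": 2, "AC": 1})
    assert tally_segments([]).counts == {}


@settings(max_examples=30, deadline=None)
@given(
    st.lists(st.sampled_from(["AA", "AC", "AG", "AT"]), max_size=40),
    st.integers(min_value=1, max_value=7),
)
def test_chunked_tally_merge_equals_single_pass(seqs, chunk_size):
    """Merging per-chunk tallies reproduces the one-pass count for any
    chunking (invariance of the merge barrier)."""
    recs = [_rec({"bc": s}) for s in seqs]
    chunks = [recs[i : i + chunk_size] for i in range(0, len(recs), chunk_size)]
    merged = merge_tallies([tally_segments(c, chunk_id=i) for i, c in enumerate(chunks)])
    expected = single_pass_tally({"bc": seqs})
    assert merged.counts.get("bc", Counter()) == expected["bc"]


def test_zero_error_simulator_output_decodes_exactly(tiny_scrna):
    """With no injected errors, extracted segments equal ground truth."""
    sim, paths = tiny_scrna
    matchers = [compile_matcher(s) for s in sim.config.structures]
    truth = sim.truth.set_index("read_id")
    n = 0
    for chunk in stream_read_tuples(paths, 100):
        for tup in chunk:
            rec = extract_segments(tup, matchers)
            row = truth.loc[tup.read_id]
            assert rec.segments["cell"].seq == row["cell"]
            assert rec.segments["umi"].seq == row["umi"]
            assert rec.segments["cdna"].seq == row["gene"]
            n += 1
    assert n == len(truth)
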