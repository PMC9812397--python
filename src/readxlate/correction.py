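"""Knee-point detection and segment sequence error correction.

True barcodes dominate a rank-read-count curve; sequencing errors form
a low-count tail.  The imputation-to-majority strategy accepts every
sequence ranked at or above the maximum-curvature (knee) point of the
log10(rank)-log10(count) curve and corrects each below-knee sequence to
its nearest accepted neighbour by Levenshtein distance, dropping
sequences beyond the configured threshold.  Allowlist mapping does the
same against a user-provided list of valid sequences.  An external
command can replace both through a simple TSV-in/TSV-out contract.

Levenshtein distance is unit-cost over {A, C, G, T, N} where ``N``
mismatches everything, including another ``N``.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .config import ConfigError, CorrectionSpec, load_allowlist
from .segmentation import SegmentedRecord, SegmentTally

__all__ = [
    "DROP",
    "PluginError",
    "RankCountCurve",
    "CorrectionTable",
    "levenshtein",
    "merge_tallies",
    "rank_count_curve",
    "detect_knee",
    "build_correction_table",
    "build_tables_for_config",
    "apply_correction",
    "write_correction_tables",
    "read_correction_tables",
]

DROP = "-"


class PluginError(RuntimeError):
    """External correction command failed or violated its contract."""


def levenshtein(a: str, b: str, k: int | None = None) -> float:
    """Unit-cost edit distance; N mismatches every base including N.

    With ``k`` set, distances above ``k`` are reported as ``inf``.
    """
    # Masking N differently on each side makes N unequal to everything.
    r = edlib.align(a.replace("N", "n"), b.replace("N", "m"),
                    task="distance", k=-1 if k is None else k)
    d = r["editDistance"]
    return math.inf if d == -1 else float(d)


def merge_tallies(tallies: list[SegmentTally]) -> SegmentTally:
    """Sum per-sequence counts over chunks; associative and commutative."""
    merged = SegmentTally()
    for t in tallies:
        for name, counter in t.counts.items():
            merged.counts.setdefault(name, Counter()).update(counter)
    return merged


@dataclass
class RankCountCurve:
    """Sequences sorted by descending count with 1-based ranks."""

    sequences: list[str]
    counts: list[int]
    knee_rank: int | None = None


def rank_count_curve(counter: Counter) -> RankCountCurve:
    # descending count, ties broken lexicographically for determinism
    items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankCountCurve([s for s, _ in items], [c for _, c in items])


def detect_knee(curve: RankCountCurve) -> int:
    """Rank of the maximum-curvature (knee) point of the log-log curve.

    Duplicate counts are collapsed to their last rank; on the resulting
    log10(rank)-log10(count) polyline the knee is the interior vertex
    with the largest log-count drop to the next level, restricted to
    vertices lying above the chord joining the two endpoints.  The
    drop criterion is a robust discrete surrogate for the
    maximum-curvature point on noisy rank-count curves: raw turn
    angles wobble with plateau jitter and can even land at the bottom
    of the abundance cliff, whereas the largest multiplicative gap
    pins the cliff top, and the chord restriction keeps a dominant
    leading sequence from masquerading as the knee.  When no vertex
    lies above the chord, all interior vertices are candidates.  Ties
    go to the smaller rank.  Degenerate curves (all counts equal, or
    fewer than three sequences) accept everything; with exactly two
    count levels the knee is the edge of the upper plateau.
    """
    n = len(curve.counts)
    if n == 0:
        raise ValueError("empty curve")
    levels: list[tuple[int, int]] = []  # (last rank, count), count descending
    for rank, count in enumerate(curve.counts, start=1):
        if levels and levels[-1][1] == count:
            levels[-1] = (rank, count)
        else:
            levels.append((rank, count))
    if n <= 2 or len(levels) == 1:
        curve.knee_rank = n
        return n
    if len(levels) == 2:
        curve.knee_rank = levels[0][0]
        return curve.knee_rank
    pts = [(math.log10(r), math.log10(c)) for r, c in levels]
    (x0, y0), (x1, y1) = pts[0], pts[-1]

    def drop(i: int) -> float:
        return pts[i][1] - pts[i + 1][1]

    def above_chord(i: int) -> bool:
        x, y = pts[i]
        return (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0) > 1e-12

    interior = range(1, len(pts) - 1)
    candidates = [i for i in interior if above_chord(i)] or list(interior)
    best = min(candidates, key=lambda i: (-drop(i), levels[i][0]))
    curve.knee_rank = levels[best][0]
    return curve.knee_rank


@dataclass
class CorrectionTable:
    """Total map raw sequence -> corrected sequence or DROP for one segment."""

    segment: str
    method: str
    levenshtein_max: int
    mapping: dict[str, str] = field(default_factory=dict)
    accepted: set[str] = field(default_factory=set)

    def correct(self, seq: str) -> str:
        if seq in self.mapping:
            return self.mapping[seq]
        if self.method == "none":
            return seq
        if seq in self.accepted:
            return seq
        raise KeyError(f"segment {self.segment!r}: sequence {seq!r} absent from correction table")


def _nearest(seq: str, candidates: list[str], max_dist: int) -> tuple[str | None, int]:
    """Nearest candidate within max_dist and the number of co-minimal
    candidates.  `candidates` must already be in tie-break order."""
    best: str | None = None
    best_d = max_dist + 1
    n_min = 0
    for cand in candidates:
        d = levenshtein(seq, cand, k=max_dist)
        if d < best_d:
            best, best_d, n_min = cand, int(d), 1
        elif d == best_d:
            n_min += 1
    return (best, n_min) if best is not None else (None, 0)


def _imputation_table(segment: str, counter: Counter, max_dist: int) -> CorrectionTable:
    curve = rank_count_curve(counter)
    knee = detect_knee(curve)
    accepted = curve.sequences[:knee]
    table = CorrectionTable(segment, "imputation_to_majority", max_dist, accepted=set(accepted))
    # tie-break order for nearest-neighbour: higher count, then lexicographic
    for seq in accepted:
        table.mapping[seq] = seq
    for seq in curve.sequences[knee:]:
        target, _ = _nearest(seq, accepted, max_dist)
        table.mapping[seq] = target if target is not None else DROP
    return table


def _allowlist_table(segment: str, counter: Counter, allowlist: list[str],
                     max_dist: int) -> CorrectionTable:
    members = set(allowlist)
    table = CorrectionTable(segment, "allowlist", max_dist, accepted=members)
    for seq in counter:
        if seq in members:
            table.mapping[seq] = seq
            continue
        target, n_min = _nearest(seq, allowlist, max_dist)
        # ambiguity fabricates identity: equidistant allowlist hits drop
        table.mapping[seq] = target if (target is not None and n_min == 1) else DROP
    return table


def _plugin_table(segment: str, counter: Counter, command: str,
                  max_dist: int) -> CorrectionTable:
    """External contract: the command is invoked with an input TSV path
    (sequence, count) and an output path, and must write a total
    2-column TSV (raw, corrected-or-"-")."""
    with tempfile.TemporaryDirectory(prefix="readxlate-plugin-") as tmp:
        inp = Path(tmp) / f"{segment}.counts.tsv"
        out = Path(tmp) / f"{segment}.table.tsv"
        with open(inp, "w") as fh:
            for seq, count in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{seq}\t{count}\n")
        proc = subprocess.run(
            command.split() + [str(inp), str(out)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise PluginError(
                f"plugin for segment {segment!r} exited {proc.returncode}: {proc.stderr.strip()}"
            )
        if not out.exists():
            raise PluginError(f"plugin for segment {segment!r} wrote no output table")
        mapping: dict[str, str] = {}
        with open(out) as fh:
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise PluginError(f"plugin table for {segment!r}: expected 2 columns")
                mapping[parts[0]] = parts[1]
    missing = set(counter) - set(mapping)
    if missing:
        raise PluginError(
            f"plugin table for {segment!r} is not total: {len(missing)} sequences missing"
        )
    accepted = {v for v in mapping.values() if v != DROP}
    return CorrectionTable(segment, "plugin", max_dist, mapping, accepted)


def build_correction_table(
    tally: SegmentTally, segment: str, spec: CorrectionSpec, allowlist=None
) -> CorrectionTable:
    """Build the per-segment table for one correction policy.

    `allowlist` overrides the spec's allowlist source (used when a
    combinatorial variable carries one list per member segment).
    """
    counter = tally.counts.get(segment, Counter())
    if spec.method == "none":
        return CorrectionTable(segment, "none", spec.levenshtein_max,
                               {s: s for s in counter}, set(counter))
    if spec.method == "imputation_to_majority":
        if not counter:
            return CorrectionTable(segment, spec.method, spec.levenshtein_max)
        return _imputation_table(segment, counter, spec.levenshtein_max)
    if spec.method == "allowlist":
        seqs = load_allowlist(allowlist if allowlist is not None else spec.allowlist)
        return _allowlist_table(segment, counter, seqs, spec.levenshtein_max)
    if spec.method == "plugin":
        return _plugin_table(segment, counter, spec.plugin_command, spec.levenshtein_max)
    raise ConfigError(f"unknown correction method {spec.method!r}")


def _allowlist_for_member(spec: CorrectionSpec, member_index: int, n_members: int):
    src = spec.allowlist
    if src is None:
        return None
    # one allowlist per member segment: a list of paths or of inline lists
    if isinstance(src, (list, tuple)) and n_members > 1 and len(src) == n_members \
            and all(isinstance(x, (str, list, tuple)) for x in src) \
            and not all(isinstance(x, str) and set(x) <= set("ACGT") for x in src):
        return src[member_index]
    return src


def build_tables_for_config(tally: SegmentTally, cfg) -> dict[str, CorrectionTable]:
    """Per-segment correction tables for every variable of a config."""
    tables: dict[str, CorrectionTable] = {}
    for var in cfg.variables:
        n = len(var.member_segments)
        for i, seg in enumerate(var.member_segments):
            allow = _allowlist_for_member(var.correction, i, n)
            tables[seg] = build_correction_table(tally, seg, var.correction, allowlist=allow)
    return tables


def apply_correction(
    record: SegmentedRecord, tables: dict[str, CorrectionTable]
) -> SegmentedRecord | None:
    """Replace every governed segment by its corrected sequence.

    Any DROP discards the whole record (None).  Per-segment quality
    summaries carry over unchanged.  Applying a table twice is a
    no-op: corrected sequences are accepted-set members mapping to
    themselves.
    """
    corrected: dict[str, object] = {}
    for name, seg in record.segments.items():
        table = tables.get(name)
        if table is None or table.method == "none":
            corrected[name] = seg
            continue
        new_seq = table.correct(seg.seq)
        if new_seq == DROP:
            return None
        if new_seq == seg.seq:
            corrected[name] = seg
        else:
            corrected[name] = type(seg)(new_seq, seg.qual, seg.avg_q, seg.min_q)
    return SegmentedRecord(record.read_id, record.structure_index, corrected)


def write_correction_tables(tables: dict[str, CorrectionTable], path) -> None:
    """Persist as 3-column TSV (segment, raw, corrected|"-")."""
    with open(path, "w") as fh:
        fh.write("segment\traw\tcorrected\n")
        for seg in sorted(tables):
            t = tables[seg]
            for raw in sorted(t.mapping):
                fh.write(f"{seg}\t{raw}\t{t.mapping[raw]}\n")


def read_correction_tables(path) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            seg, raw, corr = line.rstrip("\n").split("\t")
            out.setdefault(seg, {})[raw] = corr
    return out
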