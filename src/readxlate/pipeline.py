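"""End-to-end interpret/translate workflow over chunked FASTQ input.

The interpret stage streams read tuples in chunks, extracts segments
with first-match precedence over the declared structures, applies the
quality policy, tallies segment sequences per chunk, merges the
tallies, builds correction tables once from the merged tallies, and
applies them back to every record.  The translate stage encodes
corrected records into the value tree, optimizes the value space (or
uses the scope-blind control map), and emits destination FASTQ files.

Chunks are embarrassingly parallel between the two single-node merge
barriers (tally merge; tree merge and optimization); every final
artifact is independent of the chunking.  Interpret and translate are
deterministic given config and inputs; the only randomness in the
package lives in the simulators.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .config import PipelineConfig, compile_matcher
from .correction import apply_correction, build_tables_for_config, merge_tallies, write_correction_tables
from .segmentation import Segment, SegmentedRecord, extract_segments, stream_read_tuples, tally_segments
from .translation import build_pools, emit_destination_fastq, load_tables_for_config, translate_record
from .valuespace import ValueTree, encode_values, global_value_map, merge_value_trees, optimize_value_space, write_value_tree

__all__ = ["RunManifest", "InterpretResult", "TranslateResult", "interpret", "translate", "load_interpret_dir"]

log = logging.getLogger("readxlate")


@dataclass
class RunManifest:
    """Per-stage record accounting; counts telescope stage by stage."""

    config_checksum: str = ""
    inputs: list[str] = field(default_factory=list)
    chunk_count: int = 0
    counts: dict[str, int] = field(default_factory=dict)
    dropped: Counter = field(default_factory=Counter)
    seed: int = 0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"config_checksum\t{self.config_checksum}\n")
            fh.write(f"inputs\t{','.join(self.inputs)}\n")
            fh.write(f"chunk_count\t{self.chunk_count}\n")
            fh.write(f"seed\t{self.seed}\n")
            for key in sorted(self.counts):
                fh.write(f"count:{key}\t{self.counts[key]}\n")
            for reason in sorted(self.dropped):
                fh.write(f"dropped:{reason}\t{self.dropped[reason]}\n")


@dataclass
class InterpretResult:
    records: list[SegmentedRecord]
    tables: dict
    tally: object
    tree: ValueTree
    manifest: RunManifest
    per_structure: Counter = field(default_factory=Counter)


def interpret(
    cfg: PipelineConfig,
    fastq_paths: list,
    outdir=None,
    chunk_size: int | None = None,
) -> InterpretResult:
    """Run segment identification, quality filtering and error
    correction; optionally persist the stage artifacts to ``outdir``."""
    chunk_size = chunk_size or cfg.chunk_size
    matchers = [compile_matcher(st) for st in cfg.structures]
    manifest = RunManifest(
        config_checksum=cfg.checksum(),
        inputs=[str(p) for p in fastq_paths],
        seed=cfg.random_seed,
    )

    chunks: list[list[SegmentedRecord]] = []
    tallies = []
    per_structure: Counter = Counter()
    n_input = n_matched = n_qpass = 0
    for chunk_id, chunk in enumerate(stream_read_tuples(fastq_paths, chunk_size)):
        kept: list[SegmentedRecord] = []
        for tup in chunk:
            n_input += 1
            rec = extract_segments(tup, matchers)
            if rec is None:
                manifest.dropped["no_match"] += 1
                continue
            n_matched += 1
            per_structure[rec.structure_index] += 1
            ok = True
            for name, seg in rec.segments.items():
                if cfg.quality.governs(name) and (
                    seg.avg_q < cfg.quality.min_avg_q or seg.min_q < cfg.quality.min_base_q
                ):
                    ok = False
                    break
            if not ok:
                manifest.dropped["quality"] += 1
                continue
            n_qpass += 1
            kept.append(rec)
        tallies.append(tally_segments(kept, chunk_id=chunk_id))
        chunks.append(kept)
    manifest.chunk_count = len(chunks)

    tally = merge_tallies(tallies)
    tables = build_tables_for_config(tally, cfg)

    corrected: list[SegmentedRecord] = []
    trees = []
    for chunk_records in chunks:
        chunk_corrected = []
        for rec in chunk_records:
            out = apply_correction(rec, tables)
            if out is None:
                manifest.dropped["correction_drop"] += 1
            else:
                chunk_corrected.append(out)
        _, tree = encode_values(chunk_corrected, cfg)
        trees.append(tree)
        corrected.extend(chunk_corrected)
    tree = merge_value_trees(trees) if trees else encode_values([], cfg)[1]

    manifest.counts.update(
        input=n_input, matched=n_matched, quality_pass=n_qpass, corrected=len(corrected)
    )
    log.info("interpret: %s", dict(manifest.counts))

    result = InterpretResult(corrected, tables, tally, tree, manifest, per_structure)
    if outdir is not None:
        _write_interpret_artifacts(result, cfg, Path(outdir))
    return result


def _write_interpret_artifacts(result: InterpretResult, cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.manifest.write(outdir / "manifest.tsv")
    with open(outdir / "tally.tsv", "w") as fh:
        fh.write("segment\tsequence\tcount\n")
        for seg in sorted(result.tally.counts):
            for seq, n in sorted(result.tally.counts[seg].items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{seg}\t{seq}\t{n}\n")
    write_correction_tables(result.tables, outdir / "correction_tables.tsv")
    write_value_tree(result.tree, outdir / "value_tree.tsv")
    by_structure: dict[int, list[SegmentedRecord]] = {}
    for rec in result.records:
        by_structure.setdefault(rec.structure_index, []).append(rec)
    for si, st in enumerate(cfg.structures):
        names = [s.name for s in st.segments]
        with open(outdir / f"records.{si}.tsv", "w") as fh:
            cols = ["read_id"] + [f"{n}.{f}" for n in names for f in ("seq", "qual", "avg_q", "min_q")]
            fh.write("\t".join(cols) + "\n")
            for rec in by_structure.get(si, []):
                row = [rec.read_id]
                for n in names:
                    seg = rec.segments[n]
                    row += [seg.seq, seg.qual, repr(seg.avg_q), str(seg.min_q)]
                fh.write("\t".join(row) + "\n")


def load_interpret_dir(path, cfg: PipelineConfig) -> list[SegmentedRecord]:
    """Reload corrected records written by :func:`interpret`."""
    path = Path(path)
    records: list[SegmentedRecord] = []
    for si, st in enumerate(cfg.structures):
        f = path / f"records.{si}.tsv"
        if not f.exists():
            raise FileNotFoundError(
                f"missing interpret artifact {f}; run the interpret stage first"
            )
        names = [s.name for s in st.segments]
        with open(f) as fh:
            next(fh)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                segments = {}
                for i, n in enumerate(names):
                    seq, qual, avg_q, min_q = parts[1 + 4 * i : 5 + 4 * i]
                    segments[n] = Segment(seq, qual, float(avg_q), int(min_q))
                records.append(SegmentedRecord(parts[0], si, segments))
    return records


@dataclass
class TranslateResult:
    tuples: list
    opt: object
    manifest: RunManifest
    output_paths: list[str] = field(default_factory=list)

    def destination_sequence_map(self, cfg: PipelineConfig, dest_name: str) -> dict:
        """(parent path, source sequence tuple) -> emitted destination
        sequence, for one reassign destination.  Values beyond pool
        capacity are absent (those records dropped)."""
        dest = next(d for d in cfg.destinations if d.name == dest_name)
        pools = build_pools(cfg)
        pool = pools[dest_name]
        out = {}
        for (path, seqtup), value in self.opt.assignments[dest.source].items():
            if value < pool.capacity:
                out[(path, seqtup)] = pool.sequence_for(value)
        return out


def translate(
    cfg: PipelineConfig,
    interp: InterpretResult | list[SegmentedRecord],
    outdir=None,
    no_optimize: bool = False,
    output_prefix: str = "read",
) -> TranslateResult:
    """Translate corrected records into destination reads.

    ``no_optimize`` switches to the scope-blind global value map (the
    degraded control); otherwise values are renumbered per parent
    scope.  Destination FASTQ files land in ``outdir`` as
    ``<prefix><i>.fastq``.
    """
    records = interp.records if isinstance(interp, InterpretResult) else interp
    manifest = RunManifest(config_checksum=cfg.checksum(), seed=cfg.random_seed)

    vrecords, tree = encode_values(records, cfg)
    opt = global_value_map(tree) if no_optimize else optimize_value_space(tree)
    for var, width in opt.species_count.items():
        log.info("value species for %s: %d", var, width)
    pools = build_pools(cfg)
    tables = load_tables_for_config(cfg)

    tuples = []
    for vrec in vrecords:
        out = translate_record(vrec, opt, cfg, pools, tables)
        if isinstance(out, tuple) and out[0] is None:
            manifest.dropped[out[1]] += 1
        else:
            tuples.append(out)
    manifest.counts.update(input=len(records), translated=len(tuples))
    log.info("translate: %s dropped=%s", dict(manifest.counts), dict(manifest.dropped))

    result = TranslateResult(tuples, opt, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n_reads = max((len(t.seqs) for t in tuples), default=0)
        paths = [outdir / f"{output_prefix}{i + 1}.fastq" for i in range(n_reads)]
        emit_destination_fastq(tuples, paths)
        result.output_paths = [str(p) for p in paths]
        manifest.write(outdir / "manifest.tsv")
    return result
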