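"""Value trees and the parental-local value-space optimization.

Every corrected sequence tuple of a valued variable becomes a value.
Values are scoped: a local variable's values live inside one value of
its parent, so the same UMI sequence under two different cells is two
different objects.  The observed (parent path -> value -> count)
hierarchy is the *value tree*; chunked trees merge by sequence.

Optimization renumbers values to minimize the number of value species
per variable while preserving tree topology: roots are renumbered
0..n-1 by descending total count, and every local scope is renumbered
independently 0..k-1 by descending in-scope count.  The species count
of a variable then equals its maximum scope cardinality, which is the
minimum any topology-preserving renumbering can achieve.  Frequency
ties break by the lexicographic order of the underlying sequence
tuples, keeping the map deterministic across runs and chunkings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .config import PipelineConfig
from .segmentation import SegmentedRecord

__all__ = [
    "SeqTuple",
    "ValueRecord",
    "ValueTree",
    "OptimizationMap",
    "encode_values",
    "merge_value_trees",
    "optimize_value_space",
    "global_value_map",
    "write_value_tree",
]

SeqTuple = tuple[str, ...]
Path = tuple[SeqTuple, ...]  # ancestor sequence tuples, root first


@dataclass
class ValueRecord:
    """Per-read variable values (keyed by sequence tuple) plus the
    corrected record they came from (for pass-through segments)."""

    read_id: str
    values: dict[str, SeqTuple]
    record: SegmentedRecord


@dataclass
class ValueTree:
    """Counts of value tuples organized by the variable hierarchy.

    ``scopes[var][parent_path]`` counts the sequence tuples of ``var``
    observed under that chain of ancestor values; root variables are
    keyed by the empty path.
    """

    variables: tuple[str, ...]  # topological order, parents first
    parents: dict[str, str | None]
    scopes: dict[str, dict[Path, Counter]] = field(default_factory=dict)

    def add(self, var: str, path: Path, value: SeqTuple, count: int = 1) -> None:
        self.scopes.setdefault(var, {}).setdefault(path, Counter())[value] += count

    def n_values(self, var: str) -> int:
        return sum(len(c) for c in self.scopes.get(var, {}).values())


def _value_of(record: SegmentedRecord, members: tuple[str, ...]) -> SeqTuple:
    return tuple(record.segments[m].seq for m in members)


def encode_values(
    records: Iterable[SegmentedRecord], cfg: PipelineConfig
) -> tuple[list[ValueRecord], ValueTree]:
    """Convert corrected records into value records and a value tree.

    A record contributes a variable only when every member segment of
    that variable (and of its ancestors) was extracted by the matched
    structure; payload variables are not valued and pass through raw.
    """
    topo = cfg.topological_variables()
    tree = ValueTree(
        variables=tuple(v.name for v in topo),
        parents={v.name: v.parent for v in topo},
    )
    out: list[ValueRecord] = []
    for rec in records:
        values: dict[str, SeqTuple] = {}
        for var in topo:
            if not all(m in rec.segments for m in var.member_segments):
                continue
            chain = cfg.ancestry(var.name)
            if not all(a in values for a in chain):
                continue
            path: Path = tuple(values[a] for a in chain)
            val = _value_of(rec, var.member_segments)
            values[var.name] = val
            tree.add(var.name, path, val)
        out.append(ValueRecord(rec.read_id, values, rec))
    return out, tree


def merge_value_trees(trees: list[ValueTree]) -> ValueTree:
    """Union scopes and sum counts; requires one shared hierarchy."""
    if not trees:
        raise ValueError("no trees to merge")
    first = trees[0]
    merged = ValueTree(first.variables, dict(first.parents))
    for t in trees:
        if t.variables != first.variables or t.parents != first.parents:
            raise ValueError("value trees disagree on the variable hierarchy")
        for var, scopes in t.scopes.items():
            for path, counter in scopes.items():
                for val, count in counter.items():
                    merged.add(var, path, val, count)
    return merged


@dataclass
class OptimizationMap:
    """Per variable: (parent path, sequence tuple) -> optimized value.

    Within each parent scope the map is injective and assigns 0..k-1
    by descending count; ``species_count`` is the maximum scope size,
    i.e. the number of distinct values the variable needs.
    """

    assignments: dict[str, dict[tuple[Path, SeqTuple], int]]
    species_count: dict[str, int]

    def value(self, var: str, path: Path, seqtuple: SeqTuple) -> int:
        return self.assignments[var][(path, seqtuple)]


def _rank_scope(counter: Counter) -> dict[SeqTuple, int]:
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return {val: i for i, (val, _) in enumerate(ordered)}


def optimize_value_space(tree: ValueTree) -> OptimizationMap:
    assignments: dict[str, dict[tuple[Path, SeqTuple], int]] = {}
    species: dict[str, int] = {}
    for var in tree.variables:
        amap: dict[tuple[Path, SeqTuple], int] = {}
        width = 0
        for path, counter in tree.scopes.get(var, {}).items():
            ranks = _rank_scope(counter)
            width = max(width, len(ranks))
            for val, opt in ranks.items():
                amap[(path, val)] = opt
        assignments[var] = amap
        species[var] = width
    return OptimizationMap(assignments, species)


def global_value_map(tree: ValueTree) -> OptimizationMap:
    """Scope-blind control map: every variable's values are numbered
    globally by descending total count (ties lexicographic), ignoring
    the parental hierarchy.  Reproduces the degraded translation used
    to show what the scoped optimization buys."""
    assignments: dict[str, dict[tuple[Path, SeqTuple], int]] = {}
    species: dict[str, int] = {}
    for var in tree.variables:
        totals: Counter = Counter()
        for counter in tree.scopes.get(var, {}).values():
            totals.update(counter)
        ranks = _rank_scope(totals)
        amap: dict[tuple[Path, SeqTuple], int] = {}
        for path, counter in tree.scopes.get(var, {}).items():
            for val in counter:
                amap[(path, val)] = ranks[val]
        assignments[var] = amap
        species[var] = len(ranks)
    return OptimizationMap(assignments, species)


def _fmt_path(path: Path) -> str:
    return "|".join("+".join(v) for v in path)


def write_value_tree(tree: ValueTree, path) -> None:
    """Serialize as TSV (variable, parent_path, value, count); levels of
    the parent path join with '|', combinatorial members with '+'."""
    with open(path, "w") as fh:
        fh.write("variable\tparent_path\tvalue\tcount\n")
        for var in tree.variables:
            for ppath in sorted(tree.scopes.get(var, {})):
                counter = tree.scopes[var][ppath]
                for val in sorted(counter):
                    fh.write(f"{var}\t{_fmt_path(ppath)}\t{'+'.join(val)}\t{counter[val]}\n")
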