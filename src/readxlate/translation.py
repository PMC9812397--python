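"""Destination read assembly: value-to-sequence assignment, quality
bequeathing, spatial conversion tables, and FASTQ emission.

Each destination variable owns an ordered list of *units* (an IUPAC
template or an allowlist pool).  An optimized value is encoded in
mixed radix over the unit capacities, most-significant unit first;
IUPAC positions enumerate their base set alphabetically and allowlist
units index file order.  The scheme is injective over the pool
capacity, and because optimized values rank frequent values first, the
most frequent values land in the earliest pool entries.  Values beyond
capacity drop the read (frequent values are prioritized).

Average source-segment Q scores are bequeathed to every base of the
corresponding destination segment; bases carrying no source value
(constant fillers, pad bases) get exactly Q40.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import floor, prod
from typing import Iterable, Sequence

import numpy as np

from .config import (
    DestinationSpec,
    PipelineConfig,
    UnitSpec,
    iupac_base_set,
    load_allowlist,
    load_conversion_table,
)
from .segmentation import PHRED_OFFSET, ReadTuple, write_fastq
from .valuespace import OptimizationMap, ValueRecord

__all__ = [
    "CapacityOverflow",
    "DestinationUnit",
    "DestinationPool",
    "build_pools",
    "destination_capacity",
    "assign_destination_sequence",
    "bequeath_quality",
    "translate_record",
    "SpatialAssignment",
    "build_spatial_conversion_table",
    "emit_destination_fastq",
    "DROP_REASONS",
]

DROP_REASONS = ("no_match", "quality", "correction_drop", "capacity", "table_miss")

Q_FILLER = 40
Q_MIN, Q_MAX = 2, 40


class CapacityOverflow(ValueError):
    """Optimized value exceeds the destination pool capacity."""


@dataclass(frozen=True)
class DestinationUnit:
    """One unit with a deterministic, injective index -> sequence map."""

    base_sets: tuple[str, ...] | None  # IUPAC template, one set per position
    pool: tuple[str, ...] | None  # allowlist entries in file order

    @classmethod
    def from_spec(cls, spec: UnitSpec) -> "DestinationUnit":
        if spec.iupac is not None:
            return cls(tuple(iupac_base_set(c) for c in spec.iupac), None)
        return cls(None, tuple(load_allowlist(spec.allowlist)))

    @property
    def capacity(self) -> int:
        if self.pool is not None:
            return len(self.pool)
        return prod(len(s) for s in self.base_sets)

    def sequence_at(self, index: int) -> str:
        if not 0 <= index < self.capacity:
            raise CapacityOverflow(f"unit index {index} outside capacity {self.capacity}")
        if self.pool is not None:
            return self.pool[index]
        # per-position mixed radix over the base sets, leftmost most significant
        out = []
        rem = index
        for s in reversed(self.base_sets):
            rem, digit = divmod(rem, len(s))
            out.append(s[digit])
        return "".join(reversed(out))


@dataclass(frozen=True)
class DestinationPool:
    """Ordered units of one destination variable; capacity is the
    product of unit capacities."""

    units: tuple[DestinationUnit, ...]

    @property
    def capacity(self) -> int:
        return prod(u.capacity for u in self.units)

    def sequence_for(self, value: int) -> str:
        if not 0 <= value < self.capacity:
            raise CapacityOverflow(f"value {value} outside pool capacity {self.capacity}")
        digits: list[int] = []
        rem = value
        for unit in reversed(self.units):
            rem, digit = divmod(rem, unit.capacity)
            digits.append(digit)
        return "".join(u.sequence_at(d) for u, d in zip(self.units, reversed(digits)))


def build_pools(cfg: PipelineConfig) -> dict[str, DestinationPool]:
    return {
        d.name: DestinationPool(tuple(DestinationUnit.from_spec(u) for u in d.units))
        for d in cfg.destinations
        if d.strategy == "reassign"
    }


def destination_capacity(units: Sequence[UnitSpec]) -> int:
    return prod(DestinationUnit.from_spec(u).capacity for u in units)


def assign_destination_sequence(value: int, units: Sequence[UnitSpec]) -> str:
    return DestinationPool(tuple(DestinationUnit.from_spec(u) for u in units)).sequence_for(value)


def bequeath_quality(source_qs: Sequence[float], dest_len: int,
                     inherited: Sequence[bool] | None = None) -> str:
    """Phred+33 quality string for one destination segment.

    Inherited positions carry round-half-up of the mean of the
    contributing segments' average Q, clamped to [2, 40]; positions
    carrying no source value get exactly Q40.
    """
    if dest_len < 1:
        raise ValueError("dest_len must be >= 1")
    if inherited is None:
        inherited = [bool(source_qs)] * dest_len
    if any(inherited):
        mean = sum(source_qs) / len(source_qs)
        q = min(Q_MAX, max(Q_MIN, floor(mean + 0.5)))
    else:
        q = Q_FILLER
    inh, fill = chr(q + PHRED_OFFSET), chr(Q_FILLER + PHRED_OFFSET)
    return "".join(inh if m else fill for m in inherited)


def _segments_of(vrec: ValueRecord, members: tuple[str, ...]):
    return [vrec.record.segments[m] for m in members]


def translate_record(
    vrec: ValueRecord,
    opt: OptimizationMap,
    cfg: PipelineConfig,
    pools: dict[str, DestinationPool],
    tables: dict[str, dict[str, str]] | None = None,
) -> ReadTuple | tuple[None, str]:
    """Build the destination read tuple for one value record.

    Returns the tuple, or ``(None, reason)`` with reason ``capacity``
    or ``table_miss`` when the record cannot be represented.
    """
    tables = tables or {}
    parts: dict[int, list[tuple[int, str, str]]] = {}
    for dest in cfg.destinations:
        if dest.strategy == "constant":
            seq = dest.constant
            qual = chr(Q_FILLER + PHRED_OFFSET) * len(seq)
        else:
            var = cfg.variable(dest.source)
            if not all(m in vrec.record.segments for m in var.member_segments):
                return None, "no_match"
            segs = _segments_of(vrec, var.member_segments)
            if dest.strategy == "passthrough":
                seq = "".join(s.seq for s in segs)
                qual = "".join(s.qual for s in segs)
            elif dest.strategy == "bequeath_pad":
                src = "".join(s.seq for s in segs)
                if dest.length < len(src):
                    return None, "capacity"
                seq = src + dest.pad_base * (dest.length - len(src))
                mask = [True] * len(src) + [False] * (dest.length - len(src))
                qual = bequeath_quality([s.avg_q for s in segs], dest.length, mask)
            elif dest.strategy == "conversion_table":
                key = "".join(s.seq for s in segs)
                table = tables.get(dest.name)
                if table is None or key not in table:
                    return None, "table_miss"
                seq = table[key]
                qual = bequeath_quality([s.avg_q for s in segs], len(seq))
            else:  # reassign
                path = tuple(vrec.values[a] for a in cfg.ancestry(var.name))
                value = opt.value(var.name, path, vrec.values[var.name])
                pool = pools[dest.name]
                if value >= pool.capacity:
                    return None, "capacity"
                seq = pool.sequence_for(value)
                qual = bequeath_quality([s.avg_q for s in segs], len(seq))
        parts.setdefault(dest.read_index, []).append((dest.order, seq, qual))

    n_reads = max(parts) + 1
    seqs, quals = [], []
    for ri in range(n_reads):
        chunks = sorted(parts.get(ri, []))
        seqs.append("".join(c[1] for c in chunks))
        quals.append("".join(c[2] for c in chunks))
    return ReadTuple(vrec.read_id, tuple(seqs), tuple(quals))


# ---------------------------------------------------------------------------
# spatial tiling conversion-table builder
# ---------------------------------------------------------------------------


@dataclass
class SpatialAssignment:
    """Bead -> (tile, spot) assignment plus coverage statistics."""

    table: dict[str, tuple[tuple[int, int], str]]
    unassigned: list[str]
    beads_per_spot: Counter = field(default_factory=Counter)
    unique_fraction: float = 0.0

    def conversion_table(self) -> dict[str, str]:
        """Bead barcode -> spot barcode (tile membership dropped)."""
        return {bead: spot for bead, (_, spot) in self.table.items()}


def build_spatial_conversion_table(
    bead_coords: dict[str, tuple[float, float]],
    spot_layout: dict[str, tuple[float, float]],
    tile_size: tuple[float, float],
    grid_shape: tuple[int, int],
    scale: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> SpatialAssignment:
    """Tile destination arrays across the scaled source field and assign
    every bead to the Euclidean-nearest spot of its containing tile.

    Bead coordinates are multiplied by ``scale``; the tile grid starts
    at ``origin`` with pitch ``tile_size`` and spans ``grid_shape``
    (nx, ny) tiles, each carrying ``spot_layout`` in local coordinates.
    Beads falling outside the grid are reported as unassigned.
    Equidistant spots resolve to the lowest spot index (layout order);
    many beads may share one spot.
    """
    spot_names = list(spot_layout)
    spot_xy = np.array([spot_layout[s] for s in spot_names], dtype=float)
    (w, h), (nx, ny) = tile_size, grid_shape
    table: dict[str, tuple[tuple[int, int], str]] = {}
    unassigned: list[str] = []
    per_spot: Counter = Counter()
    for bead in bead_coords:
        x, y = bead_coords[bead]
        sx, sy = x * scale - origin[0], y * scale - origin[1]
        tx, ty = int(np.floor(sx / w)), int(np.floor(sy / h))
        if not (0 <= tx < nx and 0 <= ty < ny):
            unassigned.append(bead)
            continue
        local = np.array([sx - tx * w, sy - ty * h])
        d2 = ((spot_xy - local) ** 2).sum(axis=1)
        spot = spot_names[int(np.argmin(d2))]  # first minimum = lowest index
        table[bead] = ((tx, ty), spot)
        per_spot[((tx, ty), spot)] += 1
    n_beads = len(bead_coords)
    unique = sum(1 for key, n in per_spot.items() if n == 1)
    frac = unique / n_beads if n_beads else 0.0
    return SpatialAssignment(table, unassigned, per_spot, frac)


def emit_destination_fastq(
    tuples: Iterable[ReadTuple], paths: Sequence
) -> dict[str, int]:
    """Write destination tuples as one FASTQ(.gz) per output read.

    Returns a manifest of per-file record counts; read IDs are
    preserved from the source.
    """
    tuples = list(tuples)
    manifest: dict[str, int] = {}
    for ri, path in enumerate(paths):
        n = write_fastq(path, ((t.read_id, t.seqs[ri], t.quals[ri]) for t in tuples))
        manifest[str(path)] = n
    return manifest


def load_tables_for_config(cfg: PipelineConfig) -> dict[str, dict[str, str]]:
    return {
        d.name: load_conversion_table(d.table)
        for d in cfg.destinations
        if d.strategy == "conversion_table"
    }
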