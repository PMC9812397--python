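"""Declarative description of sequencing-read structures.

A single process configuration declares everything a run needs:

* ``source_structures`` -- one or more read layouts over the input FASTQ
  tuple, each a list of named segments located either by a fixed span or
  by fuzzy flanking motifs (anchors);
* ``variables`` -- how segments combine into information-bearing
  variables (singleton or combinatorial), their parental/local
  hierarchy, and the error-correction policy per variable;
* ``quality`` -- segment-level Phred thresholds;
* ``destinations`` -- how each variable is re-emitted into the output
  read structure (value reassignment into IUPAC/allowlist pools,
  bequeath-and-pad, conversion table, or verbatim pass-through);
* ``settings`` -- chunk size and the simulator seed.

The dialect is YAML with those five top-level sections.  Coordinates are
0-based half-open.  Reads are taken exactly as stored in FASTQ; a
reverse-complement layout must be declared as its own structure.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "ConfigError",
    "FixedSpan",
    "Anchored",
    "SegmentSpec",
    "CorrectionSpec",
    "VariableSpec",
    "QualityPolicy",
    "UnitSpec",
    "DestinationSpec",
    "ReadStructure",
    "PipelineConfig",
    "ReadMatcher",
    "parse_config",
    "load_config",
    "serialize_config",
    "compile_matcher",
    "iupac_base_set",
    "load_allowlist",
    "load_conversion_table",
]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent process configurations."""


# IUPAC degenerate nucleotide codes, each expanded to its (sorted) base set.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_base_set(code: str) -> str:
    """Return the alphabetically ordered base set for one IUPAC code.

    Lowercase codes are rejected: templates are uppercase by contract.
    """
    try:
        return _IUPAC[code]
    except KeyError:
        raise ConfigError(f"invalid IUPAC code {code!r}") from None


@dataclass(frozen=True)
class FixedSpan:
    """Segment located at fixed 0-based half-open coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ConfigError(f"fixed span requires 0 <= start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class Anchored:
    """Segment located between two flanking motifs with fuzzy matching.

    Each motif is matched with an ``inner_exact_len``-base exact core on
    the edge adjacent to the segment, tolerating up to
    ``outer_max_mismatch`` substitutions in the remaining outer bases.
    ``N`` in the read mismatches every motif base.
    """

    upstream: str
    downstream: str
    inner_exact_len: int = 3
    outer_max_mismatch: int = 2

    def __post_init__(self) -> None:
        for motif in (self.upstream, self.downstream):
            if not motif or set(motif) - set("ACGT"):
                raise ConfigError(f"anchor motif must be non-empty over ACGT, got {motif!r}")
        if self.inner_exact_len > min(len(self.upstream), len(self.downstream)):
            raise ConfigError("inner_exact_len exceeds motif length")
        if self.inner_exact_len < 0 or self.outer_max_mismatch < 0:
            raise ConfigError("anchor policy values must be non-negative")


@dataclass(frozen=True)
class SegmentSpec:
    name: str
    read_index: int
    locator: FixedSpan | Anchored
    min_len: int | None = None  # anchored only; fixed spans imply their length
    max_len: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.locator, Anchored):
            if self.min_len is None or self.max_len is None:
                raise ConfigError(f"segment {self.name!r}: anchored locator requires min_len and max_len")
            if not (0 < self.min_len <= self.max_len):
                raise ConfigError(f"segment {self.name!r}: need 0 < min_len <= max_len")


@dataclass(frozen=True)
class CorrectionSpec:
    """Error-correction policy of one variable (applied per member segment).

    ``method`` is one of ``imputation_to_majority`` (knee-point accepted
    set), ``allowlist``, ``plugin`` (external command contract), or
    ``none``.  ``allowlist`` may be a file path, an inline sequence
    list, or -- for combinatorial variables -- one per member segment.
    """

    method: str = "none"
    levenshtein_max: int = 1
    allowlist: object = None  # path | [seq, ...] | [path-or-list per member segment]
    plugin_command: str | None = None

    _METHODS = ("imputation_to_majority", "allowlist", "plugin", "none")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ConfigError(f"unknown correction method {self.method!r}")
        if self.levenshtein_max < 0:
            raise ConfigError("levenshtein_max must be >= 0")
        if self.method == "allowlist" and self.allowlist is None:
            raise ConfigError("allowlist correction requires an allowlist")
        if self.method == "plugin" and not self.plugin_command:
            raise ConfigError("plugin correction requires plugin_command")


@dataclass(frozen=True)
class VariableSpec:
    """One information-bearing variable over one or more segments.

    ``role`` is ``independent``, ``parental`` or ``local``; ``local``
    requires ``parent``.  A variable is *valued* (participates in the
    value tree and can be reassigned on translation) when it is part of
    the hierarchy or carries a correction method; payload variables
    (independent, method ``none``) pass through as raw sequence+quality.
    """

    name: str
    member_segments: tuple[str, ...]
    role: str = "independent"
    parent: str | None = None
    correction: CorrectionSpec = field(default_factory=CorrectionSpec)
    valued: bool | None = None  # None = derive from role/correction

    def __post_init__(self) -> None:
        if self.role not in ("independent", "parental", "local"):
            raise ConfigError(f"variable {self.name!r}: unknown role {self.role!r}")
        if (self.role == "local") != (self.parent is not None):
            raise ConfigError(f"variable {self.name!r}: role 'local' and 'parent' must be set together")
        if not self.member_segments:
            raise ConfigError(f"variable {self.name!r}: needs at least one member segment")

    @property
    def is_valued(self) -> bool:
        if self.valued is not None:
            return self.valued
        return self.role in ("parental", "local") or self.correction.method != "none"


@dataclass(frozen=True)
class QualityPolicy:
    """Segment-level Phred thresholds; a record failing any governed
    segment is dropped whole. Thresholds read "below X fails", so equal
    values pass."""

    min_avg_q: float = 0.0
    min_base_q: int = 0
    applies_to: object = "all"  # "all" | tuple of segment names

    def __post_init__(self) -> None:
        if not (0 <= self.min_base_q <= self.min_avg_q <= 41):
            raise ConfigError("quality policy requires 0 <= min_base_q <= min_avg_q <= 41")

    def governs(self, segment: str) -> bool:
        return self.applies_to == "all" or segment in self.applies_to


@dataclass(frozen=True)
class UnitSpec:
    """One destination unit: an IUPAC template or an allowlist pool."""

    iupac: str | None = None
    allowlist: object = None  # path | inline [seq, ...]

    def __post_init__(self) -> None:
        if (self.iupac is None) == (self.allowlist is None):
            raise ConfigError("destination unit needs exactly one of iupac/allowlist")
        if self.iupac is not None:
            if self.iupac != self.iupac.upper():
                raise ConfigError("lowercase IUPAC template rejected")
            for code in self.iupac:
                iupac_base_set(code)


@dataclass(frozen=True)
class DestinationSpec:
    """Placement and construction rule for one destination segment."""

    name: str
    read_index: int
    order: int
    strategy: str = "reassign"  # reassign|bequeath_pad|conversion_table|passthrough|constant
    source: str | None = None  # source variable name (all but constant)
    units: tuple[UnitSpec, ...] = ()
    length: int | None = None  # bequeath_pad target length
    pad_base: str = "A"
    table: object = None  # conversion table: path | inline {src: dst}
    constant: str | None = None

    _STRATEGIES = ("reassign", "bequeath_pad", "conversion_table", "passthrough", "constant")

    def __post_init__(self) -> None:
        if self.strategy not in self._STRATEGIES:
            raise ConfigError(f"destination {self.name!r}: unknown strategy {self.strategy!r}")
        if self.strategy == "constant":
            if not self.constant or set(self.constant) - set("ACGT"):
                raise ConfigError(f"destination {self.name!r}: constant requires an ACGT literal")
        elif self.source is None:
            raise ConfigError(f"destination {self.name!r}: requires a source variable")
        if self.strategy == "reassign" and not self.units:
            raise ConfigError(f"destination {self.name!r}: reassign requires >= 1 unit")
        if self.strategy == "bequeath_pad":
            if self.length is None or self.length < 1:
                raise ConfigError(f"destination {self.name!r}: bequeath_pad requires a positive length")
            if self.pad_base not in "ACGT" or len(self.pad_base) != 1:
                raise ConfigError(f"destination {self.name!r}: pad_base must be one of ACGT")
        if self.strategy == "conversion_table" and self.table is None:
            raise ConfigError(f"destination {self.name!r}: conversion_table requires a table")


@dataclass(frozen=True)
class ReadStructure:
    name: str
    segments: tuple[SegmentSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ConfigError(f"structure {self.name!r}: duplicate segment names")

    @property
    def n_reads(self) -> int:
        return 1 + max(s.read_index for s in self.segments)


@dataclass(frozen=True)
class PipelineConfig:
    structures: tuple[ReadStructure, ...]
    variables: tuple[VariableSpec, ...]
    quality: QualityPolicy = field(default_factory=QualityPolicy)
    destinations: tuple[DestinationSpec, ...] = ()
    chunk_size: int = 100_000
    random_seed: int = 0

    def __post_init__(self) -> None:
        self._validate()

    # -- lookups ---------------------------------------------------------

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def variable_of_segment(self, segment: str) -> VariableSpec:
        for v in self.variables:
            if segment in v.member_segments:
                return v
        raise KeyError(segment)

    def ancestry(self, name: str) -> tuple[str, ...]:
        """Ancestor variable names from root down to the parent of `name`."""
        chain: list[str] = []
        var = self.variable(name)
        while var.parent is not None:
            chain.append(var.parent)
            var = self.variable(var.parent)
        return tuple(reversed(chain))

    def topological_variables(self) -> tuple[VariableSpec, ...]:
        """Valued variables ordered parents-before-children."""
        return tuple(
            sorted(
                (v for v in self.variables if v.is_valued),
                key=lambda v: (len(self.ancestry(v.name)), v.name),
            )
        )

    def checksum(self) -> str:
        return hashlib.sha256(serialize_config(self).encode()).hexdigest()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        if not self.structures:
            raise ConfigError("at least one source structure is required")
        if self.chunk_size < 1:
            raise ConfigError("chunk_size must be >= 1")
        var_names = [v.name for v in self.variables]
        if len(set(var_names)) != len(var_names):
            raise ConfigError("duplicate variable names")

        # every segment belongs to exactly one variable
        owner: dict[str, str] = {}
        for v in self.variables:
            for seg in v.member_segments:
                if seg in owner and owner[seg] != v.name:
                    raise ConfigError(
                        f"segment {seg!r} referenced by two variables ({owner[seg]!r}, {v.name!r})"
                    )
                owner[seg] = v.name
        declared = {s.name for st in self.structures for s in st.segments}
        for seg, var in owner.items():
            if seg not in declared:
                raise ConfigError(f"variable {var!r} references undeclared segment {seg!r}")
        for seg in declared:
            if seg not in owner:
                raise ConfigError(f"segment {seg!r} belongs to no variable")

        # parental graph must be a forest
        for v in self.variables:
            if v.parent is not None and v.parent not in set(var_names):
                raise ConfigError(f"variable {v.name!r}: unknown parent {v.parent!r}")
            seen = {v.name}
            cur = v.parent
            while cur is not None:
                if cur in seen:
                    raise ConfigError(f"parental cycle involving variable {cur!r}")
                seen.add(cur)
                cur = self.variable(cur).parent
        for v in self.variables:
            if v.role == "local" and not self.variable(v.parent).is_valued:
                raise ConfigError(f"variable {v.name!r}: parent {v.parent!r} is not valued")

        for d in self.destinations:
            if d.strategy == "constant":
                continue
            if d.source not in set(var_names):
                raise ConfigError(f"destination {d.name!r}: unknown source variable {d.source!r}")
            if d.strategy == "reassign" and not self.variable(d.source).is_valued:
                raise ConfigError(
                    f"destination {d.name!r}: reassign requires a valued source variable"
                )


# ---------------------------------------------------------------------------
# matcher
# ---------------------------------------------------------------------------


def _flank_matches(seq: str, pos: int, motif: str, inner: str,
                   inner_len: int, max_mm: int) -> bool:
    """Does `motif` match `seq` at `pos` under the inner-exact/outer-fuzzy
    policy?  `inner` names which motif edge abuts the segment."""
    end = pos + len(motif)
    if pos < 0 or end > len(seq):
        return False
    window = seq[pos:end]
    if inner_len:
        core = window[-inner_len:] if inner == "right" else window[:inner_len]
        want = motif[-inner_len:] if inner == "right" else motif[:inner_len]
        if core != want:
            return False
    mm = 0
    if inner == "right":
        outer = range(0, len(motif) - inner_len)
    else:
        outer = range(inner_len, len(motif))
    for k in outer:
        if window[k] != motif[k]:
            mm += 1
            if mm > max_mm:
                return False
    return True


class ReadMatcher:
    """Compiled matcher for one read structure.

    Applied to the per-file sequences of a read tuple it yields every
    declared segment span ``{name: (read_index, start, end)}`` or
    ``None`` (no-match).  Anchored search scans left to right and takes
    the first admissible flank pair, so it is deterministic on
    repetitive reads.
    """

    def __init__(self, structure: ReadStructure):
        self.structure = structure
        by_read: dict[int, list[SegmentSpec]] = {}
        for seg in structure.segments:
            by_read.setdefault(seg.read_index, []).append(seg)
        for ri, segs in by_read.items():
            spans = sorted(
                (s.locator.start, s.locator.end, s.name)
                for s in segs
                if isinstance(s.locator, FixedSpan)
            )
            for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ConfigError(
                        f"structure {structure.name!r}: fixed spans of {n1!r} and {n2!r} "
                        f"overlap on read {ri}"
                    )

    def match(self, seqs: list[str]) -> dict[str, tuple[int, int, int]] | None:
        out: dict[str, tuple[int, int, int]] = {}
        for seg in self.structure.segments:
            if seg.read_index >= len(seqs):
                return None
            seq = seqs[seg.read_index]
            loc = seg.locator
            if isinstance(loc, FixedSpan):
                if loc.end > len(seq):
                    return None
                out[seg.name] = (seg.read_index, loc.start, loc.end)
            else:
                span = self._find_anchored(seq, loc, seg.min_len, seg.max_len)
                if span is None:
                    return None
                out[seg.name] = (seg.read_index, span[0], span[1])
        return out

    @staticmethod
    def _find_anchored(seq: str, loc: Anchored, min_len: int,
                       max_len: int) -> tuple[int, int] | None:
        up, dn = loc.upstream, loc.downstream
        k, mm = loc.inner_exact_len, loc.outer_max_mismatch
        last_up = len(seq) - len(up) - min_len - len(dn)
        for i in range(0, last_up + 1):
            if not _flank_matches(seq, i, up, "right", k, mm):
                continue
            start = i + len(up)
            for L in range(min_len, max_len + 1):
                end = start + L
                if end + len(dn) > len(seq):
                    break
                if _flank_matches(seq, end, dn, "left", k, mm):
                    return (start, end)
        return None


def compile_matcher(structure: ReadStructure) -> ReadMatcher:
    return ReadMatcher(structure)


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

_TOP_KEYS = {"source_structures", "variables", "quality", "destinations", "settings"}


def _require_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_segment(raw: dict, where: str) -> SegmentSpec:
    _require_keys(raw, {"name", "read", "span", "anchored"}, where)
    try:
        name, read = raw["name"], int(raw["read"])
    except KeyError as e:
        raise ConfigError(f"{where}: missing key {e.args[0]!r}") from None
    if ("span" in raw) == ("anchored" in raw):
        raise ConfigError(f"{where}: exactly one of span/anchored is required")
    if "span" in raw:
        start, end = raw["span"]
        return SegmentSpec(name, read, FixedSpan(int(start), int(end)))
    a = raw["anchored"]
    _require_keys(
        a,
        {"upstream", "downstream", "inner_exact_len", "outer_max_mismatch", "min_len", "max_len"},
        f"{where}.anchored",
    )
    loc = Anchored(
        a["upstream"],
        a["downstream"],
        int(a.get("inner_exact_len", 3)),
        int(a.get("outer_max_mismatch", 2)),
    )
    return SegmentSpec(name, read, loc, int(a["min_len"]), int(a["max_len"]))


def _parse_variable(raw: dict) -> VariableSpec:
    where = f"variable {raw.get('name', '?')!r}"
    _require_keys(raw, {"name", "segments", "role", "parent", "correction", "valued"}, where)
    corr = raw.get("correction") or {}
    _require_keys(corr, {"method", "levenshtein_max", "allowlist", "plugin_command"},
                  f"{where}.correction")
    segs = raw.get("segments")
    if isinstance(segs, str):
        segs = [segs]
    return VariableSpec(
        name=raw["name"],
        member_segments=tuple(segs or ()),
        role=raw.get("role", "independent"),
        parent=raw.get("parent"),
        correction=CorrectionSpec(
            method=corr.get("method", "none"),
            levenshtein_max=int(corr.get("levenshtein_max", 1)),
            allowlist=corr.get("allowlist"),
            plugin_command=corr.get("plugin_command"),
        ),
        valued=raw.get("valued"),
    )


def _parse_destination(raw: dict) -> DestinationSpec:
    where = f"destination {raw.get('name', '?')!r}"
    _require_keys(
        raw,
        {"name", "read", "order", "strategy", "source", "units", "length",
         "pad_base", "table", "constant"},
        where,
    )
    units = []
    for u in raw.get("units") or ():
        _require_keys(u, {"iupac", "allowlist"}, f"{where}.units")
        units.append(UnitSpec(iupac=u.get("iupac"), allowlist=u.get("allowlist")))
    strategy = raw.get("strategy", "constant" if "constant" in raw else "reassign")
    return DestinationSpec(
        name=raw["name"],
        read_index=int(raw["read"]),
        order=int(raw["order"]),
        strategy=strategy,
        source=raw.get("source"),
        units=tuple(units),
        length=None if raw.get("length") is None else int(raw["length"]),
        pad_base=raw.get("pad_base", "A"),
        table=raw.get("table"),
        constant=raw.get("constant"),
    )


def parse_config(text: str) -> PipelineConfig:
    """Parse a process configuration document into a validated config."""
    try:
        doc = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as e:
        raise ConfigError(f"malformed configuration: {e}") from None
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping of sections")
    _require_keys(doc, _TOP_KEYS, "top level")

    structures = []
    for i, raw in enumerate(doc.get("source_structures") or ()):
        _require_keys(raw, {"name", "segments"}, f"source_structures[{i}]")
        segs = tuple(
            _parse_segment(s, f"structure {raw.get('name', i)!r} segment {j}")
            for j, s in enumerate(raw.get("segments") or ())
        )
        structures.append(ReadStructure(raw.get("name", f"structure_{i}"), segs))

    variables = tuple(_parse_variable(v) for v in doc.get("variables") or ())

    q = doc.get("quality") or {}
    _require_keys(q, {"min_avg_q", "min_base_q", "applies_to"}, "quality")
    applies = q.get("applies_to", "all")
    quality = QualityPolicy(
        min_avg_q=float(q.get("min_avg_q", 0)),
        min_base_q=int(q.get("min_base_q", 0)),
        applies_to="all" if applies == "all" else tuple(applies),
    )

    destinations = tuple(_parse_destination(d) for d in doc.get("destinations") or ())

    s = doc.get("settings") or {}
    _require_keys(s, {"chunk_size", "random_seed"}, "settings")
    return PipelineConfig(
        structures=tuple(structures),
        variables=variables,
        quality=quality,
        destinations=destinations,
        chunk_size=int(s.get("chunk_size", 100_000)),
        random_seed=int(s.get("random_seed", 0)),
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return parse_config(fh.read())


def _segment_doc(seg: SegmentSpec) -> dict:
    if isinstance(seg.locator, FixedSpan):
        return {"name": seg.name, "read": seg.read_index,
                "span": [seg.locator.start, seg.locator.end]}
    loc = seg.locator
    return {
        "name": seg.name,
        "read": seg.read_index,
        "anchored": {
            "upstream": loc.upstream,
            "downstream": loc.downstream,
            "inner_exact_len": loc.inner_exact_len,
            "outer_max_mismatch": loc.outer_max_mismatch,
            "min_len": seg.min_len,
            "max_len": seg.max_len,
        },
    }


def serialize_config(cfg: PipelineConfig) -> str:
    """Render a config back to the dialect; parse(serialize(c)) == c."""
    doc: dict = {
        "source_structures": [
            {"name": st.name, "segments": [_segment_doc(s) for s in st.segments]}
            for st in cfg.structures
        ],
        "variables": [],
        "quality": {
            "min_avg_q": cfg.quality.min_avg_q,
            "min_base_q": cfg.quality.min_base_q,
            "applies_to": "all" if cfg.quality.applies_to == "all" else list(cfg.quality.applies_to),
        },
        "destinations": [],
        "settings": {"chunk_size": cfg.chunk_size, "random_seed": cfg.random_seed},
    }
    for v in cfg.variables:
        raw: dict = {"name": v.name, "segments": list(v.member_segments), "role": v.role}
        if v.parent is not None:
            raw["parent"] = v.parent
        corr: dict = {"method": v.correction.method,
                      "levenshtein_max": v.correction.levenshtein_max}
        if v.correction.allowlist is not None:
            corr["allowlist"] = v.correction.allowlist
        if v.correction.plugin_command is not None:
            corr["plugin_command"] = v.correction.plugin_command
        raw["correction"] = corr
        if v.valued is not None:
            raw["valued"] = v.valued
        doc["variables"].append(raw)
    for d in cfg.destinations:
        raw = {"name": d.name, "read": d.read_index, "order": d.order, "strategy": d.strategy}
        if d.source is not None:
            raw["source"] = d.source
        if d.units:
            raw["units"] = [
                {"iupac": u.iupac} if u.iupac is not None else {"allowlist": u.allowlist}
                for u in d.units
            ]
        if d.length is not None:
            raw["length"] = d.length
        if d.strategy == "bequeath_pad":
            raw["pad_base"] = d.pad_base
        if d.table is not None:
            raw["table"] = d.table
        if d.constant is not None:
            raw["constant"] = d.constant
        doc["destinations"].append(raw)
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# external resources
# ---------------------------------------------------------------------------


def load_allowlist(source) -> list[str]:
    """Load an allowlist: inline sequence list, or a path to a one-
    sequence-per-line text file.  Order is preserved (file order indexes
    destination pools)."""
    if isinstance(source, (list, tuple)):
        seqs = [str(s) for s in source]
    else:
        with open(source) as fh:
            seqs = [line.split("\t")[0].strip() for line in fh if line.strip()]
    if not seqs:
        raise ConfigError(f"allowlist {source!r} is empty")
    for s in seqs:
        if set(s) - set("ACGT"):
            raise ConfigError(f"allowlist entry {s!r} is not uppercase ACGT")
    if len(set(seqs)) != len(seqs):
        raise ConfigError(f"allowlist {source!r} contains duplicates")
    return seqs


def load_conversion_table(source) -> dict[str, str]:
    """Load a source->destination sequence table: inline mapping, or a
    headerless 2-column TSV path."""
    if isinstance(source, dict):
        return {str(k): str(v) for k, v in source.items()}
    table: dict[str, str] = {}
    with open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ConfigError(f"{source}:{lineno}: expected 2 tab-separated columns")
            table[parts[0]] = parts[1]
    if not table:
        raise ConfigError(f"conversion table {source!r} is empty")
    return table


def with_seed(cfg: PipelineConfig, seed: int) -> PipelineConfig:
    return replace(cfg, random_seed=seed)
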