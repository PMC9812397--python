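"""Synthetic structured-read libraries with ground truth.

Each generator emulates one family of read structures demonstrated in
the field -- droplet scRNA-seq (cell ID + UMI + cDNA payload),
row/column/plate well barcoding, combinatorial-index ATAC,
spatially barcoded bead libraries, and anchored long reads -- at desk
scale, and returns the FASTQ tuples, a per-read truth table, and the
matching process configuration, so that interpretation and translation
can be checked against known values.

Sequencing error is a per-base substitution rate plus an optional
single-indel rate; zero-error output is exactly decodable.  All
randomness flows from one integer seed and the same seed reproduces
byte-identical FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    Anchored,
    CorrectionSpec,
    DestinationSpec,
    FixedSpan,
    PipelineConfig,
    QualityPolicy,
    ReadStructure,
    SegmentSpec,
    UnitSpec,
    VariableSpec,
)
from .correction import levenshtein
from .segmentation import write_fastq

__all__ = [
    "SimResult",
    "random_barcodes",
    "simulate_scrna",
    "simulate_rcppcr",
    "simulate_combinatorial_atac",
    "simulate_spatial",
    "simulate_longread",
    "scrna_destinations",
    "POOL_4BP",
    "LOX_SITE",
]

_BASES = "ACGT"

# ten fixed 4-bp pool sequences for multi-unit destination segments
POOL_4BP = ["AAAA", "CCCC", "GGGG", "TTTT", "AACC", "CCAA", "GGTT", "TTGG", "ACGT", "TGCA"]

# stand-in recombination-site constant checked for integrity in well calling
LOX_SITE = "ATAACTTCGTAT"


@dataclass
class SimResult:
    """FASTQ tuples plus ground truth and the matching configuration."""

    reads: list[list[tuple[str, str, str]]]  # per file: (read_id, seq, qual)
    truth: pd.DataFrame
    config: PipelineConfig
    aux: dict = field(default_factory=dict)

    def write(self, outdir, prefix: str = "read", gz: bool = False) -> list[str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        suffix = ".fastq.gz" if gz else ".fastq"
        paths = []
        for i, recs in enumerate(self.reads):
            p = outdir / f"{prefix}{i + 1}{suffix}"
            write_fastq(p, recs)
            paths.append(str(p))
        return paths


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def random_barcodes(
    rng: np.random.Generator, n: int, length: int, min_dist: int = 0
) -> list[str]:
    """Distinct random barcodes with pairwise Levenshtein distance >=
    `min_dist` (rejection sampling)."""
    out: list[str] = []
    seen: set[str] = set()
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200 * n + 1000:
            raise RuntimeError(f"cannot place {n} barcodes of length {length} at distance {min_dist}")
        cand = _rand_seq(rng, length)
        if cand in seen:
            continue
        if min_dist > 1 and any(
            levenshtein(cand, b, k=min_dist - 1) < min_dist for b in out
        ):
            continue
        out.append(cand)
        seen.add(cand)
    return out


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            indel_rate: float = 0.0) -> tuple[str, int]:
    """Inject substitutions at `sub_rate` per base and, with probability
    `indel_rate`, one 1-base insertion or deletion."""
    edits = 0
    if sub_rate > 0:
        chars = list(seq)
        for i in np.flatnonzero(rng.random(len(chars)) < sub_rate):
            alt = _BASES.replace(chars[i], "")
            chars[i] = alt[rng.integers(0, 3)]
            edits += 1
        seq = "".join(chars)
    if indel_rate > 0 and rng.random() < indel_rate:
        pos = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5:
            seq = seq[:pos] + _BASES[rng.integers(0, 4)] + seq[pos:]
        else:
            seq = seq[:pos] + seq[pos + 1 :]
        edits += 1
    return seq, edits


def _qual(length: int) -> str:
    return "I" * length  # Q40


# ---------------------------------------------------------------------------
# droplet scRNA-seq: cell ID + UMI on read 1, cDNA payload on read 2
# ---------------------------------------------------------------------------


def _scrna_config(cell_len: int, umi_len: int, gene_len: int,
                  cells: list[str], cell_correction: str) -> PipelineConfig:
    corr = {"none": CorrectionSpec("none"),
            "imputation_to_majority": CorrectionSpec("imputation_to_majority", 1),
            "allowlist": CorrectionSpec("allowlist", 1, allowlist=list(cells))}[cell_correction]
    structure = ReadStructure(
        "scrna",
        (
            SegmentSpec("cell", 0, FixedSpan(0, cell_len)),
            SegmentSpec("umi", 0, FixedSpan(cell_len, cell_len + umi_len)),
            SegmentSpec("cdna", 1, FixedSpan(0, gene_len)),
        ),
    )
    variables = (
        VariableSpec("cellID", ("cell",), role="parental", correction=corr),
        VariableSpec("umiID", ("umi",), role="local", parent="cellID"),
        VariableSpec("payload", ("cdna",)),
    )
    return PipelineConfig((structure,), variables, QualityPolicy())


def scrna_destinations(kind: str, gene_len: int = 20) -> tuple[DestinationSpec, ...]:
    """Canonical destination layouts for the scRNA family.

    ``tenx_v3``: 16-base cell ID and 12-base UMI on read 1 (droplet
    V3 layout); ``hypothetical``: compressed 11-base cell ID and
    7-base UMI; ``multilayer``: the cell ID as five 4-bp units drawn
    from a ten-sequence pool and the UMI as five 2-bp degenerate
    units.  cDNA passes through on read 2 in every layout.
    """
    if kind == "tenx_v3":
        cell = (UnitSpec(iupac="N" * 16),)
        umi = (UnitSpec(iupac="N" * 12),)
    elif kind == "hypothetical":
        cell = (UnitSpec(iupac="N" * 11),)
        umi = (UnitSpec(iupac="N" * 7),)
    elif kind == "multilayer":
        cell = tuple(UnitSpec(allowlist=list(POOL_4BP)) for _ in range(5))
        umi = tuple(UnitSpec(iupac="NN") for _ in range(5))
    else:
        raise ValueError(f"unknown destination kind {kind!r}")
    return (
        DestinationSpec("d_cell", 0, 0, "reassign", source="cellID", units=cell),
        DestinationSpec("d_umi", 0, 1, "reassign", source="umiID", units=umi),
        DestinationSpec("d_cdna", 1, 0, "passthrough", source="payload"),
    )


def simulate_scrna(
    n_cells: int = 50,
    n_genes: int = 20,
    max_umis: int = 5,
    geom_p: float = 0.4,
    reads_per_umi: int = 1,
    cell_len: int = 16,
    umi_len: int = 12,
    gene_len: int = 20,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    min_cell_dist: int = 3,
    cell_correction: str = "none",
    seed: int = 0,
) -> SimResult:
    """Droplet scRNA-seq style library.

    Every (cell, gene) pair receives a truncated-geometric number of
    molecules (1..max_umis), each with a fresh UMI local to the cell;
    the uneven per-cell UMI scope sizes are what makes value-space
    minimization non-trivial.  Cell barcodes keep pairwise Levenshtein
    distance >= `min_cell_dist` so that error correction is decidable.
    """
    rng = np.random.default_rng(seed)
    cells = random_barcodes(rng, n_cells, cell_len, min_dist=min_cell_dist)
    genes = random_barcodes(rng, n_genes, gene_len)
    r1, r2, rows = [], [], []
    rid = 0
    for cell in cells:
        used_umis: set[str] = set()
        for gene in genes:
            n_umis = min(int(rng.geometric(geom_p)), max_umis)
            for _ in range(n_umis):
                umi = _rand_seq(rng, umi_len)
                while umi in used_umis:
                    umi = _rand_seq(rng, umi_len)
                used_umis.add(umi)
                for _ in range(reads_per_umi):
                    s1, e1 = _mutate(rng, cell + umi, sub_rate, indel_rate)
                    s2, e2 = _mutate(rng, gene, sub_rate, indel_rate)
                    name = f"r{rid:07d}"
                    r1.append((name, s1, _qual(len(s1))))
                    r2.append((name, s2, _qual(len(s2))))
                    rows.append((name, cell, umi, gene, e1 + e2))
                    rid += 1
    truth = pd.DataFrame(rows, columns=["read_id", "cell", "umi", "gene", "n_edits"])
    cfg = _scrna_config(cell_len, umi_len, gene_len, cells, cell_correction)
    return SimResult([r1, r2], truth, cfg, {"cells": cells, "genes": genes})


# ---------------------------------------------------------------------------
# row/column/plate well barcoding (two Tag/Lox layouts per cassette family)
# ---------------------------------------------------------------------------

_LIBTAGS = ["ACACACAC", "GTGTGTGT", "TTGGCCAA", "CCAATTGG"]  # DB-Tag, DB-Lox, AD-Tag, AD-Lox
_SPACER = "ACGTACGT"


def _rcppcr_config(pbcs, rbcs, cbcs) -> PipelineConfig:
    def tag_structure(name, libtag):
        return ReadStructure(name, (
            SegmentSpec("pbc", 0, Anchored(libtag, _SPACER, 8, 0), 6, 6),
            SegmentSpec("rbc", 0, FixedSpan(22, 28)),
            SegmentSpec("cbc", 0, FixedSpan(28, 34)),
            SegmentSpec("uptag", 0, FixedSpan(34, 44)),
            SegmentSpec("dntag", 0, FixedSpan(44, 54)),
        ))

    def lox_structure(name, libtag):
        return ReadStructure(name, (
            SegmentSpec("pbc", 0, Anchored(libtag, _SPACER, 8, 0), 6, 6),
            SegmentSpec("rbc", 0, FixedSpan(22, 28)),
            SegmentSpec("cbc", 0, FixedSpan(28, 34)),
            SegmentSpec("loxtag", 0, FixedSpan(34, 44)),
            SegmentSpec("lox", 0, FixedSpan(44, 44 + len(LOX_SITE))),
        ))

    structures = (
        tag_structure("DB_Tag", _LIBTAGS[0]),
        lox_structure("DB_Lox", _LIBTAGS[1]),
        tag_structure("AD_Tag", _LIBTAGS[2]),
        lox_structure("AD_Lox", _LIBTAGS[3]),
    )
    variables = (
        VariableSpec("PBC", ("pbc",), correction=CorrectionSpec("allowlist", 1, allowlist=list(pbcs))),
        VariableSpec("RBC", ("rbc",), correction=CorrectionSpec("allowlist", 1, allowlist=list(rbcs))),
        VariableSpec("CBC", ("cbc",), correction=CorrectionSpec("allowlist", 1, allowlist=list(cbcs))),
        VariableSpec("Uptag", ("uptag",)),
        VariableSpec("Dntag", ("dntag",)),
        VariableSpec("LoxTag", ("loxtag",)),
        VariableSpec("LoxSite", ("lox",)),
    )
    return PipelineConfig(structures, variables, QualityPolicy(min_avg_q=20, min_base_q=10))


def simulate_rcppcr(
    n_plates: int = 2,
    rows: int = 16,
    cols: int = 24,
    reads_per_well: int = 12,
    nonclonal_frac: float = 0.15,
    lox_error_frac: float = 0.0,
    sub_rate: float = 0.0,
    seed: int = 0,
) -> SimResult:
    """Pooled mixture of the four well-barcoding layouts.

    Each plate alternates between the two cassette families; every well
    carries a clonal Uptag/Dntag pair except a `nonclonal_frac`
    fraction, whose reads split 50/50 between two competing pairs.  The
    full 384-well geometry (16 rows x 24 columns) is the default.
    """
    rng = np.random.default_rng(seed)
    pbcs = random_barcodes(rng, n_plates, 6, min_dist=3)
    rbcs = random_barcodes(rng, rows, 6, min_dist=3)
    cbcs = random_barcodes(rng, cols, 6, min_dist=3)
    r0, rows_out = [], []
    wells: dict[tuple[str, str, str], dict] = {}
    rid = 0
    for pi, pbc in enumerate(pbcs):
        family = pi % 2  # 0 = DB (structures 0/1), 1 = AD (structures 2/3)
        for rbc in rbcs:
            for cbc in cbcs:
                clonal = rng.random() >= nonclonal_frac
                tags = [( _rand_seq(rng, 10), _rand_seq(rng, 10))]
                if not clonal:
                    tags.append((_rand_seq(rng, 10), _rand_seq(rng, 10)))
                wells[(pbc, rbc, cbc)] = {"clonal": clonal, "uptag": tags[0][0], "dntag": tags[0][1]}
                for kind in ("tag", "lox"):
                    sidx = (2 * family) + (0 if kind == "tag" else 1)
                    libtag = _LIBTAGS[sidx]
                    for k in range(reads_per_well):
                        uptag, dntag = tags[k % len(tags)]
                        if kind == "tag":
                            payload = uptag + dntag
                        else:
                            loxtag = uptag if family == 0 else dntag
                            lox = LOX_SITE
                            lox_ok = True
                            if rng.random() < lox_error_frac:
                                lox, _ = _mutate(rng, LOX_SITE, 0.25)
                                lox_ok = lox == LOX_SITE
                            payload = loxtag + lox
                        seq = libtag + pbc + _SPACER + rbc + cbc + payload
                        seq, edits = _mutate(rng, seq, sub_rate)
                        name = f"w{rid:07d}"
                        r0.append((name, seq, _qual(len(seq))))
                        rows_out.append(
                            (name, sidx, pbc, rbc, cbc, uptag, dntag,
                             kind == "lox" and lox_ok, edits)
                        )
                        rid += 1
    truth = pd.DataFrame(
        rows_out,
        columns=["read_id", "structure", "pbc", "rbc", "cbc", "uptag", "dntag", "lox_ok", "n_edits"],
    )
    cfg = _rcppcr_config(pbcs, rbcs, cbcs)
    return SimResult([r0], truth, cfg, {"pbcs": pbcs, "rbcs": rbcs, "cbcs": cbcs, "wells": wells})


# ---------------------------------------------------------------------------
# combinatorial-index ATAC: 4 index tiers over two index reads
# ---------------------------------------------------------------------------


def simulate_combinatorial_atac(
    n_cells: int = 40,
    n_per_tier: int = 8,
    tier_len: int = 8,
    reads_per_cell: int = 10,
    payload_len: int = 30,
    sub_rate: float = 0.0,
    seed: int = 0,
) -> SimResult:
    """Split-pool indexed library: the cell identity is the joint value
    of four index-tier barcodes carried on two index reads; the two
    genomic reads are payload."""
    rng = np.random.default_rng(seed)
    tiers = [random_barcodes(rng, n_per_tier, tier_len, min_dist=3) for _ in range(4)]
    combos: set[tuple[int, ...]] = set()
    while len(combos) < n_cells:
        combos.add(tuple(int(rng.integers(0, n_per_tier)) for _ in range(4)))
    cells = sorted(combos)
    files: list[list[tuple[str, str, str]]] = [[], [], [], []]
    rows = []
    rid = 0
    for cell in cells:
        t = [tiers[i][cell[i]] for i in range(4)]
        for _ in range(reads_per_cell):
            g1, g2 = _rand_seq(rng, payload_len), _rand_seq(rng, payload_len)
            i1, e1 = _mutate(rng, t[0] + t[1], sub_rate)
            i2, e2 = _mutate(rng, t[2] + t[3], sub_rate)
            name = f"a{rid:07d}"
            files[0].append((name, g1, _qual(payload_len)))
            files[1].append((name, g2, _qual(payload_len)))
            files[2].append((name, i1, _qual(len(i1))))
            files[3].append((name, i2, _qual(len(i2))))
            rows.append((name, "+".join(t), e1 + e2))
            rid += 1
    truth = pd.DataFrame(rows, columns=["read_id", "cell", "n_edits"])
    L = tier_len
    structure = ReadStructure("sci_atac", (
        SegmentSpec("gdna1", 0, FixedSpan(0, payload_len)),
        SegmentSpec("gdna2", 1, FixedSpan(0, payload_len)),
        SegmentSpec("t1", 2, FixedSpan(0, L)),
        SegmentSpec("t2", 2, FixedSpan(L, 2 * L)),
        SegmentSpec("t3", 3, FixedSpan(0, L)),
        SegmentSpec("t4", 3, FixedSpan(L, 2 * L)),
    ))
    variables = (
        VariableSpec(
            "cellID", ("t1", "t2", "t3", "t4"),
            correction=CorrectionSpec("allowlist", 1, allowlist=[list(t) for t in tiers]),
        ),
        VariableSpec("payload1", ("gdna1",)),
        VariableSpec("payload2", ("gdna2",)),
    )
    cfg = PipelineConfig((structure,), variables, QualityPolicy())
    return SimResult(files, truth, cfg, {"tiers": tiers, "cells": cells})


# ---------------------------------------------------------------------------
# spatially barcoded beads
# ---------------------------------------------------------------------------


def simulate_spatial(
    n_beads: int = 60,
    bead_len: int = 14,
    umi_len: int = 8,
    payload_len: int = 20,
    reads_per_bead: int = 5,
    field_size: tuple[float, float] = (100.0, 100.0),
    sub_rate: float = 0.0,
    seed: int = 0,
) -> SimResult:
    """Bead library with random 2-D coordinates: read 1 carries the
    positional bead barcode plus UMI, read 2 a cDNA payload.  Bead
    coordinates ship in ``aux['coords']`` for the tiling conversion-
    table builder; bead barcodes are matched against their allowlist
    exactly (distance threshold 0)."""
    rng = np.random.default_rng(seed)
    beads = random_barcodes(rng, n_beads, bead_len, min_dist=3)
    coords = {
        b: (float(x), float(y))
        for b, (x, y) in zip(
            beads, rng.uniform((0, 0), field_size, size=(n_beads, 2))
        )
    }
    r1, r2, rows = [], [], []
    rid = 0
    for bead in beads:
        for _ in range(reads_per_bead):
            umi = _rand_seq(rng, umi_len)
            payload = _rand_seq(rng, payload_len)
            s1, e1 = _mutate(rng, bead + umi, sub_rate)
            name = f"s{rid:07d}"
            r1.append((name, s1, _qual(len(s1))))
            r2.append((name, payload, _qual(payload_len)))
            rows.append((name, bead, umi, e1))
            rid += 1
    truth = pd.DataFrame(rows, columns=["read_id", "bead", "umi", "n_edits"])
    structure = ReadStructure("beads", (
        SegmentSpec("bead", 0, FixedSpan(0, bead_len)),
        SegmentSpec("umi", 0, FixedSpan(bead_len, bead_len + umi_len)),
        SegmentSpec("cdna", 1, FixedSpan(0, payload_len)),
    ))
    variables = (
        VariableSpec("beadID", ("bead",), role="parental",
                     correction=CorrectionSpec("allowlist", 0, allowlist=list(beads))),
        VariableSpec("umiID", ("umi",), role="local", parent="beadID"),
        VariableSpec("payload", ("cdna",)),
    )
    cfg = PipelineConfig((structure,), variables, QualityPolicy())
    return SimResult([r1, r2], truth, cfg, {"coords": coords, "beads": beads})


# ---------------------------------------------------------------------------
# anchored long reads: barcode and insert located by fuzzy 20-bp flanks
# ---------------------------------------------------------------------------


def simulate_longread(
    n_reads: int = 50,
    n_barcodes: int = 10,
    barcode_len: int = 13,
    insert_len: int = 60,
    flank_len: int = 20,
    pad_len: int = 15,
    sub_rate: float = 0.0,
    seed: int = 0,
) -> SimResult:
    """Long reads carrying a barcode and a coding insert, each flanked
    by fixed 20-bp motifs; segments are located by fuzzy anchoring
    (3-bp exact inner edge, up to two outer mismatches)."""
    rng = np.random.default_rng(seed)
    flanks = [_rand_seq(rng, flank_len) for _ in range(4)]
    barcodes = random_barcodes(rng, n_barcodes, barcode_len, min_dist=3)
    inserts = {b: _rand_seq(rng, insert_len) for b in barcodes}
    r0, rows = [], []
    for rid in range(n_reads):
        bc = barcodes[int(rng.integers(0, n_barcodes))]
        pad5, gap, pad3 = (_rand_seq(rng, pad_len) for _ in range(3))
        seq = pad5 + flanks[0] + bc + flanks[1] + gap + flanks[2] + inserts[bc] + flanks[3] + pad3
        seq, edits = _mutate(rng, seq, sub_rate)
        name = f"l{rid:07d}"
        r0.append((name, seq, _qual(len(seq))))
        rows.append((name, bc, inserts[bc], edits))
    truth = pd.DataFrame(rows, columns=["read_id", "barcode", "insert", "n_edits"])
    structure = ReadStructure("longread", (
        SegmentSpec("barcode", 0, Anchored(flanks[0], flanks[1], 3, 2),
                    barcode_len, barcode_len),
        SegmentSpec("insert", 0, Anchored(flanks[2], flanks[3], 3, 2),
                    insert_len - 2, insert_len + 2),
    ))
    variables = (
        VariableSpec("barcodeID", ("barcode",),
                     correction=CorrectionSpec("allowlist", 1, allowlist=list(barcodes))),
        VariableSpec("insertSeq", ("insert",)),
    )
    cfg = PipelineConfig((structure,), variables, QualityPolicy())
    return SimResult([r0], truth, cfg, {"barcodes": barcodes, "inserts": inserts, "flanks": flanks})
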