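"""Desk-scale evaluation statistics for interpreted/translated reads.

Covers the three readouts used to judge a translation: distinct-UMI
count matrices per (cell, gene tag), the nonparametric rank-difference
statistic comparing pairwise-distance structure between an original
and a translated dataset, and clonal-well calling for row/column/plate
barcoded libraries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ranksums

from .valuespace import ValueRecord

__all__ = [
    "umi_count_matrix",
    "umi_triples",
    "rank_difference",
    "RankDifferenceResult",
    "rank_difference_stat",
    "WellReadout",
    "WellVerdict",
    "call_clonal_wells",
    "well_readouts_from_records",
]


def umi_triples(
    vrecords: Iterable[ValueRecord],
    cell_var: str = "cellID",
    umi_var: str = "umiID",
    gene_segment: str = "cdna",
) -> list[tuple[str, str, str]]:
    """(cell, gene, umi) triples from value records; the gene tag is
    the raw pass-through payload sequence."""
    out = []
    for v in vrecords:
        if cell_var not in v.values or umi_var not in v.values:
            continue
        out.append(
            ("+".join(v.values[cell_var]),
             v.record.segments[gene_segment].seq,
             "+".join(v.values[umi_var]))
        )
    return out


def umi_count_matrix(triples) -> pd.DataFrame:
    """Cell x gene matrix of distinct UMI counts.

    Accepts (cell, gene, umi) triples or a DataFrame with columns
    cell/gene/umi.  Duplicate molecules (same UMI under one cell and
    gene) collapse to one.
    """
    if not isinstance(triples, pd.DataFrame):
        triples = pd.DataFrame(list(triples), columns=["cell", "gene", "umi"])
    if triples.empty:
        return pd.DataFrame()
    counts = triples.groupby(["cell", "gene"])["umi"].nunique()
    return counts.unstack(fill_value=0)


# ---------------------------------------------------------------------------
# rank-difference statistic
# ---------------------------------------------------------------------------


def rank_difference(dist_a, dist_b) -> np.ndarray:
    """|rank(d_a) - rank(d_b)| over the same sampled pairs (average
    ranks on ties)."""
    a, b = np.asarray(dist_a, float), np.asarray(dist_b, float)
    if a.shape != b.shape:
        raise ValueError("distance sets must cover the same sampled pairs")
    return np.abs(rankdata(a) - rankdata(b))


@dataclass
class RankDifferenceResult:
    delta: np.ndarray
    delta_null: np.ndarray
    median: float
    null_median: float
    pvalue: float


def rank_difference_stat(
    points_a: dict, points_b: dict, n_pairs: int = 1000, seed: int = 0
) -> RankDifferenceResult:
    """Compare pairwise Euclidean distance structure of two datasets
    indexed by the same identifiers.

    For `n_pairs` sampled identifier pairs (i, j), the statistic is
    the absolute difference between the distance rank of (i, j) in
    dataset A and of the corresponding (i', j') in dataset B.  The
    null ranks two pair sets sampled independently from each dataset;
    identical datasets give an all-zero distribution regardless of
    seed.  The summary p-value is a two-sided Wilcoxon rank-sum test
    of the observed deltas against the null deltas.
    """
    if set(points_a) != set(points_b):
        raise ValueError("datasets must be indexed by the same identifiers")
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    ids = sorted(points_a)
    if len(ids) < 2:
        raise ValueError("need at least two data points")
    A = np.asarray([points_a[i] for i in ids], float)
    B = np.asarray([points_b[i] for i in ids], float)
    rng = np.random.default_rng(seed)

    def sample_pairs():
        i = rng.integers(0, len(ids), size=n_pairs)
        j = rng.integers(0, len(ids), size=n_pairs)
        clash = i == j
        while clash.any():
            j[clash] = rng.integers(0, len(ids), size=int(clash.sum()))
            clash = i == j
        return i, j

    def dist(mat, i, j):
        return np.linalg.norm(mat[i] - mat[j], axis=1)

    i, j = sample_pairs()
    delta = rank_difference(dist(A, i, j), dist(B, i, j))
    ia, ja = sample_pairs()
    ib, jb = sample_pairs()
    delta_null = np.abs(
        rankdata(dist(A, ia, ja)) - rankdata(dist(B, ib, jb))
    )
    stat = ranksums(delta, delta_null)
    return RankDifferenceResult(
        delta, delta_null, float(np.median(delta)), float(np.median(delta_null)),
        float(stat.pvalue),
    )


# ---------------------------------------------------------------------------
# clonal-well calling
# ---------------------------------------------------------------------------


@dataclass
class WellReadout:
    """Per-well tallies from the Tag- and Lox-layout reads."""

    uptags: Counter = field(default_factory=Counter)
    dntags: Counter = field(default_factory=Counter)
    lox_tags: Counter = field(default_factory=Counter)
    lox_kind: str = "uptag"  # which tag the Lox layout re-reads
    lox_correct: int = 0
    lox_total: int = 0


@dataclass
class WellVerdict:
    clonal: bool
    reason: str
    uptag: str | None = None
    dntag: str | None = None
    uptag_frac: float = 0.0
    dntag_frac: float = 0.0
    lox_frac: float = 0.0


def _dominant(counter: Counter) -> tuple[str | None, float]:
    total = sum(counter.values())
    if not total:
        return None, 0.0
    # deterministic on count ties: lexicographically smallest tag
    tag, n = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return tag, n / total

def call_clonal_wells(
    readouts: dict, lox_min_frac: float = 0.70
) -> dict[object, WellVerdict]:
    """Verdict per well: clonal iff the dominant Uptag AND Dntag each
    occupy strictly more than 50% of the Tag reads, at least 70% of
    the Lox reads carry intact recombination sites, the dominant tag
    in the Lox reads also exceeds 50%, and the Tag and Lox dominant
    tags agree; otherwise rejected with the first failing reason.
    """
    verdicts: dict[object, WellVerdict] = {}
    for well, r in readouts.items():
        uptag, uf = _dominant(r.uptags)
        dntag, df = _dominant(r.dntags)
        loxtag, lf = _dominant(r.lox_tags)
        lox_frac = r.lox_correct / r.lox_total if r.lox_total else 0.0
        v = WellVerdict(False, "", uptag, dntag, uf, df, lox_frac)
        if uptag is None or uf <= 0.5:
            v.reason = "uptag_not_dominant"
        elif dntag is None or df <= 0.5:
            v.reason = "dntag_not_dominant"
        elif lox_frac < lox_min_frac:
            v.reason = "lox_invalid"
        elif loxtag is None or lf <= 0.5:
            v.reason = "lox_tag_not_dominant"
        elif loxtag != (uptag if r.lox_kind == "uptag" else dntag):
            v.reason = "conflict"
        else:
            v.clonal, v.reason = True, "clonal"
        verdicts[well] = v
    return verdicts


def well_readouts_from_records(
    records,
    tag_structures: dict[int, None] | set,
    lox_structures: dict[int, str],
    lox_site: str,
    well_segments: tuple[str, str, str] = ("pbc", "rbc", "cbc"),
) -> dict[tuple[str, str, str], WellReadout]:
    """Aggregate corrected segment records into per-well readouts.

    `lox_structures` maps structure index -> which tag ("uptag" or
    "dntag") that layout re-reads; wells key on the corrected
    plate/row/column barcode triple.
    """
    readouts: dict[tuple[str, str, str], WellReadout] = {}
    for rec in records:
        key = tuple(rec.segments[s].seq for s in well_segments)
        r = readouts.setdefault(key, WellReadout())
        if rec.structure_index in tag_structures:
            r.uptags[rec.segments["uptag"].seq] += 1
            r.dntags[rec.segments["dntag"].seq] += 1
        elif rec.structure_index in lox_structures:
            r.lox_kind = lox_structures[rec.structure_index]
            r.lox_tags[rec.segments["loxtag"].seq] += 1
            r.lox_total += 1
            if rec.segments["lox"].seq == lox_site:
                r.lox_correct += 1
    return readouts
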