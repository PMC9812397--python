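"""Value encoding, tree merging, and value-space optimization."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import scrna_structure_config
from oracles import min_species_per_variable
from readxlate.segmentation import Segment, SegmentedRecord
from readxlate.valuespace import (
    ValueTree,
    encode_values,
    global_value_map,
    merge_value_trees,
    optimize_value_space,
)


def _rec(rid, cell, umi, cdna="ACGTACGTACGTACGTACGT"):
    return SegmentedRecord(
        rid, 0,
        {k: Segment(v, "I" * len(v), 40.0, 40) for k, v in
         {"cell": cell, "umi": umi, "cdna": cdna}.items()},
    )


CFG = scrna_structure_config(2, 2)


def test_encode_builds_scoped_tree():
    """The same UMI under different cells is two different objects."""
    records = [
        _rec("r0", "AA", "TT"), _rec("r1", "AA", "TG"),
        _rec("r2", "CC", "TT"), _rec("r3", "AA", "TT"),
    ]
    vrecs, tree = encode_values(records, CFG)
    assert tree.scopes["cellID"][()] == Counter({("AA",): 3, ("CC",): 1})
    assert tree.scopes["umiID"][(("AA",),)] == Counter({("TT",): 2, ("TG",): 1})
    assert tree.scopes["umiID"][(("CC",),)] == Counter({("TT",): 1})
    assert vrecs[0].values == {"cellID": ("AA",), "umiID": ("TT",)}
    # payload variables are not valued
    assert "payload" not in tree.variables


def test_encode_empty_input_gives_empty_tree():
    _, tree = encode_values([], CFG)
    assert tree.scopes == {}
    assert tree.n_values("cellID") == 0


def test_merge_trees_equals_single_pass_encode():
    records = [_rec(f"r{i}", c, u) for i, (c, u) in enumerate(
        [("AA", "TT"), ("AA", "TG"), ("CC", "TT"), ("AA", "TT"), ("CC", "AA")]
    )]
    _, whole = encode_values(records, CFG)
    parts = [encode_values(records[i : i + 2], CFG)[1] for i in range(0, 5, 2)]
    merged = merge_value_trees(parts)
    assert merged.scopes == whole.scopes


def test_merge_rejects_mismatched_hierarchy():
    t1 = ValueTree(("a",), {"a": None})
    t2 = ValueTree(("b",), {"b": None})
    with pytest.raises(ValueError, match="hierarchy"):
        merge_value_trees([t1, t2])


def test_optimize_orders_roots_by_frequency():
    tree = ValueTree(("v",), {"v": None})
    tree.add("v", (), ("v1",), 10)
    tree.add("v", (), ("v2",), 30)
    opt = optimize_value_space(tree)
    assert opt.value("v", (), ("v2",)) == 0
    assert opt.value("v", (), ("v1",)) == 1
    assert opt.species_count["v"] == 2


def test_local_species_count_is_max_scope_size_not_total():
    tree = ValueTree(("p", "c"), {"p": None, "c": "p"})
    tree.add("p", (), ("A",), 5)
    tree.add("p", (), ("B",), 4)
    for v in ("x", "y", "z"):
        tree.add("c", (("A",),), (v,), 1)
    for v in ("p", "q"):
        tree.add("c", (("B",),), (v,), 1)
    opt = optimize_value_space(tree)
    assert opt.species_count["c"] == 3  # max scope size, not 5
    # within each scope values are 0..k-1
    assert {opt.value("c", (("A",),), (v,)) for v in ("x", "y", "z")} == {0, 1, 2}
    assert {opt.value("c", (("B",),), (v,)) for v in ("p", "q")} == {0, 1}


def test_three_layer_hierarchy_species_by_exhaustive_enumeration():
    """sample -> cell -> molecule toy tree: the molecule species count
    is the largest per-cell scope over all samples."""
    tree = ValueTree(("s", "c", "u"), {"s": None, "c": "s", "u": "c"})
    rng = np.random.default_rng(3)
    observations: dict[tuple, list] = {}
    for si in range(3):
        tree.add("s", (), (f"S{si}",), 1)
        for ci in range(3):
            cpath = ((f"S{si}",),)
            tree.add("c", cpath, (f"C{ci}",), 1)
            upath = ((f"S{si}",), (f"C{ci}",))
            for ui in range(int(rng.integers(1, 5))):
                tree.add("u", upath, (f"U{ui}",), 1)
                observations.setdefault(upath, []).append((f"U{ui}",))
    opt = optimize_value_space(tree)
    assert opt.species_count["u"] == min_species_per_variable(observations)
    assert opt.species_count["c"] == 3


def _random_tree(rng) -> tuple[ValueTree, dict]:
    tree = ValueTree(("p", "c"), {"p": None, "c": "p"})
    observations: dict[tuple, list] = {(): []}
    for pi in range(int(rng.integers(1, 5))):
        pval = (f"P{pi}",)
        count = int(rng.integers(1, 10))
        tree.add("p", (), pval, count)
        observations[()].append(pval)
        kids = int(rng.integers(0, 5))
        for ci in range(kids):
            tree.add("c", (pval,), (f"C{ci}",), int(rng.integers(1, 6)))
            observations.setdefault((pval,), []).append((f"C{ci}",))
    return tree, observations


def test_minimality_on_many_random_trees():
    """No topology-preserving renumbering can beat the maximum scope
    cardinality; the optimizer always achieves it."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        tree, obs = _random_tree(rng)
        opt = optimize_value_space(tree)
        child_obs = {k: v for k, v in obs.items() if k != ()}
        assert opt.species_count["p"] == len(set(obs[()]))
        assert opt.species_count["c"] == min_species_per_variable(child_obs)


def test_topology_preserved_and_deterministic():
    rng = np.random.default_rng(7)
    tree, _ = _random_tree(rng)
    opt1 = optimize_value_space(tree)
    opt2 = optimize_value_space(tree)
    assert opt1.assignments == opt2.assignments  # determinism
    # bijection within every scope: distinct source values never collide
    for var in ("p", "c"):
        for path, counter in tree.scopes.get(var, {}).items():
            imgs = [opt1.value(var, path, v) for v in counter]
            assert sorted(imgs) == list(range(len(imgs)))


def test_combinatorial_values_are_distinct_tuples():
    cfg = scrna_structure_config(2, 2)
    from readxlate.config import (PipelineConfig, QualityPolicy, ReadStructure,
                                  SegmentSpec, FixedSpan, VariableSpec)
    structure = ReadStructure("split", (
        SegmentSpec("b1", 0, FixedSpan(0, 2)),
        SegmentSpec("b2", 0, FixedSpan(2, 4)),
        SegmentSpec("b3", 0, FixedSpan(4, 6)),
    ))
    cfg = PipelineConfig(
        (structure,),
        (VariableSpec("cellID", ("b1", "b2", "b3"), valued=True),),
        QualityPolicy(),
    )
    recs = []
    for i, triple in enumerate([("AA", "CC", "GG"), ("AA", "CC", "TT"), ("AA", "CC", "GG")]):
        segs = {f"b{j+1}": Segment(s, "II", 40.0, 40) for j, s in enumerate(triple)}
        recs.append(SegmentedRecord(f"r{i}", 0, segs))
    _, tree = encode_values(recs, cfg)
    assert tree.scopes["cellID"][()] == Counter(
        {("AA", "CC", "GG"): 2, ("AA", "CC", "TT"): 1}
    )


def test_global_map_ignores_scopes():
    tree = ValueTree(("p", "c"), {"p": None, "c": "p"})
    tree.add("p", (), ("A",), 2)
    tree.add("p", (), ("B",), 1)
    tree.add("c", (("A",),), ("u1",), 1)
    tree.add("c", (("B",),), ("u2",), 5)
    gmap = global_value_map(tree)
    assert gmap.species_count["c"] == 2  # u1 and u2 globally distinct
    assert gmap.value("c", (("B",),), ("u2",)) == 0  # most frequent overall
    assert gmap.value("c", (("A",),), ("u1",)) == 1


@settings(max_examples=25, deadline=None)
@given(st.lists(
    st.tuples(st.sampled_from(["AA", "CC", "GG"]), st.sampled_from(["TT", "TG", "GA"])),
    max_size=30,
))
def test_merge_invariant_under_chunking(pairs):
    records = [_rec(f"r{i}", c, u) for i, (c, u) in enumerate(pairs)]
    _, whole = encode_values(records, CFG)
    for k in (1, 3, 7):
        parts = [encode_values(records[i : i + k], CFG)[1] for i in range(0, max(len(records), 1), k)]
        assert merge_value_trees(parts).scopes == whole.scopes if parts else True
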