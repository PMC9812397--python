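"""Knee detection and correction-table construction/application."""

from __future__ import annotations

import sys
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_knee, dp_levenshtein, nearest_by_enumeration
from readxlate.config import CorrectionSpec
from readxlate.correction import (
    DROP,
    CorrectionTable,
    PluginError,
    apply_correction,
    build_correction_table,
    detect_knee,
    levenshtein,
    merge_tallies,
    rank_count_curve,
)
from readxlate.segmentation import Segment, SegmentedRecord, SegmentTally
from readxlate.simulate import random_barcodes, simulate_scrna


def _tally(counter_by_segment):
    return SegmentTally({k: Counter(v) for k, v in counter_by_segment.items()})


@settings(max_examples=50, deadline=None)
@given(
    st.text(alphabet="ACGTN", max_size=12),
    st.text(alphabet="ACGTN", max_size=12),
)
def test_levenshtein_matches_dp_oracle(a, b):
    assert levenshtein(a, b) == dp_levenshtein(a, b)


def test_levenshtein_n_mismatches_n():
    assert levenshtein("AN", "AN") == 1
    assert levenshtein("N", "A") == 1
    assert levenshtein("ACGT", "ACGT") == 0


def test_levenshtein_cap_reports_inf():
    assert levenshtein("AAAA", "TTTT", k=2) == float("inf")


def test_merge_tallies_sums_counts():
    merged = merge_tallies([_tally({"bc": {"AA": 2}}), _tally({"bc": {"AA": 1, "AC": 1}})])
    assert merged.counts["bc"] == Counter({"AA": 3, "AC": 1})
    single = _tally({"bc": {"AA": 2}})
    assert merge_tallies([single]).counts == single.counts


def test_knee_on_plateau_cliff_curve():
    """100 abundant sequences over a 900-sequence error tail knee at
    rank 100 (verified against the brute-force curvature oracle)."""
    counts = [1000] * 100 + [5] * 900
    curve = rank_count_curve(Counter({f"s{i:04d}": c for i, c in enumerate(counts)}))
    assert detect_knee(curve) == brute_force_knee(counts) == 100


def test_knee_degenerate_curves():
    flat = rank_count_curve(Counter({f"s{i}": 7 for i in range(10)}))
    assert detect_knee(flat) == 10  # no curvature: accept all
    single = rank_count_curve(Counter({"AAAA": 3}))
    assert detect_knee(single) == 1


def test_knee_matches_oracle_on_random_curves():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(3, 40))
        counts = sorted(rng.integers(1, 1000, size=n).tolist(), reverse=True)
        curve = rank_count_curve(Counter({f"s{i:03d}": c for i, c in enumerate(counts)}))
        assert detect_knee(curve) == brute_force_knee(counts)


def test_imputation_corrects_below_knee_to_nearest_above():
    tally = _tally({"bc": {"AACGA": 900, "CCCCC": 880, "GGTTA": 870, "AACGT": 3}})
    table = build_correction_table(tally, "bc", CorrectionSpec("imputation_to_majority", 1))
    # knee sits at the cliff edge: the three abundant sequences are accepted
    assert table.accepted == {"AACGA", "CCCCC", "GGTTA"}
    assert table.mapping["AACGA"] == "AACGA"
    assert table.mapping["AACGT"] == "AACGA"
    assert dp_levenshtein("AACGT", "AACGA") == 1


def test_imputation_tie_breaks_by_count_then_lexicographic():
    # GAAAT is distance 1 from both above-knee sequences; count 500 wins
    tally = _tally({"bc": {"GAAAA": 500, "GAAAC": 400, "CCCCC": 450, "GAAAT": 2, "CCCCG": 1}})
    table = build_correction_table(tally, "bc", CorrectionSpec("imputation_to_majority", 1))
    assert table.mapping["GAAAT"] == nearest_by_enumeration(
        "GAAAT", [("GAAAA", 500), ("GAAAC", 400), ("CCCCC", 450)], 1
    ) == "GAAAA"


def test_imputation_drops_beyond_threshold():
    tally = _tally({"bc": {"AAAAA": 900, "CCCTT": 850, "TTTCC": 840, "GGGGG": 1}})
    table = build_correction_table(tally, "bc", CorrectionSpec("imputation_to_majority", 1))
    assert table.mapping["GGGGG"] == DROP


def test_allowlist_mapping_and_ambiguity_drop():
    spec = CorrectionSpec("allowlist", 1, allowlist=["AAAAA", "CCCCC"])
    tally = _tally({"bc": {"AAAAA": 5, "AAAAT": 2, "GGGGG": 1, "ACCCC": 1}})
    table = build_correction_table(tally, "bc", spec)
    assert table.mapping["AAAAA"] == "AAAAA"
    assert table.mapping["AAAAT"] == "AAAAA"
    assert table.mapping["GGGGG"] == DROP  # beyond threshold: ignored
    assert table.mapping["ACCCC"] == "CCCCC"
    # equidistant between two allowlist entries: identity cannot be resolved
    spec2 = CorrectionSpec("allowlist", 1, allowlist=["AAAAC", "AAAAG"])
    table2 = build_correction_table(_tally({"bc": {"AAAAT": 3}}), "bc", spec2)
    assert table2.mapping["AAAAT"] == DROP


def test_correction_agrees_with_exhaustive_oracle_on_random_pool():
    """Implementation vs DP-enumeration oracle over a whole random pool."""
    rng = np.random.default_rng(17)
    majors = random_barcodes(rng, 20, 8, min_dist=3)
    counter = Counter({b: int(rng.integers(200, 400)) for b in majors})
    minors = []
    for b in majors[:10]:
        mutant = ("T" if b[0] != "T" else "G") + b[1:]
        if mutant not in counter:
            counter[mutant] = int(rng.integers(1, 3))
            minors.append(mutant)
    table = build_correction_table(_tally({"bc": counter}), "bc",
                                   CorrectionSpec("imputation_to_majority", 1))
    accepted = [(b, counter[b]) for b in majors]
    for seq in counter:
        if seq in dict(accepted):
            assert table.mapping[seq] == seq
        else:
            expect = nearest_by_enumeration(seq, accepted, 1)
            assert table.mapping[seq] == (expect if expect is not None else DROP)


def _record(**segs):
    return SegmentedRecord(
        "r", 0, {k: Segment(v, "I" * len(v), 37.5, 35) for k, v in segs.items()}
    )


def test_apply_correction_replaces_and_drops():
    table = CorrectionTable("cell", "imputation_to_majority", 1,
                            {"AACGA": "AACGA", "AACGT": "AACGA", "GGGGG": DROP},
                            {"AACGA"})
    rec = _record(cell="AACGT", umi="TTTT")
    out = apply_correction(rec, {"cell": table})
    assert out.segments["cell"].seq == "AACGA"
    assert out.segments["umi"].seq == "TTTT"  # ungoverned segment untouched
    assert out.segments["cell"].avg_q == 37.5  # quality carries over
    assert apply_correction(_record(cell="GGGGG"), {"cell": table}) is None


def test_apply_correction_is_idempotent():
    table = CorrectionTable("cell", "imputation_to_majority", 1,
                            {"AACGA": "AACGA", "AACGT": "AACGA"}, {"AACGA"})
    once = apply_correction(_record(cell="AACGT"), {"cell": table})
    twice = apply_correction(once, {"cell": table})
    assert twice.segments["cell"].seq == once.segments["cell"].seq == "AACGA"


def test_method_none_is_identity():
    rec = _record(cdna="ACGTACGT")
    out = apply_correction(rec, {"cdna": CorrectionTable("cdna", "none", 0)})
    assert out.segments["cdna"].seq == "ACGTACGT"


def test_plugin_contract_round_trip(tmp_path):
    script = tmp_path / "fix.py"
    script.write_text(
        "import sys\n"
        "rows = [l.split('\\t') for l in open(sys.argv[1]).read().splitlines()]\n"
        "with open(sys.argv[2], 'w') as out:\n"
        "    for seq, count in rows:\n"
        "        out.write(f'{seq}\\t{rows[0][0]}\\n')  # map all to the majority\n"
    )
    spec = CorrectionSpec("plugin", 1, plugin_command=f"{sys.executable} {script}")
    table = build_correction_table(_tally({"bc": {"AAAA": 9, "AAAT": 1}}), "bc", spec)
    assert table.mapping == {"AAAA": "AAAA", "AAAT": "AAAA"}

    bad = tmp_path / "bad.py"
    bad.write_text("import sys; sys.exit(3)\n")
    with pytest.raises(PluginError, match="exited 3"):
        build_correction_table(
            _tally({"bc": {"AAAA": 1}}), "bc",
            CorrectionSpec("plugin", 1, plugin_command=f"{sys.executable} {bad}"),
        )
    partial = tmp_path / "partial.py"
    partial.write_text("import sys; open(sys.argv[2], 'w').write('')\n")
    with pytest.raises(PluginError, match="not total"):
        build_correction_table(
            _tally({"bc": {"AAAA": 1}}), "bc",
            CorrectionSpec("plugin", 1, plugin_command=f"{sys.executable} {partial}"),
        )


def test_simulated_substitution_errors_fully_recovered():
    """Well-separated barcodes (pairwise distance >= 3), high coverage
    and <= 1 substitution per read: every erroneous read corrects back
    to its true barcode."""
    sim = simulate_scrna(n_cells=20, n_genes=10, max_umis=3, reads_per_umi=3,
                         sub_rate=0.0, seed=23, cell_correction="imputation_to_majority")
    rng = np.random.default_rng(99)
    truth_cells = sim.truth["cell"].tolist()
    observed = []
    for cell in truth_cells:
        if rng.random() < 0.1:  # inject one substitution
            pos = int(rng.integers(0, len(cell)))
            alt = "ACGT".replace(cell[pos], "")[rng.integers(0, 3)]
            observed.append(cell[:pos] + alt + cell[pos + 1 :])
        else:
            observed.append(cell)
    tally = _tally({"cell": Counter(observed)})
    table = build_correction_table(tally, "cell", CorrectionSpec("imputation_to_majority", 1))
    corrected = [table.mapping[o] for o in observed]
    assert corrected == truth_cells
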