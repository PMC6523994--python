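"""Switching criteria, exhaustive oracle equivalence, detection recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patseq import SwitchParams, candidate_genes, detect_switching, evaluate_pair
from patseq.switching import events_table, switching_genes

PARAMS = SwitchParams()


def _pair(a1, b1, a2, b2, params=PARAMS, de=(True, True)):
    return evaluate_pair({"A": a1, "B": b1}, {"A": a2, "B": b2}, "A", "B", params, de)


def oracle_verdict(a1, b1, a2, b2, de1=True, de2=True, require_de=True):
    """Independent literal transcription of the five criteria."""

    def ratio_ok(num, den):
        if den == 0:
            return num > 0  # x/0 counts as infinite ratio; 0/0 fails
        return num / den >= 2

    c1 = (a1 >= 5 and b1 >= 5) or (a2 >= 5 and b2 >= 5)
    c2 = (a1 + b1) >= 20 or (a2 + b2) >= 20
    c3 = (ratio_ok(a1, a2) and ratio_ok(b2, b1)) or (ratio_ok(b1, b2) and ratio_ok(a2, a1))
    c4 = abs(a1 - a2) > 5 and abs(b1 - b2) > 5
    c5 = (de1 or de2) if require_de else True
    return c1 and c2 and c3 and c4 and c5


class TestEvaluatePair:
    def test_clear_reciprocal_switch(self):
        ev = _pair(20, 5, 5, 20)
        assert ev.c1 and ev.c2 and ev.c3 and ev.c4 and ev.c5 and ev.verdict

    def test_symmetric_counts_cannot_switch(self):
        ev = _pair(10, 10, 10, 10)
        assert not ev.c3 and not ev.verdict

    def test_ratio_passes_but_abs_diff_boundary_fails(self):
        # |8-4| = 4 <= 5: criterion 4 is strictly greater-than
        ev = _pair(8, 4, 4, 8)
        assert ev.c3 and not ev.c4 and not ev.verdict

    def test_abs_diff_exactly_five_fails(self):
        ev = _pair(10, 5, 5, 10)
        assert not ev.c4

    def test_abs_diff_six_passes(self):
        ev = _pair(12, 6, 6, 12)
        assert ev.c4

    def test_de_pac_requirement_toggle(self):
        ev = _pair(20, 5, 5, 20, de=(False, False))
        assert not ev.verdict and not ev.c5
        relaxed = SwitchParams(require_de_pac=False)
        assert _pair(20, 5, 5, 20, params=relaxed, de=(False, False)).verdict

    def test_total_counts_span_all_samples(self):
        # pair counts are small but a third group pushes the PA1 total >= 20
        counts1 = {"A": 6, "B": 6, "C": 10}
        counts2 = {"A": 0, "B": 13, "C": 0}
        ev = evaluate_pair(counts1, counts2, "A", "B", PARAMS, (True, True))
        assert ev.c2
        strict = SwitchParams(total_pair_only=True)
        assert not evaluate_pair(counts1, counts2, "A", "B", strict, (True, True)).c2

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _pair(-1, 5, 5, 5)

    def test_swap_symmetry(self):
        grid = [0, 3, 5, 8, 20]
        for a1, b1, a2, b2 in itertools.product(grid, repeat=4):
            v = _pair(a1, b1, a2, b2).verdict
            assert _pair(a2, b2, a1, b1).verdict == v  # swap PA1/PA2
            ev = evaluate_pair({"A": a1, "B": b1}, {"A": a2, "B": b2},
                               "B", "A", PARAMS, (True, True))
            assert ev.verdict == v  # swap sample A/B

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30), st.integers(2, 5))
    @settings(max_examples=200, deadline=None)
    def test_count_scaling_never_breaks_c1_c2_c4(self, a1, b1, a2, b2, k):
        before = _pair(a1, b1, a2, b2)
        after = _pair(a1 * k, b1 * k, a2 * k, b2 * k)
        for c in ("c1", "c2", "c4"):
            if getattr(before, c):
                assert getattr(after, c)


def test_exhaustive_grid_matches_oracle():
    grid = [0, 1, 4, 5, 6, 10, 19, 20, 21, 40]
    for a1, b1, a2, b2 in itertools.product(grid, repeat=4):
        ev = _pair(a1, b1, a2, b2)
        assert ev.verdict == oracle_verdict(a1, b1, a2, b2), (a1, b1, a2, b2)


def _annotated(rows, samples):
    base = {"chrom": "chr1", "strand": "+", "n_sites": 1}
    recs = []
    for i, (gene, rep, counts) in enumerate(rows):
        rec = dict(base, pac_id=f"PAC{i + 1:05d}", gene_id=gene, representative=rep,
                   start=rep, end=rep + 1, region="3UTR",
                   total=sum(counts.values()))
        rec.update(counts)
        recs.append(rec)
    return pd.DataFrame(recs)


SHEET = pd.DataFrame({"sample": ["A_1", "B_1"], "group": ["A", "B"], "replicate": [1, 1]})


class TestDetectSwitching:
    def test_single_pac_genes_excluded(self):
        pacs = _annotated([("g1", 100, {"A_1": 30, "B_1": 30})], ["A_1", "B_1"])
        assert len(candidate_genes(pacs)) == 0
        assert detect_switching(pacs, SHEET, ("A", "B"),
                                SwitchParams(require_de_pac=False)) == []

    def test_three_pacs_give_three_pairs(self):
        pacs = _annotated([("g1", 100, {"A_1": 30, "B_1": 10}),
                           ("g1", 200, {"A_1": 10, "B_1": 30}),
                           ("g1", 300, {"A_1": 20, "B_1": 20})], ["A_1", "B_1"])
        events = detect_switching(pacs, SHEET, ("A", "B"),
                                  SwitchParams(require_de_pac=False))
        assert len(events) == 3

    def test_direction_from_positions_and_strand(self):
        pacs = _annotated([("g1", 100, {"A_1": 30, "B_1": 6}),
                           ("g1", 300, {"A_1": 6, "B_1": 30})], ["A_1", "B_1"])
        (ev,) = detect_switching(pacs, SHEET, ("A", "B"),
                                 SwitchParams(require_de_pac=False))
        assert ev.verdict and ev.direction == "proximal_to_distal"
        minus = pacs.assign(strand="-")
        (ev2,) = detect_switching(minus, SHEET, ("A", "B"),
                                  SwitchParams(require_de_pac=False))
        assert ev2.direction == "distal_to_proximal"

    def test_missing_comparison_group_rejected(self):
        pacs = _annotated([("g1", 100, {"A_1": 30, "B_1": 6})], ["A_1", "B_1"])
        with pytest.raises(ValueError, match="absent"):
            detect_switching(pacs, SHEET, ("A", "X"), SwitchParams(require_de_pac=False))

    def test_relaxing_de_requirement_is_monotone(self, small_sim, small_gff, sample_ids):
        from patseq import (AnnotationIndex, PacParams, annotate_pacs,
                            build_pacs, de_test, load_annotation)
        cfg, genome, tags = small_sim["config"], small_sim["genome"], small_sim["tags"]
        tables = build_pacs(tags, genome, sample_ids, PacParams())
        ann = annotate_pacs(tables["pacs"], AnnotationIndex(load_annotation(small_gff)))
        ga = [s for s in sample_ids if s.startswith("A")]
        gb = [s for s in sample_ids if s.startswith("B")]
        de_pac = de_test(ann.set_index("pac_id")[sample_ids], ga, gb, alpha=0.05)
        sheet = cfg.sample_sheet()
        strict = switching_genes(detect_switching(ann, sheet, ("A", "B"),
                                                  SwitchParams(), de_pac))
        relaxed = switching_genes(detect_switching(
            ann, sheet, ("A", "B"), SwitchParams(require_de_pac=False), de_pac))
        assert set(strict) <= set(relaxed)

    def test_events_table_shape(self):
        pacs = _annotated([("g1", 100, {"A_1": 30, "B_1": 6}),
                           ("g1", 300, {"A_1": 6, "B_1": 30})], ["A_1", "B_1"])
        events = detect_switching(pacs, SHEET, ("A", "B"),
                                  SwitchParams(require_de_pac=False))
        table = events_table(events)
        assert list(table["gene_id"]) == ["g1"]
        assert table.loc[0, ["c1", "c2", "c3", "c4", "verdict"]].all()
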