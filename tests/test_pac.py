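"""PAS construction, internal-priming removal, clustering, support filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patseq import (PacParams, build_pas, cluster_pas, filter_internal_priming,
                    filter_pacs, pick_representative)
from patseq.pac import downstream_window, is_internal_priming

PARAMS = PacParams()


def _tags(rows):
    return pd.DataFrame(rows, columns=["chrom", "strand", "position", "sample"])


class TestBuildPas:
    def test_identical_coordinates_grouped(self):
        tags = _tags([("chr1", "+", 100, "A")] * 3)
        pas = build_pas(tags, ["A", "B"])
        assert len(pas) == 1
        assert pas.iloc[0]["A"] == 3 and pas.iloc[0]["B"] == 0

    def test_adjacent_positions_stay_distinct(self):
        pas = build_pas(_tags([("chr1", "+", 100, "A"), ("chr1", "+", 101, "A")]), ["A"])
        assert len(pas) == 2

    def test_empty_input(self):
        assert len(build_pas(_tags([]), ["A"])) == 0

    def test_count_conservation(self, small_sim, sample_ids):
        tags = small_sim["tags"]
        pas = build_pas(tags, sample_ids)
        assert pas[sample_ids].to_numpy().sum() == len(tags)


class TestInternalPrimingRule:
    @pytest.mark.parametrize(
        "window, removed",
        [
            ("AAAAAAAAAA", True),    # 10 A
            ("ACGTACGTAC", False),   # 2 A, max run 1
            ("AAAAAACGTC", True),    # 6-A run triggers the run rule
            ("AACAACAACA", True),    # 7 A scattered triggers the count rule
            ("AACAACAACC", False),   # 6 A scattered, max run 2
            ("AAAAACGTCG", False),   # 5-A run, 5 A total
        ],
    )
    def test_windows(self, window, removed):
        genome = {"chr1": "G" * 50 + "C" + window + "G" * 50}
        assert is_internal_priming(genome, "chr1", "+", 50, PARAMS) is removed

    def test_minus_strand_uses_upstream_revcomp(self):
        # transcript-strand downstream of a minus-strand PAS is the reverse
        # complement of the genomic window just 5' of it
        genome = {"chr1": "G" * 40 + "TTTTTTTTTT" + "C" + "G" * 50}
        assert downstream_window(genome, "chr1", "-", 50, 10) == "A" * 10
        assert is_internal_priming(genome, "chr1", "-", 50, PARAMS)

    def test_window_past_chromosome_end_counts_as_non_a(self):
        genome = {"chr1": "G" * 20 + "AAAA"}  # only 4 downstream bases exist
        assert not is_internal_priming(genome, "chr1", "+", 19, PARAMS)

    def test_filter_returns_both_sets(self):
        genome = {"chr1": "C" * 30 + "A" * 10 + "C" * 30}
        pas = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "strand": ["+", "+"],
            "position": [29, 60], "s": [4, 5],
        })
        retained, removed = filter_internal_priming(pas, genome, PARAMS)
        assert removed["position"].tolist() == [29]
        assert retained["position"].tolist() == [60]
        assert len(retained) + len(removed) == len(pas)


def _pas_frame(positions, counts=None, chrom="chr1", strand="+"):
    counts = counts if counts is not None else [1] * len(positions)
    return pd.DataFrame({"chrom": chrom, "strand": strand,
                         "position": positions, "s": counts})


class TestClusterPas:
    def test_gap_splits_and_joins(self):
        pacs = cluster_pas(_pas_frame([100, 110, 140]), PARAMS)
        assert len(pacs) == 2
        assert pacs.iloc[0][["start", "end"]].tolist() == [100, 111]
        assert pacs.iloc[1][["start", "end"]].tolist() == [140, 141]

    def test_gap_boundary_inclusive(self):
        assert len(cluster_pas(_pas_frame([100, 124]), PARAMS)) == 1
        assert len(cluster_pas(_pas_frame([100, 125]), PARAMS)) == 2

    def test_single_pas(self):
        pacs = cluster_pas(_pas_frame([500]), PARAMS)
        assert len(pacs) == 1 and pacs.iloc[0]["representative"] == 500

    def test_strands_never_merge(self):
        pas = pd.concat([_pas_frame([100]), _pas_frame([105], strand="-")],
                        ignore_index=True)
        assert len(cluster_pas(pas, PARAMS)) == 2

    def test_counts_summed_over_members(self):
        pacs = cluster_pas(_pas_frame([100, 110], counts=[12, 3]), PARAMS)
        assert pacs.iloc[0]["total"] == 15 and pacs.iloc[0]["s"] == 15

    @staticmethod
    def _oracle_clusters(positions, gap):
        """All-pairs transitive closure by union-find."""
        parent = list(range(len(positions)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                if abs(positions[i] - positions[j]) <= gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i, p in enumerate(positions):
            groups.setdefault(find(i), set()).add(p)
        return {frozenset(g) for g in groups.values()}

    @given(st.lists(st.integers(0, 400), min_size=1, max_size=50, unique=True))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_transitive_closure_oracle(self, positions):
        pacs = cluster_pas(_pas_frame(sorted(positions)), PARAMS)
        got = {
            frozenset(range(r.start, r.end)) & frozenset(positions)
            for r in pacs.itertuples()
        }
        assert got == self._oracle_clusters(positions, PARAMS.cluster_gap)

    @given(st.permutations(list(range(0, 120, 7))))
    @settings(max_examples=25, deadline=None)
    def test_order_independence(self, perm):
        base = cluster_pas(_pas_frame(sorted(perm)), PARAMS)
        shuffled = cluster_pas(_pas_frame(list(perm)), PARAMS)
        pd.testing.assert_frame_equal(base, shuffled)


class TestRepresentative:
    def test_most_abundant_member_wins(self):
        assert pick_representative([100, 110], [12, 3], "+") == 100

    def test_single_member(self):
        assert pick_representative([42], [7], "-") == 42

    @pytest.mark.parametrize("strand, expected", [("+", 110), ("-", 100)])
    def test_tie_breaks_three_prime_most(self, strand, expected):
        assert pick_representative([100, 110], [5, 5], strand) == expected

    def test_representative_is_member_position(self, small_sim, sample_ids):
        pas = build_pas(small_sim["tags"], sample_ids)
        pacs = cluster_pas(pas, PARAMS, sample_ids)
        positions = set(pas["position"])
        assert all(r in positions for r in pacs["representative"])


class TestFilterPacs:
    @pytest.mark.parametrize("total, kept", [(9, False), (10, True), (11, True)])
    def test_support_boundary(self, total, kept):
        pacs = cluster_pas(_pas_frame([100], counts=[total]), PARAMS)
        retained, discarded = filter_pacs(pacs, PARAMS)
        assert (len(retained) == 1) is kept
        assert len(retained) + len(discarded) == 1

    def test_all_below_threshold_gives_empty(self):
        pacs = cluster_pas(_pas_frame([100, 300], counts=[2, 3]), PARAMS)
        retained, _ = filter_pacs(pacs, PARAMS)
        assert len(retained) == 0

    def test_count_conservation_through_clustering(self, small_sim, sample_ids):
        pas = build_pas(small_sim["tags"], sample_ids)
        retained_pas, _ = filter_internal_priming(pas, small_sim["genome"], PARAMS)
        pacs = cluster_pas(retained_pas, PARAMS, sample_ids)
        kept, dropped = filter_pacs(pacs, PARAMS)
        assert (kept["total"].sum() + dropped["total"].sum()
                == retained_pas[sample_ids].to_numpy().sum())
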