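import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itraqpipe.quant_io import IdentificationSets
from itraqpipe.profile_analysis import (
    cluster_profiles,
    overlap_percentage,
    regulation_patterns,
    set_overlap_percentage,
    stage_venn,
    tissue_specific_sets,
)
from itraqpipe.ratio_quant import RatioMatrix, compare

from test_ratio_quant import matrix_from_values


def sets_from(pericarp=((), (), ()), endosperm=((), (), ())):
    d = {}
    for tissue, triple in (("pericarp", pericarp), ("endosperm", endosperm)):
        for stage, members in zip((10, 20, 33), triple):
            d[(tissue, stage)] = frozenset(members)
    return IdentificationSets(sets=d)


class TestStageVenn:
    def test_identical_sets_all_in_core(self):
        s = sets_from(pericarp=(("a", "b", "c"),) * 3)
        v = stage_venn(s, "pericarp")
        assert v.count(10, 20, 33) == 3
        assert v.union_size() == 3
        assert all(v.count(*c) == 0 for c in v.cells if len(c) < 3)

    def test_symmetric_pairwise_toy(self):
        s = sets_from(pericarp=(("a", "b"), ("b", "c"), ("c", "a")))
        v = stage_venn(s, "pericarp")
        assert v.count(10, 20) == 1 and v.count(20, 33) == 1 and v.count(10, 33) == 1
        assert v.count(10, 20, 33) == 0
        assert v.stage_specific_counts() == {10: 0, 20: 0, 33: 0}

    @settings(deadline=None, max_examples=100)
    @given(
        triple=st.tuples(
            *[st.sets(st.integers(0, 40), max_size=30) for _ in range(3)]
        )
    )
    def test_cells_reconstruct_all_margins(self, triple):
        s = sets_from(pericarp=tuple(tuple(map(str, t)) for t in triple))
        v = stage_venn(s, "pericarp")
        # disjointness and conservation
        all_members = [m for cell in v.cells.values() for m in cell]
        assert len(all_members) == len(set(all_members)) == v.union_size()
        for stage, members in zip((10, 20, 33), triple):
            assert v.stage_total(stage) == len(members)


class TestTissueSpecific:
    def test_disjoint_unions_share_nothing(self):
        s = sets_from(pericarp=(("a",), ("b",), ()), endosperm=(("c",), (), ("d",)))
        p, e, shared = tissue_specific_sets(s)
        assert shared == frozenset()
        assert p == {"a", "b"} and e == {"c", "d"}

    def test_partition_conserves_universe(self, design, planted_study):
        from itraqpipe.quant_io import filter_by_fdr, identification_sets

        records, truth = planted_study
        sets = identification_sets(filter_by_fdr(records), design)
        p, e, shared = tissue_specific_sets(sets)
        assert p | e | shared == sets.overall_union()
        assert not (p & e) and not (p & shared) and not (e & shared)
        # planted pericarp-only proteins are recovered
        assert truth.tissue_specific["pericarp"] <= p


class TestOverlapPercentage:
    def test_worked_example(self):
        assert overlap_percentage(16, 36) == 44.44

    def test_set_based_variant(self):
        spots = {f"s{i}" for i in range(36)}
        itraq = {f"s{i}" for i in range(16)} | {"x", "y"}
        assert set_overlap_percentage(spots, itraq) == 44.44

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            overlap_percentage(1, 0)
        with pytest.raises(ValueError):
            overlap_percentage(5, 4)


class TestClusterProfiles:
    def test_identical_profiles_merge_at_zero(self, design):
        values = np.array(
            [[1, 2, 4, 1, 2, 4], [1, 2, 4, 1, 2, 4], [8, 4, 1, 8, 2, 1]], dtype=float
        )
        m = matrix_from_values(design, values, ["A", "B", "C"])
        res = cluster_profiles(m)
        members, height = res.merges()[0]
        assert members == frozenset({"A", "B"})
        assert height == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_merges_before_anticorrelated(self, design):
        base = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        values = np.vstack([base, base * 1.02, base[::-1]])
        m = matrix_from_values(design, values, ["A", "B", "C"])
        res = cluster_profiles(m)
        # exhaustive check over the three possible first merges
        dists = {}
        log2 = np.log2(values)
        for i, j in itertools.combinations(range(3), 2):
            r = np.corrcoef(log2[i], log2[j])[0, 1]
            dists[frozenset((i, j))] = 1 - r
        expected_first = min(dists, key=dists.get)
        assert res.merges()[0][0] == frozenset(
            ["A", "B", "C"][i] for i in expected_first
        )
        assert expected_first == frozenset((0, 1))

    def test_input_order_invariance(self, design):
        rng = np.random.default_rng(3)
        values = 2.0 ** rng.normal(0, 1, size=(12, 6))
        names = [f"P{i:02d}" for i in range(12)]
        m1 = matrix_from_values(design, values, names)
        perm = rng.permutation(12)
        m2 = matrix_from_values(design, values[perm], [names[i] for i in perm])
        assert cluster_profiles(m1).canonical_merges() == cluster_profiles(m2).canonical_merges()
        assert cluster_profiles(m1).newick() == cluster_profiles(m2).newick()

    def test_uniform_scaling_of_one_profile_is_invisible(self, design):
        rng = np.random.default_rng(4)
        values = 2.0 ** rng.normal(0, 1, size=(6, 6))
        m1 = matrix_from_values(design, values)
        values2 = values.copy()
        values2[2] *= 39.0
        m2 = matrix_from_values(design, values2)
        assert cluster_profiles(m1).canonical_merges() == cluster_profiles(m2).canonical_merges()

    def test_masked_and_flat_profiles_excluded(self, design):
        values = 2.0 ** np.random.default_rng(5).normal(0, 1, size=(4, 6))
        values[0, 3] = np.nan  # masked cell
        values[1] = 3.0  # zero variance
        m = matrix_from_values(design, values, ["A", "B", "C", "D"])
        res = cluster_profiles(m)
        assert res.excluded == ["A", "B"]
        assert res.leaves == ["C", "D"]

    def test_too_few_profiles_error(self, design):
        m = matrix_from_values(design, np.full((2, 6), np.nan))
        with pytest.raises(ValueError, match="at least 2"):
            cluster_profiles(m)


class TestRegulationPatterns:
    def _comparisons(self, design, values, proteins):
        m = matrix_from_values(design, values, proteins)
        return {
            cid: compare(m, *cid.split("/"))
            for cid in ("N2/N1", "N3/N2", "N5/N4", "N6/N5")
        }

    def test_down_everywhere_is_both_down_in_intersection_mode(self, design):
        # ratios halve at every step in both tissues
        values = [[4, 2, 1, 4, 2, 1]]
        comps = self._comparisons(design, values, ["P"])
        part = regulation_patterns(comps, mode="intersection")
        assert part.both_down == {"P"}

    def test_single_comparison_up_union_vs_intersection(self, design):
        # up only in N5/N4, flat elsewhere
        values = [[1, 1, 1, 1, 2, 2]]
        comps = self._comparisons(design, values, ["P"])
        union = regulation_patterns(comps, mode="union")
        inter = regulation_patterns(comps, mode="intersection")
        assert union.endosperm_only_up == {"P"}
        assert all("P" not in members for members in inter.classes.values())

    def test_classes_partition_classified_proteins(self, design):
        rng = np.random.default_rng(9)
        values = 2.0 ** rng.normal(0, 1.2, size=(80, 6))
        comps = self._comparisons(design, values, [f"P{i}" for i in range(80)])
        for mode in ("intersection", "union"):
            part = regulation_patterns(comps, mode=mode)
            seen = [acc for members in part.classes.values() for acc in members]
            assert len(seen) == len(set(seen))
            for (p_status, e_status), members in part.classes.items():
                for acc in members:
                    assert part.tissue_status["pericarp"][acc] == p_status
                    assert part.tissue_status["endosperm"][acc] == e_status

    def test_unknown_mode_rejected(self, design):
        comps = self._comparisons(design, [[1, 1, 1, 1, 1, 1]], ["P"])
        with pytest.raises(ValueError):
            regulation_patterns(comps, mode="majority")
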