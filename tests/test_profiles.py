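"""Jaccard analysis, distinct-profile counting, distribution comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereobind import (
    compare_distributions,
    count_distinct_profiles,
    distinct_profile_breakdown,
    generate_library,
    identify_stereoisomer_groups,
    jaccard_distance,
    pair_category_distances,
    SyntheticLibraryConfig,
)
from stereobind.grouping import StereoGroup


def _group(member_ids):
    return StereoGroup(
        group_id="G", connectivity_key="X" * 14, member_ids=tuple(member_ids)
    )


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 0], [1, 2, 0], 0.0),  # identical
            ([1, 0, 0], [0, 2, 0], 1.0),  # disjoint bound sets
            ([1, 1, 0], [0, 2, 1], 1 - 1 / 3),  # A={t0,t1}, B={t1,t2}
            ([2, 1, 0], [1, 2, 0], 0.0),  # weak/strong swap binarizes away
            ([0, 0, 0], [0, 0, 0], 0.0),  # both-empty convention
        ],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard_distance(np.array(a), np.array(b)) == pytest.approx(expected)

    def test_mismatched_target_lists_raise(self):
        with pytest.raises(ValueError):
            jaccard_distance(np.array([1, 0]), np.array([1, 0, 2]))

    def test_invalid_values_raise(self):
        with pytest.raises(ValueError):
            jaccard_distance(np.array([3, 0]), np.array([1, 0]))

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 2), st.integers(0, 2), st.integers(0, 2)
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_metric_properties(self, triples):
        """Jaccard distance is a metric: symmetric, in [0,1], triangular."""
        arr = np.array(triples)
        p, q, r = arr[:, 0], arr[:, 1], arr[:, 2]
        dpq = jaccard_distance(p, q)
        dqr = jaccard_distance(q, r)
        dpr = jaccard_distance(p, r)
        assert dpq == jaccard_distance(q, p)
        assert 0.0 <= dpq <= 1.0
        assert dpr <= dpq + dqr + 1e-12


class TestDistinctProfiles:
    def test_counts(self, small_library):
        import pandas as pd

        profiles = pd.DataFrame(
            [[1, 0], [1, 0], [2, 0], [0, 1]],
            index=["a", "b", "c", "d"],
            columns=["T0", "T1"],
        )
        assert count_distinct_profiles(_group(["a", "b"]), profiles) == 1
        assert count_distinct_profiles(_group(["a", "c", "d"]), profiles) == 3
        # weak-vs-strong at one target is a distinct profile (no binarization)
        assert count_distinct_profiles(_group(["a", "c"]), profiles) == 2
        # invariant under member reordering
        assert count_distinct_profiles(_group(["d", "c", "a"]), profiles) == 3

    def test_missing_member_raises_with_name(self, small_library):
        with pytest.raises(KeyError, match="ghost"):
            count_distinct_profiles(_group(["ghost", "M0000_0"]), small_library.profiles)

    @pytest.mark.parametrize("p,expected_distinct", [(0.0, {1}), (1.0, {2})])
    def test_breakdown_extremes(self, p, expected_distinct):
        lib = generate_library(
            SyntheticLibraryConfig(
                n_families=20,
                stereocenters_per_family=(1, 1),
                isomers_per_family=(2, 2),
                n_targets=10,
                stereo_sensitivity=p,
                undefined_fraction=0.0,
                seed=3,
            )
        )
        groups = identify_stereoisomer_groups(lib.molecules).groups
        breakdown = distinct_profile_breakdown(groups, lib.profiles)
        assert set(breakdown) == {2}
        assert set(breakdown[2]) == expected_distinct
        assert sum(breakdown[2].values()) == pytest.approx(1.0)

    def test_breakdown_matches_truth_table(self, single_center_library):
        lib = single_center_library
        groups = identify_stereoisomer_groups(lib.molecules).groups
        breakdown = distinct_profile_breakdown(groups, lib.profiles)
        frac_two_truth = lib.truth.profile_differs.mean()
        assert breakdown[2].get(2, 0.0) == pytest.approx(frac_two_truth)


class TestPairCategories:
    def test_category_semantics_and_ordering(self, small_library):
        groups = identify_stereoisomer_groups(small_library.molecules).groups
        records = pair_category_distances(
            groups, small_library.profiles, n_random_pairs=2000, seed=5
        )
        by_cat = {}
        for r in records:
            by_cat.setdefault(r.category, []).append(r.jaccard)
        assert set(by_cat) == {"share0", "share_ge1", "stereoisomer"}
        # share0 pairs have disjoint bound sets, hence distance exactly 1
        assert all(d == 1.0 for d in by_cat["share0"])
        assert all(d < 1.0 for d in by_cat["share_ge1"])
        # within-group profiles are most similar, random pairs least
        assert (
            np.mean(by_cat["stereoisomer"])
            < np.mean(by_cat["share_ge1"])
            < np.mean(by_cat["share0"])
        )

    def test_deterministic_given_seed(self, small_library):
        groups = identify_stereoisomer_groups(small_library.molecules).groups
        a = pair_category_distances(groups, small_library.profiles, 500, seed=1)
        b = pair_category_distances(groups, small_library.profiles, 500, seed=1)
        assert a == b

    def test_binarization_is_a_lower_bound(self, small_library):
        """Fraction of stereoisomer pairs at Jaccard > 0 never exceeds the
        fraction with distinct ternary profiles."""
        lib = small_library
        frac_ternary = lib.truth.profile_differs.mean()
        groups = identify_stereoisomer_groups(lib.molecules).groups
        records = [
            r
            for r in pair_category_distances(groups, lib.profiles, 10, seed=0)
            if r.category == "stereoisomer"
        ]
        frac_jaccard = np.mean([r.jaccard > 0 for r in records])
        assert frac_jaccard <= frac_ternary + 1e-12


class TestCompareDistributions:
    def test_identical_samples_give_p_near_one(self):
        x = np.arange(100.0)
        _, p = compare_distributions(x, x)
        assert p > 0.9

    def test_large_shift_saturates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        _, p = compare_distributions(x, x + 100.0)
        assert p < 1e-10

    def test_small_sample_u_statistic(self):
        """All four cross-comparisons favour y: U for x is 0."""
        u, _ = compare_distributions([1, 2], [3, 4])
        assert u == 0.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])
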