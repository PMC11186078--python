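"""Stereoisomer group identification against brute-force and generator oracles."""

import numpy as np
import pytest

from stereobind import (
    generate_library,
    group_size_histogram,
    identify_stereoisomer_groups,
    standardize_molecule,
    SyntheticLibraryConfig,
)


def brute_force_groups(records):
    """O(n²) oracle: pairwise compare filter fields, no hashing involved.

    Two fully-defined, isotope-free records are stereoisomers iff their
    stereo-stripped canonical SMILES, protonation character and formal
    charge all agree while their full canonical SMILES differ.
    """
    recs = {}
    for r in sorted(records, key=lambda r: r.id):  # duplicate collapse
        recs.setdefault(r.inchikey, r)
    recs = list(recs.values())
    eligible = [
        r
        for r in recs
        if r.stereo_status == "fully_defined" and not r.has_isotope
    ]
    parent = {r.id: r.id for r in eligible}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(len(eligible)):
        for j in range(i + 1, len(eligible)):
            a, b = eligible[i], eligible[j]
            if (
                a.canonical_smiles_nostereo == b.canonical_smiles_nostereo
                and a.protonation_char == b.protonation_char
                and a.formal_charge == b.formal_charge
            ):
                parent[find(a.id)] = find(b.id)
    clusters = {}
    for r in eligible:
        clusters.setdefault(find(r.id), set()).add(r.id)
    return sorted(tuple(sorted(c)) for c in clusters.values() if len(c) >= 2)


class TestIdentifyGroups:
    def test_penicillamine_enantiomers_form_one_group(self, penicillamine_records):
        result = identify_stereoisomer_groups(list(penicillamine_records))
        assert len(result.groups) == 1
        (group,) = result.groups
        assert group.n_members == 2
        assert group.member_ids == ("pen_R", "pen_S")
        assert group.connectivity_key == "VVNCNSJFMMFHPL"

    def test_isotope_labeled_pair_is_excluded(self):
        records = [
            standardize_molecule("plain", "C[C@H](N)C(=O)O"),
            standardize_molecule("heavy", "[13CH3][C@@H](N)C(=O)O"),
        ]
        result = identify_stereoisomer_groups(records)
        assert result.groups == ()
        assert result.excluded_as_dict()["heavy"] == "isotope"

    def test_synthetic_library_matches_family_partition(self, small_library):
        """Groups must equal the generator's family partition restricted to
        fully-defined members with ≥2 survivors."""
        result = identify_stereoisomer_groups(small_library.molecules)
        by_fam = {}
        for m in small_library.molecules:
            if m.stereo_status == "fully_defined":
                by_fam.setdefault(
                    int(small_library.family_labels[m.id]), set()
                ).add(m.id)
        expected = sorted(
            tuple(sorted(v)) for v in by_fam.values() if len(v) >= 2
        )
        assert sorted(g.member_ids for g in result.groups) == expected

    def test_equals_brute_force_oracle(self, small_library):
        result = identify_stereoisomer_groups(small_library.molecules)
        assert sorted(g.member_ids for g in result.groups) == brute_force_groups(
            small_library.molecules
        )

    def test_permutation_invariance(self, small_library):
        records = list(small_library.molecules)
        baseline = identify_stereoisomer_groups(records)
        rng = np.random.default_rng(3)
        shuffled = [records[k] for k in rng.permutation(len(records))]
        assert identify_stereoisomer_groups(shuffled) == baseline

    def test_adding_a_molecule_never_removes_a_pair(self, penicillamine_records):
        records = list(penicillamine_records)
        before = identify_stereoisomer_groups(records)
        pairs_before = {
            frozenset((a, b))
            for g in before.groups
            for i, a in enumerate(g.member_ids)
            for b in g.member_ids[i + 1 :]
        }
        extra = standardize_molecule("unrelated", "c1ccccc1CC")
        after = identify_stereoisomer_groups(records + [extra])
        pairs_after = {
            frozenset((a, b))
            for g in after.groups
            for i, a in enumerate(g.member_ids)
            for b in g.member_ids[i + 1 :]
        }
        assert pairs_before <= pairs_after

    def test_duplicate_inchikeys_collapse(self, penicillamine_records):
        s, r = penicillamine_records
        dup = standardize_molecule("zz_dup_of_S", s.canonical_smiles)
        result = identify_stereoisomer_groups([s, r, dup])
        assert len(result.groups) == 1
        assert result.groups[0].member_ids == ("pen_R", "pen_S")
        assert result.excluded_as_dict()["zz_dup_of_S"] == "duplicate"

    def test_partially_defined_members_excluded_with_reason(self, small_library):
        result = identify_stereoisomer_groups(small_library.molecules)
        reasons = result.excluded_as_dict()
        for m in small_library.molecules:
            if m.stereo_status == "partially_defined":
                assert reasons[m.id] == "partially_defined"
        for g in result.groups:
            assert len(g.member_ids) >= 2
            blocks = [
                next(m for m in small_library.molecules if m.id == i).stereo_block
                for i in g.member_ids
            ]
            assert len(set(blocks)) == len(blocks)

    def test_lone_survivor_is_singleton(self):
        # one fully-defined compound whose only bucket-mate is excluded
        records = [
            standardize_molecule("ok", "C[C@H](N)C(=O)O"),
            standardize_molecule("rac", "CC(N)C(=O)O"),  # undefined centre
        ]
        result = identify_stereoisomer_groups(records)
        assert result.groups == ()
        assert result.excluded_as_dict() == {
            "ok": "singleton",
            "rac": "partially_defined",
        }


class TestHistogram:
    def test_empty(self):
        assert group_size_histogram([]) == {}

    def test_counts(self, small_library):
        result = identify_stereoisomer_groups(small_library.molecules)
        hist = group_size_histogram(result.groups)
        assert sum(hist.values()) == len(result.groups)
        assert all(size >= 2 for size in hist)

    def test_fixed_isomer_count_gives_single_bar(self):
        cfg = SyntheticLibraryConfig(
            n_families=10,
            stereocenters_per_family=(2, 2),
            isomers_per_family=(2, 2),
            undefined_fraction=0.0,
            seed=2,
        )
        lib = generate_library(cfg)
        result = identify_stereoisomer_groups(lib.molecules)
        assert set(group_size_histogram(result.groups)) == {2}
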