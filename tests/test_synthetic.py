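"""Generator contracts: determinism, mutation semantics, closed-form recovery."""

import numpy as np
import pytest
from scipy.spatial.distance import cosine as cosine_dist

from stereobind import SyntheticLibraryConfig, generate_library
from stereobind.io import read_library, write_library


def _config(**kw):
    base = dict(
        n_families=30,
        stereocenters_per_family=(1, 2),
        isomers_per_family=(2, 2),
        n_targets=20,
        stereo_sensitivity=0.1,
        undefined_fraction=0.0,
        seed=4,
    )
    base.update(kw)
    return SyntheticLibraryConfig(**base)


class TestConfigValidation:
    def test_unsatisfiable_isomer_count(self):
        with pytest.raises(ValueError, match="unsatisfiable"):
            _config(stereocenters_per_family=(1, 1), isomers_per_family=(3, 4))

    @pytest.mark.parametrize(
        "field,value",
        [
            ("stereo_sensitivity", 1.5),
            ("undefined_fraction", -0.1),
            ("n_targets", 0),
            ("isomers_per_family", (1, 2)),
        ],
    )
    def test_invalid_fields(self, field, value):
        with pytest.raises(ValueError):
            _config(**{field: value})


class TestGeneration:
    def test_zero_sensitivity_means_identical_profiles(self):
        lib = generate_library(_config(stereo_sensitivity=0.0))
        assert len(lib.truth) > 0
        assert not lib.truth.profile_differs.any()

    def test_full_sensitivity_two_isomer_families_differ_everywhere(self):
        lib = generate_library(
            _config(stereo_sensitivity=1.0, isomers_per_family=(2, 2))
        )
        assert lib.truth.profile_differs.all()
        for _, row in lib.truth.iterrows():
            a = lib.profiles.loc[row.id_a].to_numpy()
            b = lib.profiles.loc[row.id_b].to_numpy()
            assert (a != b).all()

    def test_distinct_pair_fraction_matches_bernoulli_complement(self):
        """Single-centre library: P(pair distinct) = 1 - (1-p)^T exactly."""
        p, T = 0.01, 50
        lib = generate_library(
            SyntheticLibraryConfig(
                n_families=200,
                stereocenters_per_family=(1, 1),
                isomers_per_family=(2, 2),
                n_targets=T,
                stereo_sensitivity=p,
                undefined_fraction=0.0,
                seed=0,
            )
        )
        expected = 1.0 - (1.0 - p) ** T  # ~0.395
        n = len(lib.truth)
        observed = lib.truth.profile_differs.mean()
        assert abs(observed - expected) <= 1.96 * np.sqrt(
            expected * (1 - expected) / n
        )

    def test_mutation_semantics_truth_flag_iff_vectors_differ(self, small_library):
        for _, row in small_library.truth.iterrows():
            a = small_library.profiles.loc[row.id_a].to_numpy()
            b = small_library.profiles.loc[row.id_b].to_numpy()
            assert bool((a != b).any()) == bool(row.profile_differs)

    def test_fully_defined_compounds_have_nonzero_profile(self, small_library):
        for m in small_library.molecules:
            if m.stereo_status == "fully_defined":
                assert small_library.profiles.loc[m.id].to_numpy().any()

    def test_family_labels_consistent_with_constitution(self, small_library):
        seen = {}
        for m in small_library.molecules:
            fam = int(small_library.family_labels[m.id])
            seen.setdefault(m.canonical_smiles_nostereo, set()).add(fam)
        assert all(len(v) == 1 for v in seen.values())
        fams = [min(v) for v in seen.values()]
        assert len(fams) == len(set(fams))

    def test_signature_separation(self):
        """Profile-divergent within-family pairs sit farther apart in
        signature space than profile-identical pairs (mean cosine)."""
        lib = generate_library(
            _config(n_families=120, stereo_sensitivity=0.03, n_targets=20, seed=9)
        )
        diff, same = [], []
        for _, row in lib.truth.iterrows():
            d = cosine_dist(
                lib.signatures.loc[row.id_a], lib.signatures.loc[row.id_b]
            )
            (diff if row.profile_differs else same).append(d)
        assert len(diff) >= 30 and len(same) >= 30
        assert np.mean(diff) > np.mean(same)


class TestWriteRead:
    def test_round_trip_identity(self, tmp_path, small_library):
        write_library(small_library, tmp_path / "lib")
        back = read_library(tmp_path / "lib")
        assert [m.__dict__ for m in back.molecules] == [
            m.__dict__ for m in small_library.molecules
        ]
        assert back.profiles.equals(small_library.profiles)
        assert np.allclose(
            back.signatures.to_numpy(),
            small_library.signatures.to_numpy(),
            atol=1e-12,
            rtol=0,
        )
        assert back.family_labels.equals(small_library.family_labels)
        assert back.truth.equals(small_library.truth)
        assert back.config == small_library.config

    def test_hdf5_round_trip(self, tmp_path, small_library):
        write_library(small_library, tmp_path / "lib", signature_fmt="hdf5")
        back = read_library(tmp_path / "lib")
        np.testing.assert_array_equal(
            back.signatures.to_numpy(), small_library.signatures.to_numpy()
        )

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = _config(n_families=10, undefined_fraction=0.3)
        for d in ("a", "b"):
            write_library(generate_library(cfg), tmp_path / d)
        for name in (
            "molecules.smi",
            "profiles.tsv",
            "signatures.csv",
            "families.tsv",
            "truth.tsv",
            "manifest.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_different_seeds_differ(self):
        a = generate_library(_config(seed=1))
        b = generate_library(_config(seed=2))
        assert not a.profiles.equals(b.profiles)

    def test_empty_library(self, tmp_path):
        lib = generate_library(_config(n_families=0))
        assert lib.molecules == []
        assert len(lib.truth) == 0
        manifest = write_library(lib, tmp_path / "empty")
        assert manifest["n_molecules"] == 0
        assert (tmp_path / "empty" / "profiles.tsv").read_text().startswith(
            "compound_id"
        )
        back = read_library(tmp_path / "empty")
        assert back.molecules == []

    def test_single_family_counts(self, tmp_path):
        lib = generate_library(
            _config(n_families=1, stereocenters_per_family=(1, 1))
        )
        write_library(lib, tmp_path / "one")
        smi_lines = (tmp_path / "one" / "molecules.smi").read_text().splitlines()
        assert len(smi_lines) == 2
        truth_lines = (tmp_path / "one" / "truth.tsv").read_text().splitlines()
        assert len(truth_lines) == 2  # header + 1 pair row
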