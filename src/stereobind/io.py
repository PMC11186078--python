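"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: ``.smi`` (whitespace-separated SMILES and
id, no header), TSV matrices for ternary binding profiles and truth
tables, CSV (or HDF5) for continuous signature/descriptor matrices, SDF
(V2000) for conformers, and a JSON manifest with config and SHA-256
checksums.  Floats are written with 17 significant digits so matrices
round-trip bit-exactly through CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from rdkit import Chem

from .conformers import Conformer3D, conformer_to_mol
from .grouping import GroupingResult, StereoGroup
from .registry import MoleculeRecord, standardize_molecule
from .synthetic import SyntheticLibrary, SyntheticLibraryConfig

__all__ = [
    "write_library",
    "read_library",
    "read_smi",
    "write_smi",
    "read_profiles_tsv",
    "read_signatures",
    "write_signatures",
    "write_records_csv",
    "read_records_csv",
    "write_groups_tsv",
    "write_conformers_sdf",
    "write_conformers_csv",
]

_FLOAT_FMT = "%.17g"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------- .smi files


def write_smi(path: Path, entries: list[tuple[str, str]]) -> None:
    """Write (smiles, id) lines; whitespace-separated, no header."""
    with open(path, "w") as fh:
        for smiles, mol_id in entries:
            fh.write(f"{smiles}\t{mol_id}\n")


def read_smi(path: Path) -> list[tuple[str, str]]:
    """Read (smiles, id) pairs; ids autogenerated when absent."""
    out = []
    for k, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol{k:06d}"
        out.append((smiles, mol_id))
    return out


# ------------------------------------------------------------- flat matrices


def read_profiles_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_signatures(path: Path, signatures: pd.DataFrame, fmt: str = "csv") -> None:
    if fmt == "csv":
        signatures.to_csv(path, float_format=_FLOAT_FMT)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=signatures.to_numpy(dtype=float))
            fh.create_dataset(
                "compound_id", data=np.array(signatures.index, dtype="S")
            )
            fh.create_dataset("columns", data=np.array(signatures.columns, dtype="S"))
    else:
        raise ValueError(f"unknown signature format {fmt!r}")


def read_signatures(path: Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            ids = [s.decode() for s in fh["compound_id"][()]]
            cols = [s.decode() for s in fh["columns"][()]]
            values = fh["values"][()]
        return pd.DataFrame(
            values, index=pd.Index(ids, name="compound_id"), columns=cols
        )
    return pd.read_csv(path, index_col=0)


# ------------------------------------------------------------ library bundle


def write_library(lib: SyntheticLibrary, out_dir: Path, signature_fmt: str = "csv") -> dict:
    """Write a synthetic library bundle and return its manifest.

    Emits ``molecules.smi``, ``profiles.tsv``, ``signatures.csv`` (or
    ``.h5``), ``families.tsv``, ``truth.tsv`` and ``manifest.json``.
    Deterministic: byte-identical across calls for the same library.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_smi(
            out_dir / "molecules.smi",
            [(lib.smiles_in.get(m.id, m.canonical_smiles), m.id) for m in lib.molecules],
        )
        lib.profiles.to_csv(out_dir / "profiles.tsv", sep="\t")
        sig_name = "signatures.csv" if signature_fmt == "csv" else "signatures.h5"
        write_signatures(out_dir / sig_name, lib.signatures, signature_fmt)
        lib.family_labels.to_frame().to_csv(out_dir / "families.tsv", sep="\t")
        lib.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing library under {out_dir}: {exc}") from exc

    files = ["molecules.smi", "profiles.tsv", sig_name, "families.tsv", "truth.tsv"]
    manifest = {
        "config": lib.config.__dict__ | {
            "stereocenters_per_family": list(lib.config.stereocenters_per_family),
            "isomers_per_family": list(lib.config.isomers_per_family),
        },
        "n_molecules": len(lib.molecules),
        "n_families": int(lib.family_labels.nunique()) if len(lib.family_labels) else 0,
        "files": {name: _sha256(out_dir / name) for name in files},
        "signature_format": signature_fmt,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_library(out_dir: Path) -> SyntheticLibrary:
    """Round-trip reader for :func:`write_library` bundles."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["stereocenters_per_family"] = tuple(cfg_dict["stereocenters_per_family"])
    cfg_dict["isomers_per_family"] = tuple(cfg_dict["isomers_per_family"])
    config = SyntheticLibraryConfig(**cfg_dict)

    entries = read_smi(out_dir / "molecules.smi")
    molecules = [standardize_molecule(mid, smi) for smi, mid in entries]
    profiles = read_profiles_tsv(out_dir / "profiles.tsv")
    sig_name = (
        "signatures.csv" if manifest["signature_format"] == "csv" else "signatures.h5"
    )
    signatures = read_signatures(out_dir / sig_name)
    families = pd.read_csv(out_dir / "families.tsv", sep="\t", index_col=0)["family"]
    truth = pd.read_csv(
        out_dir / "truth.tsv",
        sep="\t",
        dtype={
            "id_a": str,
            "id_b": str,
            "family": int,
            "same_family": bool,
            "profile_differs": bool,
            "pair_fully_defined": bool,
        },
    )
    return SyntheticLibrary(
        config=config,
        molecules=molecules,
        profiles=profiles,
        signatures=signatures,
        family_labels=families,
        truth=truth,
        smiles_in={mid: smi for smi, mid in entries},
    )


# ------------------------------------------------------------ other artifacts


_RECORD_COLUMNS = [
    "id",
    "smiles_in",
    "canonical_smiles",
    "canonical_smiles_nostereo",
    "inchikey",
    "connectivity_key",
    "stereo_block",
    "protonation_char",
    "formula",
    "formal_charge",
    "has_isotope",
    "n_potential_stereocenters",
    "n_assigned_stereocenters",
    "stereo_status",
]


def write_records_csv(path: Path, records: list[MoleculeRecord]) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=_RECORD_COLUMNS).to_csv(
        path, index=False
    )


def read_records_csv(path: Path) -> list[MoleculeRecord]:
    df = pd.read_csv(path, dtype={"has_isotope": bool})
    return [MoleculeRecord(**row) for row in df.to_dict(orient="records")]


def write_groups_tsv(out_dir: Path, result: GroupingResult) -> None:
    out_dir = Path(out_dir)
    rows = [
        {"group_id": g.group_id, "connectivity_key": g.connectivity_key, "member_id": m}
        for g in result.groups
        for m in g.member_ids
    ]
    pd.DataFrame(rows, columns=["group_id", "connectivity_key", "member_id"]).to_csv(
        out_dir / "groups.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        list(result.exclusions), columns=["molecule_id", "reason"]
    ).to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)


def write_conformers_sdf(
    path: Path, conformers: list[Conformer3D], smiles_by_id: dict[str, str] | None = None
) -> None:
    """SDF (V2000), heavy atoms only, one conformer per molecule."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    try:
        for conf in conformers:
            smiles = smiles_by_id.get(conf.molecule_id) if smiles_by_id else None
            writer.write(conformer_to_mol(conf, smiles))
    finally:
        writer.close()


def write_conformers_csv(path: Path, conformers: list[Conformer3D]) -> None:
    rows = [
        {
            "molecule_id": c.molecule_id,
            "atom_index": i,
            "element": sym,
            "x": x,
            "y": y,
            "z": z,
        }
        for c in conformers
        for i, (sym, (x, y, z)) in enumerate(zip(c.atom_symbols, c.coordinates))
    ]
    pd.DataFrame(
        rows, columns=["molecule_id", "atom_index", "element", "x", "y", "z"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
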