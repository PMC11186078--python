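"""Single-conformer 3D embedding.

One optimized conformer per compound: ETKDG distance-geometry embedding
followed by MMFF94 relaxation, hydrogens added for the embedding and
removed before export.  Compounds with partially defined stereochemistry
are refused — a conformer of an ambiguous structure would silently pick
one stereoisomer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDistGeom, rdForceFieldHelpers

from .registry import MoleculeRecord

__all__ = ["Conformer3D", "ConformerError", "generate_conformer"]

log = logging.getLogger(__name__)

_MMFF_MAX_ITERS = 1000  # single relaxation; non-convergence is accepted
_EMBED_RETRIES = 5


class ConformerError(RuntimeError):
    """Raised when embedding fails or the input stereochemistry is ambiguous."""


@dataclass(frozen=True)
class Conformer3D:
    """Heavy-atom coordinates (Å) of a single embedded conformer."""

    molecule_id: str
    atom_symbols: tuple[str, ...]
    coordinates: np.ndarray  # (n_heavy, 3)
    optimized: bool
    embed_seed: int

    def __post_init__(self) -> None:
        if self.coordinates.shape != (len(self.atom_symbols), 3):
            raise ValueError("coordinates must be (n_atoms, 3)")
        if "H" in self.atom_symbols:
            raise ValueError("conformers are heavy-atom only")


def generate_conformer(rec: MoleculeRecord, embed_seed: int = 42) -> Conformer3D:
    """Embed and optimize one 3D conformer for a standardized record.

    Deterministic for a fixed ``embed_seed``.  The retry schedule on
    embedding failure is itself seeded, so repeated calls are identical.

    Raises
    ------
    ConformerError
        If the record is ``partially_defined``, or embedding fails after
        the configured retries.
    """
    if rec.stereo_status == "partially_defined":
        raise ConformerError(
            f"refusing conformer for {rec.id}: stereochemistry partially defined"
        )
    mol = Chem.MolFromSmiles(rec.canonical_smiles)
    if mol is None:  # pragma: no cover - canonical SMILES always reparse
        raise ConformerError(f"cannot reparse canonical SMILES for {rec.id}")
    molh = Chem.AddHs(mol)

    cid = -1
    for attempt in range(_EMBED_RETRIES):
        params = rdDistGeom.ETKDGv3()
        params.randomSeed = int(embed_seed) + attempt
        params.useRandomCoords = attempt >= 2
        cid = rdDistGeom.EmbedMolecule(molh, params)
        if cid >= 0:
            break
    if cid < 0:
        raise ConformerError(
            f"ETKDG embedding failed for {rec.id} after {_EMBED_RETRIES} attempts"
        )

    optimized = False
    if molh.GetNumAtoms() > 1:
        try:
            status = rdForceFieldHelpers.MMFFOptimizeMolecule(
                molh, maxIters=_MMFF_MAX_ITERS
            )
        except Exception:  # force-field setup failure
            status = -1
        if status >= 0:
            optimized = True
        else:
            log.warning(
                "MMFF94 setup failed for %s; keeping unoptimized embedding", rec.id
            )
    heavy = Chem.RemoveHs(molh)
    coords = np.asarray(heavy.GetConformer().GetPositions(), dtype=float)
    symbols = tuple(a.GetSymbol() for a in heavy.GetAtoms())
    return Conformer3D(
        molecule_id=rec.id,
        atom_symbols=symbols,
        coordinates=coords,
        optimized=optimized,
        embed_seed=int(embed_seed),
    )


def conformer_to_mol(conf: Conformer3D, smiles: str | None = None) -> Chem.Mol:
    """Rebuild an RDKit molecule carrying the conformer, for SDF export."""
    if smiles is not None:
        mol = Chem.MolFromSmiles(smiles)
        mol = Chem.RemoveHs(mol)
    else:
        mol = Chem.RWMol()
        for sym in conf.atom_symbols:
            mol.AddAtom(Chem.Atom(sym))
        mol = mol.GetMol()
    c = Chem.Conformer(len(conf.atom_symbols))
    for i, (x, y, z) in enumerate(conf.coordinates):
        c.SetAtomPosition(i, (float(x), float(y), float(z)))
    mol.RemoveAllConformers()
    mol.AddConformer(c, assignId=True)
    mol.SetProp("_Name", conf.molecule_id)
    return mol
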