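"""Molecule standardization and structure-key computation.

Every compound entering the pipeline is normalised once into a
:class:`MoleculeRecord`: canonical SMILES with and without stereo
descriptors, the hashed InChIKey and its layers (connectivity block,
stereo block, protonation character), and a classification of how
completely the stereochemistry is specified.  The stereo-definition
status drives the downstream exhaustiveness filter that keeps the
analysis restricted to enantiomerically pure entries, excluding
racemic or partially characterised registrations.

Potential stereo elements include both tetrahedral centres and double-bond
(E/Z) geometry; a molecule is ``fully_defined`` only when every potential
element carries an explicit descriptor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit.rdBase import BlockLogs

__all__ = [
    "MoleculeRecord",
    "StandardizationError",
    "standardize_molecule",
    "assess_stereo_definition",
]

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

_STEREO_ELEMENT_TYPES = (
    Chem.StereoType.Atom_Tetrahedral,
    Chem.StereoType.Bond_Double,
)


class StandardizationError(ValueError):
    """Raised when an input structure cannot be parsed or keyed."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized compound with structure keys and stereo status.

    ``stereo_status`` is one of ``achiral`` (no potential stereo elements),
    ``fully_defined`` (every potential element assigned) or
    ``partially_defined`` (at least one potential element unassigned).
    """

    id: str
    smiles_in: str
    canonical_smiles: str
    canonical_smiles_nostereo: str
    inchikey: str
    connectivity_key: str
    stereo_block: str
    protonation_char: str
    formula: str
    formal_charge: int
    has_isotope: bool
    n_potential_stereocenters: int
    n_assigned_stereocenters: int
    stereo_status: str


def _count_stereo_elements(mol: Chem.Mol) -> tuple[int, int]:
    """Count (potential, assigned) stereo elements: tetrahedral + double bond."""
    elements = Chem.FindPotentialStereo(mol)
    n_pot = 0
    n_asg = 0
    for e in elements:
        if e.type not in _STEREO_ELEMENT_TYPES:
            continue
        n_pot += 1
        if e.specified == Chem.StereoSpecified.Specified:
            n_asg += 1
    return n_pot, n_asg


def standardize_molecule(mol_id: str, smiles: str) -> MoleculeRecord:
    """Parse a SMILES string and populate a :class:`MoleculeRecord`.

    Canonicalization is idempotent: standardizing ``canonical_smiles``
    reproduces the same record (apart from ``smiles_in``).

    Raises
    ------
    StandardizationError
        If the structure cannot be parsed (syntax or valence errors) or
        no InChIKey can be derived.
    """
    with BlockLogs():
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(
            f"cannot parse structure for {mol_id!r}: {smiles!r}"
        )
    canonical = Chem.MolToSmiles(mol)

    nostereo = Chem.Mol(mol)
    Chem.RemoveStereochemistry(nostereo)
    canonical_nostereo = Chem.MolToSmiles(nostereo)

    with BlockLogs():
        inchikey = Chem.MolToInchiKey(mol)
    if not inchikey or not _INCHIKEY_RE.match(inchikey):
        raise StandardizationError(
            f"no valid InChIKey for {mol_id!r} ({smiles!r}): got {inchikey!r}"
        )

    n_pot, n_asg = _count_stereo_elements(mol)

    return MoleculeRecord(
        id=mol_id,
        smiles_in=smiles,
        canonical_smiles=canonical,
        canonical_smiles_nostereo=canonical_nostereo,
        inchikey=inchikey,
        connectivity_key=inchikey[:14],
        stereo_block=inchikey[15:23],
        protonation_char=inchikey[-1],
        formula=rdMolDescriptors.CalcMolFormula(mol),
        formal_charge=Chem.GetFormalCharge(mol),
        has_isotope=any(a.GetIsotope() != 0 for a in mol.GetAtoms()),
        n_potential_stereocenters=n_pot,
        n_assigned_stereocenters=n_asg,
        stereo_status=_status(n_pot, n_asg),
    )


def _status(n_potential: int, n_assigned: int) -> str:
    if n_potential == 0:
        return "achiral"
    if n_assigned == n_potential:
        return "fully_defined"
    return "partially_defined"


def assess_stereo_definition(rec: MoleculeRecord) -> str:
    """Classify how completely a record's stereochemistry is specified.

    Total on valid records: ``achiral`` when there is nothing to specify,
    ``fully_defined`` when every potential stereo element (tetrahedral or
    double-bond) is assigned, ``partially_defined`` otherwise — including
    the fully-unassigned case, which is how racemic registrations appear.
    """
    return _status(rec.n_potential_stereocenters, rec.n_assigned_stereocenters)
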