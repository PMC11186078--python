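"""Molecular descriptor families contrasted by the benchmark.

Two vector descriptors with opposite stereo behaviour:

* ``fp2d`` — a hashed circular (Morgan, radius 2) fingerprint computed on
  the stereo-stripped constitution.  By construction it is identical for
  all stereoisomers of one constitution: the stereo-blind 2D baseline.

* ``geo3d`` — a shape descriptor computed from one 3D conformer.  It
  concatenates (a) USR-style distance-distribution moments taken from four
  reference points (centroid, atom closest to it, atom farthest from it,
  atom farthest from that) and (b) a chirality block built from signed
  tetrahedral volumes over atom quadruples.  Block (a) is invariant to
  any rigid motion *and* to reflection; block (b) is rigid-invariant but
  changes sign under reflection, which is exactly what separates
  enantiomers — plain distance moments cannot.

Signed volumes are normalised by the cube of the mean interatomic
distance (dimensionless, size-independent) and the chirality block is
rescaled to the norm of the moment block so that neither block dominates
the cosine geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .conformers import Conformer3D
from .registry import MoleculeRecord

__all__ = [
    "DescriptorVector",
    "fingerprint_2d",
    "descriptor_3d",
    "cosine_distance",
]

DESCRIPTOR_KINDS = ("fp2d", "geo3d", "signature")

_MAX_QUADRUPLES = 5000
_QUADRUPLE_SEED = 0x1234


@dataclass(frozen=True)
class DescriptorVector:
    compound_id: str
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in DESCRIPTOR_KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")


def fingerprint_2d(
    rec: MoleculeRecord, radius: int = 2, n_bits: int = 2048
) -> DescriptorVector:
    """Hashed circular fingerprint of the stereo-stripped constitution.

    Deliberately blind to stereochemistry: the fingerprint is computed on
    ``canonical_smiles_nostereo``, so all stereoisomers of a constitution
    map to bitwise-identical vectors.
    """
    mol = Chem.MolFromSmiles(rec.canonical_smiles_nostereo)
    if mol is None:  # pragma: no cover
        raise ValueError(f"cannot reparse constitution for {rec.id}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = gen.GetFingerprintAsNumPy(mol)
    return DescriptorVector(rec.id, "fp2d", np.asarray(bits, dtype=float))


def _usr_moments(coords: np.ndarray) -> np.ndarray:
    """Mean/σ/cbrt-skew of distances from four reference points (12 values)."""
    centroid = coords.mean(axis=0)
    d_ctd = np.linalg.norm(coords - centroid, axis=1)
    cst = coords[int(np.argmin(d_ctd))]  # closest to centroid
    fct = coords[int(np.argmax(d_ctd))]  # farthest from centroid
    d_fct = np.linalg.norm(coords - fct, axis=1)
    ftf = coords[int(np.argmax(d_fct))]  # farthest from the farthest

    out = []
    for ref in (centroid, cst, fct, ftf):
        d = np.linalg.norm(coords - ref, axis=1)
        mu = d.mean()
        sigma = d.std()
        skew = np.cbrt(((d - mu) ** 3).mean())
        out.extend((mu, sigma, skew))
    return np.asarray(out, dtype=float)


def _quadruple_indices(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """All atom quadruples when few, else a seeded sample of 5000."""
    total = n_atoms * (n_atoms - 1) * (n_atoms - 2) * (n_atoms - 3) // 24
    quads = np.fromiter(
        (i for q in combinations(range(n_atoms), 4) for i in q),
        dtype=np.int64,
    ).reshape(total, 4) if total <= _MAX_QUADRUPLES else None
    if quads is not None:
        return quads
    picks = rng.choice(total, size=_MAX_QUADRUPLES, replace=False)
    return np.array([_unrank_quadruple(int(r), n_atoms) for r in np.sort(picks)])


def _unrank_quadruple(rank: int, n: int) -> tuple[int, int, int, int]:
    """Combinatorial unranking of the `rank`-th 4-combination of range(n)."""
    from math import comb

    out = []
    prev = -1
    for slots_left in (3, 2, 1, 0):
        c = prev + 1
        while True:
            count = comb(n - c - 1, slots_left)
            if rank < count:
                break
            rank -= count
            c += 1
        out.append(c)
        prev = c
    return tuple(out)


def _chirality_block(coords: np.ndarray) -> np.ndarray:
    """Signed-volume moments over atom quadruples (2 values in [-1, 1]).

    Both entries are odd under reflection (they negate when the conformer
    is mirrored) and invariant under proper rigid motions.  Returns zeros
    for planar or < 4-atom inputs.
    """
    n = coords.shape[0]
    if n < 4:
        return np.zeros(2)
    rng = np.random.default_rng(_QUADRUPLE_SEED)
    quads = _quadruple_indices(n, rng)
    a = coords[quads[:, 0]]
    vols = np.linalg.det(
        np.stack(
            [coords[quads[:, 1]] - a, coords[quads[:, 2]] - a, coords[quads[:, 3]] - a],
            axis=1,
        )
    ) / 6.0
    # dimensionless: normalise by the cube of the mean interatomic distance
    diffs = coords[:, None, :] - coords[None, :, :]
    mean_dist = np.linalg.norm(diffs, axis=-1)[np.triu_indices(n, k=1)].mean()
    if mean_dist > 0:
        vols = vols / mean_dist**3
    abs_vols = np.abs(vols)
    if abs_vols.max() == 0.0:
        return np.zeros(2)
    m1 = vols.mean() / abs_vols.mean()
    m3 = np.cbrt((vols**3).mean()) / np.cbrt((abs_vols**3).mean())
    return np.array([m1, m3])


def descriptor_3d(conf: Conformer3D) -> DescriptorVector:
    """Chirality-aware shape descriptor of a single conformer (14 values).

    Entries 0–11 are the USR distance moments; entries 12–13 the chirality
    block, rescaled to the moment block's norm.  Invariant to rotation and
    translation; the chirality block negates under reflection, so mirror
    image conformers of a chiral molecule yield distinct vectors.
    """
    coords = np.asarray(conf.coordinates, dtype=float)
    if coords.shape[0] < 1:
        raise ValueError("conformer has no atoms")
    moments = _usr_moments(coords)
    chirality = _chirality_block(coords)
    scale = np.linalg.norm(moments)
    return DescriptorVector(
        conf.molecule_id, "geo3d", np.concatenate([moments, chirality * scale])
    )


def cosine_distance(a: DescriptorVector, b: DescriptorVector) -> float:
    """1 − cosine similarity, clipped to [0, 2].

    Raises on kind or length mismatch and on all-zero vectors (undefined
    direction).
    """
    if a.kind != b.kind:
        raise ValueError(f"descriptor kind mismatch: {a.kind} vs {b.kind}")
    va = np.asarray(a.values, dtype=float)
    vb = np.asarray(b.values, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("descriptor length mismatch")
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for all-zero vectors")
    if np.array_equal(va, vb):  # exact zero for identical vectors
        return 0.0
    return float(np.clip(1.0 - va @ vb / (na * nb), 0.0, 2.0))
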