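"""Synthetic stereoisomer library generator.

Produces a self-contained, fully ground-truthed stand-in for a
target-binding bioactivity corpus: families of stereoisomers sharing one
constitution, ternary binding profiles (0 none / 1 weak / 2 strong) whose
within-family divergence is controlled by a stereo-sensitivity parameter,
and 128-dimensional continuous signatures correlated with the profiles.

Constitutions are assembled procedurally from a template pool (head +
chain of substituted tetrahedral stereocenters + tail) and verified with
RDKit: each candidate scaffold must parse, expose exactly the requested
number of potential stereo elements, and be constitutionally unique
across families, so grouping can never merge two families.

Binding-profile mechanics
-------------------------
Each family draws a sparse base profile (a target is active with
probability 0.15, split weak/strong by ``weak_strong_ratio``).  Each
stereocenter of the family carries a Bernoulli(``stereo_sensitivity``)
susceptibility mask over targets plus a fixed mutation step in {1, 2}.
An isomer whose configuration differs from the family base at centres F
mutates target t iff some centre in F is susceptible at t, taking the
value determined by the lowest susceptible flipped centre (a cyclic step,
so a mutated value always differs from the base value).  Hence a pair
separated by d centres differs per target with probability 1−(1−p)^d —
bioactivity divergence scales with stereochemical divergence, and for
single-centre families the per-target mutation probability is exactly p.

Signatures are ``family base vector + profile-determined offset + noise``:
the offset direction is a deterministic function of the profile and its
magnitude grows with the profile's Hamming distance from the family base,
so identical profiles imply near-identical signatures.

All randomness flows from one root seed through per-family child streams
(stable integer-sequence seeding), so generation is deterministic and
independent of evaluation order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .registry import MoleculeRecord, StandardizationError, standardize_molecule

__all__ = ["SyntheticLibraryConfig", "SyntheticLibrary", "generate_library"]

log = logging.getLogger(__name__)

# template pools for procedural scaffold assembly
_HEADS = ("C", "CC", "CCC", "COC", "N#C", "c1ccccc1", "CC(C)", "OCC")
_TAILS = ("C", "CC", "O", "N", "CO", "CCO", "c1ccccc1", "C(C)C", "CC(=O)O")
_SUBS = ("F", "Cl", "Br", "O", "N", "C", "CC", "OC", "C#N", "CCO")

_BASE_ACTIVITY_RATE = 0.15  # sparsity of base binding profiles
_OFFSET_SCALE = 4.0  # signature offset magnitude at maximal profile divergence
_SCAFFOLD_ATTEMPTS = 400


@dataclass(frozen=True)
class SyntheticLibraryConfig:
    """Knobs of the synthetic bioactivity universe.

    ``stereo_sensitivity`` is the per-target probability that activity
    differs between two stereoisomers separated by a single stereocentre
    flip; pairs separated by d centres diverge per target with probability
    1−(1−p)^d.  For a single-centre library the distinct-profile pair
    fraction is therefore 1−(1−p)^n_targets — with the default p = 0.01
    over 50 targets, ≈ 39% of enantiomer pairs carry distinct profiles.
    """

    n_families: int = 200
    stereocenters_per_family: tuple[int, int] = (1, 3)
    isomers_per_family: tuple[int, int] = (2, 3)
    n_targets: int = 50
    stereo_sensitivity: float = 0.01
    weak_strong_ratio: float = 0.7
    undefined_fraction: float = 0.1
    signature_dim: int = 128
    signature_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo_s, hi_s = self.stereocenters_per_family
        lo_m, hi_m = self.isomers_per_family
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if not (1 <= lo_s <= hi_s):
            raise ValueError("stereocenters_per_family must be an increasing range >= 1")
        if not (2 <= lo_m <= hi_m):
            raise ValueError("isomers_per_family must be an increasing range >= 2")
        if lo_m > 2**hi_s:
            raise ValueError(
                f"unsatisfiable config: {lo_m} isomers requested but at most "
                f"2^{hi_s} = {2**hi_s} stereoisomers exist"
            )
        if self.n_targets < 1 or self.signature_dim < 1:
            raise ValueError("n_targets and signature_dim must be >= 1")
        for name in ("stereo_sensitivity", "weak_strong_ratio", "undefined_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.signature_noise_sd < 0:
            raise ValueError("signature_noise_sd must be >= 0")


@dataclass
class SyntheticLibrary:
    """A generated library plus the ground truth the tests lean on."""

    config: SyntheticLibraryConfig
    molecules: list[MoleculeRecord]
    profiles: pd.DataFrame  # compounds × targets, int in {0,1,2}
    signatures: pd.DataFrame  # compounds × signature_dim, float
    family_labels: pd.Series  # compound id → family index
    truth: pd.DataFrame  # within-family pairs with divergence flags
    smiles_in: dict[str, str] = field(default_factory=dict)

    @property
    def compound_ids(self) -> list[str]:
        return [m.id for m in self.molecules]


def _child_rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(t) for t in tags])


def _profile_hash(values: np.ndarray) -> int:
    return int.from_bytes(
        hashlib.sha256(values.astype(np.int8).tobytes()).digest()[:4], "big"
    )


class _Scaffold:
    """A constitution template: head + stereocentre chain + tail."""

    def __init__(self, head: str, subs: tuple[str, ...], tail: str):
        self.head = head
        self.subs = subs
        self.tail = tail

    def render(self, assignment: tuple[str | None, ...]) -> str:
        parts = [self.head]
        for mark, sub in zip(assignment, self.subs):
            atom = "[CH]" if mark is None else f"[C{mark}H]"
            parts.append(f"{atom}({sub})")
        parts.append(self.tail)
        return "".join(parts)


def _draw_scaffold(
    rng: np.random.Generator,
    n_centers: int,
    min_isomers: int,
    seen_constitutions: set[str],
) -> tuple[_Scaffold, list[tuple[tuple[str, ...], MoleculeRecord]]] | None:
    """One verified, constitutionally unique scaffold plus its isomer pool."""
    for _ in range(_SCAFFOLD_ATTEMPTS):
        head = _HEADS[rng.integers(len(_HEADS))]
        tail = _TAILS[rng.integers(len(_TAILS))]
        subs = []
        for j in range(n_centers):
            while True:
                s = _SUBS[rng.integers(len(_SUBS))]
                if j == 0 or s != subs[-1]:  # avoid trivial local symmetry
                    break
            subs.append(s)
        scaffold = _Scaffold(head, tuple(subs), tail)

        try:
            probe = standardize_molecule("probe", scaffold.render(("@",) * n_centers))
        except StandardizationError:
            continue
        if (
            probe.n_potential_stereocenters != n_centers
            or probe.stereo_status != "fully_defined"
            or probe.canonical_smiles_nostereo in seen_constitutions
        ):
            continue

        # enumerate distinct, fully defined stereoisomers (meso forms collapse)
        pool: list[tuple[tuple[str, ...], MoleculeRecord]] = []
        seen_canon: set[str] = set()
        ok = True
        for assignment in product(("@", "@@"), repeat=n_centers):
            try:
                rec = standardize_molecule("probe", scaffold.render(assignment))
            except StandardizationError:
                ok = False
                break
            if (
                rec.stereo_status != "fully_defined"
                or rec.n_potential_stereocenters != n_centers
                or rec.canonical_smiles_nostereo != probe.canonical_smiles_nostereo
            ):
                ok = False
                break
            if rec.canonical_smiles in seen_canon:
                continue  # meso duplicate
            seen_canon.add(rec.canonical_smiles)
            pool.append((assignment, rec))
        if ok and len(pool) >= max(2, min_isomers):
            return scaffold, pool
    return None


def _base_profile(rng: np.random.Generator, cfg: SyntheticLibraryConfig) -> np.ndarray:
    active = rng.random(cfg.n_targets) < _BASE_ACTIVITY_RATE
    if not active.any():
        active[rng.integers(cfg.n_targets)] = True
    weak = rng.random(cfg.n_targets) < cfg.weak_strong_ratio
    return np.where(active, np.where(weak, 1, 2), 0).astype(int)


def _isomer_profile(
    base: np.ndarray,
    flips: np.ndarray,
    susceptible: np.ndarray,
    step: np.ndarray,
) -> np.ndarray:
    """Mutate the base profile at targets hit by a flipped, susceptible centre.

    The mutated value is the base value advanced by the step (1 or 2,
    mod 3) of the lowest hitting centre, so it always differs from the
    base and is shared between isomers whose flip sets hit a target
    through the same centre.
    """
    values = base.copy()
    if not flips.any():
        return values
    hit = susceptible & flips[:, None]  # centers × targets
    hit_targets = np.flatnonzero(hit.any(axis=0))
    for t in hit_targets:
        k = int(np.flatnonzero(hit[:, t])[0])
        values[t] = (base[t] + step[k, t]) % 3
    return values


def _ensure_active(values: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Guarantee ≥1 nonzero entry without reverting any mutation to base."""
    if values.any():
        return values
    t = int(np.flatnonzero(base)[0])
    values = values.copy()
    values[t] = 3 - base[t]  # the non-base, nonzero alternative
    return values


def generate_library(config: SyntheticLibraryConfig) -> SyntheticLibrary:
    """Generate a deterministic stereoisomer library from a validated config.

    Raises ``ValueError`` on unsatisfiable configs (e.g. more isomers
    requested than 2^stereocenters allows).
    """
    config.validate()
    seed = config.seed

    molecules: list[MoleculeRecord] = []
    smiles_in: dict[str, str] = {}
    family_of: dict[str, int] = {}
    profile_rows: dict[str, np.ndarray] = {}
    signature_rows: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []
    seen_constitutions: set[str] = set()

    lo_s, hi_s = config.stereocenters_per_family
    lo_m, hi_m = config.isomers_per_family

    rng_undef = _child_rng(seed, 31)

    for f in range(config.n_families):
        rng = _child_rng(seed, 17, f)
        # feasible centre counts for the family (need 2^s >= lo_m isomers)
        s_min = max(lo_s, (lo_m - 1).bit_length())
        n_centers = int(rng.integers(s_min, hi_s + 1))
        drawn = _draw_scaffold(rng, n_centers, lo_m, seen_constitutions)
        if drawn is None:
            raise RuntimeError(
                f"could not construct a unique scaffold for family {f}; "
                "template pool exhausted for this config"
            )
        scaffold, pool = drawn
        seen_constitutions.add(pool[0][1].canonical_smiles_nostereo)

        n_isomers = int(rng.integers(lo_m, min(hi_m, len(pool)) + 1))
        order = rng.permutation(len(pool) - 1) + 1
        chosen = [pool[0]] + [pool[k] for k in order[: n_isomers - 1]]

        base_assignment = np.array(chosen[0][0])
        base_prof = _base_profile(rng, config)
        susceptible = rng.random((n_centers, config.n_targets)) < config.stereo_sensitivity
        step = rng.integers(1, 3, size=(n_centers, config.n_targets))
        base_vec = rng.standard_normal(config.signature_dim)

        fam_ids: list[str] = []
        fam_profiles: list[np.ndarray] = []
        for i, (assignment, rec) in enumerate(chosen):
            mol_id = f"M{f:04d}_{i}"
            flips = np.array(assignment) != base_assignment
            prof = _ensure_active(
                _isomer_profile(base_prof, flips, susceptible, step), base_prof
            )

            hamming = int(np.count_nonzero(prof != base_prof))
            if hamming:
                rng_dir = _child_rng(seed, 23, f, _profile_hash(prof))
                direction = rng_dir.standard_normal(config.signature_dim)
                direction /= np.linalg.norm(direction)
                offset = _OFFSET_SCALE * np.sqrt(hamming / config.n_targets) * direction
            else:
                offset = np.zeros(config.signature_dim)
            noise = _child_rng(seed, 29, f, i).standard_normal(config.signature_dim)
            signature = base_vec + offset + config.signature_noise_sd * noise

            smiles = scaffold.render(assignment)
            record = standardize_molecule(mol_id, smiles)
            if rng_undef.random() < config.undefined_fraction:
                erased = list(assignment)
                erased[int(rng_undef.integers(n_centers))] = None
                smiles = scaffold.render(tuple(erased))
                record = standardize_molecule(mol_id, smiles)

            molecules.append(record)
            smiles_in[mol_id] = smiles
            family_of[mol_id] = f
            profile_rows[mol_id] = prof
            signature_rows[mol_id] = signature
            fam_ids.append(mol_id)
            fam_profiles.append(prof)

        for x in range(len(fam_ids)):
            for y in range(x + 1, len(fam_ids)):
                truth_rows.append(
                    {
                        "id_a": fam_ids[x],
                        "id_b": fam_ids[y],
                        "family": f,
                        "same_family": True,
                        "profile_differs": bool(
                            (fam_profiles[x] != fam_profiles[y]).any()
                        ),
                        "pair_fully_defined": (
                            molecules[-len(fam_ids) + x].stereo_status == "fully_defined"
                            and molecules[-len(fam_ids) + y].stereo_status
                            == "fully_defined"
                        ),
                    }
                )

    target_cols = [f"T{t:03d}" for t in range(config.n_targets)]
    sig_cols = [f"S{d:03d}" for d in range(config.signature_dim)]
    ids = [m.id for m in molecules]
    profiles = pd.DataFrame(
        np.array([profile_rows[i] for i in ids], dtype=int).reshape(
            len(ids), config.n_targets
        ),
        index=pd.Index(ids, name="compound_id"),
        columns=target_cols,
    )
    signatures = pd.DataFrame(
        np.array([signature_rows[i] for i in ids], dtype=float).reshape(
            len(ids), config.signature_dim
        ),
        index=pd.Index(ids, name="compound_id"),
        columns=sig_cols,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "id_a",
            "id_b",
            "family",
            "same_family",
            "profile_differs",
            "pair_fully_defined",
        ],
    )
    family_labels = pd.Series(family_of, name="family", dtype=int)
    family_labels.index.name = "compound_id"
    return SyntheticLibrary(
        config=config,
        molecules=molecules,
        profiles=profiles,
        signatures=signatures,
        family_labels=family_labels,
        truth=truth,
        smiles_in=smiles_in,
    )
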