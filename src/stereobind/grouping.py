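"""Stereoisomer group identification.

Partitions a standardized library into groups of ≥2 exhaustively
characterised stereoisomers sharing one constitution.  Candidate groups
are found by bucketing on the InChIKey connectivity block; within a
bucket, members must additionally agree on the stereo-stripped canonical
SMILES (guarding against hash collisions), the InChIKey protonation
character and the formal charge, carry no isotope labels, and be fully
stereo-defined.  Everything removed is reported with a machine-readable
reason code so the filtering cascade is auditable.
"""

from __future__ import annotations

import hashlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .registry import MoleculeRecord

__all__ = [
    "StereoGroup",
    "GroupingResult",
    "identify_stereoisomer_groups",
    "group_size_histogram",
]

#: reason codes attached to excluded molecules
EXCLUSION_REASONS = (
    "duplicate",
    "partially_defined",
    "achiral_duplicate",
    "isotope",
    "charge_mismatch",
    "protonation_mismatch",
    "singleton",
)


@dataclass(frozen=True)
class StereoGroup:
    group_id: str
    connectivity_key: str
    member_ids: tuple[str, ...]
    excluded_ids: tuple[tuple[str, str], ...] = field(default=())

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class GroupingResult:
    groups: tuple[StereoGroup, ...]
    exclusions: tuple[tuple[str, str], ...]  # (molecule_id, reason)

    def excluded_as_dict(self) -> dict[str, str]:
        return dict(self.exclusions)


def _group_id(member_ids: tuple[str, ...]) -> str:
    digest = hashlib.sha1("|".join(member_ids).encode()).hexdigest()[:10]
    return f"SG_{digest}"


def identify_stereoisomer_groups(
    records: list[MoleculeRecord],
) -> GroupingResult:
    """Partition standardized records into stereoisomer groups.

    Records sharing a full InChIKey are collapsed to one (lexicographically
    smallest id) first — duplicates would otherwise fabricate stereoisomer
    pairs at distance zero.  Groups are permutation-invariant: member ids
    are sorted and the group id is derived from them.
    """
    exclusions: list[tuple[str, str]] = []

    # collapse exact duplicates (identical full InChIKey)
    by_key: dict[str, MoleculeRecord] = {}
    for rec in sorted(records, key=lambda r: r.id):
        kept = by_key.get(rec.inchikey)
        if kept is None:
            by_key[rec.inchikey] = rec
        else:
            exclusions.append((rec.id, "duplicate"))

    buckets: dict[str, list[MoleculeRecord]] = defaultdict(list)
    for rec in by_key.values():
        buckets[rec.connectivity_key].append(rec)

    groups: list[StereoGroup] = []
    for ckey in sorted(buckets):
        bucket = sorted(buckets[ckey], key=lambda r: r.id)
        bucket_exclusions: list[tuple[str, str]] = []

        candidates: list[MoleculeRecord] = []
        for rec in bucket:
            if rec.has_isotope:
                bucket_exclusions.append((rec.id, "isotope"))
            elif rec.stereo_status == "partially_defined":
                bucket_exclusions.append((rec.id, "partially_defined"))
            elif rec.stereo_status == "achiral":
                # an achiral structure cannot be a stereoisomer of anything;
                # in a populated bucket it is a registration variant
                reason = "achiral_duplicate" if len(bucket) > 1 else "singleton"
                bucket_exclusions.append((rec.id, reason))
            else:
                candidates.append(rec)

        # exclusivity filters: same constitution, protonation and charge
        subkeys: dict[tuple[str, str, int], list[MoleculeRecord]] = defaultdict(list)
        for rec in candidates:
            subkeys[
                (rec.canonical_smiles_nostereo, rec.protonation_char, rec.formal_charge)
            ].append(rec)

        modal_key = None
        if subkeys:
            modal_key = max(subkeys, key=lambda k: (len(subkeys[k]), k))

        for key in sorted(subkeys):
            members = subkeys[key]
            if len(members) >= 2:
                continue  # becomes a group below
            rec = members[0]
            if modal_key is not None and key != modal_key:
                if rec.formal_charge != modal_key[2]:
                    reason = "charge_mismatch"
                elif rec.protonation_char != modal_key[1]:
                    reason = "protonation_mismatch"
                else:
                    reason = "singleton"
            else:
                reason = "singleton"
            bucket_exclusions.append((rec.id, reason))

        for key in sorted(subkeys):
            members = subkeys[key]
            if len(members) < 2:
                continue
            member_ids = tuple(sorted(r.id for r in members))
            groups.append(
                StereoGroup(
                    group_id=_group_id(member_ids),
                    connectivity_key=ckey,
                    member_ids=member_ids,
                    excluded_ids=tuple(sorted(bucket_exclusions)),
                )
            )
        exclusions.extend(bucket_exclusions)

    return GroupingResult(
        groups=tuple(sorted(groups, key=lambda g: g.member_ids)),
        exclusions=tuple(sorted(exclusions)),
    )


def group_size_histogram(groups: list[StereoGroup] | tuple[StereoGroup, ...]) -> dict[int, int]:
    """Count groups by number of members; counts sum to ``len(groups)``."""
    return dict(sorted(Counter(g.n_members for g in groups).items()))
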