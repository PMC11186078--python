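"""Within-group bioactivity divergence analysis.

Binding profiles are ternary vectors over a shared target list
(0 no binding, 1 weak, 2 strong).  Distinctness of profiles inside a
stereoisomer group is judged on the full ternary vectors — a weak-vs-strong
difference at one target makes two profiles distinct — while Jaccard
distances are computed on the binarized bound-target sets (value ≥ 1).
Binarization can merge profiles but never split them, so the fraction of
pairs at Jaccard > 0 is a lower bound on the fraction with distinct
ternary profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grouping import StereoGroup

__all__ = [
    "BindingProfile",
    "PairDistanceRecord",
    "jaccard_distance",
    "count_distinct_profiles",
    "distinct_profile_breakdown",
    "pair_category_distances",
    "compare_distributions",
]

log = logging.getLogger(__name__)

PAIR_CATEGORIES = ("share0", "share_ge1", "stereoisomer")


@dataclass(frozen=True)
class BindingProfile:
    """Ternary per-target activity vector for one compound."""

    compound_id: str
    targets: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.targets),):
            raise ValueError("values must align with the target list")
        if not np.isin(v, (0, 1, 2)).all():
            raise ValueError("profile entries must be in {0, 1, 2}")


@dataclass(frozen=True)
class PairDistanceRecord:
    id_a: str
    id_b: str
    category: str
    jaccard: float


def _validate_ternary(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=int)
    if not np.isin(v, (0, 1, 2)).all():
        raise ValueError("profile entries must be in {0, 1, 2}")
    return v


def jaccard_distance(p, q) -> float:
    """Jaccard distance between the bound-target sets of two profiles.

    Profiles are binarized (value ≥ 1 means bound); the distance is
    1 − |A∩B| / |A∪B|.  When both bound sets are empty the distance is 0
    by convention; callers building distributions should exclude such
    pairs (see :func:`pair_category_distances`).
    """
    pa = p.values if isinstance(p, BindingProfile) else p
    qa = q.values if isinstance(q, BindingProfile) else q
    if isinstance(p, BindingProfile) and isinstance(q, BindingProfile):
        if p.targets != q.targets:
            raise ValueError("profiles are over different target lists")
    va = _validate_ternary(pa)
    vb = _validate_ternary(qa)
    if va.shape != vb.shape:
        raise ValueError("profiles are over different target lists")
    a = va >= 1
    b = vb >= 1
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    inter = int(np.count_nonzero(a & b))
    return 1.0 - inter / union


def count_distinct_profiles(group: StereoGroup, profiles: pd.DataFrame) -> int:
    """Number of unique full ternary profiles among a group's members.

    Exact vector equality over all targets — no binarization.  The result
    lies in [1, n_members].
    """
    missing = [m for m in group.member_ids if m not in profiles.index]
    if missing:
        raise KeyError(
            f"group {group.group_id}: no binding profile for member(s) {missing}"
        )
    sub = profiles.loc[list(group.member_ids)].to_numpy()
    return int(np.unique(sub, axis=0).shape[0])


def distinct_profile_breakdown(
    groups, profiles: pd.DataFrame
) -> dict[int, dict[int, float]]:
    """Per group size, the distribution over distinct-profile counts.

    Returns ``{size: {n_distinct: proportion}}``; proportions within each
    size sum to 1.
    """
    counts: dict[int, dict[int, int]] = {}
    for g in groups:
        k = count_distinct_profiles(g, profiles)
        counts.setdefault(g.n_members, {}).setdefault(k, 0)
        counts[g.n_members][k] += 1
    out: dict[int, dict[int, float]] = {}
    for size in sorted(counts):
        total = sum(counts[size].values())
        out[size] = {k: c / total for k, c in sorted(counts[size].items())}
    return out


def _sample_random_pairs(n_compounds: int, n_wanted: int, forbidden: set, rng):
    """Uniform unordered index pairs, without replacement, avoiding `forbidden`."""
    total = n_compounds * (n_compounds - 1) // 2
    if total <= 2_000_000:
        ii, jj = np.triu_indices(n_compounds, k=1)
        order = rng.permutation(total)
        for k in order:
            pair = (int(ii[k]), int(jj[k]))
            if pair not in forbidden:
                yield pair
        return
    seen: set = set()
    draws = 0
    while len(seen) < n_wanted and draws < 50 * n_wanted:
        i, j = rng.integers(0, n_compounds, size=2)
        draws += 1
        if i == j:
            continue
        pair = (int(min(i, j)), int(max(i, j)))
        if pair in forbidden or pair in seen:
            continue
        seen.add(pair)
        yield pair


def pair_category_distances(
    groups,
    profiles: pd.DataFrame,
    n_random_pairs: int = 100_000,
    seed: int = 0,
) -> list[PairDistanceRecord]:
    """Jaccard distances for stereoisomer, share≥1 and share-0 pairs.

    Stereoisomer pairs are enumerated exhaustively within groups; the two
    random categories are sampled uniformly without replacement from
    non-stereoisomer pairs, up to ``n_random_pairs`` each (all available
    pairs, with a logged warning, if fewer exist).  Pairs whose bound sets
    are both empty are excluded.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng([int(seed), 0x5AFE])
    ids = list(profiles.index)
    pos = {cid: k for k, cid in enumerate(ids)}
    mat = profiles.to_numpy()
    bound = mat >= 1

    records: list[PairDistanceRecord] = []
    stereo_pairs: set[tuple[int, int]] = set()
    for g in groups:
        members = [m for m in g.member_ids if m in pos]
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                i, j = pos[members[x]], pos[members[y]]
                pair = (min(i, j), max(i, j))
                stereo_pairs.add(pair)
                d = jaccard_distance(mat[i], mat[j])
                if not bound[i].any() and not bound[j].any():
                    continue
                records.append(
                    PairDistanceRecord(ids[pair[0]], ids[pair[1]], "stereoisomer", d)
                )

    quota = {"share0": n_random_pairs, "share_ge1": n_random_pairs}
    for i, j in _sample_random_pairs(len(ids), 2 * n_random_pairs, stereo_pairs, rng):
        if not quota["share0"] and not quota["share_ge1"]:
            break
        if not bound[i].any() and not bound[j].any():
            continue
        shared = int(np.count_nonzero(bound[i] & bound[j]))
        cat = "share_ge1" if shared >= 1 else "share0"
        if quota[cat]:
            quota[cat] -= 1
            records.append(
                PairDistanceRecord(ids[i], ids[j], cat, jaccard_distance(mat[i], mat[j]))
            )
    for cat, left in quota.items():
        if left:
            log.warning(
                "pair_category_distances: only %d %s pairs available "
                "(requested %d)", n_random_pairs - left, cat, n_random_pairs
            )
    return records


def compare_distributions(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test (tie-corrected) between two samples.

    Returns ``(U, p_value)`` with U computed for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
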