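"""kNN-recapitulation benchmark.

Measures how well a candidate descriptor recovers the nearest-neighbor
structure of a reference bioactivity space.  Nearest neighbors are
defined globally: a pair is positive when its reference-space distance
falls below the empirical quantile at a small percentile of the overall
distance distribution (0.001 percentile → tail mass 10⁻⁵; 0.1 → 10⁻³).
Negatives are drawn either uniformly from the remaining pairs (easy) or
from a near-miss band just above the cutoff (stringent).  The score is
AUROC over candidate-descriptor distances, smaller distance ranking a
pair as predicted-positive, averaged over seeded subsampled repetitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvalConfig",
    "DistanceSpace",
    "KNNBenchmarkResult",
    "nn_cutoff",
    "build_eval_pairs",
    "recapitulation_auroc",
    "identical_signature_fraction",
]

log = logging.getLogger(__name__)

_MAX_CUTOFF_SAMPLE = 1_000_000


@dataclass(frozen=True)
class EvalConfig:
    """Benchmark settings.

    ``nn_percentile`` is in percent units: 0.001 defines neighbors at tail
    mass 10⁻⁵ (continuous-signature style), 0.1 at 10⁻³ (ternary-profile
    style).  ``stringent_band_multiplier`` bounds the near-miss band
    (cutoff, multiplier × cutoff] used for stringent negatives.
    """

    nn_percentile: float = 0.1
    negative_mode: str = "random"
    stringent_band_multiplier: float = 10.0
    n_subsample: int = 2500
    n_repetitions: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.nn_percentile < 100.0:
            raise ValueError("nn_percentile must be in (0, 100)")
        if self.negative_mode not in ("random", "stringent"):
            raise ValueError("negative_mode must be 'random' or 'stringent'")
        if self.stringent_band_multiplier <= 1.0:
            raise ValueError("stringent_band_multiplier must be > 1")
        if self.n_subsample < 2 or self.n_repetitions < 1:
            raise ValueError("n_subsample >= 2 and n_repetitions >= 1 required")


class DistanceSpace:
    """Pairwise cosine distances over a compound × feature matrix."""

    def __init__(self, ids: list[str], values: np.ndarray, metric: str = "cosine"):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != len(ids):
            raise ValueError("values must be (n_compounds, n_features)")
        self.ids = list(ids)
        self.values = values
        self.metric = metric
        self._pos = {cid: k for k, cid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def pairwise(self, indices: np.ndarray) -> np.ndarray:
        """Square distance matrix among a subset of compounds."""
        return squareform(pdist(self.values[indices], metric=self.metric))

    def pair_distances(self, id_pairs: list[tuple[str, str]]) -> np.ndarray:
        missing = [
            cid for pair in id_pairs for cid in pair if cid not in self._pos
        ]
        if missing:
            raise KeyError(f"no descriptor for compound(s): {sorted(set(missing))[:5]}")
        ii = np.array([self._pos[a] for a, _ in id_pairs])
        jj = np.array([self._pos[b] for _, b in id_pairs])
        a = self.values[ii]
        b = self.values[jj]
        if self.metric != "cosine":
            raise NotImplementedError(self.metric)
        num = (a * b).sum(axis=1)
        den = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        return 1.0 - num / den

    def sample_distances(self, n_pairs: int, seed: int) -> np.ndarray:
        """Reference distance distribution from random pairs (all pairs if few)."""
        n = len(self)
        total = n * (n - 1) // 2
        if total <= n_pairs:
            return pdist(self.values, metric=self.metric)
        rng = np.random.default_rng([int(seed), 0xD157])
        ii = rng.integers(0, n, size=n_pairs)
        jj = rng.integers(0, n - 1, size=n_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)
        a = self.values[ii]
        b = self.values[jj]
        num = (a * b).sum(axis=1)
        den = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        return 1.0 - num / den


@dataclass
class LabeledPairSet:
    """Positive/negative pair inventory for one benchmark run."""

    cutoff: float
    repetitions: list[dict] = field(default_factory=list)
    # each repetition: {"pairs": [(id_a, id_b)], "labels": np.ndarray}


@dataclass(frozen=True)
class KNNBenchmarkResult:
    descriptor_kind: str
    per_repetition_auroc: tuple[float, ...]
    mean_auroc: float
    n_positive_pairs: int
    n_negative_pairs: int
    cutoff_distance: float


def nn_cutoff(distances: np.ndarray, percentile: float) -> float:
    """Empirical quantile of a distance sample at ``percentile`` (percent).

    Linear interpolation; the fraction of the sample strictly below the
    cutoff approximates ``percentile / 100``.  Warns when the sample is too
    small to resolve the requested tail.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance sample")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    if d.size < 100.0 / percentile:
        warnings.warn(
            f"sample of {d.size} distances is small for the {percentile} "
            "percentile; cutoff estimate will be coarse",
            stacklevel=2,
        )
    return float(np.quantile(d, percentile / 100.0))


def build_eval_pairs(space: DistanceSpace, cfg: EvalConfig) -> LabeledPairSet:
    """Assemble balanced positive/negative pairs from a reference space.

    Per repetition a seeded subsample of compounds is drawn; positives are
    pairs with reference distance strictly below the global cutoff,
    negatives come either from the remaining pairs (random mode) or from
    the near-miss band (stringent mode).  Classes are balanced by
    downsampling the larger one.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    if len(space) < cfg.n_subsample:
        raise ValueError(
            f"reference space has {len(space)} compounds < n_subsample={cfg.n_subsample}"
        )
    ref_sample = space.sample_distances(_MAX_CUTOFF_SAMPLE, cfg.seed)
    cutoff = nn_cutoff(ref_sample, cfg.nn_percentile)

    out = LabeledPairSet(cutoff=cutoff)
    n = len(space)
    for rep in range(cfg.n_repetitions):
        rng = np.random.default_rng([int(cfg.seed), 7, rep])
        subset = np.sort(rng.choice(n, size=cfg.n_subsample, replace=False))
        dmat = space.pairwise(subset)
        iu = np.triu_indices(cfg.n_subsample, k=1)
        dists = dmat[iu]

        pos_mask = dists < cutoff
        if cfg.negative_mode == "random":
            neg_mask = ~pos_mask
        else:
            neg_mask = (dists > cutoff) & (
                dists <= cfg.stringent_band_multiplier * cutoff
            )
        n_pos = int(pos_mask.sum())
        n_neg = int(neg_mask.sum())
        if n_pos == 0 or n_neg == 0:
            log.warning(
                "repetition %d skipped: %d positives, %d negatives", rep, n_pos, n_neg
            )
            continue
        m = min(n_pos, n_neg)
        pos_idx = np.flatnonzero(pos_mask)
        neg_idx = np.flatnonzero(neg_mask)
        if n_pos > m:
            pos_idx = rng.choice(pos_idx, size=m, replace=False)
        if n_neg > m:
            neg_idx = rng.choice(neg_idx, size=m, replace=False)

        labels = np.concatenate([np.ones(len(pos_idx), int), np.zeros(len(neg_idx), int)])
        pairs = [
            (space.ids[subset[int(iu[0][k])]], space.ids[subset[int(iu[1][k])]])
            for k in np.concatenate([pos_idx, neg_idx])
        ]
        out.repetitions.append({"pairs": pairs, "labels": labels})
    if not out.repetitions:
        raise ValueError("no repetition produced both positives and negatives")
    return out


def recapitulation_auroc(
    pair_set: LabeledPairSet, candidate: DistanceSpace, descriptor_kind: str = ""
) -> KNNBenchmarkResult:
    """AUROC of candidate-descriptor distances against reference NN labels.

    Smaller candidate distance ⇒ predicted positive; rank-based with
    midrank tie handling, per repetition, then averaged.
    """
    aurocs = []
    n_pos = 0
    n_neg = 0
    for rep in pair_set.repetitions:
        d = candidate.pair_distances(rep["pairs"])
        labels = rep["labels"]
        aurocs.append(float(roc_auc_score(labels, -d)))
        n_pos += int(labels.sum())
        n_neg += int((1 - labels).sum())
    return KNNBenchmarkResult(
        descriptor_kind=descriptor_kind or candidate.metric,
        per_repetition_auroc=tuple(aurocs),
        mean_auroc=float(np.mean(aurocs)),
        n_positive_pairs=n_pos,
        n_negative_pairs=n_neg,
        cutoff_distance=pair_set.cutoff,
    )


def identical_signature_fraction(
    pairs: list[tuple[str, str]], space: DistanceSpace, tol: float = 1e-6
) -> float:
    """Fraction of compound pairs with cosine distance below ``tol``.

    An empty pair list yields 0 with a warning.
    """
    if not pairs:
        warnings.warn("identical_signature_fraction: empty pair list", stacklevel=2)
        return 0.0
    d = space.pair_distances(pairs)
    return float(np.mean(d < tol))
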