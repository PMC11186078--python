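"""End-to-end experiment orchestration.

Runs the full analysis in dependency order — generate (or load) a
library, standardize, group stereoisomers, analyse binding-profile
divergence, embed conformers, compute descriptors, and benchmark kNN
recapitulation — writing each stage's artifacts plus a machine-readable
``report.json``.  Reruns with the same config and seed reproduce all
non-timing outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sbio
from .conformers import generate_conformer
from .descriptors import descriptor_3d, fingerprint_2d
from .evaluation import (
    DistanceSpace,
    EvalConfig,
    build_eval_pairs,
    identical_signature_fraction,
    recapitulation_auroc,
)
from .grouping import group_size_histogram, identify_stereoisomer_groups
from .profiles import (
    compare_distributions,
    distinct_profile_breakdown,
    pair_category_distances,
)
from .registry import standardize_molecule
from .synthetic import SyntheticLibrary, SyntheticLibraryConfig, generate_library

__all__ = ["RunConfig", "run_pipeline", "summarize_counts", "percent"]

log = logging.getLogger(__name__)

STAGES = (
    "generate",
    "standardize",
    "group",
    "profiles",
    "conformers",
    "descriptors",
    "benchmark",
)

_DEPENDENCIES = {
    "group": ("standardize",),
    "profiles": ("group",),
    "conformers": ("standardize",),
    "descriptors": ("conformers",),
    "benchmark": ("descriptors", "group"),
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    stages: tuple[str, ...] = STAGES
    out_dir: Path = Path("stereobind_run")
    library: SyntheticLibraryConfig = field(default_factory=SyntheticLibraryConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0
    n_random_pairs: int = 100_000
    smi_path: Path | None = None  # user library instead of the generator
    profiles_path: Path | None = None
    signatures_path: Path | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        enabled = set(self.stages)
        for stage, deps in _DEPENDENCIES.items():
            if stage in enabled:
                missing = [d for d in deps if d not in enabled]
                # "standardize" is implied by "generate"
                missing = [
                    d
                    for d in missing
                    if not (d == "standardize" and "generate" in enabled)
                ]
                if missing:
                    raise ValueError(
                        f"stage {stage!r} requires {missing} to be enabled"
                    )


def percent(numerator: int, denominator: int, decimals: int = 1) -> float | None:
    """Percentage rounded to ``decimals``; ``None`` when the denominator is 0."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, decimals) if decimals else round(
        100.0 * numerator / denominator
    )


def summarize_counts(groups, profiles: pd.DataFrame, truth: pd.DataFrame | None = None) -> dict:
    """Headline counts of the grouping + profile stages.

    Percentages follow the reporting conventions of the analysis: pair
    percentages to one decimal, group-size percentages to the nearest
    integer; all percentages are ``None`` (not 0) when undefined.
    """
    from .profiles import count_distinct_profiles

    n_groups = len(groups)
    n_compounds = sum(g.n_members for g in groups)
    hist = group_size_histogram(groups)
    n_pairs = sum(g.n_members * (g.n_members - 1) // 2 for g in groups)

    n_groups_ge2_distinct = 0
    n_pairs_distinct = 0
    for g in groups:
        sub = profiles.loc[list(g.member_ids)].to_numpy()
        if count_distinct_profiles(g, profiles) >= 2:
            n_groups_ge2_distinct += 1
        for x in range(len(sub)):
            for y in range(x + 1, len(sub)):
                if (sub[x] != sub[y]).any():
                    n_pairs_distinct += 1

    return {
        "n_compounds_in_groups": n_compounds,
        "n_groups": n_groups,
        "n_groups_with_ge2_distinct_profiles": n_groups_ge2_distinct,
        "n_stereoisomer_pairs": n_pairs,
        "n_pairs_distinct": n_pairs_distinct,
        "pct_pairs_distinct": percent(n_pairs_distinct, n_pairs, 1),
        "pct_groups_size2": percent(hist.get(2, 0), n_groups, 0),
        "group_size_histogram": hist,
    }


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.monotonic()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            report.setdefault("stages", {})[name] = report.get("_staging", {}).pop(
                name, {}
            ) | {"wall_time_s": round(time.monotonic() - self.t0, 3)}
            log.info("stage %s: done", name)

    return _Ctx()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order and write ``report.json``."""
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}, "_staging": {}}
    enabled = [s for s in STAGES if s in cfg.stages]

    lib: SyntheticLibrary | None = None
    records = None
    groups = None
    profiles = None
    signatures = None
    conformers = None
    spaces: dict[str, DistanceSpace] = {}

    for name in enabled:
        with _stage(report, name):
            info: dict = {}
            if name == "generate":
                lib = generate_library(
                    dataclasses.replace(cfg.library, seed=cfg.seed)
                )
                sbio.write_library(lib, out / "library")
                records = lib.molecules
                profiles = lib.profiles
                signatures = lib.signatures
                info = {
                    "n_molecules": len(lib.molecules),
                    "n_families": int(lib.family_labels.nunique()),
                }
            elif name == "standardize":
                if records is None:
                    if cfg.smi_path is None:
                        raise ValueError("no generated library and no smi_path given")
                    entries = sbio.read_smi(cfg.smi_path)
                    records = [standardize_molecule(mid, smi) for smi, mid in entries]
                if profiles is None and cfg.profiles_path is not None:
                    profiles = sbio.read_profiles_tsv(cfg.profiles_path)
                if signatures is None and cfg.signatures_path is not None:
                    signatures = sbio.read_signatures(cfg.signatures_path)
                sbio.write_records_csv(out / "registry.csv", records)
                info = {"n_records": len(records)}
            elif name == "group":
                result = identify_stereoisomer_groups(records)
                groups = result.groups
                sbio.write_groups_tsv(out, result)
                info = {
                    "n_groups": len(groups),
                    "n_excluded": len(result.exclusions),
                    "size_histogram": group_size_histogram(groups),
                }
            elif name == "profiles":
                if profiles is None:
                    raise ValueError("no binding profiles available")
                breakdown = distinct_profile_breakdown(groups, profiles)
                pair_records = pair_category_distances(
                    groups, profiles, n_random_pairs=cfg.n_random_pairs, seed=cfg.seed
                )
                by_cat: dict[str, list[float]] = {}
                for r in pair_records:
                    by_cat.setdefault(r.category, []).append(r.jaccard)
                summary = {}
                for cat, vals in sorted(by_cat.items()):
                    summary[cat] = {
                        "n": len(vals),
                        "mean": float(np.mean(vals)),
                        "median": float(np.median(vals)),
                    }
                pvals = {}
                cats = sorted(by_cat)
                for i in range(len(cats)):
                    for j in range(i + 1, len(cats)):
                        if by_cat[cats[i]] and by_cat[cats[j]]:
                            _, p = compare_distributions(
                                by_cat[cats[i]], by_cat[cats[j]]
                            )
                            pvals[f"{cats[i]}_vs_{cats[j]}"] = p
                counts = summarize_counts(groups, profiles)
                pd.DataFrame([r.__dict__ for r in pair_records]).to_csv(
                    out / "pair_distances.tsv", sep="\t", index=False
                )
                payload = {
                    "breakdown_by_group_size": {
                        str(k): {str(a): b for a, b in v.items()}
                        for k, v in breakdown.items()
                    },
                    "category_summary": summary,
                    "mannwhitney_p": pvals,
                    "counts": counts,
                }
                (out / "profile_summary.json").write_text(
                    json.dumps(payload, indent=2, sort_keys=True)
                )
                info = payload
            elif name == "conformers":
                grouped_ids = (
                    {m for g in groups for m in g.member_ids} if groups else None
                )
                conformers = []
                for rec in records:
                    if rec.stereo_status == "partially_defined":
                        continue
                    if grouped_ids is not None and rec.id not in grouped_ids:
                        continue
                    conformers.append(generate_conformer(rec, embed_seed=cfg.seed))
                sbio.write_conformers_sdf(
                    out / "conformers.sdf",
                    conformers,
                    {r.id: r.canonical_smiles for r in records},
                )
                info = {"n_conformers": len(conformers)}
            elif name == "descriptors":
                recs_by_id = {r.id: r for r in records}
                ids = [c.molecule_id for c in conformers]
                fp = np.stack(
                    [fingerprint_2d(recs_by_id[i]).values for i in ids]
                )
                geo = np.stack([descriptor_3d(c).values for c in conformers])
                spaces["fp2d"] = DistanceSpace(ids, fp)
                spaces["geo3d"] = DistanceSpace(ids, geo)
                sbio.write_signatures(
                    out / "descriptors_geo3d.csv",
                    pd.DataFrame(geo, index=pd.Index(ids, name="compound_id")),
                )
                info = {"n_described": len(ids), "kinds": ["fp2d", "geo3d"]}
            elif name == "benchmark":
                if signatures is None:
                    raise ValueError("benchmark requires a signature matrix")
                common = [i for i in spaces["fp2d"].ids if i in signatures.index]
                ref = DistanceSpace(common, signatures.loc[common].to_numpy())
                cand = {
                    "signature": ref,
                    "fp2d": DistanceSpace(
                        common,
                        spaces["fp2d"].values[
                            [spaces["fp2d"].ids.index(i) for i in common]
                        ],
                    ),
                    "geo3d": DistanceSpace(
                        common,
                        spaces["geo3d"].values[
                            [spaces["geo3d"].ids.index(i) for i in common]
                        ],
                    ),
                }
                stereo_pairs = [
                    (a, b)
                    for g in groups
                    for x, a in enumerate(g.member_ids)
                    for b in g.member_ids[x + 1 :]
                    if a in set(common) and b in set(common)
                ]
                bench: dict = {
                    "identical_fraction": {
                        kind: identical_signature_fraction(stereo_pairs, s)
                        for kind, s in cand.items()
                    },
                    "modes": {},
                }
                n_sub = min(cfg.eval.n_subsample, len(common))
                for mode in ("random", "stringent"):
                    ecfg = dataclasses.replace(
                        cfg.eval,
                        negative_mode=mode,
                        n_subsample=n_sub,
                        seed=cfg.seed,
                    )
                    pair_set = build_eval_pairs(ref, ecfg)
                    bench["modes"][mode] = {
                        kind: dataclasses.asdict(
                            recapitulation_auroc(pair_set, s, kind)
                        )
                        for kind, s in cand.items()
                    }
                (out / "benchmark.json").write_text(
                    json.dumps(bench, indent=2, sort_keys=True)
                )
                info = bench
            report["_staging"][name] = info

    report.pop("_staging", None)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
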