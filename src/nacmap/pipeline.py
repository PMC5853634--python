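"""End-to-end orchestration: cohort -> per-subject maps -> group comparisons.

Per subject: motion QC drops runs that breach the exclusion limits; retained
runs are temporally cleaned, converted to corrected-Z connectivity matrices,
averaged, binarized at the configured Z threshold(s), and reduced to a
centrality map (nAC0, nAC1, GC).  Subjects with no retained runs are dropped
with a logged roster.  Group comparisons (gender, digit-ratio median splits
within group, menstrual phase within females or within a digit-ratio
subgroup) then run chi-square homogeneity and the label permutation test on
the per-subject maps.

Everything is deterministic given the configured seed.  Per-subject maps are
cached on disk keyed by a content hash of the stage inputs, so re-runs with
unchanged inputs reload instead of recomputing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import CentralityMap, centrality_map
from .classification import (
    classification_thresholds,
    classify,
    group_mean_map,
    regional_distribution,
    NODE_TYPES,
)
from .connectivity import Z_THRESHOLDS, adjacency, average_z, z_matrix
from .inference import (
    GroupComparison,
    chi_square_homogeneity,
    median_split,
    menstrual_phase,
    permutation_region_test,
)
from .preprocess import PreprocessSpec, preprocess_run, session_exclusion
from .synthetic import Cohort, SubjectRecord, SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "subject_map", "run_pipeline"]

logger = logging.getLogger("nacmap")


@dataclass
class PipelineConfig:
    """What to run and how."""

    synthetic: SyntheticConfig | None = None
    data_dir: str | None = None
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    z_thresholds: tuple[float, ...] = (2.58,)
    comparisons: tuple[str, ...] = ("gender",)
    n_perm: int = 10_000
    seed: int = 0
    output_dir: str | None = None
    permutation_direction: str = "greater"

    def __post_init__(self) -> None:
        if self.synthetic is None and self.data_dir is None:
            raise ValueError("either a synthetic config or a data directory is required")
        if isinstance(self.z_thresholds, (int, float)):
            self.z_thresholds = (float(self.z_thresholds),)
        known = {"gender", "digit_ratio:male", "digit_ratio:female",
                 "menstrual", "menstrual:low", "menstrual:high"}
        bad = [c for c in self.comparisons if c not in known]
        if bad:
            raise ValueError(f"unknown comparisons {bad}; choose from {sorted(known)}")


@dataclass
class PipelineResult:
    subject_ids: list[str]
    dropped_subjects: list[str]
    maps: dict[float, list[CentralityMap]]  # z threshold -> per-subject maps
    edge_counts: dict[float, list[int]]
    comparisons: dict[float, list[GroupComparison]]
    cohort: Cohort
    config: PipelineConfig


def _subject_fingerprint(subject: SubjectRecord, spec: PreprocessSpec, zt: float) -> str:
    h = hashlib.sha256()
    for run, mot, noise in zip(subject.runs, subject.motion, subject.noise_runs):
        h.update(np.ascontiguousarray(run.data).tobytes())
        h.update(np.ascontiguousarray(mot.params).tobytes())
        h.update(np.ascontiguousarray(noise).tobytes())
        h.update(np.float64(run.tr_seconds).tobytes())
    h.update(json.dumps(asdict(spec), sort_keys=True).encode())
    h.update(np.float64(zt).tobytes())
    return h.hexdigest()


def subject_map(
    subject: SubjectRecord,
    spec: PreprocessSpec,
    z_threshold: float,
    cache_dir: Path | None = None,
) -> tuple[CentralityMap | None, int]:
    """Preprocess -> Z -> adjacency -> centrality for one subject.

    Returns ``(map, edge_count)``; the map is ``None`` when every run is
    motion-excluded.
    """
    key = None
    if cache_dir is not None:
        key = _subject_fingerprint(subject, spec, z_threshold)
        cached = cache_dir / f"{key}.npz"
        if cached.exists():
            data = np.load(cached)
            return (
                CentralityMap(nac0=data["nac0"], nac1=data["nac1"]),
                int(data["edge_count"]),
            )
    z_runs = []
    for run, mot, noise in zip(subject.runs, subject.motion, subject.noise_runs):
        if session_exclusion(mot, spec):
            logger.info("run excluded by motion QC (%s)", subject.subject_id)
            continue
        cleaned = preprocess_run(
            run.data, mot, noise if noise.size else None, run.tr_seconds, spec
        )
        z_runs.append(z_matrix(cleaned))
    if not z_runs:
        return None, 0
    adj = adjacency(average_z(z_runs), z_threshold)
    cmap = centrality_map(adj)
    if cache_dir is not None and key is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        np.savez(
            cache_dir / f"{key}.npz",
            nac0=cmap.nac0,
            nac1=cmap.nac1,
            edge_count=adj.edge_count,
        )
    return cmap, adj.edge_count


def _comparison_split(
    name: str, subjects: list[SubjectRecord]
) -> tuple[list[int], np.ndarray, str] | None:
    """Subject indices and two-level labels for a named comparison."""
    if name == "gender":
        labels = np.array([s.group_label for s in subjects])
        uniq = list(dict.fromkeys(labels.tolist()))
        if len(uniq) != 2:
            return None
        return list(range(len(subjects))), labels, "gender"
    if name.startswith("digit_ratio:"):
        group = name.split(":", 1)[1]
        idx = [i for i, s in enumerate(subjects) if s.group_label == group]
        if len(idx) < 4:
            return None
        low, high = median_split([subjects[i].digit_ratio for i in idx])
        labels = np.empty(len(idx), dtype=object)
        labels[low] = "low"
        labels[high] = "high"
        return idx, labels.astype(str), name
    if name.startswith("menstrual"):
        idx = [
            i
            for i, s in enumerate(subjects)
            if s.days_since_menses is not None
            and menstrual_phase(s.days_since_menses) != "unknown"
        ]
        if ":" in name:  # restrict to a digit-ratio subgroup first
            which = name.split(":", 1)[1]
            if idx:
                low, high = median_split([subjects[i].digit_ratio for i in idx])
                chosen = low if which == "low" else high
                idx = [idx[j] for j in chosen]
        if len(idx) < 4:
            return None
        labels = np.array(
            [menstrual_phase(subjects[i].days_since_menses) for i in idx]
        )
        if len(set(labels.tolist())) != 2:
            return None
        return idx, labels, name
    raise ValueError(f"unknown comparison {name!r}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    if config.data_dir is not None:
        from .synthetic import read_cohort

        cohort = read_cohort(config.data_dir)
    else:
        cohort = generate_cohort(config.synthetic)

    out = Path(config.output_dir) if config.output_dir else None
    cache_dir = out / "cache" if out else None

    subject_ids: list[str] = []
    dropped: list[str] = []
    maps: dict[float, list[CentralityMap]] = {zt: [] for zt in config.z_thresholds}
    edges: dict[float, list[int]] = {zt: [] for zt in config.z_thresholds}
    kept_subjects: list[SubjectRecord] = []
    for subject in cohort.subjects:
        per_threshold = {}
        for zt in config.z_thresholds:
            cmap, n_edges = subject_map(subject, config.preprocess, zt, cache_dir)
            per_threshold[zt] = (cmap, n_edges)
        if any(v[0] is None for v in per_threshold.values()):
            dropped.append(subject.subject_id)
            logger.warning("subject %s dropped: all runs motion-excluded", subject.subject_id)
            continue
        subject_ids.append(subject.subject_id)
        kept_subjects.append(subject)
        for zt, (cmap, n_edges) in per_threshold.items():
            maps[zt].append(cmap)
            edges[zt].append(n_edges)

    rng = np.random.default_rng(config.seed)
    comparisons: dict[float, list[GroupComparison]] = {zt: [] for zt in config.z_thresholds}
    for zt in config.z_thresholds:
        for name in config.comparisons:
            split = _comparison_split(name, kept_subjects)
            if split is None:
                logger.warning("comparison %r skipped: no valid two-group split", name)
                continue
            idx, labels, label = split
            sel_maps = [maps[zt][i] for i in idx]
            uniq = list(dict.fromkeys(labels.tolist()))
            mean_a = group_mean_map([m for m, l in zip(sel_maps, labels) if l == uniq[0]])
            mean_b = group_mean_map([m for m, l in zip(sel_maps, labels) if l == uniq[1]])
            thr0, thrg = classification_thresholds(mean_a, mean_b)
            dist_a = regional_distribution(classify(mean_a, thr0, thrg), cohort.atlas)
            dist_b = regional_distribution(classify(mean_b, thr0, thrg), cohort.atlas)
            chi_rows = []
            for t in NODE_TYPES:
                stat, df, p_raw, p_corr = chi_square_homogeneity(dist_a, dist_b, t)
                chi_rows.append(
                    {"node_type": t, "statistic": stat, "df": df,
                     "p_raw": p_raw, "p_corrected": p_corr}
                )
            perm_seed = int(rng.integers(2**31 - 1))
            perm = permutation_region_test(
                sel_maps,
                labels,
                cohort.atlas,
                n_perm=config.n_perm,
                seed=perm_seed,
                direction=config.permutation_direction,
            )
            comparisons[zt].append(
                GroupComparison(
                    label=f"{label}@Z>{zt}",
                    chi_square=pd.DataFrame(chi_rows),
                    permutation=perm,
                    n_perm=config.n_perm,
                    seed=perm_seed,
                    extra={
                        "groups": uniq,
                        "thr_nac0": thr0,
                        "thr_gc": thrg,
                        "dist_group1": dist_a.to_tidy(),
                        "dist_group2": dist_b.to_tidy(),
                    },
                )
            )

    result = PipelineResult(
        subject_ids=subject_ids,
        dropped_subjects=dropped,
        maps=maps,
        edge_counts=edges,
        comparisons=comparisons,
        cohort=cohort,
        config=config,
    )
    if out is not None:
        _write_report(result, out)
    return result


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def _write_report(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    run_log = {
        "nacmap_version": __version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "z_thresholds": list(cfg.z_thresholds),
        "preprocess_variant": cfg.preprocess.variant,
        "subjects": result.subject_ids,
        "dropped_subjects": result.dropped_subjects,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    for zt in cfg.z_thresholds:
        zdir = out / f"z_{zt}"
        zdir.mkdir(exist_ok=True)
        for sid, cmap in zip(result.subject_ids, result.maps[zt]):
            cmap.to_frame().to_csv(zdir / f"{sid}_centrality.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"subject_id": result.subject_ids, "edge_count": result.edge_counts[zt]}
        ).to_csv(zdir / "edge_counts.tsv", sep="\t", index=False)
        for comp in result.comparisons[zt]:
            safe = comp.label.replace(":", "_").replace(">", "").replace("@", "_")
            comp.chi_square.to_csv(zdir / f"{safe}_chisq.tsv", sep="\t", index=False)
            perm = comp.permutation.copy()
            perm["stars"] = perm["p"].map(_stars)
            perm.to_csv(zdir / f"{safe}_permutation.tsv", sep="\t", index=False)
            summary = {
                "label": comp.label,
                "groups": comp.extra["groups"],
                "n_perm": comp.n_perm,
                "seed": comp.seed,
                "thr_nac0": comp.extra["thr_nac0"],
                "thr_gc": comp.extra["thr_gc"],
                "chi_square": comp.chi_square.to_dict(orient="records"),
            }
            (zdir / f"{safe}_summary.json").write_text(
                json.dumps(summary, indent=2) + "\n"
            )
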