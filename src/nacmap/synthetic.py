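"""Synthetic resting-state cohorts with planted network structure.

The generator emulates the statistical features the analysis pipeline
assumes, at desk scale: per subject, three runs of 102 volumes at TR = 3 s;
node signals built from modular latent factors with AR(1) temporal
autocorrelation; designated noise nodes sharing physiological-like
components (for CompCor); six-parameter motion traces; and subject metadata
(group label, 2D:4D digit ratio, days since last menses).

The node model is a latent-factor construction.  Each of ``n_regions``
regions owns a module signal

    s_m(t) = rho * sum_f W[m, f] * v_f(t) + sqrt(1 - rho^2) * u_m(t),

where the ``v_f`` are a few cohort-wide *network* factors, ``u_m`` is
module-specific, and all latents are unit-variance AR(1) with coefficient
``ar_coef``.  The unit-norm weight rows ``W[m, :]`` assign each region a
primary network (cyclically) plus a weaker secondary one, emulating
distributed resting-state networks that span several anatomical regions.
The heterogeneity matters: a single uniform global factor would be removed
almost entirely by global-signal regression, leaving the modules
disconnected, whereas distinct overlapping networks survive it, as in real
data.  An ordinary node in module ``m`` is

    x_i(t) = a * s_m(t) + w * p(t) + sigma * eps_i(t),

with loading ``a = module_loading``, a small physiological artifact ``p``
shared with the noise nodes, and AR(1) node noise ``eps_i``.  Nodes in a
group's planted hub regions additionally load ``hub_loading`` on their own
region's primary network factor, which correlates them with every module
weighted on that factor and tightly with each other, making the region the
eigenvector core of its network -- the signature of a globally connected
(high-eigenvector) region that the pipeline should recover.

Two heterogeneity terms keep the cohort from being a set of statistical
clones: a cohort-fixed per-node loading jitter (stable functional anatomy)
and a per-subject, per-region multiplicative gain (individual variability).
Without them every subject's map is nearly identical, node classifications
flip region-coherently, and group count tables become quasi-deterministic --
unlike real cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classification import REGION_CODES, RegionAtlas
from .preprocess import MotionTrace

__all__ = [
    "SyntheticConfig",
    "RunTimeSeries",
    "SubjectRecord",
    "Cohort",
    "generate_cohort",
    "generate_motion",
    "write_cohort",
    "read_cohort",
]

#: Cohort marginals for the 2D:4D digit ratio: group -> (mean, sd).
DIGIT_RATIO_PARAMS = {
    "male": (0.938, 0.026),
    "female": (0.951, 0.030),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``n_per_group`` maps each group label to its subject count (an int means
    the same count for the default male/female groups).  Defaults mirror the
    emulated study design: 100 subjects per group, 3 runs x 102 volumes at
    TR = 3 s.  ``n_nodes`` defaults to a desk-scale 300 (full-scale runs are
    configuration-only).
    """

    n_per_group: dict[str, int] | int = 100
    n_nodes: int = 300
    n_regions: int = 14
    n_runs: int = 3
    n_volumes: int = 102
    tr_seconds: float = 3.0
    ar_coef: float = 0.3
    module_loading: float = 0.9
    module_mixing: float = 0.8
    n_network_factors: int = 4
    hub_loading: float = 2.0
    hub_regions_by_group: dict[str, tuple[int, ...]] = field(default_factory=dict)
    motion_scale: float = 0.1
    n_noise_nodes: int = 30
    noise_std: float = 1.0
    artifact_loading: float = 0.15
    node_jitter: float = 0.4
    subject_cv: float = 0.2
    menses_groups: tuple[str, ...] = ("female",)
    menses_over28_fraction: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = {"male": self.n_per_group, "female": self.n_per_group}
        for g, n in self.n_per_group.items():
            if n <= 0:
                raise ValueError(f"group {g!r} must have a positive subject count")
        for name in ("n_nodes", "n_regions", "n_runs", "n_volumes", "n_noise_nodes"):
            if getattr(self, name) < (0 if name == "n_noise_nodes" else 1):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must be in [0, 1)")
        if not 0.0 <= self.module_mixing < 1.0:
            raise ValueError("module_mixing must be in [0, 1)")
        if self.n_regions > self.n_nodes:
            raise ValueError("every region must receive at least one node")
        if self.noise_std <= 0.0:
            raise ValueError(
                "noise_std must be positive: with zero node noise, same-module "
                "loadings imply |correlation| = 1"
            )
        for g in self.hub_regions_by_group:
            bad = [r for r in self.hub_regions_by_group[g] if not 0 <= r < self.n_regions]
            if bad:
                raise ValueError(f"hub region indices out of range for {g!r}: {bad}")

    def node_regions(self) -> np.ndarray:
        """Node -> region index, contiguous blocks, every region non-empty."""
        sizes = np.full(self.n_regions, self.n_nodes // self.n_regions)
        sizes[: self.n_nodes % self.n_regions] += 1
        return np.repeat(np.arange(self.n_regions), sizes)

    def region_codes(self) -> list[str]:
        if self.n_regions <= len(REGION_CODES):
            return list(REGION_CODES[: self.n_regions])
        return list(REGION_CODES) + [
            f"R{i}" for i in range(len(REGION_CODES), self.n_regions)
        ]

    def atlas(self) -> RegionAtlas:
        codes = self.region_codes()
        return RegionAtlas(labels=[codes[r] for r in self.node_regions()])


@dataclass
class RunTimeSeries:
    """One run's node x volume signal matrix with its sampling interval."""

    data: np.ndarray
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("run data must be a 2-D nodes x volumes matrix")
        self.data = d

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectRecord:
    subject_id: str
    group_label: str
    digit_ratio: float
    days_since_menses: int | None
    runs: list[RunTimeSeries]
    motion: list[MotionTrace]
    noise_runs: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (len(self.runs) == len(self.motion) == len(self.noise_runs)):
            raise ValueError("runs, motion and noise_runs must have equal length")
        if self.digit_ratio <= 0:
            raise ValueError("digit ratio must be positive")


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    atlas: RegionAtlas
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_nodes = {s.runs[0].n_nodes for s in self.subjects if s.runs}
        if len(n_nodes) > 1:
            raise ValueError("all subjects must share the same node count")
        if n_nodes and self.atlas.n_nodes not in n_nodes:
            raise ValueError("atlas size must match the subjects' node count")


def _ar1(rng: np.random.Generator, n_series: int, n_samples: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series, one per row."""
    x = np.empty((n_series, n_samples))
    x[:, 0] = rng.standard_normal(n_series)
    innov_sd = np.sqrt(1.0 - phi**2)
    innov = rng.standard_normal((n_series, n_samples)) * innov_sd
    for t in range(1, n_samples):
        x[:, t] = phi * x[:, t - 1] + innov[:, t]
    return x


def generate_motion(
    config: SyntheticConfig,
    rng: np.random.Generator,
    spike_mm: float | None = None,
    spike_volume: int | None = None,
) -> MotionTrace:
    """Bounded-random-walk motion trace: 3 translations (mm) + 3 rotations (rad).

    Each parameter follows a mean-reverting AR(1) walk with stationary SD
    ``motion_scale`` mm for translations and ``motion_scale / 100`` rad for
    rotations.  ``spike_mm`` optionally injects a single-volume translation
    spike on tx (for exclusion-rule tests).
    """
    if config.n_volumes < 2:
        raise ValueError("need at least 2 volumes for a motion trace")
    walk = _ar1(rng, 6, config.n_volumes, 0.95)
    scales = np.array([config.motion_scale] * 3 + [config.motion_scale / 100.0] * 3)
    params = walk.T * scales
    if spike_mm is not None:
        v = spike_volume if spike_volume is not None else config.n_volumes // 2
        params[v, 0] += spike_mm
    return MotionTrace(params=params)


def _loading_matrix(config: SyntheticConfig, group: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-node (module loadings, per-factor hub loadings) for one group.

    Hub-region nodes load on their region's primary network factor.
    """
    regions = config.node_regions()
    load = np.zeros((config.n_nodes, config.n_regions))
    load[np.arange(config.n_nodes), regions] = config.module_loading
    hub_load = np.zeros((config.n_nodes, config.n_network_factors))
    for r in config.hub_regions_by_group.get(group, ()):
        hub_load[regions == r, r % config.n_network_factors] = config.hub_loading
    return load, hub_load


#: Loading of each region's secondary network relative to its primary.
_SECONDARY_COUPLING = 0.5


def _network_weights(config: SyntheticConfig) -> np.ndarray:
    """Region x factor mixing weights, unit-norm rows.

    Region ``m`` loads its primary network ``m % F`` with weight
    ``sqrt(1 - beta^2)`` and the next network with ``beta``
    (``beta = 0.5``), chaining the networks into one overlapping system.
    """
    f = config.n_network_factors
    beta = _SECONDARY_COUPLING if f > 1 else 0.0
    w = np.zeros((config.n_regions, f))
    rows = np.arange(config.n_regions)
    w[rows, rows % f] = np.sqrt(1.0 - beta**2)
    if f > 1:
        w[rows, (rows + 1) % f] = beta
    return w


def _subject_runs(
    config: SyntheticConfig,
    rng: np.random.Generator,
    group: str,
    weights: np.ndarray,
    node_gain: np.ndarray,
) -> tuple[list[RunTimeSeries], list[np.ndarray]]:
    load, hub_load = _loading_matrix(config, group)
    regions = config.node_regions()
    region_gain = np.clip(rng.normal(1.0, config.subject_cv, config.n_regions), 0.3, None)
    gain = node_gain * region_gain[regions]
    load = load * gain[:, None]
    hub_load = hub_load * gain[:, None]
    rho = config.module_mixing
    runs, noise_runs = [], []
    for _ in range(config.n_runs):
        t = config.n_volumes
        v = _ar1(rng, config.n_network_factors, t, config.ar_coef)
        u = _ar1(rng, config.n_regions, t, config.ar_coef)
        s = rho * (weights @ v) + np.sqrt(1.0 - rho**2) * u
        physio = _ar1(rng, 2, t, 0.5)
        eps = _ar1(rng, config.n_nodes, t, config.ar_coef)
        x = (
            load @ s
            + hub_load @ v
            + config.artifact_loading * physio[0]
            + config.noise_std * eps
        )
        runs.append(RunTimeSeries(data=x, tr_seconds=config.tr_seconds))
        if config.n_noise_nodes:
            w = 0.8 + 0.2 * rng.random((config.n_noise_nodes, 2))
            nz = w @ physio + 0.5 * _ar1(rng, config.n_noise_nodes, t, config.ar_coef)
            noise_runs.append(nz)
        else:
            noise_runs.append(np.empty((0, t)))
    return runs, noise_runs


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort; identical config and seed give identical data."""
    rng = np.random.default_rng(config.seed)
    weights = _network_weights(config)
    node_gain = rng.uniform(
        1.0 - config.node_jitter, 1.0 + config.node_jitter, config.n_nodes
    )
    subjects: list[SubjectRecord] = []
    for group, n_sub in config.n_per_group.items():
        dr_mean, dr_sd = DIGIT_RATIO_PARAMS.get(group, (0.95, 0.03))
        for i in range(n_sub):
            runs, noise_runs = _subject_runs(config, rng, group, weights, node_gain)
            motion = [generate_motion(config, rng) for _ in range(config.n_runs)]
            digit_ratio = float(rng.normal(dr_mean, dr_sd))
            days: int | None = None
            if group in config.menses_groups:
                if rng.random() < config.menses_over28_fraction:
                    days = int(rng.integers(29, 61))
                else:
                    days = int(rng.integers(1, 29))
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{group}-{i:03d}",
                    group_label=group,
                    digit_ratio=digit_ratio,
                    days_since_menses=days,
                    runs=runs,
                    motion=motion,
                    noise_runs=noise_runs,
                )
            )
    return Cohort(
        subjects=subjects,
        atlas=config.atlas(),
        truth={"hub_regions_by_group": {
            g: list(r) for g, r in config.hub_regions_by_group.items()
        }},
    )


# ---------------------------------------------------------------------------
# plain-text cohort I/O


def write_cohort(cohort: Cohort, path: str | Path, config: SyntheticConfig | None = None) -> None:
    """Write a cohort as plain-text matrices plus TSV metadata tables."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        for k, run in enumerate(s.runs):
            np.savetxt(root / f"{s.subject_id}_run-{k}_timeseries.tsv", run.data, delimiter="\t")
            np.savetxt(root / f"{s.subject_id}_run-{k}_motion.tsv", s.motion[k].params, delimiter="\t")
            np.savetxt(root / f"{s.subject_id}_run-{k}_noise.tsv", s.noise_runs[k], delimiter="\t")
        rows.append(
            f"{s.subject_id}\t{s.group_label}\t{s.digit_ratio:.6f}\t"
            f"{'' if s.days_since_menses is None else s.days_since_menses}\t"
            f"{len(s.runs)}\t{s.runs[0].tr_seconds if s.runs else ''}"
        )
    header = "subject_id\tgroup\tdigit_ratio\tdays_since_menses\tn_runs\ttr_seconds"
    (root / "subjects.tsv").write_text(header + "\n" + "\n".join(rows) + "\n")
    cohort.atlas.to_tsv(root / "atlas.tsv")
    meta = {"truth": cohort.truth}
    if config is not None:
        meta["config"] = {
            k: (v if not isinstance(v, tuple) else list(v))
            for k, v in vars(config).items()
        }
    (root / "cohort.json").write_text(json.dumps(meta, indent=2, default=list))


def read_cohort(path: str | Path) -> Cohort:
    root = Path(path)
    lines = (root / "subjects.tsv").read_text().strip().splitlines()
    atlas = RegionAtlas.from_tsv(root / "atlas.tsv")
    meta = json.loads((root / "cohort.json").read_text()) if (root / "cohort.json").exists() else {}
    subjects = []
    for line in lines[1:]:
        sid, group, dr, days, n_runs, tr = line.split("\t")
        tr_s = float(tr) if tr else 3.0
        runs, motion, noise_runs = [], [], []
        for k in range(int(n_runs)):
            data = np.loadtxt(root / f"{sid}_run-{k}_timeseries.tsv", delimiter="\t", ndmin=2)
            runs.append(RunTimeSeries(data=data, tr_seconds=tr_s))
            motion.append(MotionTrace(params=np.loadtxt(root / f"{sid}_run-{k}_motion.tsv", delimiter="\t", ndmin=2)))
            noise = np.loadtxt(root / f"{sid}_run-{k}_noise.tsv", delimiter="\t", ndmin=2)
            noise_runs.append(noise if noise.size else np.empty((0, data.shape[1])))
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group_label=group,
                digit_ratio=float(dr),
                days_since_menses=int(days) if days else None,
                runs=runs,
                motion=motion,
                noise_runs=noise_runs,
            )
        )
    return Cohort(subjects=subjects, atlas=atlas, truth=meta.get("truth", {}))
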