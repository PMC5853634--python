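"""Four-way node typing and regional node-type distributions.

Group mean centrality maps are thresholded at mean + 1 SD of the pooled node
values of the two maps under comparison, separately for nAC0 and GC.  A node
is a *hub* when its nAC0 strictly exceeds the nAC0 threshold and *global*
when its GC strictly exceeds the GC threshold, yielding four exclusive
types: global hub, global node, local hub, local node.  Because the mean of
GC is exactly 0, its mean + SD threshold is always positive.

Regional distributions count and percentage each type among the nodes of
each atlas region (14 AAL-derived region groups in the emulated study).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import CentralityMap

__all__ = [
    "REGION_CODES",
    "NODE_TYPES",
    "RegionAtlas",
    "NodeTypeMap",
    "RegionalDistribution",
    "group_mean_map",
    "classification_thresholds",
    "classify",
    "regional_distribution",
]

#: The 14 AAL-derived region groups.
REGION_CODES = (
    "FRv", "FRm", "FRl", "SM", "CIN", "PAl", "PAm",
    "INS", "LIM", "TE", "OC", "CER", "BG", "TH",
)

NODE_TYPES = ("global_hub", "global_node", "local_hub", "local_node")


@dataclass
class RegionAtlas:
    """Per-node region label; region order follows first appearance."""

    labels: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(c) for c in self.labels]
        if not self.labels:
            raise ValueError("atlas must label at least one node")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.labels:
            seen.setdefault(c)
        return list(seen)

    def indices(self) -> np.ndarray:
        """Node -> region index in ``self.regions`` order."""
        order = {c: i for i, c in enumerate(self.regions)}
        return np.array([order[c] for c in self.labels])

    def to_tsv(self, path: str | Path) -> None:
        lines = ["node_id\tregion_code"] + [
            f"{i}\t{c}" for i, c in enumerate(self.labels)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionAtlas":
        lines = Path(path).read_text().strip().splitlines()[1:]
        pairs = [ln.split("\t") for ln in lines]
        labels = [c for _, c in sorted(pairs, key=lambda p: int(p[0]))]
        return cls(labels=labels)


@dataclass
class NodeTypeMap:
    """Per-node type plus the thresholds that produced it."""

    types: np.ndarray  # array of strings from NODE_TYPES
    thr_nac0: float
    thr_gc: float

    def __post_init__(self) -> None:
        t = np.asarray(self.types, dtype=object)
        bad = set(t.tolist()) - set(NODE_TYPES)
        if bad:
            raise ValueError(f"unknown node types: {sorted(bad)}")
        self.types = t

    @property
    def n_nodes(self) -> int:
        return self.types.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": np.arange(self.n_nodes), "node_type": self.types}
        )


@dataclass
class RegionalDistribution:
    """Counts and percentages of the four types per region.

    ``counts`` is a region x type DataFrame; percentages are per region
    (rows sum to 100).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=list(NODE_TYPES), fill_value=0)

    @property
    def percentages(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0) * 100.0

    def region_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_tidy(self) -> pd.DataFrame:
        pct = self.percentages
        rows = [
            {
                "region": r,
                "node_type": t,
                "count": int(self.counts.loc[r, t]),
                "percent": float(pct.loc[r, t]),
            }
            for r in self.counts.index
            for t in NODE_TYPES
        ]
        return pd.DataFrame(rows)


def group_mean_map(maps: list[CentralityMap]) -> CentralityMap:
    """Element-wise mean of per-subject maps; GC recomputed from the means.

    Linearity preserves the normalization: the mean map's nAC0 and nAC1 sum
    to 100 and its GC sums to 0.
    """
    if not maps:
        raise ValueError("need at least one map")
    n = maps[0].n_nodes
    if any(m.n_nodes != n for m in maps):
        raise ValueError("all maps must share the same node count")
    nac0 = np.mean([m.nac0 for m in maps], axis=0)
    nac1 = np.mean([m.nac1 for m in maps], axis=0)
    return CentralityMap(nac0=nac0, nac1=nac1)


def classification_thresholds(
    map_a: CentralityMap, map_b: CentralityMap, ddof: int = 1
) -> tuple[float, float]:
    """Mean + 1 SD thresholds from the pooled nodes of the two mean maps.

    The pooled distribution concatenates the node values of both maps;
    sample SD (``ddof=1``) by default.  Since pooled GC has mean 0, the GC
    threshold is always positive (unless degenerate).
    """
    if map_a.n_nodes != map_b.n_nodes:
        raise ValueError("maps must share the same node count")
    thrs = []
    for values in (
        np.concatenate([map_a.nac0, map_b.nac0]),
        np.concatenate([map_a.gc, map_b.gc]),
    ):
        sd = float(np.std(values, ddof=ddof))
        if sd == 0.0:
            warnings.warn("degenerate (constant) pooled values; threshold = mean",
                          stacklevel=2)
        thrs.append(float(np.mean(values)) + sd)
    return thrs[0], thrs[1]


def classify(mean_map: CentralityMap, thr_nac0: float, thr_gc: float) -> NodeTypeMap:
    """Four-way typing: hub iff nAC0 > thr (strict), global iff GC > thr."""
    if not (np.isfinite(thr_nac0) and np.isfinite(thr_gc)):
        raise ValueError("thresholds must be finite")
    hub = mean_map.nac0 > thr_nac0
    glob = mean_map.gc > thr_gc
    types = np.where(
        hub,
        np.where(glob, "global_hub", "local_hub"),
        np.where(glob, "global_node", "local_node"),
    ).astype(object)
    return NodeTypeMap(types=types, thr_nac0=thr_nac0, thr_gc=thr_gc)


def regional_distribution(types: NodeTypeMap, atlas: RegionAtlas) -> RegionalDistribution:
    """Per-region counts and percentages of the four node types."""
    if types.n_nodes != atlas.n_nodes:
        raise ValueError("node type map and atlas label different node sets")
    regions = atlas.regions
    counts = pd.DataFrame(0, index=regions, columns=list(NODE_TYPES))
    ridx = atlas.indices()
    tidx = np.array([NODE_TYPES.index(t) for t in types.types])
    flat = np.bincount(ridx * len(NODE_TYPES) + tidx,
                       minlength=len(regions) * len(NODE_TYPES))
    counts.iloc[:, :] = flat.reshape(len(regions), len(NODE_TYPES))
    return RegionalDistribution(counts=counts)
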