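"""Group-level statistics on regional node-type distributions.

Two complementary tests compare the regional distribution of each node type
between two groups:

* a Pearson chi-square test of homogeneity on the 2 x 14 table of that
  type's per-region counts, Bonferroni-corrected for the four node types;
* a label permutation test: subjects are randomly re-split into two groups
  of the original sizes, the group mean maps, pooled mean + SD thresholds,
  node typing and regional percentages are re-derived from scratch for
  every permutation, and the per-(region, type) percentage difference is
  compared with the observed one.  The one-sided permutation p is
  ``#{permuted difference >= observed} / n_perm`` (group1 minus group2, ties
  counted as exceeding); the opposite tail is reported alongside so
  group2-dominant cells can be read directly.

Also here: the median split used for 2D:4D digit-ratio subgroups and the
menstrual-phase rule (days 1-14 follicular, 15-28 luteal, later unknown).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import CentralityMap
from .classification import (
    NODE_TYPES,
    RegionAtlas,
    RegionalDistribution,
)

__all__ = [
    "GroupComparison",
    "chi_square_homogeneity",
    "permutation_region_test",
    "median_split",
    "menstrual_phase",
    "N_NODE_TYPES",
]

#: Bonferroni factor: one chi-square test per node type.
N_NODE_TYPES = len(NODE_TYPES)


@dataclass
class GroupComparison:
    """Results of one two-group comparison."""

    label: str
    chi_square: pd.DataFrame  # per node type: statistic, df, p_raw, p_corrected
    permutation: pd.DataFrame  # per (region, type): diff, p_greater, p_less, p
    n_perm: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def significant_cells(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.permutation[self.permutation["p"] < alpha]


def chi_square_homogeneity(
    dist1: RegionalDistribution,
    dist2: RegionalDistribution,
    node_type: str,
    yates: bool = False,
) -> tuple[float, int, float, float]:
    """Pearson chi-square on the group x region table of one type's counts.

    Regions where both groups have zero counts of the type carry no
    information (zero expected count) and are dropped with a warning, with
    the degrees of freedom reduced accordingly.  The corrected p applies a
    Bonferroni factor of 4 (one test per node type), capped at 1.

    Returns ``(statistic, df, p_raw, p_corrected)``.
    """
    if node_type not in NODE_TYPES:
        raise ValueError(f"unknown node type {node_type!r}")
    c1 = dist1.counts[node_type]
    c2 = dist2.counts[node_type]
    if list(c1.index) != list(c2.index):
        raise ValueError("distributions cover different region sets")
    table = np.vstack([c1.to_numpy(), c2.to_numpy()]).astype(float)
    keep = table.sum(axis=0) > 0
    if not keep.all():
        dropped = [c1.index[j] for j in np.flatnonzero(~keep)]
        warnings.warn(
            f"regions with zero {node_type} counts in both groups dropped "
            f"from the chi-square table: {dropped}",
            stacklevel=2,
        )
        table = table[:, keep]
    if table.shape[1] < 2 or np.any(table.sum(axis=1) == 0):
        warnings.warn(
            f"degenerate {node_type} table (fewer than two informative "
            "regions or an empty group); returning p = 1",
            stacklevel=2,
        )
        return 0.0, 0, 1.0, 1.0
    stat, p_raw, df, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), int(df), float(p_raw), min(1.0, N_NODE_TYPES * float(p_raw))


def _stack_maps(maps: list[CentralityMap]) -> tuple[np.ndarray, np.ndarray]:
    nac0 = np.vstack([m.nac0 for m in maps])
    nac1 = np.vstack([m.nac1 for m in maps])
    return nac0, nac1


def _regional_percentages(
    nac0: np.ndarray,
    nac1: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
    ridx: np.ndarray,
    region_sizes: np.ndarray,
    ddof: int,
) -> np.ndarray:
    """Percentage difference table (region x type) for one split.

    Re-derives mean maps, pooled thresholds and typing from scratch.
    """
    n_regions = region_sizes.size
    out = np.empty((2, n_regions, N_NODE_TYPES))
    m0 = np.empty((2, nac0.shape[1]))
    m1 = np.empty((2, nac0.shape[1]))
    for k, idx in enumerate((idx1, idx2)):
        m0[k] = nac0[idx].mean(axis=0)
        m1[k] = nac1[idx].mean(axis=0)
    gc = m1 - m0
    thr0 = m0.mean() + np.std(m0, ddof=ddof)
    thrg = gc.mean() + np.std(gc, ddof=ddof)
    for k in range(2):
        hub = m0[k] > thr0
        glob = gc[k] > thrg
        tidx = np.where(hub, np.where(glob, 0, 2), np.where(glob, 1, 3))
        flat = np.bincount(ridx * N_NODE_TYPES + tidx, minlength=n_regions * N_NODE_TYPES)
        out[k] = flat.reshape(n_regions, N_NODE_TYPES) / region_sizes[:, None] * 100.0
    return out[0] - out[1]


def permutation_region_test(
    subject_maps: list[CentralityMap],
    labels: list | np.ndarray,
    atlas: RegionAtlas,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    direction: str = "greater",
    plus_one: bool = False,
    ddof: int = 1,
    groups: tuple | None = None,
    return_null: bool = False,
) -> pd.DataFrame:
    """Permutation p per (region, node type) for a two-group comparison.

    ``labels`` holds exactly two distinct group labels; group order (and the
    sign of the difference, group1 minus group2) follows first appearance
    unless ``groups`` fixes it explicitly.
    Group sizes are preserved under permutation.  Each permutation fully
    re-derives the mean maps, the pooled mean + SD thresholds, the node
    typing and the regional percentages; nothing is frozen from the observed
    split.

    ``direction``: ``"greater"`` (default) counts permutations with a
    difference >= the observed one; ``"less"`` the opposite tail;
    ``"observed"`` picks the tail from the sign of each observed cell
    (anticonservative under the null -- see the reported ``p_greater`` and
    ``p_less`` columns, which are always both present).
    ``plus_one`` reports ``(n + 1)/(n_perm + 1)`` instead of ``n/n_perm``.
    ``return_null`` additionally returns the sampled null differences as an
    (n_perm, n_regions, n_types) array.
    """
    labels = np.asarray(labels)
    if len(subject_maps) != labels.size:
        raise ValueError("one label per subject map required")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    if groups is not None:
        if sorted(map(str, groups)) != sorted(map(str, uniq)):
            raise ValueError(f"groups {groups} do not match the labels {uniq}")
        uniq = list(groups)
    idx1 = np.flatnonzero(labels == uniq[0])
    idx2 = np.flatnonzero(labels == uniq[1])
    if min(idx1.size, idx2.size) < 2:
        raise ValueError("each group needs at least two subjects")
    if n_perm < 100:
        warnings.warn(
            f"n_perm = {n_perm} gives a p-value resolution of only {1 / n_perm:.3g}",
            stacklevel=2,
        )
    if direction not in ("greater", "less", "observed"):
        raise ValueError(f"unknown direction {direction!r}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nac0, nac1 = _stack_maps(subject_maps)
    ridx = atlas.indices()
    regions = atlas.regions
    region_sizes = np.bincount(ridx, minlength=len(regions)).astype(float)

    observed = _regional_percentages(nac0, nac1, idx1, idx2, ridx, region_sizes, ddof)

    n_sub = labels.size
    n1 = idx1.size
    ge = np.zeros_like(observed)
    le = np.zeros_like(observed)
    null = np.empty((n_perm, *observed.shape)) if return_null else None
    for k in range(n_perm):
        perm = rng.permutation(n_sub)
        diff = _regional_percentages(
            nac0, nac1, perm[:n1], perm[n1:], ridx, region_sizes, ddof
        )
        ge += diff >= observed
        le += diff <= observed
        if null is not None:
            null[k] = diff
    denom = n_perm + 1 if plus_one else n_perm
    add = 1 if plus_one else 0
    p_greater = (ge + add) / denom
    p_less = (le + add) / denom
    if direction == "greater":
        p = p_greater
    elif direction == "less":
        p = p_less
    else:
        p = np.where(observed >= 0, p_greater, p_less)

    rows = []
    for i, region in enumerate(regions):
        for j, t in enumerate(NODE_TYPES):
            rows.append(
                {
                    "region": region,
                    "node_type": t,
                    "diff_percent": observed[i, j],
                    "p_greater": p_greater[i, j],
                    "p_less": p_less[i, j],
                    "p": p[i, j],
                }
            )
    result = pd.DataFrame(rows)
    if return_null:
        return result, null
    return result


def median_split(values: list[float] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split subject indices into (low, high) halves of a median split.

    A stable ascending sort by value preserves subject order among ties; the
    first ``n // 2`` subjects form the low group, the remainder (including
    the middle subject of an odd-sized group) the high group.  Tied values
    straddling the midpoint may therefore appear in both groups.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 subjects for a median split")
    order = np.argsort(v, kind="stable")
    half = v.size // 2
    return order[:half], order[half:]


def menstrual_phase(days_since_last_period: int) -> str:
    """Phase from days since last menses: 1-14 follicular, 15-28 luteal.

    Beyond 28 days the cycle date cannot be estimated and the subject is
    excluded from phase analyses (``"unknown"``).
    """
    days = int(days_since_last_period)
    if days < 1:
        raise ValueError("days since last menses must be >= 1")
    if days <= 14:
        return "follicular"
    if days <= 28:
        return "luteal"
    return "unknown"
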