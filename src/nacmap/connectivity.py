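"""Pairwise connectivity: autocorrelation-corrected Fisher Z and adjacency.

Resting-state node signals are temporally autocorrelated, so the nominal
number of volumes overstates the information content of a Pearson correlation
between two nodes.  Following the Bartlett AR(1) correction, the effective
sample size for a node pair with lag-1 autocorrelations ``a_x``, ``a_y`` is

    N_eff = n * (1 - a_x * a_y) / (1 + a_x * a_y),

and the corrected Fisher statistic ``Z = atanh(r) * sqrt(N_eff - 3)`` is
approximately standard normal under independence.  Mean Z across runs is
thresholded at a two-sided normal quantile (1.96, 2.58 or 3.28) to obtain a
binary adjacency matrix per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ZMatrix",
    "AdjacencyMatrix",
    "lag1_autocorr",
    "effective_n",
    "fisher_z",
    "z_matrix",
    "average_z",
    "z_threshold_for_p",
    "adjacency",
    "Z_THRESHOLDS",
]

#: The three adjacency cutoffs used throughout: Z for two-sided p of
#: .05, .01 and .001 as conventionally printed.
Z_THRESHOLDS = (1.96, 2.58, 3.28)


@dataclass
class ZMatrix:
    """Symmetric matrix of corrected Fisher Z values, zero diagonal."""

    matrix: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Z matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("Z matrix must be symmetric")
        if not np.all(np.isfinite(m)):
            raise ValueError("Z matrix must be finite")
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class AdjacencyMatrix:
    """Binary symmetric adjacency with the Z cutoff that produced it."""

    matrix: np.ndarray
    z_threshold: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        m = m.astype(np.uint8).copy()
        np.fill_diagonal(m, 0)
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.matrix.sum()) // 2

    @property
    def degree(self) -> np.ndarray:
        return self.matrix.sum(axis=1).astype(int)


def lag1_autocorr(series: np.ndarray) -> float:
    """Sample lag-1 autocorrelation of a 1-D series.

    Uses the standard biased-denominator estimator
    ``sum((x_t - m)(x_{t+1} - m)) / sum((x_t - m)^2)``.

    Raises
    ------
    ValueError
        For series shorter than 3 samples or constant series (undefined).
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 samples for a lag-1 autocorrelation")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        raise ValueError("lag-1 autocorrelation is undefined for a constant series")
    return float(x[:-1] @ x[1:]) / denom


def _lag1_autocorr_rows(series: np.ndarray) -> np.ndarray:
    """Vectorized row-wise lag-1 autocorrelation for a nodes x volumes matrix."""
    x = series - series.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", x, x)
    if np.any(denom == 0.0):
        bad = np.flatnonzero(denom == 0.0).tolist()
        raise ValueError(f"constant node series (autocorrelation undefined): {bad}")
    num = np.einsum("ij,ij->i", x[:, :-1], x[:, 1:])
    return num / denom


def effective_n(n: float, ac_x: float, ac_y: float) -> float:
    """Bartlett AR(1) effective sample size ``n (1 - ax ay)/(1 + ax ay)``.

    Monotone decreasing in the autocorrelation product; equals ``n`` when
    either series is white.
    """
    prod = ac_x * ac_y
    if abs(prod) >= 1.0:
        raise ValueError("autocorrelation product must have magnitude < 1")
    return float(n) * (1.0 - prod) / (1.0 + prod)


def fisher_z(r: float, n_eff: float) -> float:
    """Corrected Fisher Z: ``atanh(r) * sqrt(n_eff - 3)``."""
    if not np.all(np.abs(r) < 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if not np.all(np.asarray(n_eff) > 3.0):
        raise ValueError("effective sample size must exceed 3")
    return np.arctanh(r) * np.sqrt(np.asarray(n_eff) - 3.0)


def z_matrix(series: np.ndarray, cap_policy: str = "error") -> ZMatrix:
    """Corrected-Z connectivity matrix for one run (nodes x volumes).

    Pearson correlation for every node pair, converted with
    :func:`fisher_z` using the pairwise Bartlett effective sample size from
    the two nodes' lag-1 autocorrelations.

    Parameters
    ----------
    series:
        Preprocessed node x volume matrix; every node must be non-constant.
    cap_policy:
        ``"error"`` (default) raises when any off-diagonal ``|r| = 1``
        (duplicated series); ``"cap"`` clips ``|r|`` to ``1 - 1e-7``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be a 2-D nodes x volumes matrix")
    n_nodes, n_vol = x.shape
    if n_vol < 4:
        raise ValueError("need at least 4 volumes")
    ac = _lag1_autocorr_rows(x)
    r = np.corrcoef(x)
    iu = np.triu_indices(n_nodes, k=1)
    at_one = np.abs(r[iu]) >= 1.0 - 1e-12
    if np.any(at_one):
        if cap_policy == "error":
            pairs = [
                (int(iu[0][k]), int(iu[1][k])) for k in np.flatnonzero(at_one)[:10]
            ]
            raise ValueError(
                f"perfectly correlated node pairs (|r| = 1): {pairs}; "
                "pass cap_policy='cap' to clip"
            )
        if cap_policy != "cap":
            raise ValueError(f"unknown cap_policy {cap_policy!r}")
    r = np.clip(r, -1.0 + 1e-7, 1.0 - 1e-7)
    prod = np.outer(ac, ac)
    n_eff = n_vol * (1.0 - prod) / (1.0 + prod)
    if np.any(n_eff[iu] <= 3.0):
        raise ValueError("pairwise effective sample size <= 3; run too short")
    z = np.arctanh(r) * np.sqrt(n_eff - 3.0)
    np.fill_diagonal(z, 0.0)
    return ZMatrix(matrix=z)


def average_z(per_run: list[ZMatrix]) -> ZMatrix:
    """Element-wise mean Z across the retained runs (Z1 + ... + Zk)/k."""
    if not per_run:
        raise ValueError("need at least one retained run to average")
    n = per_run[0].n_nodes
    if any(zm.n_nodes != n for zm in per_run):
        raise ValueError("all runs must share the same node count")
    mean = np.mean([zm.matrix for zm in per_run], axis=0)
    prov = [p for zm in per_run for p in (zm.provenance or [])]
    return ZMatrix(matrix=mean, provenance=prov)


def z_threshold_for_p(p: float) -> float:
    """Two-sided standard-normal quantile for tail probability ``p``, to 2 dp.

    ``p = .05 -> 1.96`` and ``p = .01 -> 2.58``.  Note ``p = .001`` gives
    3.29 at two decimals (the quantile is 3.2905); the conventional printed
    cutoff 3.28 in :data:`Z_THRESHOLDS` corresponds to p ~ .00104.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return round(float(stats.norm.ppf(1.0 - p / 2.0)), 2)


def adjacency(z: ZMatrix | np.ndarray, z_threshold: float) -> AdjacencyMatrix:
    """Binarize a Z matrix: edge iff ``Z > z_threshold`` (strict)."""
    m = z.matrix if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("Z matrix must be symmetric")
    adj = (0.5 * (m + m.T) > z_threshold).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return AdjacencyMatrix(matrix=adj, z_threshold=z_threshold)
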