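"""Temporal denoising and motion quality control for node time series.

Two cleaning variants are supported, mirroring the common resting-state
choices:

* ``full_denoise`` -- CompCor noise components, the six rigid-body motion
  parameters and the global (across-node mean) signal are regressed out
  jointly, then a 0.01-0.1 Hz band-pass is applied;
* ``compcor_only`` -- only the CompCor components are regressed out before
  the band-pass.

Quality control uses Power's framewise displacement (back-projected onto a
50 mm sphere) and a hard per-run exclusion rule: any realignment parameter
reaching 2 mm of translation or 0.02 rad of rotation drops the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "MotionTrace",
    "PreprocessSpec",
    "framewise_displacement",
    "session_exclusion",
    "compcor_components",
    "regress_out",
    "bandpass",
    "preprocess_run",
    "FD_SPHERE_RADIUS_MM",
]

#: Radius (mm) used to convert rotations to arc displacement in FD.
FD_SPHERE_RADIUS_MM = 50.0


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per volume.

    ``params`` is a (n_volumes, 6) array ordered tx, ty, tz (mm) then
    rx, ry, rz (radians).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError("motion trace must be (n_volumes, 6)")
        self.params = p

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class PreprocessSpec:
    """Cleaning variant and its parameters."""

    variant: str = "full_denoise"  # or "compcor_only"
    n_compcor: int = 5
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.1
    translation_limit_mm: float = 2.0
    rotation_limit_rad: float = 0.02

    def __post_init__(self) -> None:
        if self.variant not in ("full_denoise", "compcor_only"):
            raise ValueError(f"unknown preprocessing variant {self.variant!r}")
        if not 0 < self.bandpass_low_hz < self.bandpass_high_hz:
            raise ValueError("need 0 < bandpass_low_hz < bandpass_high_hz")


def framewise_displacement(motion: MotionTrace) -> tuple[np.ndarray, float]:
    """Power's FD series (mm) and its mean.

    ``FD_t = sum |d translation| + R * sum |d rotation|`` with
    ``R = 50 mm``; the first frame has FD 0 by convention.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 volumes for framewise displacement")
    if not np.all(np.isfinite(p)):
        raise ValueError("motion parameters must be finite")
    diffs = np.abs(np.diff(p, axis=0))
    fd = np.zeros(p.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + FD_SPHERE_RADIUS_MM * diffs[:, 3:].sum(axis=1)
    return fd, float(fd.mean())


def session_exclusion(motion: MotionTrace, spec: PreprocessSpec | None = None) -> bool:
    """True (exclude) iff any axis reaches the translation or rotation limit.

    The limits apply per axis to the raw realignment parameters, inclusive
    (a translation of exactly 2 mm excludes the run).
    """
    spec = spec or PreprocessSpec()
    max_t = np.max(np.abs(motion.translations))
    max_r = np.max(np.abs(motion.rotations))
    return bool(max_t >= spec.translation_limit_mm or max_r >= spec.rotation_limit_rad)


def compcor_components(noise_series: np.ndarray, k: int) -> np.ndarray:
    """Top-``k`` principal-component time courses of the noise-node signals.

    ``noise_series`` is nodes x volumes from designated non-gray (noise)
    nodes; each node series is mean-centered and the left singular vectors of
    the resulting volumes x nodes matrix are returned as a volumes x ``k``
    matrix with orthonormal columns.
    """
    x = np.asarray(noise_series, dtype=float)
    if x.ndim != 2:
        raise ValueError("noise series must be 2-D (nodes x volumes)")
    n_nodes, n_vol = x.shape
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k == 0:
        return np.empty((n_vol, 0))
    xc = (x - x.mean(axis=1, keepdims=True)).T  # volumes x nodes, centered
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        raise ValueError(f"k = {k} exceeds the rank {rank} of the noise matrix")
    return u[:, :k]


def regress_out(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Least-squares residual of each node series on [intercept | regressors].

    ``series`` is nodes x volumes; ``regressors`` is volumes x q (q may be
    0, in which case only the intercept -- i.e. the mean -- is removed).

    Raises
    ------
    ValueError
        If the design matrix is rank deficient, naming the collinear columns.
    """
    y = np.asarray(series, dtype=float)
    r = np.asarray(regressors, dtype=float)
    if r.ndim == 1:
        r = r[:, None]
    if r.shape[0] != y.shape[1]:
        raise ValueError("regressors must have one row per volume")
    design = np.column_stack([np.ones(y.shape[1]), r])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = np.ones((design.shape[0], 0))
        for j in range(design.shape[1]):
            trial = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(j - 1)  # report in regressor indexing (intercept = -1)
            else:
                kept = trial
        raise ValueError(
            f"rank-deficient design: regressor columns {bad} are collinear "
            "with the intercept or earlier columns"
        )
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    return y - (design @ beta).T


def bandpass(
    series: np.ndarray, tr_seconds: float, low_hz: float = 0.01, high_hz: float = 0.1
) -> np.ndarray:
    """Zero-phase Butterworth (order 4) band-pass of each node series.

    Applied forward-backward (``sosfiltfilt``) so correlations are not
    distorted by filter lag; removes constant offset and slow trends along
    with out-of-band fluctuations.
    """
    y = np.asarray(series, dtype=float)
    fs = 1.0 / tr_seconds
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for Nyquist {nyq:.4g} Hz"
        )
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    n_vol = y.shape[-1]
    if n_vol <= padlen:
        raise ValueError(
            f"series length {n_vol} is too short for the filter warm-up ({padlen})"
        )
    return signal.sosfiltfilt(sos, y, axis=-1)


def _drop_constant_columns(regs: np.ndarray, names: list[str]) -> np.ndarray:
    """Drop regressor columns with no variance (absorbed by the intercept)."""
    if regs.shape[1] == 0:
        return regs
    keep = regs.std(axis=0) > 1e-12
    if not keep.all():
        dropped = [names[j] for j in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping constant nuisance regressors: {dropped}", stacklevel=3
        )
    return regs[:, keep]


def preprocess_run(
    series: np.ndarray,
    motion: MotionTrace | None,
    noise_series: np.ndarray | None,
    tr_seconds: float,
    spec: PreprocessSpec | None = None,
) -> np.ndarray:
    """Full temporal cleaning of one run: nuisance regression then band-pass.

    All nuisance regressors (CompCor components from ``noise_series``, the
    six motion parameters, and the global signal -- the across-node mean of
    ``series``) are computed from the raw input and removed in a single
    joint regression, then the band-pass is applied.
    """
    spec = spec or PreprocessSpec()
    y = np.asarray(series, dtype=float)
    n_vol = y.shape[1]
    regs: list[np.ndarray] = []
    names: list[str] = []
    if noise_series is not None and spec.n_compcor > 0:
        cc = compcor_components(noise_series, spec.n_compcor)
        regs.append(cc)
        names += [f"compcor{i}" for i in range(cc.shape[1])]
    if spec.variant == "full_denoise":
        if motion is not None:
            regs.append(motion.params)
            names += ["tx", "ty", "tz", "rx", "ry", "rz"]
        regs.append(y.mean(axis=0)[:, None])
        names.append("global_signal")
    design = np.column_stack(regs) if regs else np.empty((n_vol, 0))
    design = _drop_constant_columns(design, names)
    cleaned = regress_out(y, design)
    return bandpass(cleaned, tr_seconds, spec.bandpass_low_hz, spec.bandpass_high_hz)
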