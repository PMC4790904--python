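"""Per-subject (first-level) GLM: beta and t maps from a voxel-wise OLS fit.

The model is the standard massively-univariate ordinary least squares fit of
each voxel's timecourse on a design matrix (task boxcar plus intercept at
minimum).  For a contrast vector ``c``::

    beta = c' (X'X)^-1 X' y
    t    = beta / sqrt(sigma2 * c' (X'X)^-1 c),   df = T - k

Voxels with exactly zero residual variance (noise-free synthetic data) get a
``+inf`` t sentinel: they survive any p threshold and are never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .grid import GridMismatchError, ROIMask, ScalarMap, VolumeGrid

__all__ = [
    "DesignMatrix",
    "SubjectFirstLevel",
    "make_block_design",
    "canonical_hrf",
    "fit_glm",
    "activation_mask",
]


@dataclass
class DesignMatrix:
    """A T x k regressor matrix with a contrast vector."""

    X: np.ndarray
    contrast: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2-D (T x k)")
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length must equal the number of regressors")
        if not np.any(self.contrast):
            raise ValueError("contrast vector must not be all zero")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if not self.names:
            self.names = tuple(f"reg{i}" for i in range(self.X.shape[1]))

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return self.X.shape[1]


@dataclass
class SubjectFirstLevel:
    """One subject's fitted contrast: beta map, t map, df, optional series."""

    beta: ScalarMap
    tmap: ScalarMap
    df: int
    series: np.ndarray | None = field(default=None, repr=False)  # (x, y, z, T)

    def __post_init__(self) -> None:
        if self.beta.grid != self.tmap.grid:
            raise GridMismatchError("beta and t maps must share a grid")
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")
        if self.series is not None:
            self.series = np.asarray(self.series, dtype=float)
            if tuple(self.series.shape[:3]) != self.grid.shape:
                raise GridMismatchError("series shape does not match grid")

    @property
    def grid(self) -> VolumeGrid:
        return self.beta.grid


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``tr`` seconds.

    Peak at ~5 s, undershoot at ~15 s with a 1:6 ratio; normalized to unit sum.
    """
    t = np.arange(0.0, duration, tr)
    peak = sps.gamma.pdf(t, a=6, scale=1.0)
    undershoot = sps.gamma.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.sum()


def make_block_design(
    n_timepoints: int,
    block_length: int,
    tr: float = 2.0,
    hrf: bool = False,
) -> DesignMatrix:
    """Alternating-block boxcar design (control block first) plus intercept.

    The default emulates a blocked working-memory run: control and task
    conditions alternate in blocks of ``block_length`` volumes.  With
    ``hrf=True`` the boxcar is convolved with the canonical HRF; with block
    lengths much longer than the HRF this changes the fit only at block edges.
    """
    if n_timepoints % (2 * block_length) != 0:
        raise ValueError("n_timepoints must be divisible by 2 * block_length")
    cycle = np.concatenate(
        [np.zeros(block_length), np.ones(block_length)]
    )
    boxcar = np.tile(cycle, n_timepoints // (2 * block_length))
    if hrf:
        boxcar = np.convolve(boxcar, canonical_hrf(tr))[:n_timepoints]
    X = np.column_stack([boxcar, np.ones(n_timepoints)])
    return DesignMatrix(X, np.array([1.0, 0.0]), names=("task", "intercept"))


def fit_glm(
    series: np.ndarray,
    design: DesignMatrix,
    grid: VolumeGrid,
    keep_series: bool = False,
) -> SubjectFirstLevel:
    """Voxel-wise OLS fit of a 4-D series (x, y, z, T) on ``design``.

    Returns contrast beta and t maps with ``df = T - k``.  Zero-residual
    voxels get ``t = +inf`` (sentinel, see module docstring).
    """
    series = np.asarray(series, dtype=float)
    if tuple(series.shape[:3]) != grid.shape:
        raise GridMismatchError("series shape does not match grid")
    X = design.X
    T, k = X.shape
    if series.shape[-1] != T:
        raise ValueError("series length does not match design")
    if T < k + 2:
        raise ValueError("need at least k + 2 timepoints")

    Y = series.reshape(-1, T).T  # T x V
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ Y)  # k x V
    resid = Y - X @ coef
    df = T - k
    sigma2 = np.einsum("tv,tv->v", resid, resid) / df
    c = design.contrast
    beta = c @ coef  # V
    cvc = float(c @ xtx_inv @ c)

    # zero residual variance -> +inf sentinel; the cutoff sits well above the
    # float64 rounding floor of an exact fit (~1e-28 * ||y||^2) and well below
    # any genuine noise
    scale = np.maximum(np.einsum("tv,tv->v", Y, Y), 1.0)
    zero_resid = sigma2 * df <= 1e-20 * scale
    se = np.sqrt(np.where(zero_resid, 1.0, sigma2) * cvc)
    t = np.where(zero_resid, np.inf, beta / se)

    shape = grid.shape
    return SubjectFirstLevel(
        beta=ScalarMap(grid, beta.reshape(shape)),
        tmap=ScalarMap(grid, t.reshape(shape)),
        df=df,
        series=series if keep_series else None,
    )


def activation_mask(flm: SubjectFirstLevel, roi: ROIMask, p: float = 0.05) -> ROIMask:
    """Voxels of ``roi`` whose t exceeds the one-sided upper-tail critical value.

    ``p`` is the per-voxel uncorrected threshold; ``p=1`` returns the ROI
    unchanged.  An empty result is valid (downstream measures treat it as
    missing).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    if flm.grid != roi.grid:
        raise GridMismatchError("map and ROI grids differ")
    tcrit = sps.t.ppf(1.0 - p, flm.df)  # p=1 -> -inf -> keep everything
    t = flm.tmap.data
    keep = roi.data & ~np.isnan(t) & (t > tcrit)
    return ROIMask(roi.grid, keep, allow_empty=True)
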