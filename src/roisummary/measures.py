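"""The ten ROI single-value summary measures.

Each measure reduces one subject's contrast (beta) map within an ROI to a
single number.  Variant A uses every ROI voxel; variant B first restricts to
voxels whose t exceeds the one-sided per-voxel threshold (p = 0.05 by
default).  Measures:

  1  mean beta                       (A/B)
  2  median beta                     (A/B)
  3  eigenimage-weighted mean beta   (A/B)   weights = first spatial singular
                                             vector of the ROI timecourses
  4  mean beta of top-percentile-t voxels (A/B)
  5  beta at the ROI peak (max t)
  6  mean beta of the top-N contiguous voxels grown from the peak
  7  mean beta within a sphere around the peak (A/B)
  8  mean beta of voxels whose timecourse correlates with the peak's,
     connected to the peak                   (A/B)
  9  mean beta of the suprathreshold cluster containing the peak (B)
  10 extent (voxel count) of that cluster (B)

Conventions fixed for reproducibility: 26-connectivity everywhere; ties in t
broken by lexicographic voxel index; percentile selection keeps
``ceil(q/100 * m)`` voxels; a B variant with no suprathreshold voxel yields a
missing value, mirroring the explicit missing rule of measure 9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .firstlevel import SubjectFirstLevel, activation_mask
from .grid import GridMismatchError, ROIMask
from .roi import sphere_roi

__all__ = [
    "MeasureSpec",
    "SummaryValue",
    "default_measure_specs",
    "find_peak",
    "central_summary",
    "eigen_weighted_mean",
    "top_percentile_mean",
    "top_n_contiguous_mean",
    "peak_sphere_mean",
    "peak_correlated_mean",
    "peak_cluster_mean",
    "peak_cluster_extent",
    "extract_measure",
    "extract_all",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

# Table of which variants each measure admits.
_VARIANTS = {
    1: ("A", "B"),
    2: ("A", "B"),
    3: ("A", "B"),
    4: ("A", "B"),
    5: ("A",),
    6: ("A",),
    7: ("A", "B"),
    8: ("A", "B"),
    9: ("B",),
    10: ("B",),
}


@dataclass(frozen=True)
class MeasureSpec:
    """Identifies one measure, its variant, and its parameter.

    ``q`` (percentile, measure 4), ``n`` (voxel count, measure 6),
    ``radius_mm`` (measure 7) and ``corr_r`` (measure 8) must be present
    exactly when the measure uses them.
    """

    measure_id: int
    variant: str = "A"
    p_thresh: float = 0.05
    q: float | None = None
    n: int | None = None
    radius_mm: float | None = None
    corr_r: float | None = None

    def __post_init__(self) -> None:
        if self.measure_id not in _VARIANTS:
            raise ValueError(f"measure_id must be 1..10, got {self.measure_id}")
        if self.variant not in _VARIANTS[self.measure_id]:
            raise ValueError(
                f"measure {self.measure_id} does not admit variant {self.variant}"
            )
        needs = {4: "q", 6: "n", 7: "radius_mm", 8: "corr_r"}.get(self.measure_id)
        for param in ("q", "n", "radius_mm", "corr_r"):
            value = getattr(self, param)
            if param == needs and value is None:
                raise ValueError(f"measure {self.measure_id} requires {param}")
            if param != needs and value is not None:
                raise ValueError(f"measure {self.measure_id} does not use {param}")

    @property
    def name(self) -> str:
        base = f"m{self.measure_id:02d}{self.variant if self.measure_id in (1,2,3,4,7,8) else ''}"
        if self.q is not None:
            base += f"_q{self.q:g}"
        if self.n is not None:
            base += f"_n{self.n}"
        if self.radius_mm is not None:
            base += f"_r{self.radius_mm:g}mm"
        if self.corr_r is not None:
            base += f"_r{self.corr_r:g}"
        return base

    @property
    def needs_series(self) -> bool:
        return self.measure_id in (3, 8)


def default_measure_specs(
    p_thresh: float = 0.05,
    q: float = 10.0,
    n: int = 20,
    radius_mm: float = 7.5,
    corr_r: float = 0.8,
) -> list[MeasureSpec]:
    """The 16 default specs: every measure in every admitted variant,
    with the middle value of each parameter sweep (q=10%, N=20, 7.5 mm, r=0.8).
    """
    specs: list[MeasureSpec] = []
    for mid, variants in _VARIANTS.items():
        for variant in variants:
            kw: dict = {}
            if mid == 4:
                kw["q"] = q
            elif mid == 6:
                kw["n"] = n
            elif mid == 7:
                kw["radius_mm"] = radius_mm
            elif mid == 8:
                kw["corr_r"] = corr_r
            specs.append(MeasureSpec(mid, variant, p_thresh=p_thresh, **kw))
    return specs


@dataclass(frozen=True)
class SummaryValue:
    """One extracted value; ``missing`` when the selection came out empty."""

    value: float
    missing: bool = False
    n_voxels_used: int = 0

    @classmethod
    def none(cls) -> "SummaryValue":
        return cls(value=float("nan"), missing=True, n_voxels_used=0)


# ---------------------------------------------------------------------------
# selection helpers

def _check(flm: SubjectFirstLevel, roi: ROIMask) -> None:
    if flm.grid != roi.grid:
        raise GridMismatchError("map and ROI grids differ")
    if roi.is_empty:
        raise ValueError("ROI is empty")


def _masked_t(flm: SubjectFirstLevel, mask: np.ndarray) -> np.ndarray:
    """t map with non-members (and NaNs) set to -inf so argmax/sort ignore them."""
    t = np.where(mask, flm.tmap.data, -np.inf)
    return np.where(np.isnan(t), -np.inf, t)


def _candidate_mask(
    flm: SubjectFirstLevel, roi: ROIMask, variant: str, p_thresh: float
) -> np.ndarray:
    """ROI voxels (A) or suprathreshold ROI voxels (B)."""
    if variant == "A":
        return roi.data
    return activation_mask(flm, roi, p_thresh).data


def _mean_beta(flm: SubjectFirstLevel, mask: np.ndarray) -> SummaryValue:
    n = int(mask.sum())
    if n == 0:
        return SummaryValue.none()
    return SummaryValue(float(flm.beta.data[mask].mean()), n_voxels_used=n)


def find_peak(flm: SubjectFirstLevel, roi: ROIMask) -> tuple[int, int, int]:
    """Voxel with the maximum t inside the ROI.

    Ties are broken toward the lexicographically smallest (x, y, z) index
    (C-order argmax), so peak finding is deterministic.
    """
    _check(flm, roi)
    t = _masked_t(flm, roi.data)
    flat = int(np.argmax(t))
    if t.ravel()[flat] == -np.inf:
        raise ValueError("ROI contains no finite t values")
    return tuple(int(i) for i in np.unravel_index(flat, t.shape))


# ---------------------------------------------------------------------------
# measures 1-2

def central_summary(
    flm: SubjectFirstLevel,
    roi: ROIMask,
    stat: str = "mean",
    variant: str = "A",
    p_thresh: float = 0.05,
) -> SummaryValue:
    """Measures 1 (mean) and 2 (median) of beta over the selected voxels."""
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    _check(flm, roi)
    mask = _candidate_mask(flm, roi, variant, p_thresh)
    n = int(mask.sum())
    if n == 0:
        return SummaryValue.none()
    values = flm.beta.data[mask]
    agg = values.mean() if stat == "mean" else np.median(values)
    return SummaryValue(float(agg), n_voxels_used=n)


# ---------------------------------------------------------------------------
# measure 3

def eigen_weighted_mean(
    flm: SubjectFirstLevel,
    roi: ROIMask,
    variant: str = "A",
    p_thresh: float = 0.05,
) -> SummaryValue:
    """Measure 3: beta mean weighted by the first eigenimage of the ROI series.

    The selected voxels' timecourses are mean-centered in time and decomposed
    by SVD of the T x V matrix; the weights are the first right singular
    vector (the spatial pattern carrying most variance-covariance), sign-fixed
    so their sum is positive, and the value is ``sum(w*beta) / sum(w)``.
    """
    _check(flm, roi)
    if flm.series is None:
        raise ValueError("measure 3 needs the subject's time series")
    if flm.series.shape[-1] < 2:
        raise ValueError("need at least 2 timepoints for the SVD")
    mask = _candidate_mask(flm, roi, variant, p_thresh)
    n = int(mask.sum())
    if n == 0:
        return SummaryValue.none()
    M = flm.series[mask]  # V x T
    M = (M - M.mean(axis=1, keepdims=True)).T  # T x V, centered in time
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    w = vt[0]
    if w.sum() < 0:
        w = -w
    denom = w.sum()
    if denom == 0:  # pathological flat pattern; fall back to plain mean
        return _mean_beta(flm, mask)
    value = float(np.dot(w, flm.beta.data[mask]) / denom)
    return SummaryValue(value, n_voxels_used=n)


# ---------------------------------------------------------------------------
# measure 4

def top_percentile_mean(
    flm: SubjectFirstLevel,
    roi: ROIMask,
    q: float,
    variant: str = "A",
    p_thresh: float = 0.05,
) -> SummaryValue:
    """Measure 4: mean beta of the top-``q``-percent-by-t candidate voxels.

    Keeps ``ceil(q/100 * m)`` voxels of the m candidates (never 0 for a
    nonempty candidate set); t ties at the cut resolved lexicographically.
    """
    if not (0 < q <= 100):
        raise ValueError("q must be in (0, 100]")
    _check(flm, roi)
    mask = _candidate_mask(flm, roi, variant, p_thresh)
    m = int(mask.sum())
    if m == 0:
        return SummaryValue.none()
    k = math.ceil(q / 100.0 * m)
    t = _masked_t(flm, mask).ravel()
    # stable sort on -t keeps ascending flat (lexicographic) order within ties
    order = np.argsort(-t, kind="stable")[:k]
    keep = np.zeros(t.shape, dtype=bool)
    keep[order] = True
    return _mean_beta(flm, keep.reshape(mask.shape))


# ---------------------------------------------------------------------------
# measure 6

def top_n_contiguous_mean(
    flm: SubjectFirstLevel, roi: ROIMask, n: int
) -> SummaryValue:
    """Measure 6: greedy best-first growth of a 26-connected set from the peak.

    Starting at the ROI peak, repeatedly add the highest-t voxel among the
    26-connected ROI neighbors of the current set until it holds
    ``min(n, |roi|)`` voxels (or the peak's component is exhausted); the value
    is the mean beta of the grown set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check(flm, roi)
    peak = find_peak(flm, roi)
    t = _masked_t(flm, roi.data)
    shape = t.shape
    target = min(n, roi.n_voxels)

    in_set = np.zeros(shape, dtype=bool)
    in_set[peak] = True
    # frontier: ROI voxels adjacent to the set, not yet members
    frontier: dict[tuple[int, int, int], float] = {}

    def _add_neighbors(idx: tuple[int, int, int]) -> None:
        x, y, z = idx
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    nb = (x + dx, y + dy, z + dz)
                    if (
                        0 <= nb[0] < shape[0]
                        and 0 <= nb[1] < shape[1]
                        and 0 <= nb[2] < shape[2]
                        and roi.data[nb]
                        and not in_set[nb]
                    ):
                        frontier[nb] = t[nb]

    _add_neighbors(peak)
    while int(in_set.sum()) < target and frontier:
        # highest t wins; ties toward the lexicographically smallest index
        best = min(frontier, key=lambda idx: (-frontier[idx], idx))
        del frontier[best]
        in_set[best] = True
        _add_neighbors(best)
    return _mean_beta(flm, in_set)


# ---------------------------------------------------------------------------
# measure 7

def peak_sphere_mean(
    flm: SubjectFirstLevel,
    roi: ROIMask,
    radius_mm: float,
    variant: str = "A",
    p_thresh: float = 0.05,
) -> SummaryValue:
    """Measure 7: mean beta within a sphere around the ROI peak.

    The sphere is restricted to the ROI (outside-ROI voxels would contaminate
    the summary); variant B further intersects with the activation mask.
    """
    _check(flm, roi)
    peak = find_peak(flm, roi)
    center_mm = roi.grid.ijk_to_mm(peak)
    sphere = sphere_roi(center_mm, radius_mm, roi.grid)
    mask = sphere.data & _candidate_mask(flm, roi, variant, p_thresh)
    return _mean_beta(flm, mask)


# ---------------------------------------------------------------------------
# measure 8

def peak_correlated_mean(
    flm: SubjectFirstLevel,
    roi: ROIMask,
    corr_r: float,
    variant: str = "A",
    p_thresh: float = 0.05,
) -> SummaryValue:
    """Measure 8: mean beta of voxels correlated with and connected to the peak.

    Pearson correlation of each candidate timecourse with the peak voxel's
    timecourse; candidates with r >= ``corr_r`` are kept, then reduced to the
    26-connected component containing the peak ("clustered together with the
    peak").  Zero-variance timecourses count as correlation 0.
    """
    _check(flm, roi)
    if flm.series is None:
        raise ValueError("measure 8 needs the subject's time series")
    mask = _candidate_mask(flm, roi, variant, p_thresh)
    if not mask.any():
        return SummaryValue.none()
    peak = find_peak(flm, roi)  # the max-t voxel is suprathreshold whenever any is

    series = flm.series[mask]  # V x T
    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ref = flm.series[peak]
    ref = ref - ref.mean()
    ref_norm = np.linalg.norm(ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = centered @ ref / np.where(norms > 0, norms, 1.0) / (
            ref_norm if ref_norm > 0 else 1.0
        )
    corr = np.where((norms > 0) & (ref_norm > 0), corr, 0.0)

    keep = np.zeros(mask.shape, dtype=bool)
    keep[mask] = corr >= corr_r
    if ref_norm > 0:
        keep[peak] = True  # self-correlation is 1 by definition
    if not keep[peak]:
        return SummaryValue.none()
    labels, _ = ndimage.label(keep, structure=_STRUCT_26)
    component = labels == labels[peak]
    return _mean_beta(flm, component)


# ---------------------------------------------------------------------------
# measures 9-10

def _peak_cluster(
    flm: SubjectFirstLevel, roi: ROIMask, p_thresh: float
) -> np.ndarray | None:
    """Suprathreshold 26-connected cluster containing the ROI peak, or None."""
    _check(flm, roi)
    supra = activation_mask(flm, roi, p_thresh).data
    if not supra.any():
        return None
    peak = find_peak(flm, roi)  # global max t, necessarily suprathreshold here
    labels, _ = ndimage.label(supra, structure=_STRUCT_26)
    return labels == labels[peak]


def peak_cluster_mean(
    flm: SubjectFirstLevel, roi: ROIMask, p_thresh: float = 0.05
) -> SummaryValue:
    """Measure 9: mean beta of the suprathreshold cluster containing the peak.

    No maximum cluster size; if no voxel is suprathreshold the subject's
    value is missing.
    """
    cluster = _peak_cluster(flm, roi, p_thresh)
    if cluster is None:
        return SummaryValue.none()
    return _mean_beta(flm, cluster)


def peak_cluster_extent(
    flm: SubjectFirstLevel, roi: ROIMask, p_thresh: float = 0.05
) -> SummaryValue:
    """Measure 10: voxel count of the suprathreshold cluster with the peak."""
    cluster = _peak_cluster(flm, roi, p_thresh)
    if cluster is None:
        return SummaryValue.none()
    n = int(cluster.sum())
    return SummaryValue(float(n), n_voxels_used=n)


# ---------------------------------------------------------------------------
# dispatch + cohort extraction

def extract_measure(
    flm: SubjectFirstLevel, roi: ROIMask, spec: MeasureSpec
) -> SummaryValue:
    """Apply one :class:`MeasureSpec` to one subject."""
    mid, var, p = spec.measure_id, spec.variant, spec.p_thresh
    if mid == 1:
        return central_summary(flm, roi, "mean", var, p)
    if mid == 2:
        return central_summary(flm, roi, "median", var, p)
    if mid == 3:
        return eigen_weighted_mean(flm, roi, var, p)
    if mid == 4:
        return top_percentile_mean(flm, roi, spec.q, var, p)
    if mid == 5:
        peak = find_peak(flm, roi)
        return SummaryValue(float(flm.beta.data[peak]), n_voxels_used=1)
    if mid == 6:
        return top_n_contiguous_mean(flm, roi, spec.n)
    if mid == 7:
        return peak_sphere_mean(flm, roi, spec.radius_mm, var, p)
    if mid == 8:
        return peak_correlated_mean(flm, roi, spec.corr_r, var, p)
    if mid == 9:
        return peak_cluster_mean(flm, roi, p)
    if mid == 10:
        return peak_cluster_extent(flm, roi, p)
    raise ValueError(f"unknown measure id {mid}")


def extract_all(
    subjects: Sequence[SubjectFirstLevel],
    roi: ROIMask,
    specs: Iterable[MeasureSpec],
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per subject, one column per measure spec; NaN marks missing.

    ``meta`` (optional) supplies identifier/covariate columns and must align
    with ``subjects`` row for row; otherwise a bare ``subject_id`` column is
    generated.
    """
    specs = list(specs)
    for flm in subjects:
        if flm.grid != roi.grid:
            raise GridMismatchError("all subjects must share the ROI grid")
    if meta is None:
        meta = pd.DataFrame({"subject_id": [f"sub_{i:03d}" for i in range(len(subjects))]})
    if len(meta) != len(subjects):
        raise ValueError("meta must have one row per subject")

    columns = {spec.name: np.full(len(subjects), np.nan) for spec in specs}
    for i, flm in enumerate(subjects):
        for spec in specs:
            sv = extract_measure(flm, roi, spec)
            if not sv.missing:
                columns[spec.name][i] = sv.value
    out = meta.reset_index(drop=True).copy()
    for name, values in columns.items():
        out[name] = values
    return out
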