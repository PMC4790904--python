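"""NIfTI and CSV round trips for maps, series, cohorts and peak tables."""

from __future__ import annotations

import dataclasses

import nibabel as nib
import numpy as np
import pandas as pd

from .firstlevel import DesignMatrix
from .grid import GridMismatchError, ScalarMap, VolumeGrid
from .simulate import SubjectTruth

__all__ = [
    "save_map",
    "load_map",
    "save_series",
    "load_series",
    "save_design",
    "load_design",
    "truths_to_frame",
    "save_peaks",
    "load_peaks",
]


def save_map(smap: ScalarMap, path) -> None:
    nib.save(nib.Nifti1Image(smap.data.astype(np.float64), smap.grid.affine), str(path))


def load_map(path, expected_grid: VolumeGrid | None = None) -> ScalarMap:
    img = nib.load(str(path))
    grid = VolumeGrid.from_affine(img.affine, img.shape)
    if expected_grid is not None and grid != expected_grid:
        raise GridMismatchError(f"map grid {grid} != expected {expected_grid}")
    return ScalarMap(grid, np.asanyarray(img.dataobj, dtype=float))


def save_series(series: np.ndarray, grid: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(series, dtype=np.float64), grid.affine), str(path))


def load_series(path, expected_grid: VolumeGrid | None = None) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    grid = VolumeGrid.from_affine(img.affine, img.shape[:3])
    if expected_grid is not None and grid != expected_grid:
        raise GridMismatchError(f"series grid {grid} != expected {expected_grid}")
    return np.asanyarray(img.dataobj, dtype=float), grid


def save_design(design: DesignMatrix, path) -> None:
    df = pd.DataFrame(design.X, columns=list(design.names))
    df.attrs["contrast"] = list(design.contrast)
    # store the contrast as an extra header-comment-free row-0-safe column block:
    # first row after the header holds the contrast, marked in an extra column.
    out = df.copy()
    out.insert(0, "_row", "data")
    contrast_row = pd.DataFrame(
        [["contrast", *design.contrast]], columns=["_row", *design.names]
    )
    pd.concat([contrast_row, out], ignore_index=True).to_csv(path, index=False)


def load_design(path) -> DesignMatrix:
    raw = pd.read_csv(path)
    names = [c for c in raw.columns if c != "_row"]
    contrast = raw.loc[raw["_row"] == "contrast", names].to_numpy(dtype=float)[0]
    X = raw.loc[raw["_row"] == "data", names].to_numpy(dtype=float)
    return DesignMatrix(X, contrast, names=tuple(names))


def truths_to_frame(truths) -> pd.DataFrame:
    """Subject ground truth / covariate table (one row per subject)."""
    rows = []
    for t in truths:
        d = dataclasses.asdict(t)
        px, py, pz = d.pop("peak_ijk")
        d.update(peak_i=px, peak_j=py, peak_k=pz)
        rows.append(d)
    return pd.DataFrame(rows)


def save_peaks(peaks_mm: np.ndarray, labels, subject_ids, path) -> None:
    pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": labels,
            "x_mm": np.asarray(peaks_mm)[:, 0],
            "y_mm": np.asarray(peaks_mm)[:, 1],
            "z_mm": np.asarray(peaks_mm)[:, 2],
        }
    ).to_csv(path, index=False)


def load_peaks(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        df["group"].to_numpy(),
        df["subject_id"].to_numpy(),
    )
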