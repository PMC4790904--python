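"""ROI definition: spheres, task-activated joint clusters, mask file I/O.

Three ROI strategies are supported, mirroring common practice: a literature
sphere around published coordinates, a user-supplied anatomical mask, and a
task-activated ROI built from group one-sample t maps inside the anatomical
mask, familywise-error corrected by Bonferroni over the mask's voxels.
"""

from __future__ import annotations

from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import stats as sps

from .firstlevel import SubjectFirstLevel
from .grid import GridMismatchError, ROIMask, VolumeGrid

__all__ = [
    "sphere_roi",
    "task_activated_roi",
    "load_mask",
    "save_mask",
    "EmptyROIError",
]


class EmptyROIError(ValueError):
    """A derived ROI came out empty where downstream steps need voxels."""


def sphere_roi(center_mm, radius_mm: float, grid: VolumeGrid) -> ROIMask:
    """Voxels whose center lies within ``radius_mm`` of ``center_mm``.

    Membership is by voxel-center distance (no partial-volume weighting).
    Radius 0 selects exactly the voxel containing the center.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if not grid.contains_mm(center_mm):
        raise ValueError(f"sphere center {center_mm} lies outside the grid")
    centers = grid.voxel_centers_mm()
    d2 = np.sum((centers - np.asarray(center_mm, dtype=float)) ** 2, axis=-1)
    data = d2 <= float(radius_mm) ** 2
    if not data.any():  # radius 0 between voxel centers: take the nearest voxel
        ijk = grid.clip_ijk(grid.mm_to_ijk(center_mm, round=True))
        data[tuple(ijk)] = True
    return ROIMask(grid, data)


def task_activated_roi(
    group_maps: Sequence[Sequence[SubjectFirstLevel]],
    anatomical: ROIMask,
    alpha: float = 0.05,
    joint: str = "union",
) -> ROIMask:
    """Task-activated ROI: joint suprathreshold map of group one-sample t tests.

    Per group, a voxel-wise one-sample t across the subjects' beta maps is
    thresholded (one-sided, positive) at ``alpha`` familywise-error corrected
    by Bonferroni over the anatomical mask's voxel count.  The joint map is
    the union of the per-group suprathreshold masks by default
    (``joint="intersection"`` for the stricter reading).
    """
    if joint not in ("union", "intersection"):
        raise ValueError("joint must be 'union' or 'intersection'")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if not group_maps:
        raise ValueError("need at least one group")

    m = anatomical.n_voxels
    joint_data: np.ndarray | None = None
    for flms in group_maps:
        if len(flms) < 3:
            raise ValueError("each group needs >= 3 subjects for a one-sample t")
        for flm in flms:
            if flm.grid != anatomical.grid:
                raise GridMismatchError("subject map grid differs from mask grid")
        betas = np.stack([flm.beta.data for flm in flms], axis=0)
        n = betas.shape[0]
        mean = betas.mean(axis=0)
        sd = betas.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (np.where(sd > 0, sd, 1.0) / np.sqrt(n))
            # zero across-subject SD: sign(mean) * inf sentinel, 0 stays 0
            t = np.where(sd > 0, t, np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0)))
        # Bonferroni within the anatomical mask; alpha=1 keeps every voxel
        p_vox = min(alpha / m, 1.0) if alpha < 1.0 else 1.0
        tcrit = sps.t.ppf(1.0 - p_vox, n - 1)
        supra = anatomical.data & (t > tcrit)
        if joint_data is None:
            joint_data = supra
        elif joint == "union":
            joint_data = joint_data | supra
        else:
            joint_data = joint_data & supra

    assert joint_data is not None
    if not joint_data.any():
        raise EmptyROIError("task-activated joint map is empty at this alpha")
    return ROIMask(anatomical.grid, joint_data)


def save_mask(mask: ROIMask, path) -> None:
    """Write a mask as a NIfTI-1 volume of 0/1 bytes with the grid affine."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def load_mask(path, expected_grid: VolumeGrid | None = None) -> ROIMask:
    """Load a binary mask; nonzero voxels are members.

    An all-false file loads with the empty flag set.  If ``expected_grid`` is
    given, a grid mismatch raises.
    """
    img = nib.load(str(path))
    grid = VolumeGrid.from_affine(img.affine, img.shape)
    if expected_grid is not None and grid != expected_grid:
        raise GridMismatchError(
            f"mask grid {grid} does not match expected grid {expected_grid}"
        )
    data = np.asanyarray(img.dataobj) != 0
    return ROIMask(grid, data, allow_empty=True)
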