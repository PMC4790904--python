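"""Extract all 16 summary-measure variants under the three ROI strategies.

ROIs: (a) a 10-mm sphere at the nominal activation center, (b) a large
box "anatomical" ROI, (c) the task-activated joint ROI (per-group one-sample
t maps, Bonferroni-corrected within the anatomical box, union across groups).
One CSV per ROI type in results/, one row per subject, one column per
measure; empty cells are missing values.
"""

import pathlib

import numpy as np
import pandas as pd

from roisummary import (
    ROIMask,
    SimulationConfig,
    SubjectFirstLevel,
    default_measure_specs,
    extract_all,
    sphere_roi,
    task_activated_roi,
)
from roisummary.io import load_map, load_series
from roisummary.roi import save_mask

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def load_cohort():
    config = SimulationConfig.from_yaml(RESULTS / "cohort_config.yaml")
    meta = pd.read_csv(RESULTS / "cohort_subjects.csv")
    df = config.n_timepoints - 2
    subjects = []
    for sid in meta["subject_id"]:
        beta = load_map(SCRATCH / f"{sid}_beta.nii", expected_grid=config.grid)
        tmap = load_map(SCRATCH / f"{sid}_t.nii", expected_grid=config.grid)
        series, _ = load_series(SCRATCH / f"{sid}_series.nii", expected_grid=config.grid)
        subjects.append(SubjectFirstLevel(beta, tmap, df=df, series=series))
    return config, meta, subjects


def build_rois(config, meta, subjects):
    grid = config.grid
    sphere = sphere_roi(config.nominal_center_mm, 10.0, grid)
    box = np.zeros(grid.shape, dtype=bool)
    box[1:11, 1:11, 1:11] = True
    anatomical = ROIMask(grid, box)
    groups = [
        [s for s, g in zip(subjects, meta["group"]) if g == label]
        for label in meta["group"].unique()
    ]
    activated = task_activated_roi(groups, anatomical, alpha=0.05)
    return {"sphere": sphere, "anatomical": anatomical, "task_activated": activated}


def main() -> None:
    config, meta, subjects = load_cohort()
    rois = build_rois(config, meta, subjects)
    specs = default_measure_specs()
    for name, roi in rois.items():
        table = extract_all(subjects, roi, specs, meta=meta)
        out = RESULTS / f"measures_{name}.csv"
        table.to_csv(out, index=False)
        n_missing = int(table[[s.name for s in specs]].isna().sum().sum())
        print(
            f"{name:>14}: {roi.n_voxels:4d} voxels, "
            f"{len(table)} subjects x {len(specs)} measures, "
            f"{n_missing} missing cells -> {out.name}"
        )
        save_mask(roi, ROOT / "scratch" / f"roi_{name}.nii")


if __name__ == "__main__":
    main()
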