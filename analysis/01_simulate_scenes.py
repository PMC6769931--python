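#!/usr/bin/env python
"""Generate the synthetic reference datasets used by the downstream
analysis steps and summarise their ground truth.

Writes per-object ground truth for 20 spheroid scenes, true time-lapse path
statistics, and the cytometry condition grid's expected intensities to
``results/``. Run from the repository root: ``python analysis/01_simulate_scenes.py``.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spheromet import (
    SpheroidScene,
    generate_cytometry_events,
    generate_spheroid_image,
    generate_timelapse,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0):
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for i in range(20):
        scene = SpheroidScene(seed=seed + i)
        _, gt = generate_spheroid_image(scene)
        for (x, y), label, d in zip(gt.matrix_cell_positions,
                                    gt.matrix_cell_labels, gt.true_distances):
            rows.append(dict(scene=i, x_um=x, y_um=y, label=label,
                             distance_um=d))
    objects = pd.DataFrame(rows)
    objects.to_csv(RESULTS / "ground_truth_objects.csv", index=False)
    by_label = objects.groupby("label").size()
    print(f"20 spheroid scenes: {len(objects)} objects "
          f"({by_label.to_dict()}), distances "
          f"{objects.distance_um.min():.1f}-{objects.distance_um.max():.1f} um")

    _, gt = generate_timelapse(200, 13, 5.0, "straight", seed=seed)
    acc = [float(np.hypot(*np.diff(p, axis=0).T).sum()) for p in gt.track_paths]
    print(f"straight time-lapse: 200 paths, accumulated length "
          f"{np.unique(np.round(acc, 9))} um (12 steps x 5 um)")

    _, gt = generate_cytometry_events(10_000, 500.0, 300.0, seed=seed)
    exp = pd.DataFrame(
        [{"stained": s, "treatment": t, **v}
         for (s, t), v in gt.expected_mfi.items()])
    exp.to_csv(RESULTS / "cytometry_expected_mfi.csv", index=False)
    print("cytometry grid expected pecy7 MFIs:")
    print(exp[["stained", "treatment", "pecy7"]].to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
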