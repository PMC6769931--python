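#!/usr/bin/env python
"""Detect, classify and localise matrix-cells on 20 seeded scenes, with and
without camera noise, and compare against generator truth.

Finding: at zero noise the pipeline recovers every count and label exactly
(33 objects = 20 live + 10 dead + 3 conglomerates per scene, viability
66.7%); at signal-to-noise 5 the counts stay within a few objects per
scene and the mean matrix-cell distance within one pixel. Writes
``results/outgrowth_recovery.csv``.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spheromet import SpheroidScene, analyze_outgrowth, generate_spheroid_image
from spheromet.segmentation import segment_image

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0):
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for noise_sd in (0.0, 120.0):  # 120 a.u. = SNR 5 for 600 a.u. cells
        for i in range(20):
            scene = SpheroidScene(seed=seed + i, noise_sd=noise_sd)
            img, gt = generate_spheroid_image(scene)
            mask = segment_image(img)
            _, s = analyze_outgrowth(img, mask)
            true_live = [d for d, l in zip(gt.true_distances,
                                           gt.matrix_cell_labels) if l == "live"]
            rows.append(dict(
                scene=i, noise_sd=noise_sd, n_detected=s.n_detected,
                n_excluded=s.n_conglomerates_excluded, n_live=s.n_live,
                n_dead=s.n_dead, pct_viable=s.pct_viable,
                mean_distance_live_um=s.mean_distance_live,
                true_mean_distance_live_um=float(np.mean(true_live)),
            ))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "outgrowth_recovery.csv", index=False)

    for noise_sd, sub in df.groupby("noise_sd"):
        exact = ((sub.n_detected == 33) & (sub.n_live == 20)
                 & (sub.n_dead == 10) & (sub.n_excluded == 3)).mean()
        dist_err = (sub.mean_distance_live_um
                    - sub.true_mean_distance_live_um).abs().max()
        print(f"noise_sd={noise_sd:5.0f}: {exact:.0%} of scenes with exact "
              f"counts; max |mean distance error| {dist_err:.2f} um "
              f"(pixel = 2 um)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
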