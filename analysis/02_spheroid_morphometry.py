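#!/usr/bin/env python
"""Segment synthetic spheroids and measure symmetry, threshold compactness,
profile and area across controlled shape sweeps.

Findings this script demonstrates: the moment-based symmetry score is 1 for
a rotationally symmetric spheroid and falls monotonically as border lobes
grow; compactness tracks the generated core extent quadratically (area
ratio); the profile equals the analytic border-to-core distance. Writes
``results/morphometry_sweeps.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from spheromet import SpheroidScene, generate_spheroid_image, morphometry
from spheromet.segmentation import segment_image

RESULTS = Path(__file__).resolve().parents[1] / "results"


def measure(scene):
    img, gt = generate_spheroid_image(scene)
    mask = segment_image(img)
    res = morphometry(img["dil"], mask)
    inter = (mask.mask & gt.spheroid_mask).sum()
    dice = 2 * inter / (mask.mask.sum() + gt.spheroid_mask.sum())
    return res, dice


def main(seed: int = 0):
    RESULTS.mkdir(exist_ok=True)
    rows = []

    for amp in (0.0, 0.1, 0.2, 0.3):
        scene = SpheroidScene(seed=seed, n_matrix_cells=0, n_conglomerates=0,
                              spheroid_radius=150.0, lobe_amplitude=amp)
        res, dice = measure(scene)
        rows.append(dict(sweep="lobe_amplitude", value=amp, dice=dice,
                         symmetry=res.symmetry,
                         compactness_norm=res.compactness_norm,
                         profile_um=res.profile, area_um2=res.area))
    syms = [r["symmetry"] for r in rows]
    print("symmetry vs lobe amplitude 0/.1/.2/.3:",
          " > ".join(f"{s:.4f}" for s in syms),
          "(strictly decreasing)" if all(a > b for a, b in zip(syms, syms[1:]))
          else "(NOT monotone!)")

    for cf in (0.3, 0.5, 0.7):
        scene = SpheroidScene(seed=seed + 1, n_matrix_cells=0,
                              n_conglomerates=0, spheroid_radius=200.0,
                              core_fraction=cf)
        res, dice = measure(scene)
        rows.append(dict(sweep="core_fraction", value=cf, dice=dice,
                         symmetry=res.symmetry,
                         compactness_norm=res.compactness_norm,
                         profile_um=res.profile, area_um2=res.area))
        print(f"core radius fraction {cf}: compactness_norm "
              f"{res.compactness_norm:.4f} (analytic {cf**2:.4f}), profile "
              f"{res.profile:.1f} um (analytic {200 * (1 - cf):.0f} um)")

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "morphometry_sweeps.csv", index=False)
    print(f"wrote {len(df)} rows to results/morphometry_sweeps.csv; "
          f"all segmentations Dice >= {df.dice.min():.4f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
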