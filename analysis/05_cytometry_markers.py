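#!/usr/bin/env python
"""Quantify adhesion-marker expression on simulated event tables with
treatment-matched autofluorescence correction.

Finding: because the unstained control of the *same* treatment condition is
subtracted, the corrected MFI recovers the true stain signal (500 a.u.)
regardless of how strongly treatment shifts autofluorescence (0/300/600
a.u.); a simulated two-fold upregulation yields a fold change of 2; and
DAPI-based floater enumeration is exact. Writes
``results/cytometry_markers.csv``.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spheromet import (
    corrected_mfi,
    count_floaters,
    fold_change,
    gate_events,
    generate_cytometry_events,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def gated(table, stained, treatment):
    sub, _ = gate_events(table[(table.stained == stained)
                               & (table.treatment == treatment)])
    return sub


def main(seed: int = 0):
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for i, shift in enumerate((0.0, 300.0, 600.0)):
        table, _ = generate_cytometry_events(10_000, 500.0, shift,
                                             seed=seed + i)
        for treatment in ("untreated", "plasma"):
            res = corrected_mfi(gated(table, True, treatment),
                                gated(table, False, treatment), "pecy7")
            rows.append(dict(autofluorescence_shift=shift,
                             treatment=treatment,
                             mfi_stained=res.mfi_stained,
                             mfi_unstained=res.mfi_unstained_matched,
                             corrected_mfi=res.corrected_mfi))
        print(f"shift {shift:5.0f}: corrected MFI "
              f"{rows[-1]['corrected_mfi']:.1f} (true stain 500)")

    control, _ = generate_cytometry_events(10_000, 500.0, 300.0, seed=seed + 10)
    treated, _ = generate_cytometry_events(10_000, 1000.0, 300.0, seed=seed + 11)
    fc = fold_change(
        corrected_mfi(gated(treated, True, "plasma"),
                      gated(treated, False, "plasma"), "pecy7"),
        corrected_mfi(gated(control, True, "untreated"),
                      gated(control, False, "untreated"), "pecy7"))
    print(f"fold change for simulated 2x upregulation: "
          f"{fc.fold_change_vs_control:.3f}")

    table, _ = generate_cytometry_events(500, 500.0, 300.0,
                                         dapi_positive_fraction=0.8,
                                         doublet_fraction=0.0, seed=seed + 12)
    n = count_floaters(table[(~table.stained)
                             & (table.treatment == "untreated")], 1000.0)
    print(f"floaters counted: {n} (constructed: 400 of 500 events nucleated)")

    rows.append(dict(autofluorescence_shift=np.nan, treatment="fold_change",
                     corrected_mfi=fc.fold_change_vs_control))
    rows.append(dict(autofluorescence_shift=np.nan, treatment="floaters",
                     corrected_mfi=float(n)))
    pd.DataFrame(rows).to_csv(RESULTS / "cytometry_markers.csv", index=False)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
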