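"""Event-level cytometry quantification: sequential gating, mean
fluorescence intensity (MFI), treatment-matched autofluorescence
subtraction, fold change to untreated control, and absolute floater counts.

The correction rule is the study design's core: plasma exposure itself
raises cellular autofluorescence, so the unstained-control MFI subtracted
from a stained sample must come from the *same treatment condition*
(stained untreated − unstained untreated; stained treated − unstained
treated). ``corrected_mfi`` enforces that matching and raises on a
treatment mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GateConfig",
    "MarkerResult",
    "gate_events",
    "corrected_mfi",
    "fold_change",
    "count_floaters",
]

REQUIRED_CHANNELS = ("fsc_a", "fsc_h", "ssc_a", "dapi")


@dataclass
class GateConfig:
    """Sequential gate parameters.

    ``singlet_band`` bounds the fsc_h/fsc_a ratio (doublets fall below it);
    ``scatter`` is a rectangle (fsc_a_min, fsc_a_max, ssc_a_min, ssc_a_max);
    ``dapi_cutoff`` separates DAPI⁻ (viable) from DAPI⁺ events.
    """

    singlet_band: tuple[float, float] = (0.85, 1.10)
    scatter: tuple[float, float, float, float] = (0.0, np.inf, 0.0, np.inf)
    dapi_cutoff: float = 1000.0


@dataclass
class MarkerResult:
    marker: str
    treatment: str
    mfi_stained: float
    mfi_unstained_matched: float
    corrected_mfi: float        # mfi_stained − mfi_unstained_matched
    fold_change_vs_control: float | None = None
    n_stained: int = 0
    n_unstained: int = 0


def gate_events(table: pd.DataFrame,
                config: GateConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Apply singlet → scatter → DAPI⁻ gates; return (subset, per-gate counts)."""
    config = config or GateConfig()
    missing = [c for c in REQUIRED_CHANNELS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required channel(s): {', '.join(missing)}")
    counts = {"input": len(table)}
    ratio = table["fsc_h"] / table["fsc_a"]
    lo, hi = config.singlet_band
    sub = table[(ratio >= lo) & (ratio <= hi)]
    counts["singlets"] = len(sub)
    fa0, fa1, sa0, sa1 = config.scatter
    sub = sub[(sub["fsc_a"] >= fa0) & (sub["fsc_a"] <= fa1)
              & (sub["ssc_a"] >= sa0) & (sub["ssc_a"] <= sa1)]
    counts["scatter"] = len(sub)
    sub = sub[sub["dapi"] <= config.dapi_cutoff]
    counts["dapi_negative"] = len(sub)
    return sub, counts


def _mfi(values: np.ndarray, geometric: bool) -> float:
    if geometric:
        vals = values[values > 0]
        return float(np.exp(np.mean(np.log(vals)))) if len(vals) else float("nan")
    return float(np.mean(values))


def corrected_mfi(stained: pd.DataFrame, unstained: pd.DataFrame,
                  channel: str, geometric: bool = False) -> MarkerResult:
    """MFI of *channel* on gated events, autofluorescence-corrected.

    Both tables must carry the same single treatment label; correction is
    ``MFI(stained) − MFI(unstained)``. MFI is the arithmetic mean by
    default (``geometric=True`` switches to the geometric mean). Negative
    corrected values are reported as-is — clipping would bias fold changes.
    """
    for name, tab in (("stained", stained), ("unstained", unstained)):
        if channel not in tab.columns:
            raise ValueError(f"channel {channel!r} missing from {name} table")
    t_s = set(stained["treatment"].unique()) if "treatment" in stained else set()
    t_u = set(unstained["treatment"].unique()) if "treatment" in unstained else set()
    if len(t_s) != 1 or len(t_u) != 1 or t_s != t_u:
        raise ValueError(
            "treatment mismatch: autofluorescence must be subtracted from the "
            f"stained signal of the same treatment (stained={sorted(t_s)}, "
            f"unstained={sorted(t_u)})")
    mfi_s = _mfi(stained[channel].to_numpy(float), geometric)
    mfi_u = _mfi(unstained[channel].to_numpy(float), geometric)
    return MarkerResult(
        marker=channel,
        treatment=next(iter(t_s)),
        mfi_stained=mfi_s,
        mfi_unstained_matched=mfi_u,
        corrected_mfi=mfi_s - mfi_u,
        n_stained=len(stained),
        n_unstained=len(unstained),
    )


def fold_change(treated: MarkerResult, control: MarkerResult) -> MarkerResult:
    """Fold change of corrected MFI, treated over untreated control.

    Returns a copy of *treated* with ``fold_change_vs_control`` set; a
    non-positive control corrected MFI yields ``None`` (undefined ratio,
    reported as missing with the reason discoverable from the control).
    """
    if treated.marker != control.marker:
        raise ValueError(
            f"marker mismatch: {treated.marker!r} vs {control.marker!r}")
    fc = (treated.corrected_mfi / control.corrected_mfi
          if control.corrected_mfi > 0 else None)
    return MarkerResult(**{**treated.__dict__, "fold_change_vs_control": fc})


def count_floaters(table: pd.DataFrame, dapi_cutoff: float) -> int:
    """Absolute count of nucleated (DAPI > cutoff) events.

    Counting mode deliberately skips the viability DAPI⁻ gate: floaters are
    fixed/permeabilised before acquisition, so every nucleated cell is
    DAPI-positive and the count is the readout.
    """
    if "dapi" not in table.columns:
        raise ValueError("missing required channel(s): dapi")
    return int((table["dapi"].to_numpy(float) > dapi_cutoff).sum())
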