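"""Shared intensity cut-off policies.

Every stage that binarises an intensity image (spheroid detection, matrix-cell
detection, per-frame cell detection, cluster area) accepts the same policy
triple: ``absolute`` (a fixed intensity), ``fraction`` (fraction of the image
maximum — scale-invariant), or ``otsu`` (scikit-image Otsu on the nonzero
support — also scale-invariant).
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

POLICIES = ("absolute", "fraction", "otsu")


def resolve_cutoff(arr: np.ndarray, policy: str, value: float | None = None) -> float:
    """Return the absolute intensity threshold implied by *policy* on *arr*.

    ``value`` is the policy parameter: the threshold itself for ``absolute``,
    the fraction of max for ``fraction`` (default 0.2); ignored for ``otsu``.
    """
    if policy == "absolute":
        if value is None:
            raise ValueError("absolute policy requires a cutoff value")
        return float(value)
    if policy == "fraction":
        frac = 0.2 if value is None else float(value)
        if not 0 < frac < 1:
            raise ValueError(f"fraction-of-max cutoff must be in (0,1), got {frac}")
        return frac * float(np.max(arr))
    if policy == "otsu":
        flat = np.asarray(arr, dtype=float).ravel()
        if flat.size < 2 or np.ptp(flat) == 0:
            return float(np.max(arr))  # degenerate: nothing below threshold
        return float(threshold_otsu(flat))
    raise ValueError(f"unknown cutoff policy {policy!r}; expected one of {POLICIES}")
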