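"""Spheroid shape and organisation metrics: rotational symmetry, threshold
compactness, and edge profile.

Symmetry is scored from angular moments of the masked intensity mapped onto
the unit disk: Z_nm = Σ ρⁿ e^{−imφ} I(ρ, φ) over mask pixels, for
0 ≤ m ≤ n ≤ max_order with n − m even (the index lattice of a Zernike
basis; the radial part is the monomial ρⁿ). For a rotationally symmetric
intensity every m > 0 moment vanishes, so

    symmetry = 1 − Σ_{m>0} |Z_nm| / Σ_{all} |Z_nm|

is 1 for perfect rotational symmetry, decreases with angular structure, and
is invariant to intensity rescaling.

Threshold compactness relates the high-intensity core (pixels at or above
``core_fraction`` — default 60% — of the in-mask maximum) to the whole
spheroid region: s_body = core area, s_border = spheroid area, both µm²;
the raw score is c = s_body²/s_border (µm², as conventionally printed) and
the normalised score s_body/s_border ∈ [0, 1]. The profile is the mean
shortest Euclidean distance from border pixels to the core — smaller means
a steeper intensity fall-off at the spheroid edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import SpheroidMask

__all__ = [
    "ZernikeConfig",
    "MorphometryResult",
    "symmetry_score",
    "threshold_compactness",
    "profile",
    "morphometry",
]

CLIP_PERCENTILE = 99.9  # hot-pixel guard for the in-mask maximum


@dataclass
class ZernikeConfig:
    max_order_n: int = 8
    radius_mode: str = "enclosing-circle"  # or "equivalent-radius"

    def __post_init__(self):
        if self.max_order_n < 2:
            raise ValueError(f"max_order_n must be >= 2, got {self.max_order_n}")
        if self.radius_mode not in ("enclosing-circle", "equivalent-radius"):
            raise ValueError(f"unknown radius_mode {self.radius_mode!r}")


@dataclass
class MorphometryResult:
    symmetry: float
    compactness_raw: float      # µm²
    compactness_norm: float     # dimensionless in [0, 1]
    profile: float              # µm (NaN when the core is empty)
    area: float                 # µm²
    s_body: float               # µm²
    s_border: float             # µm²
    core_threshold_fraction: float


def _core_mask(intensity: np.ndarray, mask: np.ndarray,
               core_fraction: float) -> np.ndarray:
    vals = intensity[mask]
    peak = float(np.percentile(vals, CLIP_PERCENTILE))
    return mask & (intensity >= core_fraction * peak)


def symmetry_score(intensity: np.ndarray, mask: SpheroidMask,
                   cfg: ZernikeConfig | None = None) -> float:
    """m>0 angular-moment energy ratio; 1 = perfect rotational symmetry."""
    cfg = cfg or ZernikeConfig()
    m_arr = mask.mask
    if m_arr.sum() < 9:
        raise ValueError(f"degenerate mask: area {int(m_arr.sum())} px < 9 px")
    ys, xs = np.nonzero(m_arr)
    cx, cy = mask.centroid
    dx, dy = xs - cx, ys - cy
    r = np.hypot(dx, dy)
    if cfg.radius_mode == "enclosing-circle":
        radius = r.max()
    else:
        radius = np.sqrt(m_arr.sum() / np.pi)
    rho = np.minimum(r / radius, 1.0)
    phi = np.arctan2(dy, dx)
    vals = np.asarray(intensity, dtype=float)[ys, xs]

    total = 0.0
    asym = 0.0
    exp_m = {}
    for n in range(cfg.max_order_n + 1):
        rho_n = rho**n
        for m in range(n % 2, n + 1, 2):  # n − m even
            if m not in exp_m:
                exp_m[m] = np.exp(-1j * m * phi)
            z = abs(np.sum(rho_n * exp_m[m] * vals))
            total += z
            if m > 0:
                asym += z
    if total == 0:
        return 1.0
    return float(np.clip(1.0 - asym / total, 0.0, 1.0))


def threshold_compactness(intensity: np.ndarray, mask: SpheroidMask,
                          core_fraction: float = 0.6):
    """Return ``(compactness_raw, compactness_norm, s_body, s_border)``."""
    if not 0 < core_fraction < 1:
        raise ValueError(f"core_fraction must be in (0, 1), got {core_fraction}")
    if not mask.mask.any():
        raise ValueError("empty spheroid mask")
    px2 = mask.pixel_size**2
    core = _core_mask(np.asarray(intensity, float), mask.mask, core_fraction)
    s_body = float(core.sum()) * px2
    s_border = float(mask.mask.sum()) * px2
    return s_body**2 / s_border, s_body / s_border, s_body, s_border


def profile(intensity: np.ndarray, mask: SpheroidMask,
            core_fraction: float = 0.6) -> float:
    """Mean shortest border→core distance in µm (NaN if the core is empty).

    Computed with an exact Euclidean distance transform of the core
    complement sampled at the border pixels; equals a brute-force
    nearest-core-pixel search to float precision.
    """
    core = _core_mask(np.asarray(intensity, float), mask.mask, core_fraction)
    if not core.any():
        return float("nan")
    dist = ndimage.distance_transform_edt(~core)
    bx = mask.border[:, 0].astype(int)
    by = mask.border[:, 1].astype(int)
    return float(dist[by, bx].mean()) * mask.pixel_size


def morphometry(intensity: np.ndarray, mask: SpheroidMask,
                core_fraction: float = 0.6,
                cfg: ZernikeConfig | None = None) -> MorphometryResult:
    """All shape metrics for one spheroid on one intensity channel."""
    c_raw, c_norm, s_body, s_border = threshold_compactness(
        intensity, mask, core_fraction)
    return MorphometryResult(
        symmetry=symmetry_score(intensity, mask, cfg),
        compactness_raw=c_raw,
        compactness_norm=c_norm,
        profile=profile(intensity, mask, core_fraction),
        area=mask.area,
        s_body=s_body,
        s_border=s_border,
        core_threshold_fraction=core_fraction,
    )
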