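"""Synthetic microscopy scenes, time-lapse sequences, and cytometry event
tables with exact ground truth.

The generators emulate the three acquisition modalities of a spheroid
outgrowth study:

* **Spheroid scenes** — a bright DiL-labeled tumor spheroid whose intensity
  decays toward an (optionally lobed) irregular border, embedded in a dark
  matrix that contains satellite "matrix-cells" at known distances from the
  spheroid border, a configurable fraction of them dead (sytox-green
  positive), plus large autofluorescent conglomerates whose summed DiL
  signal is forced above the conglomerate-exclusion threshold by
  construction. Channels: ``brightfield`` (dark spheroid on a bright
  background), ``dil``, ``sytox``.
* **Time-lapse sequences** — point-spread-like blobs drifting with known
  per-frame paths (straight, fixed-step random walk, or a single shrinking
  cell cluster).
* **Cytometry event tables** — a stained/unstained × treated/untreated
  condition grid in which "treatment" shifts every channel's
  autofluorescence baseline, with log-normal event-level noise.

Every generator is deterministic for a fixed seed and returns a
:class:`GroundTruth` carrying the exact quantities the downstream modules
are supposed to recover.

Intensity scales are chosen so that the study's printed classification
cut-offs are meaningful on synthetic data: a matrix cell's summed DiL
intensity sits near 1.1×10⁴ (well below the 2×10⁵ conglomerate exclusion),
a conglomerate's near 6×10⁵ (well above it); dead cells carry a flat sytox
disk of 8×10³ (above the 3×10³ dead cut-off), live cells 4×10² (below it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .image import MultiChannelImage

__all__ = [
    "SceneConfigError",
    "SpheroidScene",
    "GroundTruth",
    "generate_spheroid_image",
    "generate_timelapse",
    "generate_cytometry_events",
    "radial_profile",
]


class SceneConfigError(ValueError):
    """A scene parameter violates a stated invariant; the message names it."""


# ---------------------------------------------------------------------------
# intensity scales (a.u., loosely 16-bit camera counts)
DIL_PEAK = 1000.0        # spheroid center DiL intensity
BF_BACKGROUND = 1000.0   # brightfield background level
BF_CONTRAST = 600.0      # brightfield attenuation inside the spheroid
CELL_AMP = 600.0         # matrix-cell DiL Gaussian amplitude
CELL_SIGMA = 2.0         # px
CONGLOMERATE_AMP = 3000.0
CONGLOMERATE_SIGMA = 6.0  # px; summed DiL ~6e5, forced above the 2e5 cut-off
SYTOX_DEAD = 8000.0      # flat disk value on dead cells (> 3e3 cut-off)
SYTOX_LIVE = 400.0       # flat disk value on live cells (< 3e3 cut-off)
SYTOX_DISK_RADIUS = 4.0  # px
CORE_PLATEAU = 0.05      # central plateau extent (fraction of border radius)


@dataclass
class SpheroidScene:
    """Parameters of one synthetic spheroid scene.

    ``core_fraction`` is the fraction of the border radius occupied by the
    ≥60%-of-maximum intensity core; ``lobe_amplitude`` perturbs the border
    radius as r(θ) = R·(1 + lobe_amplitude·cos(n_lobes·θ)), giving analytic
    control over rotational symmetry.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 2.0                      # µm / pixel
    spheroid_center: tuple[float, float] | None = None  # (x, y) px; default image center
    spheroid_radius: float = 120.0               # µm
    core_fraction: float = 0.6
    lobe_amplitude: float = 0.0
    n_lobes: int = 3
    n_matrix_cells: int = 30
    matrix_cell_distances: list[float] | None = None  # µm from border
    dead_fraction: float = 1.0 / 3.0
    n_conglomerates: int = 3
    noise_sd: float = 0.0
    intensity_profile: str = "graded"            # 'graded' | 'uniform'
    seed: int = 0

    def center_px(self) -> tuple[float, float]:
        if self.spheroid_center is not None:
            return self.spheroid_center
        h, w = self.image_shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def validate(self) -> None:
        if abs(self.lobe_amplitude) >= 1:
            raise SceneConfigError(
                f"|lobe_amplitude| must be < 1, got {self.lobe_amplitude}"
            )
        h, w = self.image_shape
        cx, cy = self.center_px()
        r_max = self.spheroid_radius / self.pixel_size * (1 + abs(self.lobe_amplitude))
        edge = min(cx, cy, (w - 1) - cx, (h - 1) - cy)
        if r_max > 0.9 * edge:
            raise SceneConfigError(
                "spheroid must fit within image bounds with >=10% margin: "
                f"max radius {r_max:.1f} px vs 0.9*edge distance {0.9 * edge:.1f} px"
            )
        if not 0 <= self.dead_fraction <= 1:
            raise SceneConfigError(
                f"dead_fraction must be in [0, 1], got {self.dead_fraction}"
            )
        if not 0 < self.core_fraction < 1:
            raise SceneConfigError(
                f"core_fraction must be in (0, 1), got {self.core_fraction}"
            )
        if self.matrix_cell_distances is not None:
            if len(self.matrix_cell_distances) != self.n_matrix_cells:
                raise SceneConfigError(
                    "matrix_cell_distances length "
                    f"{len(self.matrix_cell_distances)} != n_matrix_cells "
                    f"{self.n_matrix_cells}"
                )
            if any(d < 0 for d in self.matrix_cell_distances):
                raise SceneConfigError("matrix cell distances must be nonnegative")
        if self.noise_sd < 0:
            raise SceneConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.intensity_profile not in ("graded", "uniform"):
            raise SceneConfigError(
                f"intensity_profile must be 'graded' or 'uniform', got "
                f"{self.intensity_profile!r}"
            )


@dataclass
class GroundTruth:
    """Exact generator-side truth for one synthetic dataset.

    Only the fields relevant to the generating modality are populated.
    """

    spheroid_mask: np.ndarray | None = None
    spheroid_border: np.ndarray | None = None     # (n, 2) float (x, y) px
    matrix_cell_positions: np.ndarray | None = None  # (n, 2) µm
    matrix_cell_labels: list[str] = field(default_factory=list)
    true_distances: np.ndarray | None = None      # µm, per object
    track_paths: np.ndarray | None = None         # (n_cells, n_frames, 2) µm
    cluster_areas: np.ndarray | None = None       # µm² per frame (cluster mode)
    true_stain_mfi: dict | None = None
    autofluorescence_shift: dict | None = None
    event_flags: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# spheroid scene


def radial_profile(u: np.ndarray, core_fraction: float) -> np.ndarray:
    """Normalized DiL intensity as a function of u = ρ / r_border(θ).

    Plateau at 1 up to ``CORE_PLATEAU``, linear decay crossing exactly 0.6 at
    ``core_fraction``, then a half-cosine taper that reaches zero with zero
    slope at the border. The C¹ approach to zero keeps the square-lattice
    quadrature error of the angular moment sums far below the symmetry
    score's 1e-6 contract (a hard-edged profile leaks ~1e-3 of moment energy
    into the 4-fold lattice harmonics).
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    u0 = CORE_PLATEAU
    cf = core_fraction
    seg1 = u <= u0
    seg2 = (u > u0) & (u <= cf)
    seg3 = (u > cf) & (u <= 1.0)
    out[seg1] = 1.0
    out[seg2] = 1.0 - 0.4 * (u[seg2] - u0) / (cf - u0)
    out[seg3] = 0.6 * 0.5 * (1.0 + np.cos(np.pi * (u[seg3] - cf) / (1.0 - cf)))
    return out


def _spheroid_fields(scene: SpheroidScene):
    """Mask, border radius field, and normalized radial coordinate u."""
    h, w = scene.image_shape
    cx, cy = scene.center_px()
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - cx, yy - cy
    theta = np.arctan2(dy, dx)
    r_px = scene.spheroid_radius / scene.pixel_size
    r_border = r_px * (1.0 + scene.lobe_amplitude * np.cos(scene.n_lobes * theta))
    rr = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = rr / r_border
    mask = u <= 1.0
    return mask, u


def _border_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels 8-adjacent to background, as (n, 2) float (x, y)."""
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
    by, bx = np.nonzero(mask & ~eroded)
    return np.column_stack([bx, by]).astype(float)


def _render_gaussian(arr, x, y, amp, sigma):
    h, w = arr.shape
    r = int(math.ceil(7 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    arr[y0:y1, x0:x1] += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))


def _render_disk(arr, x, y, value, radius):
    h, w = arr.shape
    r = int(math.ceil(radius)) + 1
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    sel = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    arr[y0:y1, x0:x1][sel] = np.maximum(arr[y0:y1, x0:x1][sel], value)


def _place_at_distance(rng, target_px, border_tree, border_xy, mask, occupied,
                       footprint, n_tries=2000):
    """Find a point outside *mask* whose min distance to the border pixel
    set is *target_px*.

    Starts from a random border pixel pushed outward, then iterates
    p ← b_nearest + target·(p − b_nearest)/|p − b_nearest|, which converges
    because after each step the distance to the current nearest border pixel
    is exactly *target*. Rejects candidates inside the mask, violating image
    bounds (object footprint must fit), or whose footprint would touch an
    already placed object's footprint. ``occupied`` holds (position,
    footprint_radius) pairs.
    """
    h, w = mask.shape
    n_border = len(border_xy)
    cy, cx = ndimage.center_of_mass(mask)
    for _ in range(n_tries):
        b = border_xy[rng.integers(n_border)]
        outward = b - np.array([cx, cy])
        nv = np.hypot(*outward)
        outward = outward / nv if nv else np.array([1.0, 0.0])
        p = b + (target_px + 1.0) * outward
        ok = False
        for _ in range(25):
            d, idx = border_tree.query(p)
            if abs(d - target_px) <= 1e-9:
                ok = True
                break
            bn = border_xy[idx]
            v = p - bn
            nv = np.hypot(*v)
            if nv == 0:
                break
            p = bn + target_px * v / nv
        if not ok:
            d, _ = border_tree.query(p)
            if abs(d - target_px) > 0.05:
                continue
        margin = footprint + 2.0
        if not (margin <= p[0] <= w - 1 - margin and margin <= p[1] <= h - 1 - margin):
            continue
        xi, yi = int(round(p[0])), int(round(p[1]))
        if mask[yi, xi]:
            continue
        if occupied and any(np.hypot(*(q - p)) < footprint + fr + 4.0
                            for q, fr in occupied):
            continue
        return p
    raise SceneConfigError(
        f"could not place object at distance {target_px:.1f} px from the "
        "spheroid border within image bounds"
    )


def generate_spheroid_image(scene: SpheroidScene):
    """Render one spheroid scene.

    Returns ``(MultiChannelImage, GroundTruth)``. Channels: ``brightfield``
    (dark spheroid on bright background), ``dil`` (bright spheroid plus
    matrix cells and conglomerates), ``sytox`` (flat disks on dead-labeled
    cells above the dead cut-off; live cells far below it). Deterministic
    for a fixed seed; additive Gaussian noise is a fixed unit-normal field
    scaled by ``noise_sd`` so that noise ladders share one realisation.
    """
    scene.validate()
    h, w = scene.image_shape
    ss = np.random.SeedSequence(scene.seed)
    rng_place, rng_labels, rng_noise, rng_dist = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    mask, u = _spheroid_fields(scene)
    if scene.intensity_profile == "uniform":
        prof = mask.astype(float)
    else:
        prof = np.where(mask, radial_profile(np.where(mask, u, 1.0),
                                             scene.core_fraction), 0.0)

    dil = DIL_PEAK * prof
    brightfield = np.full((h, w), BF_BACKGROUND)
    brightfield[mask] -= BF_CONTRAST + 100.0 * prof[mask]
    sytox = np.zeros((h, w))

    border_xy = _border_pixels(mask)
    tree = cKDTree(border_xy)

    # distances to realise (µm -> px)
    if scene.matrix_cell_distances is not None:
        cell_d_px = [d / scene.pixel_size for d in scene.matrix_cell_distances]
    else:
        cx, cy = scene.center_px()
        edge = min(cx, cy, (w - 1) - cx, (h - 1) - cy)
        d_max = max(12.0, edge - scene.spheroid_radius / scene.pixel_size
                    * (1 + abs(scene.lobe_amplitude)) - 15.0)
        cell_d_px = rng_dist.uniform(6.0, d_max, scene.n_matrix_cells).tolist()

    occupied: list[tuple[np.ndarray, float]] = []
    n_dead = int(round(scene.dead_fraction * scene.n_matrix_cells))
    dead_idx = set(rng_labels.choice(scene.n_matrix_cells, size=n_dead,
                                     replace=False).tolist()) if scene.n_matrix_cells else set()

    # big objects first: the few conglomerates need the most clearance
    congl_px = []
    for _ in range(scene.n_conglomerates):
        d_px = rng_dist.uniform(18.0, 40.0)
        p = _place_at_distance(rng_place, d_px, tree, border_xy, mask,
                               occupied, footprint=15.0)
        occupied.append((p, 15.0))
        congl_px.append(p)
        _render_gaussian(dil, p[0], p[1], CONGLOMERATE_AMP, CONGLOMERATE_SIGMA)

    positions_px = []
    labels: list[str] = []
    for i, d_px in enumerate(cell_d_px):
        p = _place_at_distance(rng_place, d_px, tree, border_xy, mask,
                               occupied, footprint=4.0)
        occupied.append((p, 4.0))
        positions_px.append(p)
        dead = i in dead_idx
        labels.append("dead" if dead else "live")
        _render_gaussian(dil, p[0], p[1], CELL_AMP, CELL_SIGMA)
        _render_disk(sytox, p[0], p[1],
                     SYTOX_DEAD if dead else SYTOX_LIVE, SYTOX_DISK_RADIUS)

    positions_px.extend(congl_px)
    labels.extend(["conglomerate"] * len(congl_px))

    positions_px = (np.array(positions_px).reshape(-1, 2)
                    if positions_px else np.empty((0, 2)))
    # exact brute-force distance of each true center to the border pixel set
    if len(positions_px):
        diffs = positions_px[:, None, :] - border_xy[None, :, :]
        true_d = np.min(np.hypot(diffs[..., 0], diffs[..., 1]), axis=1)
    else:
        true_d = np.empty(0)

    for arr in (brightfield, dil, sytox):
        arr += scene.noise_sd * rng_noise.standard_normal((h, w))

    img = MultiChannelImage(
        channels={"brightfield": brightfield, "dil": dil, "sytox": sytox},
        pixel_size=scene.pixel_size,
    )
    gt = GroundTruth(
        spheroid_mask=mask,
        spheroid_border=border_xy,
        matrix_cell_positions=positions_px * scene.pixel_size,
        matrix_cell_labels=labels,
        true_distances=true_d * scene.pixel_size,
    )
    return img, gt


# ---------------------------------------------------------------------------
# time-lapse


def generate_timelapse(
    n_cells: int,
    n_frames: int,
    step_length: float,
    mode: str = "straight",
    seed: int = 0,
    *,
    image_shape: tuple[int, int] = (1536, 1536),
    pixel_size: float = 2.5,
    min_spacing: float = 40.0,
    blob_sigma: float = 2.0,
    blob_amp: float = 1000.0,
    cluster_radius: float = 150.0,
    cluster_area_factor: float = 0.9,
):
    """Simulate a drifting-cell time-lapse sequence.

    Modes: ``straight`` (one random heading per cell, fixed step length, so
    every path has accumulated length exactly ``(n_frames-1)·step_length``),
    ``random_walk`` (fresh uniform heading per step, step length drawn from
    a Rayleigh distribution with scale ``step_length``, giving expected
    accumulated length ``(n_frames-1)·step_length·sqrt(π/2)``), and
    ``clustered`` (a single central disk whose area changes by
    ``cluster_area_factor`` per frame).

    Distances are µm; ``min_spacing`` must exceed ``2·step_length`` so that
    greedy nearest-neighbour linking is identifiable. Cells start on a
    jittered grid whose pitch guarantees the spacing for the whole sequence.
    Returns ``(frames, GroundTruth)`` with frames shaped (n_frames, H, W).
    """
    if n_frames < 2:
        raise SceneConfigError(f"n_frames must be >= 2, got {n_frames}")
    if mode not in ("straight", "random_walk", "clustered"):
        raise SceneConfigError(f"unknown mode {mode!r}")
    if mode != "clustered" and min_spacing <= 2 * step_length:
        raise SceneConfigError(
            f"min_spacing ({min_spacing}) must exceed 2*step_length "
            f"({2 * step_length}) for identifiable linking"
        )
    h, w = image_shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames = np.zeros((n_frames, h, w), dtype=np.float32)

    if mode == "clustered":
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        radii_px = (cluster_radius / pixel_size
                    * cluster_area_factor ** (np.arange(n_frames) / 2.0))
        for t, r in enumerate(radii_px):
            fr = np.zeros((h, w))
            _render_disk(fr, cx, cy, blob_amp, r)
            frames[t] = fr
        areas = np.pi * (radii_px * pixel_size) ** 2
        gt = GroundTruth(track_paths=np.empty((0, n_frames, 2)),
                         cluster_areas=areas)
        return frames, gt

    if mode == "straight":
        drift = (n_frames - 1) * step_length         # exact bound
    else:
        # 3x the rms net displacement of the Rayleigh walk (rms = sqrt(2F)·σ)
        drift = 3.0 * np.sqrt(2.0 * (n_frames - 1)) * step_length
    pitch = (min_spacing + 2 * drift) / 0.8          # jitter keeps 0.8·pitch
    margin = drift + 10 * blob_sigma * pixel_size + 10.0
    span_x, span_y = (w - 1) * pixel_size - 2 * margin, (h - 1) * pixel_size - 2 * margin
    nx, ny = int(span_x // pitch) + 1, int(span_y // pitch) + 1
    if nx * ny < n_cells:
        raise SceneConfigError(
            f"spacing constraint unsatisfiable in image bounds: grid capacity "
            f"{nx * ny} < n_cells {n_cells}"
        )
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny))
    grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float) * pitch + margin
    order = rng.permutation(len(grid))[:n_cells]
    start = grid[order]
    start += rng.uniform(-0.1 * pitch, 0.1 * pitch, size=start.shape)

    paths = np.zeros((n_cells, n_frames, 2))
    paths[:, 0] = start
    if n_cells:
        if mode == "straight":
            ang = rng.uniform(0, 2 * np.pi, n_cells)
            step = step_length * np.column_stack([np.cos(ang), np.sin(ang)])
            for t in range(1, n_frames):
                paths[:, t] = paths[:, t - 1] + step
        else:  # random_walk
            for t in range(1, n_frames):
                ang = rng.uniform(0, 2 * np.pi, n_cells)
                length = rng.rayleigh(step_length, n_cells)
                step = length[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
                paths[:, t] = paths[:, t - 1] + step

    for t in range(n_frames):
        fr = np.zeros((h, w))
        for i in range(n_cells):
            x, y = paths[i, t] / pixel_size
            _render_gaussian(fr, x, y, blob_amp, blob_sigma)
        frames[t] = fr

    return frames, GroundTruth(track_paths=paths)


# ---------------------------------------------------------------------------
# cytometry

CHANNELS = ("fsc_a", "fsc_h", "ssc_a", "dapi", "pe", "pecy7", "af488", "bv605")
MARKER_CHANNELS = ("pe", "pecy7", "af488", "bv605")
SINGLET_BAND = (0.85, 1.10)
DAPI_NEG_MEAN, DAPI_POS_MEAN = 200.0, 5000.0
DAPI_CUTOFF_DEFAULT = 1000.0


def generate_cytometry_events(
    n_events: int,
    stain_mfi: dict[str, float] | float = 500.0,
    autofluorescence_shift: dict[str, float] | float = 300.0,
    dapi_positive_fraction: float = 0.05,
    doublet_fraction: float = 0.05,
    seed: int = 0,
    *,
    noise_sigma: float = 0.25,
    baseline_autofluorescence: float = 0.0,
    treated_label: str = "plasma",
):
    """Simulate the stained/unstained × treated/untreated condition grid.

    Marker-channel values are ``expected · LogNormal(−σ²/2, σ)`` so the
    event-level mean equals the expected intensity:
    ``baseline_autofluorescence`` (default 0), plus ``autofluorescence_shift``
    under treatment, plus ``stain_mfi`` when stained — so the expected
    stained-treated intensity is exactly ``stain_mfi + shift``. Exactly ``round(fraction·n)`` events per condition are flagged
    doublet / DAPI-positive (seeded subsets), so count-based readouts are
    exact by construction. Returns one annotated table (``stained``,
    ``treatment`` columns) and a GroundTruth with per-condition expected
    MFIs and the event flags.
    """
    for name, frac in (("dapi_positive_fraction", dapi_positive_fraction),
                       ("doublet_fraction", doublet_fraction)):
        if not 0 <= frac <= 1:
            raise SceneConfigError(f"{name} must be in [0, 1], got {frac}")
    if isinstance(stain_mfi, (int, float)):
        stain_mfi = {"pecy7": float(stain_mfi)}
    if isinstance(autofluorescence_shift, (int, float)):
        autofluorescence_shift = {c: float(autofluorescence_shift)
                                  for c in MARKER_CHANNELS}

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    flags = []
    expected: dict[tuple[bool, str], dict[str, float]] = {}
    for stained in (False, True):
        for treatment in ("untreated", treated_label):
            n = n_events
            fsc_a = rng.normal(5e5, 5e4, n).clip(2e5, 9e5)
            ratio = rng.normal(0.98, 0.02, n).clip(0.88, 1.08)
            n_dbl = int(round(doublet_fraction * n))
            dbl = np.zeros(n, bool)
            dbl[rng.choice(n, n_dbl, replace=False)] = True
            ratio[dbl] = rng.normal(0.55, 0.03, n_dbl).clip(0.45, 0.65)
            fsc_h = ratio * fsc_a
            ssc_a = np.exp(rng.normal(np.log(2e5), 0.3, n)).clip(1e4, 3e6)
            n_pos = int(round(dapi_positive_fraction * n))
            pos = np.zeros(n, bool)
            pos[rng.choice(n, n_pos, replace=False)] = True
            dapi = rng.normal(DAPI_NEG_MEAN, 50.0, n).clip(0, 500)
            dapi[pos] = rng.normal(DAPI_POS_MEAN, 500.0, n_pos).clip(2000, None)

            cond = {"fsc_a": fsc_a, "fsc_h": fsc_h, "ssc_a": ssc_a, "dapi": dapi}
            exp_cond = {}
            for ch in MARKER_CHANNELS:
                mu = baseline_autofluorescence
                if treatment == treated_label:
                    mu += autofluorescence_shift.get(ch, 0.0)
                if stained:
                    mu += stain_mfi.get(ch, 0.0)
                noise = np.exp(rng.normal(-noise_sigma**2 / 2, noise_sigma, n))
                cond[ch] = mu * noise
                exp_cond[ch] = mu
            expected[(stained, treatment)] = exp_cond
            df = pd.DataFrame(cond)
            df["stained"] = stained
            df["treatment"] = treatment
            rows.append(df)
            flags.append(pd.DataFrame({"doublet": dbl, "dapi_positive": pos,
                                       "stained": stained, "treatment": treatment}))

    table = pd.concat(rows, ignore_index=True)
    gt = GroundTruth(
        true_stain_mfi=dict(stain_mfi),
        autofluorescence_shift={"untreated": {c: 0.0 for c in MARKER_CHANNELS},
                                treated_label: dict(autofluorescence_shift)},
        event_flags=pd.concat(flags, ignore_index=True),
    )
    gt.expected_mfi = expected  # per (stained, treatment) condition
    return table, gt
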