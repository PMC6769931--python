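"""Detection, filtering, and classification of matrix-cells — objects that
have spread from the spheroid into the surrounding matrix — plus their
distance to the main spheroid.

Classification follows the study's two printed cut-offs: objects whose
summed DiL intensity exceeds 2×10⁵ a.u. are excluded as autofluorescent
conglomerates; of the remainder, objects whose mean sytox-green intensity
exceeds 3×10³ a.u. are dead, the rest viable. Both comparisons are strict
("higher than"): boundary-equal objects are retained / considered live.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._thresh import resolve_cutoff
from .image import MultiChannelImage
from .segmentation import SpheroidMask

__all__ = [
    "MatrixCellRecord",
    "OutgrowthSummary",
    "detect_matrix_cells",
    "classify_records",
    "distance_to_spheroid",
    "summarize_outgrowth",
    "analyze_outgrowth",
    "CONGLOMERATE_SUM_CUTOFF",
    "DEAD_MEAN_CUTOFF",
]

CONGLOMERATE_SUM_CUTOFF = 2e5   # a.u., summed DiL
DEAD_MEAN_CUTOFF = 3e3          # a.u., mean sytox green
_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class MatrixCellRecord:
    """One extra-spheroidal object."""

    centroid: tuple[float, float]          # (x, y) µm
    area: float                            # µm²
    dil_sum: float                         # summed DiL intensity (a.u.)
    sytox_mean: float                      # mean sytox intensity (a.u.)
    excluded_conglomerate: bool = False
    viable: bool = True
    distance_to_spheroid: float = float("nan")  # µm
    inside_spheroid: bool = False          # centroid fell inside the mask
    pixels: np.ndarray | None = field(default=None, repr=False)  # (n, 2) px (x, y)


@dataclass
class OutgrowthSummary:
    n_detected: int
    n_conglomerates_excluded: int
    n_live: int
    n_dead: int
    pct_viable: float | None               # None when no live+dead objects
    mean_distance_live: float | None       # µm; None when no live objects
    distances: list[float]


def detect_matrix_cells(
    image: MultiChannelImage,
    spheroid: SpheroidMask,
    min_area: float = 12.0,
    policy: str = "absolute",
    cutoff: float | None = 150.0,
    smooth_sigma: float = 1.0,
) -> list[MatrixCellRecord]:
    """Segment DiL-positive objects outside the spheroid.

    The DiL channel is thresholded outside a 1-pixel-dilated spheroid mask
    (the guard ring keeps border-touching fragments out of the count);
    8-connected components with area ≥ ``min_area`` (µm²) become records.
    Detection runs on a lightly Gaussian-smoothed copy (``smooth_sigma`` px,
    0 disables) for noise robustness, but intensity summaries (``dil_sum``,
    ``sytox_mean``) and centroids are measured on the raw channels.
    """
    dil = np.asarray(image["dil"], dtype=float)
    sytox = np.asarray(image["sytox"], dtype=float)
    guard = ndimage.binary_dilation(spheroid.mask, structure=_STRUCT8)
    work = ndimage.gaussian_filter(dil, smooth_sigma) if smooth_sigma > 0 else dil
    thr = resolve_cutoff(np.where(guard, 0.0, work), policy, cutoff)
    fg = (work > thr) & ~guard
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    if n == 0:
        return []
    px = image.pixel_size
    min_px = min_area / px**2
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(dil), labels, idx)
    keep = idx[sizes >= min_px]
    records = []
    for lab in keep:
        sel = labels == lab
        ys, xs = np.nonzero(sel)
        w = dil[ys, xs]
        wsum = w.sum()
        if wsum > 0:
            cx = float((xs * w).sum() / wsum)
            cy = float((ys * w).sum() / wsum)
        else:
            cx, cy = float(xs.mean()), float(ys.mean())
        records.append(MatrixCellRecord(
            centroid=(cx * px, cy * px),
            area=float(sel.sum()) * px**2,
            dil_sum=float(wsum),
            sytox_mean=float(sytox[ys, xs].mean()),
            pixels=np.column_stack([xs, ys]).astype(float),
        ))
    return records


def classify_records(
    records: list[MatrixCellRecord],
    conglomerate_sum_cutoff: float = CONGLOMERATE_SUM_CUTOFF,
    dead_mean_cutoff: float = DEAD_MEAN_CUTOFF,
) -> list[MatrixCellRecord]:
    """Apply the conglomerate exclusion, then viability, with strict '>'."""
    out = []
    for rec in records:
        excluded = rec.dil_sum > conglomerate_sum_cutoff
        viable = (not excluded) and rec.sytox_mean <= dead_mean_cutoff
        out.append(replace(rec, excluded_conglomerate=excluded, viable=viable))
    return out


def distance_to_spheroid(record: MatrixCellRecord,
                         spheroid: SpheroidMask,
                         mode: str = "centroid") -> MatrixCellRecord:
    """Shortest Euclidean distance from the object to the spheroid border,
    in µm (KD-tree over border pixel centers), attached to the record.

    ``mode='centroid'`` (default) measures from the intensity-weighted
    centroid — robust to segmentation jitter; ``mode='nearest-pixel'``
    measures from the closest object pixel. A centroid inside the mask gets
    distance 0 with ``inside_spheroid=True``.
    """
    if len(spheroid.border) == 0:
        raise ValueError("spheroid border is empty")
    px = spheroid.pixel_size
    cx, cy = record.centroid[0] / px, record.centroid[1] / px
    xi, yi = int(round(cx)), int(round(cy))
    h, w = spheroid.mask.shape
    if 0 <= yi < h and 0 <= xi < w and spheroid.mask[yi, xi]:
        return replace(record, distance_to_spheroid=0.0, inside_spheroid=True)
    tree = cKDTree(spheroid.border)
    if mode == "nearest-pixel":
        if record.pixels is None:
            raise ValueError("nearest-pixel mode requires the record's pixels")
        d = float(np.min(tree.query(record.pixels)[0]))
    elif mode == "centroid":
        d = float(tree.query([cx, cy])[0])
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return replace(record, distance_to_spheroid=d * px)


def summarize_outgrowth(records: list[MatrixCellRecord]) -> OutgrowthSummary:
    """Aggregate classified records; mean distance is over viable cells only."""
    n_detected = len(records)
    excl = [r for r in records if r.excluded_conglomerate]
    live = [r for r in records if not r.excluded_conglomerate and r.viable]
    dead = [r for r in records if not r.excluded_conglomerate and not r.viable]
    n_live, n_dead = len(live), len(dead)
    pct = 100.0 * n_live / (n_live + n_dead) if (n_live + n_dead) else None
    live_d = [r.distance_to_spheroid for r in live
              if not math.isnan(r.distance_to_spheroid)]
    mean_d = float(np.mean(live_d)) if live_d else None
    return OutgrowthSummary(
        n_detected=n_detected,
        n_conglomerates_excluded=len(excl),
        n_live=n_live,
        n_dead=n_dead,
        pct_viable=pct,
        mean_distance_live=mean_d,
        distances=[r.distance_to_spheroid for r in records],
    )


def analyze_outgrowth(image: MultiChannelImage, spheroid: SpheroidMask,
                      **kwargs) -> tuple[list[MatrixCellRecord], OutgrowthSummary]:
    """Full pipeline: detect → classify → distances → summary."""
    detect_kw = {k: kwargs[k] for k in
                 ("min_area", "policy", "cutoff", "smooth_sigma") if k in kwargs}
    cls_kw = {k: kwargs[k] for k in
              ("conglomerate_sum_cutoff", "dead_mean_cutoff") if k in kwargs}
    records = detect_matrix_cells(image, spheroid, **detect_kw)
    records = classify_records(records, **cls_kw)
    records = [distance_to_spheroid(r, spheroid) for r in records]
    return records, summarize_outgrowth(records)
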