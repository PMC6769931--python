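"""Spheroid detection: brightfield inversion, channel merging, intensity
cut-off, largest-component selection, border extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._thresh import resolve_cutoff
from .image import MultiChannelImage

__all__ = ["SpheroidMask", "merge_channels", "segment_spheroid", "segment_image"]

_STRUCT8 = np.ones((3, 3), bool)  # 8-connectivity throughout


@dataclass
class SpheroidMask:
    """Binary spheroid region with its ordered border.

    ``border`` lists the (x, y) pixel coordinates of mask pixels 8-adjacent
    to background, ordered by polar angle around the centroid (the generated
    spheroids are star-convex, so angular order traces the contour).
    ``area`` is in µm², ``centroid`` in pixel coordinates (x, y).
    """

    mask: np.ndarray
    border: np.ndarray          # (n, 2) float (x, y) px
    area: float                 # µm²
    centroid: tuple[float, float]
    pixel_size: float
    threshold: float            # absolute intensity cut-off actually applied

    @classmethod
    def from_binary(cls, mask: np.ndarray, pixel_size: float,
                    threshold: float = float("nan")) -> "SpheroidMask":
        ys, xs = np.nonzero(mask)
        cx, cy = float(xs.mean()), float(ys.mean())
        eroded = ndimage.binary_erosion(mask, structure=_STRUCT8)
        by, bx = np.nonzero(mask & ~eroded)
        ang = np.arctan2(by - cy, bx - cx)
        order = np.argsort(ang, kind="stable")
        border = np.column_stack([bx, by]).astype(float)[order]
        return cls(mask=mask, border=border,
                   area=float(mask.sum()) * pixel_size**2,
                   centroid=(cx, cy), pixel_size=pixel_size,
                   threshold=threshold)


def merge_channels(image: MultiChannelImage,
                   weights: dict[str, float] | None = None) -> np.ndarray:
    """Weighted channel sum with the brightfield channel inverted first.

    Inversion maps brightfield to ``max(brightfield) − brightfield`` so that
    the dark spheroid becomes a bright foreground consistent with the
    fluorescence channels. ``weights`` maps channel name to a nonnegative
    weight; channels absent from the mapping contribute nothing. Default:
    equal weight 1 on every channel present.
    """
    if weights is None:
        weights = {name: 1.0 for name in image.channels}
    if not weights or all(w == 0 for w in weights.values()):
        raise ValueError("at least one channel weight must be positive")
    if any(w < 0 for w in weights.values()):
        raise ValueError("channel weights must be nonnegative")
    shape = image.shape
    composite = np.zeros(shape, dtype=float)
    for name, w in weights.items():
        if w == 0:
            continue
        if name not in image:
            raise ValueError(f"channel {name!r} not present in image")
        ch = np.asarray(image[name], dtype=float)
        if ch.shape != shape:
            raise ValueError(
                f"channel {name!r} shape {ch.shape} != image shape {shape}")
        if name == "brightfield":
            ch = ch.max() - ch
        composite += w * ch
    return composite


def segment_spheroid(composite: np.ndarray, pixel_size: float = 1.0,
                     policy: str = "fraction",
                     cutoff: float | None = None) -> SpheroidMask | None:
    """Threshold the composite, fill holes, keep the largest 8-connected
    component as the spheroid and extract its border.

    The largest-component rule detects the spheroid area independent of the
    surrounding matrix cells, whose blobs form separate small components.
    ``policy``/``cutoff`` follow :mod:`spheromet._thresh` (default:
    fraction-of-max at 0.2, which is invariant to intensity rescaling).
    Returns ``None`` when thresholding leaves no foreground ("no spheroid
    detected") rather than raising.
    """
    composite = np.asarray(composite, dtype=float)
    thr = resolve_cutoff(composite, policy, cutoff)
    fg = composite > thr
    if not fg.any():
        return None
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return SpheroidMask.from_binary(mask, pixel_size, threshold=thr)


def segment_image(image: MultiChannelImage,
                  weights: dict[str, float] | None = None,
                  policy: str = "otsu",
                  cutoff: float | None = None) -> SpheroidMask | None:
    """Convenience pipeline: merge channels, then segment.

    Defaults suit brightfield-delineated spheroid scenes: the merge uses
    inverted brightfield + DiL (a sytox weight would let one bright dead
    cell dominate any max-normalised policy), and Otsu adapts the cut-off
    to the composite's background level, which the max-based brightfield
    inversion shifts upward on noisy images.
    """
    if weights is None:
        weights = {"brightfield": 1.0, "dil": 1.0}
        weights = {k: w for k, w in weights.items() if k in image}
    composite = merge_channels(image, weights)
    return segment_spheroid(composite, image.pixel_size, policy, cutoff)
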