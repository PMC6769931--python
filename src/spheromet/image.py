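"""Multi-channel image container and TIFF round-trip.

Conventions used throughout the package: arrays are indexed ``[row, col]``
(y, x); coordinates are pixel-centered with ``x = column`` and ``y = row``,
origin at the top-left pixel center; physical distances are obtained by
multiplying pixel distances with ``pixel_size`` (µm/pixel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["MultiChannelImage"]


@dataclass
class MultiChannelImage:
    """Registered 2D intensity arrays per named channel.

    Parameters
    ----------
    channels
        Mapping channel name -> 2D nonnegative float array. Typical names:
        ``brightfield``, ``dil`` (cell-tracer fluorescence), ``sytox``
        (dead-cell stain), ``autofluorescence``.
    pixel_size
        Physical pixel edge length in µm/pixel (> 0).
    """

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D (shape {arr.shape})")

    @property
    def shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    # ---------------------------------------------------------------- I/O
    def to_tiff(self, path) -> None:
        """Write one page per channel; channel names + pixel size go into the
        ImageDescription tag as JSON."""
        names = list(self.channels)
        stack = np.stack([np.asarray(self.channels[n], dtype=np.float32) for n in names])
        meta = json.dumps({"channels": names, "pixel_size_um": self.pixel_size})
        tifffile.imwrite(path, stack, description=meta,
                         photometric="minisblack")

    @classmethod
    def from_tiff(cls, path) -> "MultiChannelImage":
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc)
        if stack.ndim == 2:
            stack = stack[None]
        channels = {n: stack[i].astype(np.float64) for i, n in enumerate(meta["channels"])}
        return cls(channels=channels, pixel_size=float(meta["pixel_size_um"]))
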