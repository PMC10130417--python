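"""Multi-channel, multi-frame image container with TIFF round trip.

Coordinate convention used everywhere in this package: continuous positions
are in μm with the centre of pixel (row 0, col 0) at (x, y) = (0, 0);
x runs rightward along columns, y downward along rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """Pixel data per channel, shape (frames, rows, cols), plus geometry.

    Parameters
    ----------
    channels : mapping of channel name -> float array (frames, rows, cols)
    pixel_size : μm per pixel
    frame_interval : seconds between frames
    """

    channels: Dict[str, np.ndarray]
    pixel_size: float
    frame_interval: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[0] < 1:
                raise ValueError(
                    f"channel {name!r} must be 3-D (frames, rows, cols) with >=1 frame"
                )
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError("all channels must share the same shape")

    @property
    def channel_names(self) -> tuple:
        return tuple(self.channels)

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def field_area_um2(self) -> float:
        _, rows, cols = self.shape
        return rows * cols * self.pixel_size**2

    # -- I/O: one multi-page TIFF per channel, frame-major -----------------

    def save(self, directory, prefix: str = "stack") -> dict:
        """Write one multi-page float32 TIFF per channel plus a JSON sidecar.

        Returns a manifest mapping channel names to file names.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = {}
        for name, arr in self.channels.items():
            fname = f"{prefix}_{name}.tif"
            tifffile.imwrite(directory / fname, arr.astype(np.float32))
            files[name] = fname
        sidecar = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "channels": files,
            "meta": self.meta,
        }
        with open(directory / f"{prefix}_stack.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        return sidecar

    @classmethod
    def load(cls, directory, prefix: str = "stack") -> "ImageStack":
        directory = Path(directory)
        with open(directory / f"{prefix}_stack.json") as fh:
            sidecar = json.load(fh)
        channels = {
            name: tifffile.imread(directory / fname).astype(float)
            for name, fname in sidecar["channels"].items()
        }
        # single-frame TIFFs load as 2-D; restore the frame axis
        for name, arr in channels.items():
            if arr.ndim == 2:
                channels[name] = arr[None, :, :]
        return cls(
            channels=channels,
            pixel_size=sidecar["pixel_size_um"],
            frame_interval=sidecar["frame_interval_s"],
            meta=sidecar.get("meta", {}),
        )

    @classmethod
    def from_arrays(
        cls,
        channels: Mapping[str, np.ndarray],
        pixel_size: float,
        frame_interval: float = 0.1,
        **meta,
    ) -> "ImageStack":
        return cls(
            channels={k: np.asarray(v, dtype=float) for k, v in channels.items()},
            pixel_size=pixel_size,
            frame_interval=frame_interval,
            meta=dict(meta),
        )
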