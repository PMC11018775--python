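"""Core data carrier for image data with physical metadata.

Coordinate convention used throughout the package: 0-based indices; the
center of pixel (row i, col j) sits at continuous coordinate (i, j);
physical position = index * pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

#: canonical axis order; any ImageStack carries a subset of these, in this order
AXES_ORDER = "CTZYX"


@dataclass
class ImageStack:
    """An intensity array with named axes and physical metadata.

    ``axes`` is a string over a subset of ``CTZYX`` (in that order) naming
    the dimensions of ``pixels``. Metadata fields may be ``None`` when the
    corresponding axis is absent; any physical-unit computation requires
    the relevant field to be set.
    """

    pixels: np.ndarray
    axes: str
    pixel_size_nm: float | None = None
    z_step_um: float | None = None
    frame_interval_s: float | None = None
    channel_names: tuple[str, ...] | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != len(self.axes):
            raise ValueError(
                f"axes {self.axes!r} does not match array ndim {self.pixels.ndim}"
            )
        if any(s <= 0 for s in self.pixels.shape):
            raise ValueError("all axis lengths must be > 0")
        order = [AXES_ORDER.index(a) for a in self.axes]
        if order != sorted(order):
            raise ValueError(f"axes must be ordered as a subset of {AXES_ORDER}")

    # -- axis helpers ------------------------------------------------------
    def axis(self, name: str) -> int:
        """Index of axis ``name``; raises ``KeyError`` when absent."""
        i = self.axes.find(name)
        if i < 0:
            raise KeyError(f"stack has no {name!r} axis (axes={self.axes!r})")
        return i

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[self.axis("C")] if "C" in self.axes else 1

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[self.axis("T")] if "T" in self.axes else 1

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[self.axis("Z")] if "Z" in self.axes else 1

    def channel(self, c: int | str) -> np.ndarray:
        """Pixel data for one channel (view), dropping the C axis."""
        if "C" not in self.axes:
            if c in (0, None) or (self.channel_names and c == self.channel_names[0]):
                return self.pixels
            raise KeyError("stack has no C axis")
        if isinstance(c, str):
            if not self.channel_names or c not in self.channel_names:
                raise KeyError(f"unknown channel {c!r}")
            c = self.channel_names.index(c)
        return np.take(self.pixels, c, axis=self.axis("C"))

    def with_pixels(self, pixels: np.ndarray, op: str) -> "ImageStack":
        """New stack with replaced pixels and ``op`` appended to provenance."""
        out = replace(self, pixels=np.asarray(pixels))
        out.provenance = list(self.provenance) + [op]
        return out

    # -- I/O ---------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a JSON metadata sidecar."""
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.pixels, dtype=np.float32),
                         photometric="minisblack")
        meta = {
            "axes": self.axes,
            "pixel_size_nm": self.pixel_size_nm,
            "z_step_um": self.z_step_um,
            "frame_interval_s": self.frame_interval_s,
            "channel_names": list(self.channel_names) if self.channel_names else None,
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        pixels = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
        meta = json.loads(sidecar.read_text())
        return cls(
            pixels=pixels,
            axes=meta["axes"],
            pixel_size_nm=meta.get("pixel_size_nm"),
            z_step_um=meta.get("z_step_um"),
            frame_interval_s=meta.get("frame_interval_s"),
            channel_names=tuple(meta["channel_names"]) if meta.get("channel_names") else None,
            provenance=list(meta.get("provenance", [])),
        )


def require_metadata(stack: ImageStack, *fields_: str) -> None:
    """Raise ``ValueError`` if any named metadata field is unset."""
    for f in fields_:
        if getattr(stack, f, None) is None:
            raise ValueError(f"ImageStack metadata {f!r} required but missing")
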