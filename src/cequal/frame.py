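"""Frame container and field-of-view geometry for capsule-endoscopy stills.

A capsule frame is an 8-bit RGB raster in which only a circular optic disc
(the field of view, FOV) carries image content; pixels outside the disc are
black and are excluded from every measurement.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

#: FOV radius as a fraction of the shorter image side.
FOV_RADIUS_FRACTION = 0.48


@functools.lru_cache(maxsize=16)
def circular_fov(width: int, height: int) -> np.ndarray:
    """Boolean mask of the centred circular field of view.

    Radius is ``FOV_RADIUS_FRACTION * min(width, height)`` around the raster
    centre, mimicking the circular optic of a capsule camera.
    """
    radius = FOV_RADIUS_FRACTION * min(width, height)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.ogrid[:height, :width]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
    mask.setflags(write=False)
    return mask


def full_fov(width: int, height: int) -> np.ndarray:
    """Rectangular all-true mask (whole raster analysed); mainly for tests."""
    return np.ones((height, width), dtype=bool)


@dataclass
class Frame:
    """One still frame: 8-bit RGB pixels plus its analysis mask.

    Attributes
    ----------
    rgb : uint8 array, shape (H, W, 3)
    fov : bool array, shape (H, W)
        True where pixels belong to the analysed field of view.
    planted_bubble_fraction, planted_rg : float or None
        Ground-truth annotations attached by the synthetic generator;
        ``None`` for frames of unknown provenance.
    """

    rgb: np.ndarray
    fov: np.ndarray
    planted_bubble_fraction: float | None = None
    planted_rg: float | None = None

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError(f"rgb must be (H, W, 3), got {rgb.shape}")
        if rgb.dtype != np.uint8:
            raise ValueError(f"rgb must be uint8, got {rgb.dtype}")
        fov = np.asarray(self.fov, dtype=bool)
        if fov.shape != rgb.shape[:2]:
            raise ValueError("fov mask shape does not match image")
        self.rgb = rgb
        self.fov = fov

    @property
    def width(self) -> int:
        return self.rgb.shape[1]

    @property
    def height(self) -> int:
        return self.rgb.shape[0]

    @classmethod
    def from_array(cls, rgb: np.ndarray, fov: np.ndarray | None = None) -> "Frame":
        """Wrap an array; defaults to the standard circular FOV."""
        rgb = np.ascontiguousarray(rgb, dtype=np.uint8)
        if fov is None:
            fov = circular_fov(rgb.shape[1], rgb.shape[0])
        return cls(rgb=rgb, fov=fov)

    def save_png(self, path: str | Path) -> None:
        Image.fromarray(self.rgb, mode="RGB").save(path, format="PNG")

    @classmethod
    def load_png(cls, path: str | Path, fov: np.ndarray | None = None) -> "Frame":
        rgb = np.asarray(Image.open(path).convert("RGB"))
        return cls.from_array(rgb, fov)
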