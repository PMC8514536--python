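"""Core value types shared across the pipeline.

Coordinate convention (used everywhere in this package): 0-based ``(row, col)``
with the origin at the top-left pixel; a pixel belongs to a circle when the
Euclidean distance from its center to the circle center is at most the radius.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

LEFT = "LEFT"
RIGHT = "RIGHT"

TRAIN = "TRAIN"
VAL = "VAL"
TEST = "TEST"
UNASSIGNED = "UNASSIGNED"


@dataclass
class DiscGeometry:
    """Location and size of the optic nerve head in image coordinates.

    ``cup_radius_vertical / disc_radius`` is the vertical cup-to-disc ratio
    (VCDR) encoded by the rendered excavation.
    """

    center_row: float
    center_col: float
    disc_radius: float
    cup_radius_vertical: float = 0.0

    def __post_init__(self) -> None:
        if self.disc_radius < 0:
            raise ValueError("disc_radius must be non-negative")
        if not (0.0 <= self.cup_radius_vertical <= self.disc_radius + 1e-9):
            raise ValueError("cup_radius_vertical must lie in [0, disc_radius]")

    @property
    def vcdr(self) -> float:
        if self.disc_radius == 0:
            return 0.0
        return float(self.cup_radius_vertical / self.disc_radius)

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_row, self.center_col)

    def rescaled(self, factor: float) -> "DiscGeometry":
        """Geometry after a bilinear resize by ``factor`` (pixel-center mapping)."""
        return DiscGeometry(
            center_row=(self.center_row + 0.5) * factor - 0.5,
            center_col=(self.center_col + 0.5) * factor - 0.5,
            disc_radius=self.disc_radius * factor,
            cup_radius_vertical=self.cup_radius_vertical * factor,
        )

    def mirrored(self, width: int) -> "DiscGeometry":
        """Geometry after a horizontal flip of a ``width``-column image."""
        return replace(self, center_col=width - 1 - self.center_col)


@dataclass
class FundusImage:
    """An H x W x 3 fundus image with intensities in [0, 1].

    ``disc`` is ``None`` when the optic disc geometry is unknown (e.g. real
    images before localization); ``roi_radius`` is set once the circular
    region-of-interest clip has been applied.
    """

    pixels: np.ndarray
    laterality: str
    disc: Optional[DiscGeometry] = None
    roi_radius: Optional[float] = None
    image_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.laterality not in (LEFT, RIGHT):
            raise ValueError(f"laterality must be LEFT or RIGHT, got {self.laterality!r}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def copy(self) -> "FundusImage":
        return FundusImage(
            pixels=self.pixels.copy(),
            laterality=self.laterality,
            disc=replace(self.disc) if self.disc is not None else None,
            roi_radius=self.roi_radius,
            image_id=self.image_id,
        )


def distance_from(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Euclidean distance of every pixel center from ``center`` (row, col)."""
    rows = np.arange(shape[0], dtype=np.float64)[:, None]
    cols = np.arange(shape[1], dtype=np.float64)[None, :]
    return np.sqrt((rows - center[0]) ** 2 + (cols - center[1]) ** 2)
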