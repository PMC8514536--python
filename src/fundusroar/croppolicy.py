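"""Standardized circular crop policies centered on the optic nerve head.

``ONH_CROP`` blacks out the inside of a disc-centered circle (removes the
disc and, at larger sizes, the peripapillary area); ``PERIPHERY_CROP``
blacks out its complement (keeps only the disc region). The circle diameter
is a fixed percentage of image width — deliberately absolute, not relative
to the individual disc size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import FundusImage, distance_from

ONH_CROP = "onh"
PERIPHERY_CROP = "periphery"
NONE = "none"
POLICIES = (ONH_CROP, PERIPHERY_CROP, NONE)


@dataclass(frozen=True)
class CropSpec:
    """A crop policy cell: which region to black out, how large, and whether
    the model is retrained on cropped images (vs occlusion-style evaluation
    of a full-image model)."""

    policy: str = NONE
    size_pct: float = 0.0
    retrain: bool = True

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"policy must be one of {POLICIES}, got {self.policy!r}")
        if not (0.0 <= self.size_pct <= 100.0):
            raise ValueError(f"size_pct must lie in [0, 100], got {self.size_pct}")

    @property
    def is_identity(self) -> bool:
        return self.policy == NONE or (self.policy == ONH_CROP and self.size_pct == 0)

    def label(self) -> str:
        if self.is_identity:
            return "none"
        return f"{self.policy}{self.size_pct:g}"


def make_mask(
    spec: CropSpec, image_width: int, disc_center: tuple[float, float]
) -> np.ndarray:
    """Binary keep-mask (1 = keep, 0 = black out) for a square image.

    The circle has diameter ``size_pct``% of image width, centered on the
    disc centroid; a pixel is inside when its center is within the radius.
    """
    if not (0 <= disc_center[0] < image_width and 0 <= disc_center[1] < image_width):
        raise ValueError("disc_center must lie inside the image")
    shape = (image_width, image_width)
    if spec.policy == NONE:
        return np.ones(shape, dtype=np.float32)
    radius = (spec.size_pct / 100.0) * image_width / 2.0
    inside = distance_from(shape, disc_center) <= radius
    if spec.policy == ONH_CROP:
        return (~inside).astype(np.float32)
    return inside.astype(np.float32)


def apply_crop(image: FundusImage, spec: CropSpec) -> FundusImage:
    """Black out the masked region; geometry and laterality are unchanged."""
    if spec.policy == NONE:
        return image.copy()
    if image.disc is None:
        raise ValueError("apply_crop requires known disc geometry")
    h, w = image.pixels.shape[:2]
    if h != w:
        raise ValueError("apply_crop expects a square image")
    mask = make_mask(spec, w, image.disc.center)
    out = image.copy()
    out.pixels = (out.pixels * mask[:, :, None]).astype(np.float32)
    return out
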