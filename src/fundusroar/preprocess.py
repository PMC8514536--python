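"""Standard fundus preprocessing chain.

Order is fixed: square crop -> local contrast enhancement (background
subtraction) -> circular region-of-interest clip -> (crop policy, applied by
:mod:`fundusroar.croppolicy`) -> bilinear resize with intensities kept in
[0, 1]. All stages are deterministic and laterality-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as _sk_resize

from .types import FundusImage, distance_from


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``clip_inset`` shaves the overexposed rim left by background subtraction:
    the surviving circle has radius ``width/2 - clip_inset`` (10 px at the
    512-px full scale). ``enhancement_sigma_frac`` sets the background-blur
    scale as a fraction of the ROI radius; gain 4 with a 0.5 offset is the
    standard fundus background-subtraction recipe.
    """

    target_size: int = 512
    clip_inset: float = 10.0
    enhancement_sigma_frac: float = 1.0 / 30.0
    enhancement_gain: float = 4.0

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.clip_inset < 0:
            raise ValueError("clip_inset must be non-negative")
        if self.enhancement_sigma_frac <= 0:
            raise ValueError("enhancement_sigma_frac must be positive")

    @classmethod
    def for_size(cls, target_size: int, **kwargs) -> "PreprocessConfig":
        """Config with the clip inset scaled proportionally from the 512-px reference."""
        inset = kwargs.pop("clip_inset", round(10.0 * target_size / 512.0))
        return cls(target_size=target_size, clip_inset=inset, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        from dataclasses import asdict

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def square_crop(image: FundusImage) -> FundusImage:
    """Centered square crop of side min(H, W); identity if already square."""
    h, w = image.pixels.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("cannot square-crop an empty image")
    if h == w:
        return image.copy()
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    out = image.copy()
    out.pixels = image.pixels[r0 : r0 + side, c0 : c0 + side].copy()
    if out.disc is not None:
        out.disc.center_row -= r0
        out.disc.center_col -= c0
    return out


def enhance_local_contrast(image: FundusImage, config: PreprocessConfig) -> FundusImage:
    """Background-subtraction illumination correction.

    ``clip(gain * (image - blur(image, sigma)) + 0.5, 0, 1)`` per channel,
    with sigma = ``enhancement_sigma_frac`` x ROI radius (the inscribed-circle
    radius of the square image) and reflect padding at the border.
    """
    h, w = image.pixels.shape[:2]
    if h != w:
        raise ValueError("enhance_local_contrast expects a square image")
    roi_radius = w / 2.0
    sigma = config.enhancement_sigma_frac * roi_radius
    if sigma <= 0:
        raise ValueError("enhancement sigma must be positive")
    px = image.pixels.astype(np.float64)
    background = gaussian_filter(px, sigma=(sigma, sigma, 0), mode="reflect")
    out = image.copy()
    out.pixels = np.clip(config.enhancement_gain * (px - background) + 0.5, 0.0, 1.0).astype(
        np.float32
    )
    return out


def apply_roi_clip(image: FundusImage, config: PreprocessConfig) -> FundusImage:
    """Zero pixels outside the inscribed circle shrunk by ``clip_inset`` pixels."""
    h, w = image.pixels.shape[:2]
    if h != w:
        raise ValueError("apply_roi_clip expects a square image")
    radius = w / 2.0 - config.clip_inset
    if radius <= 0:
        raise ValueError(f"clip_inset {config.clip_inset} fully clips a {w}-px image")
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    keep = distance_from((h, w), center) <= radius
    out = image.copy()
    out.pixels = (out.pixels * keep[:, :, None]).astype(np.float32)
    out.roi_radius = radius
    return out


def resize_rescale(image: FundusImage, config: PreprocessConfig) -> FundusImage:
    """Bilinear resize to ``target_size`` (anti-aliased on downsample); [0,1] output.

    Disc geometry and ROI radius are rescaled by the same factor using
    pixel-center mapping.
    """
    h, w = image.pixels.shape[:2]
    if h != w:
        raise ValueError("resize_rescale expects a square image")
    t = config.target_size
    out = image.copy()
    if t != w:
        factor = t / w
        px = _sk_resize(
            image.pixels.astype(np.float64),
            (t, t),
            order=1,
            anti_aliasing=factor < 1.0,
            preserve_range=True,
            mode="reflect",
        )
        out.pixels = np.clip(px, 0.0, 1.0).astype(np.float32)
        if out.disc is not None:
            out.disc = out.disc.rescaled(factor)
        if out.roi_radius is not None:
            out.roi_radius = out.roi_radius * factor
    return out


def preprocess_image(
    image: FundusImage,
    config: PreprocessConfig,
    crop_spec=None,
) -> FundusImage:
    """Full chain: square crop, contrast enhancement, ROI clip, optional crop policy, resize."""
    from .croppolicy import apply_crop

    out = square_crop(image)
    out = enhance_local_contrast(out, config)
    out = apply_roi_clip(out, config)
    if crop_spec is not None:
        out = apply_crop(out, crop_spec)
    return resize_rescale(out, config)
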