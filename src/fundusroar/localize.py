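"""Optic disc localization and quality-control filtering.

Two modes: ``GROUND_TRUTH`` passes through the generator's recorded
geometry (synthetic data always carries it); ``DETECT`` finds the brightest
approximately circular blob by smoothed-intensity peak search plus region
growing, and reports NOT_FOUND when the peak-to-background contrast is
below a threshold. Images without a detected disc are discarded from all
downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import DiscGeometry, FundusImage

GROUND_TRUTH = "ground_truth"
DETECT = "detect"


@dataclass
class LocalizationResult:
    """Outcome of disc localization; ``disc is None`` means NOT_FOUND."""

    disc: Optional[DiscGeometry]
    confidence: float

    @property
    def found(self) -> bool:
        return self.disc is not None


def locate_disc(
    image: FundusImage,
    mode: str = GROUND_TRUTH,
    contrast_threshold: float = 0.2,
) -> LocalizationResult:
    """Locate the optic disc on a square (un-enhanced) fundus image.

    DETECT smooths the mean-channel luminance, takes the intensity peak,
    grows the connected region above half the peak-to-background contrast,
    and returns its centroid and equivalent-circle radius. Confidence is the
    peak-to-background contrast clipped to [0, 1].
    """
    if mode == GROUND_TRUTH:
        if image.disc is None:
            raise ValueError("GROUND_TRUTH localization requires recorded disc geometry")
        return LocalizationResult(disc=image.disc, confidence=1.0)
    if mode != DETECT:
        raise ValueError(f"unknown localization mode {mode!r}")

    h, w = image.pixels.shape[:2]
    lum = image.pixels.mean(axis=2).astype(np.float64)
    sigma = max(1.0, w / 48.0)
    smooth = ndimage.gaussian_filter(lum, sigma=sigma, mode="reflect")
    peak = float(smooth.max())
    background = float(np.median(smooth))
    contrast = peak - background
    confidence = float(np.clip(contrast, 0.0, 1.0))
    if contrast < contrast_threshold:
        return LocalizationResult(disc=None, confidence=confidence)

    level = background + 0.5 * contrast
    above = smooth >= level
    labels, _ = ndimage.label(above)
    peak_idx = np.unravel_index(int(np.argmax(smooth)), smooth.shape)
    region = labels == labels[peak_idx]
    rows, cols = np.nonzero(region)
    area = rows.size
    disc = DiscGeometry(
        center_row=float(rows.mean()),
        center_col=float(cols.mean()),
        disc_radius=float(np.sqrt(area / np.pi)),
        cup_radius_vertical=0.0,
    )
    return LocalizationResult(disc=disc, confidence=confidence)


def qc_filter(
    cohort: pd.DataFrame, results: Mapping[int, LocalizationResult]
) -> tuple[pd.DataFrame, dict]:
    """Drop images whose disc was not found; report retention per split.

    ``results`` maps image_id -> LocalizationResult (one per cohort row).
    Discarding is per image and therefore never moves a patient between
    splits.
    """
    missing = set(cohort["image_id"]) - set(results.keys())
    if missing:
        raise ValueError(f"no localization result for image ids {sorted(missing)[:5]}...")
    found = cohort["image_id"].map(lambda i: results[i].found)
    kept = cohort[found].copy()
    n = len(cohort)
    n_discarded = int(n - len(kept))
    per_split: dict[str, dict[str, int]] = {}
    for split, group in cohort.groupby("split"):
        f = group["image_id"].map(lambda i: results[i].found)
        per_split[str(split)] = {
            "retained": int(f.sum()),
            "discarded": int((~f).sum()),
        }
    report = {
        "n_images": int(n),
        "n_discarded": n_discarded,
        "discard_rate": (n_discarded / n) if n else 0.0,
        "per_split_counts": per_split,
    }
    return kept, report
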