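"""Gradient saliency maps, disc-centroid alignment and averaging.

Per-image saliency is the absolute input gradient of the model score,
reduced over channels by max and max-normalized to [0, 1]. Maps of left
eyes are mirrored horizontally so temporal/nasal sides coincide, every map
is translated so its disc centroid lands on the canvas center, and the
aligned maps are averaged with equal weight (pixels covered by fewer maps
are averaged over the covering maps only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import LEFT, RIGHT, FundusImage, distance_from
from .training import TrainedModel


@dataclass
class SaliencyMap:
    values: np.ndarray  # H x W, non-negative, max-normalized unless degenerate
    image_id: Optional[int]
    laterality: str
    disc_center: tuple[float, float]
    degenerate: bool = False


@dataclass
class AlignedSaliency:
    canvas: np.ndarray  # H' x W' mean saliency (0 where uncovered)
    coverage: np.ndarray  # H' x W' number of contributing maps per pixel
    n_maps: int
    center: tuple[int, int]  # canonical disc position on the canvas
    n_degenerate_excluded: int = 0


def gradient_saliency(
    trained: TrainedModel, image: FundusImage, normalize: bool = True
) -> SaliencyMap:
    """|d score / d pixel|, channel-reduced by max, per-image max-normalized."""
    x = image.pixels[None, ...]
    grad = trained.model.input_gradient(x)[0]
    values = np.abs(grad).max(axis=2)
    peak = float(values.max())
    degenerate = peak <= 0.0
    if normalize and not degenerate:
        values = values / peak
    if image.disc is None:
        raise ValueError("gradient_saliency requires known disc geometry")
    return SaliencyMap(
        values=values.astype(np.float64),
        image_id=image.image_id,
        laterality=image.laterality,
        disc_center=image.disc.center,
        degenerate=degenerate,
    )


def align_and_average(maps: Sequence[SaliencyMap]) -> AlignedSaliency:
    """Mirror left-eye maps, translate disc centroids to a common canvas
    center, and average. Degenerate (all-zero-gradient) maps are excluded
    and counted."""
    usable = [m for m in maps if not m.degenerate]
    n_excluded = len(maps) - len(usable)
    if not usable:
        raise ValueError("no non-degenerate saliency maps to average")
    h, w = usable[0].values.shape
    canvas_h, canvas_w = 2 * h, 2 * w
    center = (canvas_h // 2, canvas_w // 2)
    acc = np.zeros((canvas_h, canvas_w), dtype=np.float64)
    cov = np.zeros((canvas_h, canvas_w), dtype=np.int64)
    for m in usable:
        vals = m.values
        cr, cc = m.disc_center
        if m.laterality == LEFT:
            vals = vals[:, ::-1]
            cc = vals.shape[1] - 1 - cc
        dr = center[0] - int(round(cr))
        dc = center[1] - int(round(cc))
        r0, c0 = dr, dc
        rs0, cs0 = max(0, -r0), max(0, -c0)
        rd0, cd0 = max(0, r0), max(0, c0)
        nr = min(vals.shape[0] - rs0, canvas_h - rd0)
        nc = min(vals.shape[1] - cs0, canvas_w - cd0)
        if nr <= 0 or nc <= 0:
            continue
        acc[rd0 : rd0 + nr, cd0 : cd0 + nc] += vals[rs0 : rs0 + nr, cs0 : cs0 + nc]
        cov[rd0 : rd0 + nr, cd0 : cd0 + nc] += 1
    canvas = np.where(cov > 0, acc / np.maximum(cov, 1), 0.0)
    return AlignedSaliency(
        canvas=canvas,
        coverage=cov,
        n_maps=len(usable),
        center=center,
        n_degenerate_excluded=n_excluded,
    )


def save_aligned_saliency(
    aligned: AlignedSaliency,
    path_prefix,
    disc_radius: Optional[float] = None,
) -> None:
    """Write the averaged map as an 8-bit PNG heatmap plus a plain-text
    array, and (when ``disc_radius`` is given) the sector summary CSV."""
    import imageio.v3 as iio
    from pathlib import Path

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    canvas = aligned.canvas
    peak = canvas.max()
    scaled = canvas / peak if peak > 0 else canvas
    iio.imwrite(
        prefix.with_suffix(".png"),
        np.clip(np.round(scaled * 255.0), 0, 255).astype(np.uint8),
    )
    np.savetxt(prefix.with_suffix(".txt"), canvas, fmt="%.6g")
    if disc_radius is not None:
        sector_summary(aligned, disc_radius).to_csv(
            prefix.parent / (prefix.name + "_sectors.csv"), index=False
        )


SECTOR_NAMES = [
    "nasal",
    "supero-nasal",
    "superior",
    "supero-temporal",
    "temporal",
    "infero-temporal",
    "inferior",
    "infero-nasal",
]


def sector_summary(aligned: AlignedSaliency, disc_radius: float) -> pd.DataFrame:
    """Mean saliency in 8 x 45-degree sectors, inside the disc and in the
    1-2 disc-radius annulus.

    Canonical right-eye orientation: temporal is the left side of the
    canvas, superior is up. Sector k is centered on angle 45k degrees
    (0 = nasal = +col direction, counterclockwise with up positive).
    """
    h, w = aligned.canvas.shape
    if 2 * disc_radius > min(aligned.center[0], aligned.center[1]):
        raise ValueError("2 x disc_radius exceeds the canvas")
    d = distance_from((h, w), aligned.center)
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    ang = np.degrees(np.arctan2(-(rows - aligned.center[0]), cols - aligned.center[1]))
    sector_idx = (np.round(ang / 45.0).astype(int)) % 8
    covered = aligned.coverage > 0
    rings = {
        "disc": (d <= disc_radius) & covered,
        "annulus": (d > disc_radius) & (d <= 2 * disc_radius) & covered,
    }
    rows_out = []
    for ring, ring_mask in rings.items():
        for k, name in enumerate(SECTOR_NAMES):
            mask = ring_mask & (sector_idx == k)
            n_pix = int(mask.sum())
            mean_val = float(aligned.canvas[mask].mean()) if n_pix else float("nan")
            rows_out.append(
                dict(ring=ring, sector=name, mean_saliency=mean_val, n_pixels=n_pix)
            )
    return pd.DataFrame(rows_out)
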