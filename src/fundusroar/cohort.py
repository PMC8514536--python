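"""Synthetic disc-centered fundus cohort generator.

Emulates a tertiary glaucoma-clinic population: stereo fundus photographs
(two images per eye, one or two eyes per patient) with a vertical optic disc
diameter of about 23% of image height, a cup excavation encoding the vertical
cup-to-disc ratio (VCDR), two dark vessel arcades, peripapillary retinal
nerve fiber layer (RNFL) wedges in the supero- and infero-temporal sectors,
a radial illumination gradient and additive sensor noise.

The joint distribution of (age, VCDR, glaucoma) follows a latent-Gaussian
(copula-style) construction: a per-patient severity score correlated with
age drives both the continuous VCDR label and the thresholded glaucoma
label, with an inter-eye severity correlation so the two eyes of a patient
are similar but not identical. Loadings are solved in closed form from the
configured target correlations (see docs/methods.md for the derivation).

Where the planted disease signal lives in the image is controlled by
``signal_mode``: the RNFL wedges dim with severity ("periphery_only" or
"both") or stay severity-independent ("disc_only"); the cup excavation
always encodes the VCDR label itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .types import (
    LEFT,
    RIGHT,
    TRAIN,
    VAL,
    TEST,
    UNASSIGNED,
    DiscGeometry,
    FundusImage,
    distance_from,
)

DISC_ONLY = "disc_only"
PERIPHERY_ONLY = "periphery_only"
BOTH = "both"
SIGNAL_MODES = (DISC_ONLY, PERIPHERY_ONLY, BOTH)

COHORT_COLUMNS = [
    "patient_id",
    "eye_id",
    "image_id",
    "laterality",
    "age",
    "sex",
    "vcdr_true",
    "glaucoma",
    "split",
    "severity",
]

# rng stream tags so each draw is independently reproducible from the seed
_STREAM_COHORT = 1
_STREAM_EYE = 2
_STREAM_IMAGE = 3


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the clinic population statistics the generator is a
    stand-in for: mean VCDR 0.67, glaucoma prevalence 0.55, r(VCDR, age)
    0.29, point-biserial r(glaucoma, age) 0.56, age 62.9 +/- 17 years, 53%
    female, disc diameter 23% of image height.
    """

    n_patients: int = 200
    images_per_eye: int = 2
    image_size: int = 96
    disc_diameter_frac: float = 0.23
    signal_mode: str = BOTH
    effect_size: float = 4.0  # wedge dimming range, in units of noise_sd
    noise_sd: float = 0.02
    target_corr_vcdr_age: float = 0.29
    target_corr_glaucoma_age: float = 0.56
    prevalence: float = 0.55
    mean_vcdr: float = 0.67
    vcdr_sd: float = 0.15
    mean_age: float = 62.9
    sd_age: float = 17.0
    female_frac: float = 0.53
    inter_eye_corr: float = 0.8
    p_second_eye: float = 0.9
    center_jitter_frac: float = 0.03  # per-eye disc-center jitter, frac of width
    stereo_jitter_frac: float = 0.01  # extra per-image jitter within a stereo pair
    wedge_base_amplitude: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "disc_diameter_frac",
            "prevalence",
            "mean_vcdr",
            "female_frac",
            "inter_eye_corr",
            "p_second_eye",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.signal_mode not in SIGNAL_MODES:
            raise ConfigurationError(f"signal_mode must be one of {SIGNAL_MODES}")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        if self.images_per_eye < 1:
            raise ConfigurationError("images_per_eye must be at least 1")
        if self.image_size < 16:
            raise ConfigurationError("image_size must be at least 16 pixels")
        # closed-form copula loadings; fail loudly if targets are infeasible
        self.latent_loadings()

    def latent_loadings(self) -> tuple[float, float, float]:
        """Solve (rho_patient_age, lambda_vcdr, threshold) from the targets.

        With eye severity S_e ~ N(0,1), glaucoma = 1[S_e > c] where
        c = Phi^-1(1 - prevalence), the point-biserial correlation of the
        thresholded indicator with an N(0,1) variable at latent correlation
        rho_e is rho_e * phi(c) / sqrt(p (1-p)). Inverting gives the eye-age
        loading; dividing out the inter-eye mixing weight gives the patient
        loading, and the VCDR loading follows from the VCDR-age target.
        """
        p = self.prevalence
        c = norm.ppf(1.0 - p)
        attenuation = norm.pdf(c) / math.sqrt(p * (1.0 - p))
        rho_eye_age = self.target_corr_glaucoma_age / attenuation
        rho_patient_age = rho_eye_age / math.sqrt(self.inter_eye_corr)
        if not (0.0 < rho_patient_age < 1.0):
            raise ConfigurationError(
                "target_corr_glaucoma_age infeasible for the given prevalence "
                f"and inter_eye_corr (implied patient-age loading {rho_patient_age:.3f})"
            )
        lambda_vcdr = self.target_corr_vcdr_age / rho_eye_age
        if not (0.0 < lambda_vcdr < 1.0):
            raise ConfigurationError(
                "target_corr_vcdr_age infeasible given target_corr_glaucoma_age"
            )
        return rho_patient_age, lambda_vcdr, c

    def disc_radius(self) -> float:
        return self.disc_diameter_frac * self.image_size / 2.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def sample_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the cohort metadata table (no images rendered yet).

    Returns one row per image with columns ``patient_id, eye_id, image_id,
    laterality, age, sex, vcdr_true, glaucoma, split, severity``. ``split``
    is ``UNASSIGNED`` until :func:`split_by_patient` is applied. ``severity``
    is the latent per-eye disease score (standard normal scale) that drives
    both labels and the rendered RNFL attenuation.
    """
    rho_age, lam_v, cut = config.latent_loadings()
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    n = config.n_patients
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    z_age = rng.standard_normal(n)
    age = np.clip(config.mean_age + config.sd_age * z_age, 0.0, 100.0)
    sex = np.where(rng.random(n) < config.female_frac, "F", "M")
    sev_patient = rho_age * z_age + math.sqrt(1.0 - rho_age**2) * rng.standard_normal(n)

    both_eyes = rng.random(n) < config.p_second_eye
    lone_side = np.where(rng.random(n) < 0.5, RIGHT, LEFT)

    w = config.inter_eye_corr
    rows: list[dict] = []
    eye_id = 0
    image_id = 0
    for pid in range(n):
        sides = (RIGHT, LEFT) if both_eyes[pid] else (lone_side[pid],)
        for side in sides:
            sev_eye = math.sqrt(w) * sev_patient[pid] + math.sqrt(1.0 - w) * rng.standard_normal()
            vcdr_latent = lam_v * sev_eye + math.sqrt(1.0 - lam_v**2) * rng.standard_normal()
            vcdr = float(np.clip(config.mean_vcdr + config.vcdr_sd * vcdr_latent, 0.0, 1.0))
            glaucoma = int(sev_eye > cut)
            for _ in range(config.images_per_eye):
                rows.append(
                    dict(
                        patient_id=pid,
                        eye_id=eye_id,
                        image_id=image_id,
                        laterality=side,
                        age=float(age[pid]),
                        sex=str(sex[pid]),
                        vcdr_true=vcdr,
                        glaucoma=glaucoma,
                        split=UNASSIGNED,
                        severity=float(sev_eye),
                    )
                )
                image_id += 1
            eye_id += 1
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def split_by_patient(
    cohort: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign TRAIN/VAL/TEST at the patient level (all of a patient's images together)."""
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    out = cohort.copy()
    if out.empty:
        return out
    patients = np.sort(out["patient_id"].unique())
    rng = np.random.default_rng(seed)
    order = rng.permutation(patients)
    n = len(patients)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    assignment = {}
    for pid in order[:n_train]:
        assignment[pid] = TRAIN
    for pid in order[n_train : n_train + n_val]:
        assignment[pid] = VAL
    for pid in order[n_train + n_val :]:
        assignment[pid] = TEST
    out["split"] = out["patient_id"].map(assignment)
    return out


def _severity_weight(severity: float) -> float:
    """Map latent severity to a [0, 1] disease weight (its normal CDF)."""
    return float(norm.cdf(severity))


def _arcade_points(
    center: tuple[float, float], disc_radius: float, superior: bool, n_points: int = 48
) -> np.ndarray:
    """Polyline of one vessel arcade, canonical right-eye layout (temporal = left).

    The arcade leaves the disc vertically and sweeps temporally on a widening
    arc, like the real superior/inferior temporal vascular arcades.
    """
    t = np.linspace(0.0, 1.0, n_points)
    theta0 = math.pi / 2 if superior else -math.pi / 2
    theta1 = math.pi  # temporal direction (left)
    theta = theta0 + (theta1 - theta0) * t
    radius = disc_radius * (0.55 + 3.2 * t)
    rows = center[0] - radius * np.sin(theta)
    cols = center[1] + radius * np.cos(theta)
    return np.stack([rows, cols], axis=1)


def _draw_polyline(shape: tuple[int, int], points: np.ndarray, width: float) -> np.ndarray:
    """Soft indicator of the region within ``width`` pixels of the polyline."""
    rows = np.arange(shape[0], dtype=np.float32)[:, None, None]
    cols = np.arange(shape[1], dtype=np.float32)[None, :, None]
    pr = points[:, 0].astype(np.float32)[None, None, :]
    pc = points[:, 1].astype(np.float32)[None, None, :]
    d2 = (rows - pr) ** 2 + (cols - pc) ** 2
    d = np.sqrt(d2.min(axis=2))
    return np.clip(width + 0.8 - d, 0.0, 1.0)


def _angle_map(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Angle (radians) of each pixel about ``center``, math convention with up positive."""
    rows = np.arange(shape[0], dtype=np.float64)[:, None]
    cols = np.arange(shape[1], dtype=np.float64)[None, :]
    return np.arctan2(-(rows - center[0]), cols - center[1])


def wedge_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    disc_radius: float,
    inner_frac: float = 1.15,
    outer_frac: float = 3.9,
    centers_deg: tuple[float, ...] = (135.0, 225.0),
    half_width_deg: float = 22.5,
) -> np.ndarray:
    """Soft [0,1] mask of the supero- and infero-temporal RNFL wedges.

    Canonical right-eye orientation: temporal is the left side of the image,
    so the wedges sit up-left (135 deg) and down-left (225 deg) in an annulus
    between ``inner_frac`` and ``outer_frac`` disc radii. Edges taper with a
    raised-cosine profile in both angle and radius.
    """
    d = distance_from(shape, center)
    ang = np.degrees(_angle_map(shape, center))
    r_in, r_out = inner_frac * disc_radius, outer_frac * disc_radius
    radial = np.clip(np.minimum(d - r_in, r_out - d) / (0.25 * disc_radius), 0.0, 1.0)
    mask = np.zeros(shape, dtype=np.float64)
    for c_deg in centers_deg:
        delta = np.abs((ang - c_deg + 180.0) % 360.0 - 180.0)
        angular = np.clip((half_width_deg - delta) / 5.0, 0.0, 1.0)
        mask = np.maximum(mask, angular)
    return mask * radial


def _striation_pattern(
    shape: tuple[int, int],
    center: tuple[float, float],
    n_fibers: int = 40,
    phase: float = 0.0,
) -> np.ndarray:
    """Radial fiber-bundle striations: brightness oscillates across fibers.

    Fibers run radially out of the disc; intensity varies with the angular
    coordinate, giving the fine texture by which the RNFL is visible in red-
    free fundus photography. High spatial frequency, so the texture survives
    background-subtraction contrast enhancement (unlike a smooth brightness
    plateau).
    """
    ang = _angle_map(shape, center)
    return np.sin(n_fibers * ang + phase)


def render_fundus(record: pd.Series | dict, config: GeneratorConfig) -> FundusImage:
    """Render one synthetic disc-centered fundus photograph.

    Deterministic given ``(config.seed, image_id)``; left eyes are exact
    horizontal mirrors of the equivalent right-eye layout.
    """
    rec = dict(record)
    size = config.image_size
    shape = (size, size)
    image_id = int(rec["image_id"])
    eye_id = int(rec["eye_id"])
    vcdr = float(rec["vcdr_true"])
    severity = float(rec.get("severity", 0.0))
    laterality = rec["laterality"]

    eye_rng = np.random.default_rng([config.seed, _STREAM_EYE, eye_id])
    img_rng = np.random.default_rng([config.seed, _STREAM_IMAGE, image_id])

    # disc placement: per-eye jitter shared by the stereo pair, plus a small
    # per-image jitter emulating stereo camera offset
    jit_eye = eye_rng.uniform(-1.0, 1.0, size=2) * config.center_jitter_frac * size
    jit_img = img_rng.uniform(-1.0, 1.0, size=2) * config.stereo_jitter_frac * size
    center = ((size - 1) / 2.0 + jit_eye[0] + jit_img[0], (size - 1) / 2.0 + jit_eye[1] + jit_img[1])
    disc_r = config.disc_radius()
    cup_r = vcdr * disc_r

    d = distance_from(shape, center)

    # fundus background with radial illumination falloff
    d_img = distance_from(shape, ((size - 1) / 2.0, (size - 1) / 2.0))
    illum = 1.0 - 0.30 * (d_img / (size / 2.0)) ** 2
    base = np.array([0.62, 0.30, 0.15])
    img = illum[:, :, None] * base[None, None, :]

    # RNFL wedges: bright peripapillary sectors that dim with severity when
    # the planted signal lives in the periphery
    g = _severity_weight(severity)
    if config.signal_mode in (PERIPHERY_ONLY, BOTH):
        amplitude = config.wedge_base_amplitude - config.effect_size * config.noise_sd * g
    else:
        amplitude = config.wedge_base_amplitude - config.effect_size * config.noise_sd * 0.5
    amplitude = max(amplitude, 0.0)
    wedges = wedge_mask(shape, center, disc_r)
    striation = _striation_pattern(shape, center, phase=2.0 * math.pi * (eye_id % 7) / 7.0)
    texture = amplitude * wedges * (1.0 + 0.6 * striation)
    img += texture[:, :, None] * np.array([0.9, 1.0, 0.8])[None, None, :]

    # vessel arcades (dark), drawn before the disc so they dive under it
    vessel_width = max(1.0, 0.014 * size)
    for superior in (True, False):
        pts = _arcade_points(center, disc_r, superior=superior)
        stroke = _draw_polyline(shape, pts, vessel_width)
        img -= stroke[:, :, None] * np.array([0.30, 0.18, 0.10])[None, None, :]

    # optic disc (bright, sharp 1-px edge) and cup excavation (brighter)
    disc_alpha = np.clip(disc_r + 0.5 - d, 0.0, 1.0)
    disc_color = np.array([0.95, 0.82, 0.50])
    img = img * (1 - disc_alpha[:, :, None]) + disc_alpha[:, :, None] * disc_color[None, None, :]
    if cup_r > 0:
        cup_alpha = np.clip(cup_r + 0.5 - d, 0.0, 1.0)
        cup_color = np.array([1.0, 0.96, 0.72])
        img = img * (1 - cup_alpha[:, :, None]) + cup_alpha[:, :, None] * cup_color[None, None, :]

    img += img_rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    geometry = DiscGeometry(
        center_row=center[0],
        center_col=center[1],
        disc_radius=disc_r,
        cup_radius_vertical=cup_r,
    )
    if laterality == LEFT:
        img = img[:, ::-1, :].copy()
        geometry = geometry.mirrored(size)
    return FundusImage(
        pixels=img.astype(np.float32),
        laterality=laterality,
        disc=geometry,
        image_id=image_id,
    )


def render_cohort(cohort: pd.DataFrame, config: GeneratorConfig) -> list[FundusImage]:
    """Render every image in the cohort table, in row order."""
    return [render_fundus(row, config) for _, row in cohort.iterrows()]


def disc_mask(image: FundusImage) -> np.ndarray:
    """Boolean mask of pixels inside the recorded disc circle."""
    if image.disc is None:
        raise ValueError("image carries no disc geometry")
    d = distance_from(image.pixels.shape[:2], image.disc.center)
    return d <= image.disc.disc_radius


def write_cohort(
    out_dir: str | Path,
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    images: Optional[Iterable[FundusImage]] = None,
) -> Path:
    """Write cohort CSV (+ disc geometry columns), config YAML and 8-bit PNGs."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = cohort.copy()
    if images is None:
        images = render_cohort(cohort, config)
    images = list(images)
    table["center_row"] = [im.disc.center_row for im in images]
    table["center_col"] = [im.disc.center_col for im in images]
    table["disc_radius"] = [im.disc.disc_radius for im in images]
    table.to_csv(out / "cohort.csv", index=False)
    config.to_yaml(out / "generator.yaml")
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for im in images:
        arr = np.clip(np.round(im.pixels * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(img_dir / f"img_{im.image_id:06d}.png", arr)
    return out
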