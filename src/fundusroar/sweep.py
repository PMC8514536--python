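"""Experiment orchestration: crop-size sweeps, retrain vs occlusion.

A sweep cell is (task, policy, size_pct, condition, repeat). In the RETRAIN
condition a model is trained and evaluated on identically cropped images;
in the OCCLUSION condition the size-0 (full-image) model of the same repeat
is evaluated on cropped test images without retraining — both conditions
share the exact same test pixels. Under the full default grids (7 ONH sizes
and 9 periphery sizes per task, classification repeated 3 times) the
schedule totals 64 trainings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import GeneratorConfig, render_fundus
from .croppolicy import CropSpec, NONE, ONH_CROP, PERIPHERY_CROP, apply_crop
from .evaluation import EvalReport, evaluate_classification, evaluate_regression
from .preprocess import PreprocessConfig, preprocess_image, resize_rescale
from .training import (
    GLAUCOMA_CLASSIFICATION,
    VCDR_REGRESSION,
    TrainConfig,
    TrainedModel,
    build_model,
    predict,
    train,
)
from .types import TRAIN, VAL, TEST

RETRAIN = "RETRAIN"
OCCLUSION = "OCCLUSION"

ONH_SIZES_DEFAULT = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
PERIPHERY_SIZES_DEFAULT = (1.0, 2.5, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@dataclass
class ExperimentGrid:
    """The set of crop-policy cells to run for one task."""

    task: str = GLAUCOMA_CLASSIFICATION
    onh_sizes: tuple = ONH_SIZES_DEFAULT
    periphery_sizes: tuple = PERIPHERY_SIZES_DEFAULT
    repeats: int = 3
    base_seed: int = 0
    occlusion: bool = True

    @classmethod
    def full_default(cls, task: str, base_seed: int = 0) -> "ExperimentGrid":
        """Full grid: 7 ONH + 9 periphery sizes, 3 repeats for
        classification and 1 for regression."""
        repeats = 3 if task == GLAUCOMA_CLASSIFICATION else 1
        return cls(task=task, repeats=repeats, base_seed=base_seed)

    @classmethod
    def desk_default(cls, task: str, base_seed: int = 0) -> "ExperimentGrid":
        """Shrunk grid for CPU-scale runs: sizes {0, 20, 40, 60}, 1 repeat."""
        return cls(
            task=task,
            onh_sizes=(0.0, 20.0, 40.0, 60.0),
            periphery_sizes=(20.0, 40.0, 60.0),
            repeats=1,
            base_seed=base_seed,
        )

    @property
    def n_trainings(self) -> int:
        return (len(self.onh_sizes) + len(self.periphery_sizes)) * self.repeats

    def cells(self) -> list[tuple[str, float, int]]:
        out = []
        for size in self.onh_sizes:
            for rep in range(self.repeats):
                out.append((ONH_CROP, float(size), rep))
        for size in self.periphery_sizes:
            for rep in range(self.repeats):
                out.append((PERIPHERY_CROP, float(size), rep))
        return out


def count_default_trainings() -> int:
    """Trainings scheduled by the full default grids of both tasks."""
    return sum(
        ExperimentGrid.full_default(task).n_trainings
        for task in (VCDR_REGRESSION, GLAUCOMA_CLASSIFICATION)
    )


def cell_seed(base_seed: int, task: str, policy: str, size_pct: float, repeat: int) -> int:
    """Stable per-cell seed so every cell is independently reproducible."""
    key = f"{task}|{policy}|{size_pct:g}|{repeat}".encode()
    return (int(base_seed) + zlib.crc32(key)) % (2**31)


@dataclass
class SweepResult:
    """Long-format results plus the per-cell reports and trained models."""

    results: pd.DataFrame
    reports: dict
    models: dict

    def to_csv(self, path: str | Path) -> None:
        self.results.to_csv(path, index=False)


def prepare_arrays(
    cohort: pd.DataFrame,
    gen_config: GeneratorConfig,
    pre_config: PreprocessConfig,
):
    """Render + base-preprocess (square, enhance, clip) every cohort image.

    Returns ``(images, cohort)`` with images still at native size and
    carrying geometry; the crop policy and final resize are applied per
    sweep cell downstream.
    """
    from .preprocess import apply_roi_clip, enhance_local_contrast, square_crop

    images = []
    for _, row in cohort.iterrows():
        im = render_fundus(row, gen_config)
        im = square_crop(im)
        im = enhance_local_contrast(im, pre_config)
        im = apply_roi_clip(im, pre_config)
        images.append(im)
    return images, cohort.reset_index(drop=True)


def _cell_arrays(images, pre_config: PreprocessConfig, spec: CropSpec) -> np.ndarray:
    out = []
    for im in images:
        cropped = apply_crop(im, spec) if not spec.is_identity else im
        out.append(resize_rescale(cropped, pre_config).pixels)
    return np.stack(out)


def _targets(cohort: pd.DataFrame, task: str) -> np.ndarray:
    col = "vcdr_true" if task == VCDR_REGRESSION else "glaucoma"
    return cohort[col].to_numpy(dtype=np.float32)


def _evaluate(
    task: str,
    trained: TrainedModel,
    test_images: np.ndarray,
    test_meta: pd.DataFrame,
    crop_label: str,
    iterations: int,
    seed: int,
) -> EvalReport:
    scores = predict(trained, test_images)
    if task == VCDR_REGRESSION:
        return evaluate_regression(
            test_meta["vcdr_true"], scores, test_meta["patient_id"],
            crop_label=crop_label, iterations=iterations, seed=seed,
        )
    return evaluate_classification(
        test_meta["glaucoma"], scores, test_meta["patient_id"],
        crop_label=crop_label, iterations=iterations, seed=seed,
    )


def run_sweep(
    grid: ExperimentGrid,
    cohort: pd.DataFrame,
    gen_config: GeneratorConfig,
    pre_config: Optional[PreprocessConfig] = None,
    train_config: Optional[TrainConfig] = None,
    bootstrap_iterations: int = 1000,
    verbose: bool = False,
) -> SweepResult:
    """Run every grid cell on a split, QC-filtered cohort.

    RETRAIN cells train a fresh model under the cell's CropSpec; OCCLUSION
    cells (ONH policy, size > 0) evaluate the size-0 model of the same
    repeat on the cell's cropped test images. Requires size 0 in
    ``onh_sizes`` when ``grid.occlusion`` is set.
    """
    if grid.occlusion and 0.0 not in grid.onh_sizes:
        raise ValueError("occlusion condition requires the size-0 (full image) cell in onh_sizes")
    for split in (TRAIN, VAL, TEST):
        if not (cohort["split"] == split).any():
            raise ValueError(f"cohort has no {split} images; split it first")

    pre_config = pre_config or PreprocessConfig.for_size(gen_config.image_size)
    base_train_config = train_config or TrainConfig(task=grid.task)
    if base_train_config.task != grid.task:
        base_train_config = replace(base_train_config, task=grid.task)

    images, cohort = prepare_arrays(cohort, gen_config, pre_config)
    split_idx = {s: np.flatnonzero((cohort["split"] == s).to_numpy()) for s in (TRAIN, VAL, TEST)}
    split_images = {s: [images[i] for i in idx] for s, idx in split_idx.items()}
    split_meta = {s: cohort.iloc[idx].reset_index(drop=True) for s, idx in split_idx.items()}

    rows = []
    reports: dict = {}
    models: dict = {}
    none_models: dict[int, TrainedModel] = {}

    # deduplicate: size 0 appears once per repeat regardless of policy naming
    cells = grid.cells()
    for policy, size, rep in cells:
        spec = CropSpec(policy=policy, size_pct=size, retrain=True)
        label = spec.label()
        seed = cell_seed(grid.base_seed, grid.task, policy, size, rep)
        cfg = replace(base_train_config, seed=seed)
        if verbose:
            print(f"[sweep] {grid.task} {policy} {size:g}% repeat {rep} (seed {seed})")
        arrays = {s: _cell_arrays(split_images[s], pre_config, spec) for s in (TRAIN, VAL, TEST)}
        model = build_model(cfg)
        trained = train(
            model,
            arrays[TRAIN],
            _targets(split_meta[TRAIN], grid.task),
            arrays[VAL],
            _targets(split_meta[VAL], grid.task),
            cfg,
            crop_spec=spec,
            train_patients=split_meta[TRAIN]["patient_id"],
            val_patients=split_meta[VAL]["patient_id"],
        )
        report = _evaluate(
            grid.task, trained, arrays[TEST], split_meta[TEST], label, bootstrap_iterations, seed
        )
        key = (grid.task, policy, size, RETRAIN, rep)
        reports[key] = report
        models[key] = trained
        if spec.is_identity:
            none_models[rep] = trained
        for m in report.metrics_long():
            rows.append(
                dict(task=grid.task, policy=policy, size_pct=size, condition=RETRAIN,
                     repeat=rep, seed=seed, **m)
            )

        if grid.occlusion and policy == ONH_CROP and size > 0:
            base_model = none_models.get(rep)
            if base_model is None:
                raise ValueError("occlusion requested before the size-0 model was trained")
            occ_seed = cell_seed(grid.base_seed, grid.task, policy + "_occ", size, rep)
            occ_report = _evaluate(
                grid.task, base_model, arrays[TEST], split_meta[TEST],
                label + "_occlusion", bootstrap_iterations, occ_seed,
            )
            key = (grid.task, policy, size, OCCLUSION, rep)
            reports[key] = occ_report
            for m in occ_report.metrics_long():
                rows.append(
                    dict(task=grid.task, policy=policy, size_pct=size, condition=OCCLUSION,
                         repeat=rep, seed=occ_seed, **m)
                )

    results = pd.DataFrame(
        rows,
        columns=["task", "policy", "size_pct", "condition", "repeat", "seed",
                 "metric", "point", "ci_low", "ci_high"],
    )
    return SweepResult(results=results, reports=reports, models=models)


def average_repeats(results: pd.DataFrame) -> pd.DataFrame:
    """Mean point estimate (and CI bounds) across repeats per grid cell.

    Per-repeat rows stay in the input; the returned table has one row per
    (task, policy, size_pct, condition, metric) with an ``n_repeats``
    column.
    """
    if results.empty:
        return results.copy()
    keys = ["task", "policy", "size_pct", "condition", "metric"]
    agg = (
        results.groupby(keys, as_index=False)
        .agg(point=("point", "mean"), ci_low=("ci_low", "mean"),
             ci_high=("ci_high", "mean"), n_repeats=("repeat", "nunique"))
    )
    return agg


def curve_table(results: pd.DataFrame) -> pd.DataFrame:
    """Metric-vs-crop-size table per (task, policy, condition), size-sorted."""
    if results.empty:
        return results.copy()
    averaged = average_repeats(results)
    return averaged.sort_values(
        ["task", "policy", "condition", "metric", "size_pct"]
    ).reset_index(drop=True)
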