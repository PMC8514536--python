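"""Shared fixtures. Heavy trained-model fixtures are session-scoped so the
signal-recovery experiments are run once and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fundusroar.cohort import GeneratorConfig, sample_cohort, split_by_patient
from fundusroar.croppolicy import CropSpec
from fundusroar.experiments import (
    desk_cohort,
    desk_train_config,
    held_out_patient_auc,
    run_cell,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_patients=30, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return split_by_patient(sample_cohort(small_config), seed=11)


@pytest.fixture(scope="session")
def smoke_classifier():
    """Full-image glaucoma classifier on a 200-patient cohort with signal in
    both the disc and the periphery (the pipeline's standard smoke run)."""
    cohort, gen = desk_cohort(n_patients=200, signal_mode="both", seed=1)
    run = run_cell(
        "glaucoma", cohort, gen, spec=CropSpec(), seed=1,
        train_config=desk_train_config("glaucoma", seed=1, max_epochs=30),
    )
    return run, gen


@pytest.fixture(scope="session")
def signal_recovery():
    """The two ONH-crop-60% retrained classifiers that operationalize the
    signal-placement claim: trained under periphery-only vs disc-only
    planted signal, each evaluated on a large fresh held-out cohort."""
    out = {}
    spec = CropSpec("onh", 60.0)
    for mode in ("periphery_only", "disc_only"):
        cohort, gen = desk_cohort(n_patients=200, signal_mode=mode, seed=1)
        run = run_cell(
            "glaucoma", cohort, gen, spec=spec, seed=1,
            train_config=desk_train_config("glaucoma", seed=1),
        )
        auc_value, n = held_out_patient_auc(run.trained, gen, spec)
        out[mode] = dict(run=run, gen=gen, auc=auc_value, n_patients=n)
    # a 40% ONH crop on the periphery-only cohort, for saliency-pattern
    # checks: the disc is fully blacked out while part of the 1-2 disc-radius
    # annulus stays visible
    cohort, gen = desk_cohort(n_patients=200, signal_mode="periphery_only", seed=1)
    out["periphery_only_onh40"] = dict(
        run=run_cell(
            "glaucoma", cohort, gen, spec=CropSpec("onh", 40.0), seed=1,
            train_config=desk_train_config("glaucoma", seed=1),
        ),
        gen=gen,
    )
    return out
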