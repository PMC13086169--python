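"""Shared fixtures.

The expensive fixture is ``overfit_run``: a deliberate-overfit training
run of RNFL-Net on eight noise-free phantoms, shared (session scope) by
the convergence and parameter-recovery suites so the network is trained
once per test session.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from rnflseg.network import build_rnflnet, train
from rnflseg.phantom import PhantomSpec, generate_phantom
from rnflseg.preprocess import build_categorical_mask, one_hot

OVERFIT_SEED = 0


def overfit_specs() -> list[PhantomSpec]:
    """Eight noise-free, vessel-free 128x128 phantoms with varied
    geometry (ILM depth 28-42 px, band thickness 18-32 px)."""
    return [
        PhantomSpec(
            seed=s,
            n_vessels=0,
            speckle_sigma=0.0,
            ilm_baseline=28 + 2 * s,
            rnfl_thickness_mean=18 + 2 * s,
        )
        for s in range(8)
    ]


def records_to_pairs(records):
    return [
        (rec.image, one_hot(build_categorical_mask(rec.boundaries, rec.image.shape)))
        for rec in records
    ]


@pytest.fixture(scope="session")
def overfit_run():
    """(model, train state, records, training pairs) after fitting the
    eight-phantom training set to RNFL Dice >= 0.97."""
    records = [generate_phantom(spec) for spec in overfit_specs()]
    pairs = records_to_pairs(records)
    model = build_rnflnet(seed=OVERFIT_SEED)
    model, state = train(
        model,
        pairs,
        pairs,
        epochs=300,
        batch_size=2,
        seed=OVERFIT_SEED,
        target_train_dice=0.97,
        check_every=5,
    )
    return model, state, records, pairs


@pytest.fixture(scope="session")
def vesseled_records():
    """The same eight phantoms with three planted vessel shadows each
    (contrast 0.5); band geometry is identical to the clean versions."""
    return [
        generate_phantom(replace(spec, n_vessels=3, vessel_contrast=0.5))
        for spec in overfit_specs()
    ]


@pytest.fixture
def flat_record():
    """Flat noise-free phantom: ILM at row 20, band thickness 30."""
    spec = PhantomSpec(
        seed=0,
        n_vessels=0,
        speckle_sigma=0.0,
        ilm_waviness_amplitude=0.0,
        ilm_baseline=20,
        rnfl_thickness_mean=30.0,
    )
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
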