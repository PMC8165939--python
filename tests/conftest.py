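"""Shared fixtures.

Small phantoms (generated in seconds) serve the module tests; the
full-scale 36-well plate and the trained classifier are session-scoped so
the expensive end-to-end checks compute them once.
"""

from __future__ import annotations

import pytest

import deltasphere as ds


@pytest.fixture(scope="session")
def small_round_config() -> ds.PhantomConfig:
    """A fast-growing round phantom whose motion band is always segmentable."""
    return ds.PhantomConfig(
        image_size=(160, 160),
        n_timepoints=15,
        initial_radius=10.0,
        growth_rate=1.0,
        phenotype="round",
        noise_sd=0.0,
        jitter_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_round_series(small_round_config):
    return ds.generate_series(small_round_config)


@pytest.fixture(scope="session")
def phantom_plate():
    """Full-scale two-condition plate: 18 round + 18 branched wells,
    96 hourly timepoints, 256x256 8-bit frames, branching onset at t=20."""
    cfg_round = ds.PhantomConfig(phenotype="round")
    cfg_branched = ds.PhantomConfig(phenotype="branched")
    series, layout, truths = ds.generate_plate(
        cfg_round, cfg_branched, n_wells_per_condition=18, base_seed=1
    )
    return series, layout, truths


@pytest.fixture(scope="session")
def plate_masks(phantom_plate):
    series, _, _ = phantom_plate
    return ds.segment_plate(series)


@pytest.fixture(scope="session")
def plate_features(phantom_plate, plate_masks):
    series, layout, _ = phantom_plate
    return ds.plate_feature_table(series, plate_masks, layout)


@pytest.fixture(scope="session")
def plate_accuracy_curve(phantom_plate, plate_masks):
    """Train the classifier on the plate with a 4-wells-per-group hold-out
    and return (accuracy curve, n eval wells per timepoint)."""
    series, layout, _ = phantom_plate
    dataset = ds.build_dataset(series, plate_masks, layout)
    train_ds, eval_ds = ds.split_by_well(
        dataset, layout, ds.SplitSpec(n_holdout_wells_per_group=4, seed=1)
    )
    model, _ = ds.train(train_ds, ds.ModelConfig(epochs=10, seed=1))
    _, curve = ds.evaluate(model, eval_ds)
    n_eval_wells = len(set(eval_ds.wells.tolist()))
    return curve, n_eval_wells
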