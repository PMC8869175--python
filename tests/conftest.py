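"""Shared fixtures.

The expensive session fixtures (a rendered toy-cell dataset and a short
conditional-GAN training run on it) are built once and shared by the
end-to-end tests; their parameters are the package's documented
desk-scale study conditions.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cytogan.dataset import DatasetManifest, SplitSpec, stratified_split
from cytogan.fixtures import (FixtureSpec, generate_fixture_dataset,
                              hue_distance, measure_hue)
from cytogan.networks import GanConfig
from cytogan.training import TrainConfig, train

# desk-scale study conditions: 4 classes with one deliberate minority,
# 32 px images, small widths -- see docs/methods.md
FIXTURE_SEED = 7
SPLIT_SEED = 1
TRAIN_SEED = 11
GAN_KW = dict(n_classes=4, image_size=32, noise_dim=32, base_channels=8)
TRAIN_KW = dict(learning_rate=1e-3, batch_size=16, epochs=6, n_critic=2,
                seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def fixture_root(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("cells")


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(image_size=32, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def cell_manifest(fixture_root, fixture_spec) -> DatasetManifest:
    """Rendered 200/200/200/10 toy-cell dataset with train/val/test splits."""
    manifest = generate_fixture_dataset(fixture_spec, fixture_root)
    return stratified_split(manifest, SplitSpec(seed=SPLIT_SEED))


def measure_class_hue_error(generator, class_hues, rng_seed=123,
                            n_per_class=8) -> float:
    """Median circular hue error of class-conditional samples (degrees)."""
    rng = np.random.default_rng(rng_seed)
    errors = []
    for k, hue in enumerate(class_hues):
        images = generator.sample(np.full(n_per_class, k), rng)
        for img in images:
            h = measure_hue((img + 1) / 2)
            errors.append(hue_distance(h, hue) if np.isfinite(h) else 90.0)
    return float(np.median(errors))


@pytest.fixture(scope="session")
def trained_gan(fixture_root, fixture_spec, cell_manifest):
    """Short conditional-GAN training run, with per-epoch hue tracking."""
    gan_cfg = GanConfig(**GAN_KW)
    train_cfg = TrainConfig(**TRAIN_KW)
    hues = [p.hue for p in fixture_spec.class_params]
    hue_errors: list[float] = []

    def hook(epoch, generator):
        hue_errors.append(measure_class_hue_error(generator, hues))

    checkpoint, history = train(cell_manifest, gan_cfg, train_cfg,
                                root=fixture_root, epoch_hook=hook)
    return {"checkpoint": checkpoint, "history": history,
            "hue_errors": hue_errors, "gan_cfg": gan_cfg,
            "train_cfg": train_cfg}


@pytest.fixture(scope="session")
def synthetic_pool(fixture_root, trained_gan, cell_manifest):
    """Uniform per-class synthetic pool for downstream comparisons,
    rebased so real and synthetic paths share one root."""
    from cytogan.training import synthesize_balanced

    pool = synthesize_balanced(
        trained_gan["checkpoint"], {c: 120 for c in cell_manifest.labels()},
        seed=29, out_dir=fixture_root / "synthetic_pool",
        class_names=cell_manifest.labels())
    return DatasetManifest(replace(r, path=f"synthetic_pool/{r.path}")
                           for r in pool.records)
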