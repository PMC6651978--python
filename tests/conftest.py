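import numpy as np
import pytest

from plantfusion import (
    DatasetManifest,
    Observation,
    PERSPECTIVES,
    SyntheticConfig,
    array_loader,
    generate_image_arrays,
)


def make_manifest(n_species: int = 2, n_obs: int = 3) -> DatasetManifest:
    """Small balanced manifest built programmatically."""
    observations = []
    counter = 0
    for s in range(n_species):
        species = f"species_{s:03d}"
        group = "grass" if s % 2 else "forb"
        for _ in range(n_obs):
            obs_id = f"obs{counter:05d}"
            observations.append(
                Observation(
                    observation_id=obs_id,
                    species=species,
                    group=group,
                    images={p: f"images/{obs_id}_{p}.png" for p in PERSPECTIVES},
                )
            )
            counter += 1
    return DatasetManifest(observations=observations)


@pytest.fixture
def tiny_manifest() -> DatasetManifest:
    return make_manifest(2, 3)


@pytest.fixture(scope="session")
def small_image_dataset():
    """In-memory image dataset shared by backend tests: 6 species (one
    cluster of 3) × 10 observations, 32 px."""
    config = SyntheticConfig(
        n_species=6,
        n_observations_per_species=10,
        group_structure=((0, 1, 2),),
        background_confound=0.5,
        seed=42,
    )
    manifest, images = generate_image_arrays(config)
    return config, manifest, array_loader(images)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
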