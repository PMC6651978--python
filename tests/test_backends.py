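"""Scorer contract, the two training strategies, and score matrices."""

import numpy as np
import pytest

from plantfusion import (
    ALL_PERSPECTIVES,
    PERSPECTIVES,
    ScoreMatrix,
    SyntheticConfig,
    TrainConfig,
    array_loader,
    generate_image_arrays,
    score,
    split_by_observation,
    strategy_b_matrices,
    topk_accuracy,
    train_strategy_a,
    train_strategy_b,
)
from plantfusion.errors import InputError, TrainingError


def test_train_config_validation():
    with pytest.raises(InputError):
        TrainConfig(batch_size=0)
    with pytest.raises(InputError):
        TrainConfig(backend_name="resnet")
    assert TrainConfig().max_steps == 200_000  # reference recipe recorded


def test_strategy_a_returns_one_scorer_per_perspective(small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    scorers = train_strategy_a(manifest, split, TrainConfig(seed=0), loader)
    assert set(scorers) == set(PERSPECTIVES)
    for p, scorer in scorers.items():
        assert scorer.perspective_scope == p
        # strategy-A scorers see only their own perspective's images
        assert scorer.n_training_images_ == 6 * len(manifest.species_list)


def test_strategy_b_sees_five_times_the_images(small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    scorer = train_strategy_b(manifest, split, TrainConfig(seed=0), loader)
    assert scorer.perspective_scope == ALL_PERSPECTIVES
    assert scorer.n_training_images_ == 5 * 6 * len(manifest.species_list)


def test_score_matrix_shape_and_normalization(small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    scorers = train_strategy_a(manifest, split, TrainConfig(seed=0), loader)
    matrix = score(scorers["FF"], manifest, split, "FF", loader)
    n_species = len(manifest.species_list)
    assert matrix.data.shape == (2 * n_species, n_species)
    sums = matrix.data.to_numpy().sum(axis=1)
    assert np.abs(sums - 1.0).max() < 1e-6


def test_scoring_is_deterministic(small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    cfg = TrainConfig(seed=3)
    m1 = score(train_strategy_a(manifest, split, cfg, loader)["LT"], manifest, split, "LT", loader)
    m2 = score(train_strategy_a(manifest, split, cfg, loader)["LT"], manifest, split, "LT", loader)
    assert np.array_equal(m1.data.to_numpy(), m2.data.to_numpy())


def test_strategy_b_matrices_cover_all_perspectives(small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    scorer = train_strategy_b(manifest, split, TrainConfig(seed=0), loader)
    mats = strategy_b_matrices(scorer, manifest, split, loader)
    assert set(mats) == set(PERSPECTIVES)
    for p, m in mats.items():
        assert set(m.data.index.get_level_values(1)) == {p}


def test_missing_image_file_raises_io_error(small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    scorers = train_strategy_a(manifest, split, TrainConfig(seed=0), loader)
    with pytest.raises(IOError, match="not found"):
        score(scorers["FF"], manifest, split, "FF", lambda p: (_ for _ in ()).throw(
            IOError(f"image file not found: {p}")
        ))


def test_empty_training_set_fails(small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    empty = type(split)(
        train_ids=frozenset(),
        validation_ids=split.validation_ids,
        test_ids=split.test_ids,
        per_species_counts={s: (0, 2, 2) for s in manifest.species_list},
        seed=0,
    )
    with pytest.raises(TrainingError):
        train_strategy_b(manifest, empty, TrainConfig(seed=0), loader)


def test_perspective_specific_signal_is_learned_only_by_that_scorer():
    """With species signal only in FF images, the FF scorer is far above
    chance while the EP scorer stays near chance."""
    config = SyntheticConfig(
        n_species=6,
        n_observations_per_species=12,
        discriminability={"EP": 0.0, "FF": 3.0, "FL": 0.0, "LT": 0.0, "LB": 0.0},
        group_structure=None,
        background_confound=0.0,
        seed=9,
    )
    manifest, images = generate_image_arrays(config)
    loader = array_loader(images)
    split = split_by_observation(manifest, 8, 2, 2, seed=9)
    scorers = train_strategy_a(manifest, split, TrainConfig(seed=9), loader)
    truth = manifest.truth(split.test_ids)
    accs = {}
    for p in ("FF", "EP"):
        matrix = score(scorers[p], manifest, split, p, loader)
        _, accs[p] = topk_accuracy(matrix.rows_for_perspective(p), truth, 1)
    chance = 1.0 / 6
    assert accs["FF"] > 3 * chance
    assert accs["EP"] < chance + 0.25


def test_mlp_backend_satisfies_the_contract(small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    cfg = TrainConfig(backend_name="mlp", hidden_units=16, mlp_max_iter=150, seed=1)
    scorer = train_strategy_b(manifest, split, cfg, loader)
    matrix = score(scorer, manifest, split, ALL_PERSPECTIVES, loader)
    assert matrix.data.shape[0] == 5 * 2 * len(manifest.species_list)
    assert np.abs(matrix.data.to_numpy().sum(axis=1) - 1.0).max() < 1e-6


def test_augmented_training_is_deterministic(small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    cfg = TrainConfig(seed=2, augment_copies=1)
    m1 = score(train_strategy_a(manifest, split, cfg, loader)["FL"], manifest, split, "FL", loader)
    m2 = score(train_strategy_a(manifest, split, cfg, loader)["FL"], manifest, split, "FL", loader)
    assert np.array_equal(m1.data.to_numpy(), m2.data.to_numpy())


def test_score_matrix_file_round_trip(tmp_path, small_image_dataset):
    _, manifest, loader = small_image_dataset
    split = split_by_observation(manifest, 6, 2, 2, seed=0)
    scorers = train_strategy_a(manifest, split, TrainConfig(seed=0), loader)
    matrix = score(scorers["LB"], manifest, split, "LB", loader)
    path = tmp_path / "scores.csv"
    matrix.write(path)
    loaded = ScoreMatrix.read(path)
    assert list(loaded.data.columns) == list(matrix.data.columns)
    assert np.allclose(
        loaded.data.sort_index().to_numpy(), matrix.data.sort_index().to_numpy(), atol=1e-9
    )
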