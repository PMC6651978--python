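"""Top-k accuracy, combination-wide evaluation, species matrix."""

import numpy as np
import pandas as pd
import pytest

from plantfusion import (
    PERSPECTIVES,
    ScoreMatrix,
    SyntheticConfig,
    evaluate_all_combinations,
    generate_score_dataset,
    species_accuracy_matrix,
    split_by_observation,
    topk_accuracy,
)
from plantfusion.errors import IntegrityError


def brute_force_topk(frame: pd.DataFrame, truth, k):
    """Independent oracle: rank each row by (score desc, label asc) with
    python sorting and check membership of the true label in the first k."""
    per_obs = {}
    for obs_id, row in frame.iterrows():
        ranked = sorted(frame.columns, key=lambda sp: (-row[sp], sp))
        per_obs[obs_id] = truth[obs_id] in ranked[:k]
    out = {}
    for sp in sorted(set(truth[i] for i in frame.index)):
        hits = [per_obs[i] for i in frame.index if truth[i] == sp]
        out[sp] = sum(hits) / len(hits)
    return out


HAND_TABLE = pd.DataFrame(
    # 3 species × 2 observations, rankings chosen by hand
    [
        [0.7, 0.2, 0.1],  # a1: a first        -> top1 hit for a
        [0.3, 0.5, 0.2],  # a2: a second       -> top2 hit only
        [0.1, 0.8, 0.1],  # b1: b first
        [0.4, 0.4, 0.2],  # b2: tie a/b, label a wins -> b second
        [0.2, 0.3, 0.5],  # c1: c first
        [0.5, 0.3, 0.2],  # c2: c last
    ],
    index=["a1", "a2", "b1", "b2", "c1", "c2"],
    columns=["a", "b", "c"],
)
HAND_TRUTH = {"a1": "a", "a2": "a", "b1": "b", "b2": "b", "c1": "c", "c2": "c"}


def test_topk_on_handwritten_table_matches_manual_ranking():
    per1, mean1 = topk_accuracy(HAND_TABLE, HAND_TRUTH, 1)
    assert per1 == {"a": 0.5, "b": 0.5, "c": 0.5}
    assert mean1 == 0.5
    per2, mean2 = topk_accuracy(HAND_TABLE, HAND_TRUTH, 2)
    assert per2 == {"a": 1.0, "b": 1.0, "c": 0.5}
    assert mean2 == pytest.approx(5 / 6)


@pytest.mark.parametrize("k", [1, 2, 3])
def test_topk_agrees_with_brute_force_oracle_on_random_tables(k, rng):
    for _ in range(20):
        n_obs, n_species = rng.integers(2, 7), rng.integers(max(2, k), 6)
        species = [f"s{i}" for i in range(n_species)]
        if k > n_species:
            continue
        frame = pd.DataFrame(
            rng.random((n_obs, n_species)),
            index=[f"o{i}" for i in range(n_obs)],
            columns=species,
        )
        truth = {f"o{i}": species[rng.integers(n_species)] for i in range(n_obs)}
        per, mean = topk_accuracy(frame, truth, k)
        assert per == brute_force_topk(frame, truth, k)
        assert mean == pytest.approx(np.mean(list(per.values())))


def test_true_species_always_top_gives_perfect_accuracy():
    frame = HAND_TABLE.copy()
    for obs_id in frame.index:
        frame.loc[obs_id] = 0.1
        frame.loc[obs_id, HAND_TRUTH[obs_id]] = 0.8
    per, mean = topk_accuracy(frame, HAND_TRUTH, 1)
    assert mean == 1.0 and set(per.values()) == {1.0}


def test_missing_truth_label_is_an_error():
    with pytest.raises(IntegrityError, match="truth"):
        topk_accuracy(HAND_TABLE, {"a1": "a"}, 1)


def test_balanced_species_mean_equals_pooled_fraction(rng):
    """Under balance the unweighted species mean must equal the pooled
    per-image fraction to numerical precision."""
    species = [f"s{i}" for i in range(4)]
    rows, truth = [], {}
    for si, sp in enumerate(species):
        for j in range(5):
            obs = f"o{si}_{j}"
            rows.append(rng.random(4))
            truth[obs] = sp
    frame = pd.DataFrame(rows, index=list(truth), columns=species)
    per, mean = topk_accuracy(frame, truth, 1)
    ranked_hits = (frame.to_numpy().argmax(axis=1) ==
                   [species.index(truth[i]) for i in frame.index])
    assert abs(mean - ranked_hits.mean()) < 1e-12


@pytest.fixture(scope="module")
def score_report():
    config = SyntheticConfig(seed=21, n_observations_per_species=30)
    manifest, matrices = generate_score_dataset(config)
    split = split_by_observation(manifest, 20, 5, 5, seed=21)
    report = evaluate_all_combinations(matrices, manifest, split)
    return manifest, split, matrices, report


def test_report_contains_31_combinations(score_report):
    _, _, _, report = score_report
    assert len(report.per_combination) == 31
    assert len(report.combination_labels) == 31


def test_top5_dominates_top1_everywhere(score_report):
    _, _, _, report = score_report
    for res in report.per_combination.values():
        assert res.top5_mean >= res.top1_mean
        for t1, t5 in res.per_species.values():
            assert t5 >= t1


def test_group_means_are_unweighted_species_means(score_report):
    manifest, _, _, report = score_report
    res = report.per_combination["FF+FL"]
    for group, (t1, _) in res.per_group.items():
        members = [sp for sp in manifest.species_list if manifest.groups[sp] == group]
        assert t1 == pytest.approx(
            np.mean([res.per_species[sp][0] for sp in members]), abs=1e-12
        )


def test_fully_correct_counts_species_with_unit_accuracy(score_report):
    _, _, _, report = score_report
    for res in report.per_combination.values():
        expected = sum(1 for t1, _ in res.per_species.values() if t1 == 1.0)
        assert res.fully_correct == expected


def test_species_matrix_cells_match_independent_recomputation(score_report):
    manifest, split, matrices, report = score_report
    matrix = species_accuracy_matrix(report)
    assert matrix.shape == (len(manifest.species_list), 31)
    # recompute one combination from scratch through fuse + brute force
    from plantfusion import CombinationSpec, fuse

    combo = CombinationSpec(("FF", "LT"))
    fused = fuse({p: m.restrict(split.test_ids) for p, m in matrices.items()}, combo)
    truth = manifest.truth(split.test_ids)
    oracle = brute_force_topk(fused.data, truth, 1)
    for sp in manifest.species_list:
        assert matrix.loc[sp, "FF+LT"] == pytest.approx(oracle[sp], abs=1e-12)


def test_perfect_scores_give_unit_accuracy_and_full_species_count(tiny_manifest):
    manifest = tiny_manifest
    split = split_by_observation(manifest, 1, 1, 1, seed=0)
    species = manifest.species_list
    mats = {}
    for p in PERSPECTIVES:
        rows, keys = [], []
        for o in manifest.observations:
            vec = np.full(len(species), 0.01)
            vec[species.index(o.species)] = 1 - 0.01 * (len(species) - 1)
            rows.append(vec)
            keys.append((o.observation_id, p))
        frame = pd.DataFrame(
            rows,
            index=pd.MultiIndex.from_tuples(keys, names=["observation_id", "perspective"]),
            columns=species,
        )
        mats[p] = ScoreMatrix(data=frame)
    report = evaluate_all_combinations(mats, manifest, split)
    for res in report.per_combination.values():
        assert res.top1_mean == 1.0
        assert res.fully_correct == len(species)
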