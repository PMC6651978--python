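"""Balanced Top-1 / Top-5 evaluation over perspective combinations.

Because the dataset is completely balanced (same number of test
observations per species), the unweighted mean of per-species accuracies
equals the pooled per-image fraction; both are reported as one number.
Ranking ties are broken deterministically: species are ordered by (score
descending, species label ascending), and the true species counts as
Top-k only if it survives that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .backends import ScoreMatrix, TrainConfig, train_strategy_a, score as score_images_op
from .errors import IntegrityError
from .fusion import CombinationSpec, FusedScoreMatrix, enumerate_combinations, fuse
from .imageops import load_image
from .observations import PERSPECTIVES, DatasetManifest
from .splitting import SplitAssignment, reduce_training


def topk_accuracy(
    fused: FusedScoreMatrix | pd.DataFrame,
    truth: Mapping[str, str],
    k: int,
) -> tuple[dict[str, float], float]:
    """Per-species Top-k accuracy and its unweighted mean over species.

    A row counts as correct when fewer than ``k`` species outrank the true
    one under the deterministic ordering (score descending, label
    ascending).  Raises :class:`IntegrityError` for rows without a truth
    label.
    """
    frame = fused.data if isinstance(fused, FusedScoreMatrix) else fused
    species = list(frame.columns)
    if k > len(species):
        raise IntegrityError(f"k={k} exceeds the {len(species)} species scored")
    missing = [i for i in frame.index if i not in truth]
    if missing:
        raise IntegrityError(f"observation {missing[0]!r} has no truth label")
    scores = frame.to_numpy(dtype=float)
    # lexicographic rank of each column label, for tie-breaking
    label_rank = np.argsort(np.argsort(np.asarray(species, dtype=object)))
    col_of = {s: j for j, s in enumerate(species)}
    true_col = np.array([col_of[truth[i]] for i in frame.index])
    true_score = scores[np.arange(len(frame)), true_col]
    true_rank = label_rank[true_col]
    beats = (scores > true_score[:, None]).sum(axis=1)
    ties_ahead = (
        (scores == true_score[:, None]) & (label_rank[None, :] < true_rank[:, None])
    ).sum(axis=1)
    correct = (beats + ties_ahead) < k
    per_species: dict[str, float] = {}
    true_species = np.asarray([truth[i] for i in frame.index], dtype=object)
    for sp in sorted(set(true_species)):
        mask = true_species == sp
        per_species[sp] = float(correct[mask].mean())
    mean = float(np.mean(list(per_species.values())))
    return per_species, mean


@dataclass
class CombinationResult:
    """Accuracies of one perspective combination."""

    top1_mean: float
    top5_mean: float
    per_species: dict[str, tuple[float, float]]  # species -> (top1, top5)
    per_group: dict[str, tuple[float, float]]  # group -> (top1 mean, top5 mean)
    fully_correct: int  # species with top1 == 1.0
    top1_se: float  # standard error of the per-species top1 mean


@dataclass
class EvaluationReport:
    """Per-combination, per-species and per-group accuracies for one scored
    split."""

    per_combination: dict[str, CombinationResult]
    combination_labels: list[str]
    species_list: list[str]
    groups: dict[str, str]
    n_test_per_species: int
    split_seed: int
    k_top: int = 5

    def species_accuracy_matrix(self) -> pd.DataFrame:
        """Dense species × combination matrix of Top-1 accuracies (rows in
        species order, columns in combination enumeration order)."""
        data = {
            label: [self.per_combination[label].per_species[sp][0] for sp in self.species_list]
            for label in self.combination_labels
        }
        return pd.DataFrame(data, index=self.species_list, columns=self.combination_labels)

    def flat_table(self) -> pd.DataFrame:
        """Long-form summary: one row per (combination, group-scope)."""
        rows = []
        for label in self.combination_labels:
            res = self.per_combination[label]
            n = label.count("+") + 1
            rows.append((label, n, "all", res.top1_mean, res.top5_mean))
            for group in sorted(res.per_group):
                t1, t5 = res.per_group[group]
                rows.append((label, n, group, t1, t5))
        return pd.DataFrame(
            rows, columns=["combination", "n_perspectives", "scope", "top1", "top5"]
        )

    def to_json_dict(self) -> dict:
        return {
            "species_list": self.species_list,
            "groups": self.groups,
            "n_test_per_species": self.n_test_per_species,
            "split_seed": self.split_seed,
            "k_top": self.k_top,
            "combinations": {
                label: {
                    "top1_mean": res.top1_mean,
                    "top5_mean": res.top5_mean,
                    "top1_se": res.top1_se,
                    "fully_correct": res.fully_correct,
                    "per_species": {
                        sp: {"top1": t1, "top5": t5}
                        for sp, (t1, t5) in sorted(res.per_species.items())
                    },
                    "per_group": {
                        g: {"top1": t1, "top5": t5}
                        for g, (t1, t5) in sorted(res.per_group.items())
                    },
                }
                for label, res in self.per_combination.items()
            },
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _combination_result(
    fused: FusedScoreMatrix,
    truth: Mapping[str, str],
    groups: Mapping[str, str],
    k_top: int,
) -> CombinationResult:
    per1, mean1 = topk_accuracy(fused, truth, 1)
    perk, meank = topk_accuracy(fused, truth, k_top)
    per_species = {sp: (per1[sp], perk[sp]) for sp in per1}
    per_group: dict[str, tuple[float, float]] = {}
    for group in sorted(set(groups.values())):
        members = [sp for sp in per1 if groups[sp] == group]
        if members:
            per_group[group] = (
                float(np.mean([per1[sp] for sp in members])),
                float(np.mean([perk[sp] for sp in members])),
            )
    vals = np.array(list(per1.values()))
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return CombinationResult(
        top1_mean=mean1,
        top5_mean=meank,
        per_species=per_species,
        per_group=per_group,
        fully_correct=int(sum(1 for sp in per1 if per1[sp] == 1.0)),
        top1_se=se,
    )


def evaluate_all_combinations(
    matrices: Mapping[str, ScoreMatrix],
    manifest: DatasetManifest,
    split: SplitAssignment,
    combinations: Sequence[CombinationSpec] | None = None,
) -> EvaluationReport:
    """Fuse and evaluate every perspective combination (all 31 for the
    standard five codes).

    ``matrices`` maps perspective code to that perspective's test score
    matrix; a strategy-B scorer's output can be supplied for all five codes
    (see :func:`plantfusion.backends.strategy_b_matrices`) so that the two
    training strategies are compared through the identical path.
    """
    if combinations is None:
        combinations = enumerate_combinations(PERSPECTIVES)
    truth = manifest.truth(split.test_ids)
    # generators may emit scores for every observation; keep test rows only
    matrices = {p: m.restrict(split.test_ids) for p, m in matrices.items()}
    k_top = min(5, len(manifest.species_list))
    per_combination: dict[str, CombinationResult] = {}
    for combo in combinations:
        fused = fuse(matrices, combo)
        per_combination[combo.label] = _combination_result(
            fused, truth, manifest.groups, k_top
        )
    n_test = split.per_species_counts[manifest.species_list[0]][2]
    return EvaluationReport(
        per_combination=per_combination,
        combination_labels=[c.label for c in combinations],
        species_list=manifest.species_list,
        groups=dict(manifest.groups),
        n_test_per_species=n_test,
        split_seed=split.seed,
        k_top=k_top,
    )


def species_accuracy_matrix(report: EvaluationReport) -> pd.DataFrame:
    """Functional alias for :meth:`EvaluationReport.species_accuracy_matrix`."""
    return report.species_accuracy_matrix()


def ablation_curves(
    manifest: DatasetManifest,
    base_split: SplitAssignment,
    training_sizes: Sequence[int],
    config: TrainConfig = TrainConfig(),
    image_loader=load_image,
    combinations: Sequence[CombinationSpec] | None = None,
) -> tuple[pd.DataFrame, dict[int, EvaluationReport]]:
    """Retrain strategy-A scorers at several nested training sizes against
    one fixed test set and evaluate each.

    Sizes are processed in descending order; each reduced split is derived
    from the previous one, so training sets are nested and the test set is
    shared by construction.  Returns the long-form accuracy table (one row
    per training size × combination × scope) and the full report per size.
    """
    sizes = sorted(set(int(s) for s in training_sizes), reverse=True)
    reports: dict[int, EvaluationReport] = {}
    rows = []
    current = base_split
    for size in sizes:
        if size != current.n_train:
            current = reduce_training(current, manifest, size, seed=base_split.seed)
        scorers = train_strategy_a(manifest, current, config, image_loader)
        matrices = {
            p: score_images_op(scorers[p], manifest, current, p, image_loader)
            for p in PERSPECTIVES
        }
        report = evaluate_all_combinations(matrices, manifest, current, combinations)
        reports[size] = report
        table = report.flat_table()
        table.insert(0, "training_size", size)
        rows.append(table)
    return pd.concat(rows, ignore_index=True), reports
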