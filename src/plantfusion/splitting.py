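"""Observation-level train/validation/test splitting.

Splitting happens on whole observations, never on individual images: all
five images of one plant travel together into the same subset, so a test
plant is never partially seen during training.  Splits are balanced per
species and deterministic given ``(manifest, sizes, seed)``.

A split can be *reduced*: the training set is subsampled per species while
validation and test sets are inherited unchanged.  Repeated reduction yields
a nested chain (e.g. 80 ⊃ 60 ⊃ 40 ⊃ 20 training observations per species)
that shares one fixed test set, so accuracy differences along the chain
reflect training-set size only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import SplitSizeError, IntegrityError
from .observations import DatasetManifest

_SUBSETS = ("train", "val", "test")


def _species_rng(seed: int, species: str) -> np.random.Generator:
    """Independent random stream per (seed, species).

    Derived by hashing so that adding or removing one species never
    perturbs the draws of any other species.
    """
    digest = hashlib.sha256(f"{seed}:{species}".encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass
class SplitAssignment:
    """Disjoint train/validation/test observation-id sets, balanced per
    species."""

    train_ids: frozenset[str]
    validation_ids: frozenset[str]
    test_ids: frozenset[str]
    per_species_counts: dict[str, tuple[int, int, int]]
    seed: int
    parent: Optional["SplitAssignment"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        sets = (self.train_ids, self.validation_ids, self.test_ids)
        total = sum(len(s) for s in sets)
        if len(self.train_ids | self.validation_ids | self.test_ids) != total:
            raise IntegrityError("train/validation/test sets overlap")

    @property
    def n_train(self) -> int:
        """Training observations per species (balanced by construction)."""
        return next(iter(self.per_species_counts.values()))[0]

    def subset_ids(self, subset: str) -> frozenset[str]:
        return {
            "train": self.train_ids,
            "val": self.validation_ids,
            "test": self.test_ids,
        }[subset]


def split_by_observation(
    manifest: DatasetManifest,
    n_train: int,
    n_val: int,
    n_test: int,
    seed: int,
) -> SplitAssignment:
    """Sample a per-species balanced split of whole observations.

    For every species, ``n_train + n_val + n_test`` observations are drawn
    without replacement from that species' observations using a dedicated
    seeded stream; the first ``n_train`` go to training, the next ``n_val``
    to validation, the rest to test.  Raises :class:`SplitSizeError` naming
    the first species with too few observations.
    """
    train: set[str] = set()
    val: set[str] = set()
    test: set[str] = set()
    counts: dict[str, tuple[int, int, int]] = {}
    need = n_train + n_val + n_test
    for species in manifest.species_list:
        ids = sorted(o.observation_id for o in manifest.observations_of(species))
        if len(ids) < need:
            raise SplitSizeError(
                f"species {species!r} has {len(ids)} observations, "
                f"need {need} (= {n_train}+{n_val}+{n_test})"
            )
        rng = _species_rng(seed, species)
        order = rng.permutation(len(ids))
        picked = [ids[i] for i in order[:need]]
        train.update(picked[:n_train])
        val.update(picked[n_train : n_train + n_val])
        test.update(picked[n_train + n_val :])
        counts[species] = (n_train, n_val, n_test)
    return SplitAssignment(
        train_ids=frozenset(train),
        validation_ids=frozenset(val),
        test_ids=frozenset(test),
        per_species_counts=counts,
        seed=seed,
    )


def reduce_training(
    split: SplitAssignment,
    manifest: DatasetManifest,
    n_reduced: int,
    seed: int,
) -> SplitAssignment:
    """Subsample the training set per species; keep validation and test
    sets identical to the parent's.

    The child's training set is a per-species subset of the parent's, so a
    chain of reductions is nested.  ``n_reduced`` equal to the parent's
    training size returns the identical training set.
    """
    parent_n_train = split.n_train
    if n_reduced > parent_n_train:
        raise SplitSizeError(
            f"cannot reduce training to {n_reduced}: parent has "
            f"{parent_n_train} training observations per species"
        )
    train: set[str] = set()
    counts: dict[str, tuple[int, int, int]] = {}
    for species in manifest.species_list:
        ids = sorted(
            o.observation_id
            for o in manifest.observations_of(species)
            if o.observation_id in split.train_ids
        )
        if n_reduced == len(ids):
            picked = ids
        else:
            rng = _species_rng(seed, species)
            order = rng.permutation(len(ids))
            picked = [ids[i] for i in order[:n_reduced]]
        train.update(picked)
        _, n_val, n_test = split.per_species_counts[species]
        counts[species] = (n_reduced, n_val, n_test)
    return SplitAssignment(
        train_ids=frozenset(train),
        validation_ids=split.validation_ids,
        test_ids=split.test_ids,
        per_species_counts=counts,
        seed=seed,
        parent=split,
    )


def write_split(split: SplitAssignment, path: str | Path) -> None:
    """Write a split as delimited text: comment header lines carrying the
    seed (and the parent's training size for reduced splits), then one
    ``observation_id,subset`` row per observation, sorted for byte-stable
    output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# seed={split.seed}"]
    if split.parent is not None:
        lines.append(f"# derived_from=n_train={split.parent.n_train}")
    lines.append("observation_id,subset")
    rows = (
        [(i, "train") for i in split.train_ids]
        + [(i, "val") for i in split.validation_ids]
        + [(i, "test") for i in split.test_ids]
    )
    for obs_id, subset in sorted(rows):
        lines.append(f"{obs_id},{subset}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_split(path: str | Path, manifest: DatasetManifest) -> SplitAssignment:
    """Read a split file back against its manifest (recomputes per-species
    counts; raises :class:`IntegrityError` if counts are unbalanced)."""
    path = Path(path)
    seed = 0
    assign: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if "seed=" in line:
                seed = int(line.split("seed=")[1].strip())
            continue
        if line.startswith("observation_id"):
            continue
        obs_id, subset = line.split(",")
        if subset not in _SUBSETS:
            raise IntegrityError(f"{path}: line {lineno}: unknown subset {subset!r}")
        assign[obs_id] = subset
    sets: dict[str, set[str]] = {s: set() for s in _SUBSETS}
    for obs_id, subset in assign.items():
        sets[subset].add(obs_id)
    counts: dict[str, tuple[int, int, int]] = {}
    for species in manifest.species_list:
        ids = {o.observation_id for o in manifest.observations_of(species)}
        counts[species] = tuple(len(sets[s] & ids) for s in _SUBSETS)  # type: ignore[assignment]
    if len(set(counts.values())) > 1:
        raise IntegrityError(f"{path}: unbalanced per-species subset counts")
    return SplitAssignment(
        train_ids=frozenset(sets["train"]),
        validation_ids=frozenset(sets["val"]),
        test_ids=frozenset(sets["test"]),
        per_species_counts=counts,
        seed=seed,
    )
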