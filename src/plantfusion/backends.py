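"""Pluggable per-species scorers and the two training strategies.

The study design compares two ways of training image classifiers on
five-perspective observations:

* **Strategy A** — one scorer per perspective, each fitted only on training
  images of its own perspective.
* **Strategy B** — a single scorer fitted on the union of all training
  images irrespective of perspective.

Either way a fitted scorer maps one test image to a probability vector over
the species list (softmax-normalized confidence scores), which downstream
sum-rule fusion averages across perspectives.

The reference recipe of the study (Inception-ResNet-v2 transfer learning,
batch 32, learning rate 0.003, RMSProp with weight decay 4e-5, 200 000
steps) is recorded in :class:`TrainConfig` for documentation; the shipped
desk-scale backends are a multinomial logistic model and a small multilayer
perceptron, both operating on downsampled pixels.  Any object satisfying
the scorer contract (probability rows, deterministic given its seed) can be
substituted: evaluation depends on the contract only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .errors import InputError, IntegrityError, TrainingError
from .imageops import AugmentSpec, PreprocessSpec, augment, load_image, preprocess
from .observations import PERSPECTIVES, DatasetManifest
from .splitting import SplitAssignment

#: Perspective scope of a strategy-B scorer.
ALL_PERSPECTIVES = "ALL"

ImageLoader = Callable[[str], np.ndarray]


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration.

    The first block records the reference transfer-learning recipe; these
    values are carried as provenance and are honored by any backend that
    can use them.  The second block holds the desk-scale knobs the shipped
    backends actually consume.
    """

    # reference recipe (documentation defaults)
    batch_size: int = 32
    learning_rate: float = 0.003
    max_steps: int = 200_000
    optimizer_name: str = "rmsprop"
    weight_decay: float = 0.00004

    # desk-scale backend knobs
    backend_name: str = "logistic"  # "logistic" | "mlp"
    feature_size: int = 12  # side length of the downsampled pixel grid
    crop_fraction: float = 0.875
    l2_c: float = 10.0  # inverse L2 strength of the logistic backend
    hidden_units: int = 64  # hidden layer width of the mlp backend
    mlp_max_iter: int = 300
    augment_copies: int = 0  # extra augmented replicas per training image
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "learning_rate", "max_steps", "weight_decay",
                     "feature_size", "l2_c", "hidden_units", "mlp_max_iter"):
            if getattr(self, name) <= 0:
                raise InputError(f"TrainConfig.{name} must be positive")
        if self.augment_copies < 0:
            raise InputError("TrainConfig.augment_copies must be >= 0")
        if self.backend_name not in ("logistic", "mlp"):
            raise InputError(f"unknown backend {self.backend_name!r}")

    def preprocess_spec(self) -> PreprocessSpec:
        return PreprocessSpec(crop_fraction=self.crop_fraction, target_size=self.feature_size)


@dataclass
class ScoreMatrix:
    """Per-image confidence scores: one row per (observation_id,
    perspective) test image, one column per species (lexicographic order),
    each row a probability vector."""

    data: pd.DataFrame  # MultiIndex (observation_id, perspective) × species
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.nlevels != 2:
            raise IntegrityError("ScoreMatrix index must be (observation_id, perspective)")
        if self.data.index.has_duplicates:
            raise IntegrityError("duplicate (observation_id, perspective) rows")
        self.validate()

    def validate(self, atol: float = 1e-6) -> None:
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise IntegrityError("non-finite scores")
        sums = values.sum(axis=1)
        if len(sums) and np.abs(sums - 1.0).max() > atol:
            raise IntegrityError("score rows must sum to 1")

    @property
    def species_list(self) -> list[str]:
        return list(self.data.columns)

    def rows_for_perspective(self, perspective: str) -> pd.DataFrame:
        """Rows of one perspective, re-indexed by observation_id."""
        sub = self.data.xs(perspective, level=1)
        return sub

    def restrict(self, observation_ids) -> "ScoreMatrix":
        """Rows whose observation_id is in the given set (e.g. a split's
        test observations)."""
        wanted = set(observation_ids)
        mask = self.data.index.get_level_values(0).isin(wanted)
        return ScoreMatrix(data=self.data[mask], provenance=dict(self.provenance))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        flat = self.data.reset_index()
        flat.columns = ["observation_id", "perspective"] + list(self.data.columns)
        flat = flat.sort_values(["observation_id", "perspective"])
        flat.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path, provenance: dict | None = None) -> "ScoreMatrix":
        frame = pd.read_csv(path, dtype={"observation_id": str, "perspective": str})
        frame = frame.set_index(["observation_id", "perspective"])
        return cls(data=frame, provenance=provenance or {"source": str(path)})


class Scorer:
    """A fitted per-species scorer.

    ``perspective_scope`` is a single perspective code for strategy-A
    scorers or :data:`ALL_PERSPECTIVES` for a strategy-B scorer.
    """

    def __init__(
        self,
        species_list: list[str],
        perspective_scope: str,
        model,
        config: TrainConfig,
    ) -> None:
        self.species_list = list(species_list)
        self.perspective_scope = perspective_scope
        self.model = model
        self.config = config
        self.n_training_images_: int | None = None

    def featurize(self, image: np.ndarray) -> np.ndarray:
        """Preprocess one image and flatten to the backend feature vector."""
        small = preprocess(image, self.config.preprocess_spec())
        return small.astype(np.float64).ravel() / 255.0

    def score_images(self, images: list[np.ndarray]) -> np.ndarray:
        """Probability matrix (n_images × n_species) in species_list order."""
        X = np.stack([self.featurize(img) for img in images])
        proba = self.model.predict_proba(X)
        # sklearn orders columns by model.classes_ (species indices 0..S-1)
        order = np.argsort(self.model.classes_)
        proba = proba[:, order]
        return proba


def _make_model(config: TrainConfig):
    if config.backend_name == "logistic":
        return LogisticRegression(C=config.l2_c, max_iter=1000)
    return MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        max_iter=config.mlp_max_iter,
        random_state=config.seed,
    )


def _training_rows(
    manifest: DatasetManifest, split: SplitAssignment, perspective: str
) -> list[tuple[str, str, str, str]]:
    """(observation_id, perspective, path, species) training rows in a
    deterministic order."""
    codes = PERSPECTIVES if perspective == ALL_PERSPECTIVES else (perspective,)
    rows = [
        (o.observation_id, p, o.images[p], o.species)
        for o in manifest.observations
        if o.observation_id in split.train_ids
        for p in codes
    ]
    rows.sort()
    return rows


def _fit_scorer(
    manifest: DatasetManifest,
    split: SplitAssignment,
    config: TrainConfig,
    perspective: str,
    image_loader: ImageLoader,
) -> Scorer:
    rows = _training_rows(manifest, split, perspective)
    if not rows:
        raise TrainingError(f"no training images for perspective {perspective!r}")
    species_list = manifest.species_list
    index = {s: i for i, s in enumerate(species_list)}
    spec = PreprocessSpec(crop_fraction=config.crop_fraction, target_size=config.feature_size)
    X: list[np.ndarray] = []
    y: list[int] = []
    for obs_id, p, path, species in rows:
        image = image_loader(path)
        variants = [image]
        for copy in range(config.augment_copies):
            digest = hashlib.sha256(
                f"{config.seed}:{obs_id}:{p}:{copy}".encode("utf-8")
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
            variants.append(augment(image, config.augment, rng))
        for img in variants:
            small = preprocess(img, spec)
            X.append(small.astype(np.float64).ravel() / 255.0)
            y.append(index[species])
    seen = set(y)
    missing = [s for s, i in index.items() if i not in seen]
    if missing:
        raise TrainingError(f"species without training images: {missing}")
    model = _make_model(config)
    model.fit(np.asarray(X), np.asarray(y))
    scorer = Scorer(species_list, perspective, model, config)
    scorer.n_training_images_ = len(rows)
    return scorer


def train_strategy_a(
    manifest: DatasetManifest,
    split: SplitAssignment,
    config: TrainConfig = TrainConfig(),
    image_loader: ImageLoader = load_image,
) -> dict[str, Scorer]:
    """Fit one scorer per perspective, each on its own perspective's
    training images only."""
    return {
        p: _fit_scorer(manifest, split, config, p, image_loader) for p in PERSPECTIVES
    }


def train_strategy_b(
    manifest: DatasetManifest,
    split: SplitAssignment,
    config: TrainConfig = TrainConfig(),
    image_loader: ImageLoader = load_image,
) -> Scorer:
    """Fit a single scorer on all training images of all perspectives."""
    return _fit_scorer(manifest, split, config, ALL_PERSPECTIVES, image_loader)


def score(
    scorer: Scorer,
    manifest: DatasetManifest,
    split: SplitAssignment,
    perspective: str,
    image_loader: ImageLoader = load_image,
) -> ScoreMatrix:
    """Score the split's test images of one perspective (or of all five
    with ``perspective="ALL"``) with a fitted scorer.

    Returns one probability row per test image, keyed by
    ``(observation_id, perspective)``.
    """
    codes = PERSPECTIVES if perspective == ALL_PERSPECTIVES else (perspective,)
    keys: list[tuple[str, str]] = []
    images: list[np.ndarray] = []
    for o in sorted(manifest.observations, key=lambda o: o.observation_id):
        if o.observation_id not in split.test_ids:
            continue
        for p in codes:
            keys.append((o.observation_id, p))
            images.append(image_loader(o.images[p]))
    if not keys:
        raise IntegrityError("split has no test observations")
    proba = scorer.score_images(images)
    frame = pd.DataFrame(
        proba,
        index=pd.MultiIndex.from_tuples(keys, names=["observation_id", "perspective"]),
        columns=scorer.species_list,
    )
    return ScoreMatrix(
        data=frame,
        provenance={
            "scorer_scope": scorer.perspective_scope,
            "backend": scorer.config.backend_name,
            "split_seed": split.seed,
            "n_train_per_species": split.n_train,
        },
    )


def strategy_b_matrices(
    scorer: Scorer,
    manifest: DatasetManifest,
    split: SplitAssignment,
    image_loader: ImageLoader = load_image,
) -> dict[str, ScoreMatrix]:
    """Score all five perspectives' test images with one strategy-B scorer
    and return per-perspective matrices, so that A-vs-B comparisons run
    through the identical fusion/evaluation path."""
    full = score(scorer, manifest, split, ALL_PERSPECTIVES, image_loader)
    out: dict[str, ScoreMatrix] = {}
    for p in PERSPECTIVES:
        sub = full.data[full.data.index.get_level_values(1) == p]
        out[p] = ScoreMatrix(data=sub, provenance=dict(full.provenance, perspective=p))
    return out
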