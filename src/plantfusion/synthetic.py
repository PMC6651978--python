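"""Synthetic balanced multi-perspective datasets with controllable
difficulty.

Two tiers emulate the statistical structure of a structured-observation
plant dataset without any botany:

* **Score level** — per-perspective confidence scores are drawn directly
  from a latent-logit model, bypassing image rendering and training.  For
  observation *o* of species *c* seen from perspective *p*, the logit
  vector is

      z = d_p · v_c  +  σ_b · b_o  +  σ · ε ,

  where ``v_c`` is the species' signal direction, ``b_o`` an
  observation-level draw shared by all five perspectives of *o* (a stand-in
  for habitat background common to one plant's images), and ``ε``
  independent noise; scores are ``softmax(z)``.  The per-perspective
  discriminability ``d_p`` controls how informative that perspective is.

* **Image level** — small RGB images are rendered: a noisy gray field plus
  a species-coded glyph (position, shape and color derived from species
  identity; stripe texture varies by perspective) whose contrast is
  proportional to ``d_p``, plus an observation-level background tint of
  strength ``σ_b`` shared across the observation's five images.  This tier
  exercises the full preprocessing / training / scoring path.

Species may be organized into clusters of look-alikes (the grass-like
case): cluster members share a fraction ``ρ`` of their signal, making them
progressively confusable as ``ρ → 1``.  Clustered species are labelled
``"grass"``, singletons ``"forb"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .backends import ScoreMatrix
from .errors import InputError
from .observations import PERSPECTIVES, DatasetManifest, Observation

#: Default per-perspective discriminability.  The ordering (flower views
#: most informative, entire plant least) mirrors what field studies of
#: multi-organ plant photographs report; the spacing keeps the five
#: single-perspective accuracies well separated at desk scale.
DEFAULT_DISCRIMINABILITY: dict[str, float] = {
    "EP": 1.0,
    "LT": 1.75,
    "LB": 2.5,
    "FF": 3.25,
    "FL": 4.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic generators.

    ``discriminability`` maps each perspective code to a signal strength
    d_p ≥ 0 (0 = that perspective carries no species information);
    ``background_confound`` (σ_b) scales the observation-level component
    shared across one observation's five images; ``group_structure`` lists
    clusters of species indices whose signal is blended with within-cluster
    similarity ``cluster_similarity`` (ρ); ``noise_scale`` (σ) scales
    independent per-image noise.
    """

    n_species: int = 10
    n_observations_per_species: int = 30
    discriminability: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISCRIMINABILITY)
    )
    background_confound: float = 0.0
    group_structure: Sequence[Sequence[int]] | None = ((0, 1, 2), (3, 4, 5))
    cluster_similarity: float = 0.3
    noise_scale: float = 1.0
    image_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_observations_per_species < 1:
            raise InputError("counts must be >= 1")
        if not 0.0 <= self.cluster_similarity < 1.0:
            raise InputError("cluster_similarity must be in [0, 1)")
        if self.noise_scale <= 0:
            raise InputError("noise_scale must be > 0")
        if self.background_confound < 0:
            raise InputError("background_confound must be >= 0")
        if set(self.discriminability) != set(PERSPECTIVES):
            raise InputError(f"discriminability must cover exactly {PERSPECTIVES}")
        if any(v < 0 for v in self.discriminability.values()):
            raise InputError("discriminability values must be >= 0")
        if self.group_structure is not None:
            flat = [i for cl in self.group_structure for i in cl]
            if len(flat) != len(set(flat)):
                raise InputError("species clusters must be disjoint")
            if flat and (min(flat) < 0 or max(flat) >= self.n_species):
                raise InputError("cluster species indices out of range")

    def species_names(self) -> list[str]:
        return [f"species_{i:03d}" for i in range(self.n_species)]

    def cluster_of(self) -> dict[int, int | None]:
        """Species index -> cluster index (or None for singletons)."""
        out: dict[int, int | None] = {i: None for i in range(self.n_species)}
        if self.group_structure:
            for k, cluster in enumerate(self.group_structure):
                for i in cluster:
                    out[i] = k
        return out


def _build_manifest(config: SyntheticConfig, path_of) -> DatasetManifest:
    names = config.species_names()
    cluster = config.cluster_of()
    observations = []
    obs_counter = 0
    for ci, sp in enumerate(names):
        group = "grass" if cluster[ci] is not None else "forb"
        for _ in range(config.n_observations_per_species):
            obs_id = f"obs{obs_counter:05d}"
            observations.append(
                Observation(
                    observation_id=obs_id,
                    species=sp,
                    group=group,
                    images={p: path_of(obs_id, p) for p in PERSPECTIVES},
                )
            )
            obs_counter += 1
    return DatasetManifest(observations=observations)


# ---------------------------------------------------------------------------
# score-level tier
# ---------------------------------------------------------------------------

def _signal_directions(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-species signal directions v_c in logit space.

    Each species starts from its own coordinate axis, tilted by a small
    random component (so species differ slightly in intrinsic difficulty),
    then blended with its cluster's shared direction by ρ.
    """
    S = config.n_species
    tilt = 0.15
    e = np.eye(S) + tilt * rng.standard_normal((S, S))
    e /= np.linalg.norm(e, axis=1, keepdims=True)
    v = e.copy()
    rho = config.cluster_similarity
    if config.group_structure and rho > 0:
        for cluster in config.group_structure:
            members = list(cluster)
            u = e[members].mean(axis=0)
            u /= np.linalg.norm(u)
            for c in members:
                v[c] = (1.0 - rho) * e[c] + rho * u
    return v


def generate_score_dataset(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[DatasetManifest, dict[str, ScoreMatrix]]:
    """Draw per-perspective score matrices for a balanced synthetic
    dataset.

    Returns the manifest (image paths are placeholders, never opened) and
    one :class:`ScoreMatrix` per perspective covering **all** observations;
    downstream code restricts rows to a split's test subset.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    manifest = _build_manifest(config, lambda o, p: f"scores/{o}_{p}.png")
    names = config.species_names()
    S = config.n_species
    v = _signal_directions(config, rng)
    n_obs = len(manifest.observations)
    species_idx = np.array([names.index(o.species) for o in manifest.observations])
    b = rng.standard_normal((n_obs, S))  # shared across the 5 perspectives
    matrices: dict[str, ScoreMatrix] = {}
    obs_ids = [o.observation_id for o in manifest.observations]
    for p in PERSPECTIVES:
        d_p = float(config.discriminability[p])
        eps = rng.standard_normal((n_obs, S))
        z = d_p * v[species_idx] + config.background_confound * b + config.noise_scale * eps
        z -= z.max(axis=1, keepdims=True)
        scores = np.exp(z)
        scores /= scores.sum(axis=1, keepdims=True)
        frame = pd.DataFrame(
            scores,
            index=pd.MultiIndex.from_tuples(
                [(i, p) for i in obs_ids], names=["observation_id", "perspective"]
            ),
            columns=names,
        )
        matrices[p] = ScoreMatrix(
            data=frame, provenance={"tier": "score", "seed": config.seed, "d": d_p}
        )
    return manifest, matrices


# ---------------------------------------------------------------------------
# image-level tier
# ---------------------------------------------------------------------------

# Render scales chosen once so that, at the default discriminability and
# desk-scale backends, single-perspective accuracies span chance to ~0.85
# rather than saturating: a saturated benchmark cannot separate designs.
_GLYPH_AMP = 0.02
_BACKGROUND_AMP = 0.12
_NOISE_AMP = 0.10


def _stripe_field(size: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth oriented stripe pattern in [-1, 1]."""
    yy, xx = np.mgrid[0:size, 0:size] / size
    theta = rng.uniform(0, np.pi)
    freq = rng.uniform(2.0, 5.0) * 2 * np.pi
    phase = rng.uniform(0, 2 * np.pi)
    return np.sin(freq * (np.cos(theta) * xx + np.sin(theta) * yy) + phase)


def _render_images(config: SyntheticConfig) -> tuple[DatasetManifest, dict[str, np.ndarray]]:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    size = config.image_size
    S = config.n_species
    names = config.species_names()
    cluster = config.cluster_of()
    rho = config.cluster_similarity

    # species-coded appearance: disc position/radius and color direction
    centers = rng.uniform(0.25, 0.75, size=(S, 2))
    radii = rng.uniform(0.15, 0.30, size=S)
    colors = rng.standard_normal((S, 3))
    colors /= np.linalg.norm(colors, axis=1, keepdims=True)
    # cluster members share appearance up to a (1 - rho) individual offset
    if config.group_structure:
        for members in config.group_structure:
            members = list(members)
            c_center = centers[members].mean(axis=0)
            c_color = colors[members].mean(axis=0)
            c_color /= np.linalg.norm(c_color)
            for c in members:
                centers[c] = rho * c_center + (1 - rho) * centers[c]
                mixed = rho * c_color + (1 - rho) * colors[c]
                colors[c] = mixed / np.linalg.norm(mixed)

    # perspective-specific textures, blended within clusters like colors
    textures = np.empty((S, len(PERSPECTIVES), size, size))
    for c in range(S):
        for pi in range(len(PERSPECTIVES)):
            textures[c, pi] = _stripe_field(size, rng)
    if config.group_structure:
        for members in config.group_structure:
            members = list(members)
            shared = textures[members].mean(axis=0)
            for c in members:
                textures[c] = rho * shared + (1 - rho) * textures[c]

    yy, xx = np.mgrid[0:size, 0:size] / size
    masks = np.empty((S, size, size))
    for c in range(S):
        dist2 = (yy - centers[c, 0]) ** 2 + (xx - centers[c, 1]) ** 2
        masks[c] = (dist2 <= radii[c] ** 2).astype(float)

    manifest = _build_manifest(config, lambda o, p: f"images/{o}_{p}.png")
    images: dict[str, np.ndarray] = {}
    for o in manifest.observations:
        c = names.index(o.species)
        # observation-level background tint shared by all five images
        tint_color = rng.standard_normal(3)
        tint_color /= np.linalg.norm(tint_color)
        grad_dir = rng.standard_normal(2)
        ramp = grad_dir[0] * (yy - 0.5) + grad_dir[1] * (xx - 0.5)
        ramp = ramp / (np.abs(ramp).max() + 1e-12)
        background = (
            _BACKGROUND_AMP
            * config.background_confound
            * ramp[..., None]
            * tint_color[None, None, :]
        )
        for pi, p in enumerate(PERSPECTIVES):
            d_p = float(config.discriminability[p])
            glyph = (
                _GLYPH_AMP
                * d_p
                * (masks[c] * textures[c, pi])[..., None]
                * colors[c][None, None, :]
            )
            noise = _NOISE_AMP * config.noise_scale * rng.standard_normal((size, size, 3))
            img = np.clip(0.5 + glyph + background + noise, 0.0, 1.0)
            images[o.images[p]] = np.round(img * 255.0).astype(np.uint8)
    return manifest, images


def generate_image_arrays(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[DatasetManifest, dict[str, np.ndarray]]:
    """Render the image-level dataset in memory.

    Returns the manifest and a mapping from each manifest image path to its
    uint8 RGB array; pair it with :func:`array_loader` to run the training
    pipeline without touching disk.
    """
    return _render_images(config)


def array_loader(images: Mapping[str, np.ndarray]):
    """Image loader over an in-memory path -> array mapping."""

    def load(path: str) -> np.ndarray:
        try:
            return images[path]
        except KeyError:
            raise IOError(f"image file not found: {path}") from None

    return load


def generate_image_dataset(
    config: SyntheticConfig,
    out_dir: str | Path,
) -> DatasetManifest:
    """Render the image-level dataset to ``out_dir``.

    Writes ``n_species × n_observations × 5`` PNG files plus
    ``manifest.csv`` (image paths relative to ``out_dir``'s parent
    structure are made absolute).  Bit-identical output for identical
    config.  Raises ``IOError`` for an unwritable directory.
    """
    from .observations import write_manifest

    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    manifest, images = _render_images(config)
    rebased = []
    for o in manifest.observations:
        paths = {p: str(out_dir / o.images[p]) for p in PERSPECTIVES}
        rebased.append(
            Observation(
                observation_id=o.observation_id,
                species=o.species,
                group=o.group,
                images=paths,
            )
        )
        for p in PERSPECTIVES:
            Image.fromarray(images[o.images[p]], mode="RGB").save(paths[p])
    manifest = DatasetManifest(observations=rebased)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def write_score_dataset(
    config: SyntheticConfig,
    out_dir: str | Path,
) -> tuple[DatasetManifest, dict[str, ScoreMatrix]]:
    """Generate the score-level dataset and write manifest plus one score
    file per perspective to ``out_dir``."""
    from .observations import write_manifest

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, matrices = generate_score_dataset(config)
    write_manifest(manifest, out_dir / "manifest.csv")
    for p, m in matrices.items():
        m.write(out_dir / f"scores_{p}.csv")
    return manifest, matrices
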