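"""Structured multi-perspective plant observations.

An *observation* records one plant individual photographed from five
predefined perspectives: the entire plant in its habitat, the flower seen
frontally and laterally, and the upper and lower leaf surface.  A
:class:`DatasetManifest` is a balanced collection of observations — every
species contributes the same number of observations — and is the unit on
which splitting, scoring, fusion and evaluation operate.

Manifests are stored as long-form delimited text, one row per image::

    observation_id,species,group,perspective,path

with ``perspective`` drawn from the five fixed codes in :data:`PERSPECTIVES`.
Comma and tab delimiters are both accepted (auto-detected from the header).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, ManifestError

#: The five fixed perspective codes, in canonical display order.
PERSPECTIVES: tuple[str, ...] = ("EP", "FF", "FL", "LT", "LB")

#: Human-readable names for the perspective codes.
PERSPECTIVE_NAMES: dict[str, str] = {
    "EP": "entire plant",
    "FF": "flower frontal",
    "FL": "flower lateral",
    "LT": "leaf top",
    "LB": "leaf back",
}

_MANIFEST_COLUMNS = ["observation_id", "species", "group", "perspective", "path"]


@dataclass(frozen=True)
class Observation:
    """One plant individual: a species label, a group label and exactly one
    image path per perspective code.

    Parameters
    ----------
    observation_id
        Unique identifier within a manifest.
    species
        Species label (non-empty free string).
    group
        Group label; ``"forb"`` and ``"grass"`` are conventional but any
        partition of the species is accepted.
    images
        Mapping from perspective code to image path.  Must contain exactly
        the five codes in :data:`PERSPECTIVES`.
    """

    observation_id: str
    species: str
    group: str
    images: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.species:
            raise ManifestError(f"observation {self.observation_id!r}: empty species")
        if not self.group:
            raise ManifestError(f"observation {self.observation_id!r}: empty group")
        got = set(self.images)
        want = set(PERSPECTIVES)
        if got != want:
            missing = sorted(want - got)
            extra = sorted(got - want)
            raise ManifestError(
                f"observation {self.observation_id!r}: perspectives "
                f"missing={missing} unexpected={extra}"
            )


@dataclass
class DatasetManifest:
    """A balanced collection of observations.

    ``species_list`` is the lexicographically sorted list of distinct species
    labels; it defines the column order of every score matrix derived from
    this manifest.  ``groups`` maps each species to its group label.
    """

    observations: list[Observation]
    species_list: list[str] = field(init=False)
    groups: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        ids = [o.observation_id for o in self.observations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate observation ids: {dupes[:5]}")
        self.species_list = sorted({o.species for o in self.observations})
        groups: dict[str, str] = {}
        for o in self.observations:
            prev = groups.setdefault(o.species, o.group)
            if prev != o.group:
                raise ManifestError(
                    f"species {o.species!r} assigned to two groups: "
                    f"{prev!r} and {o.group!r}"
                )
        self.groups = groups

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def n_images(self) -> int:
        """Total number of image records (``5 × |observations|``)."""
        return len(self.observations) * len(PERSPECTIVES)

    def by_id(self, observation_id: str) -> Observation:
        try:
            return self._index[observation_id]
        except AttributeError:
            self._index = {o.observation_id: o for o in self.observations}
            return self._index[observation_id]

    def observations_of(self, species: str) -> list[Observation]:
        return [o for o in self.observations if o.species == species]

    def truth(self, ids: Iterable[str] | None = None) -> dict[str, str]:
        """Ground-truth mapping ``observation_id -> species``."""
        if ids is None:
            return {o.observation_id: o.species for o in self.observations}
        return {i: self.by_id(i).species for i in ids}

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (o.observation_id, o.species, o.group, p, o.images[p])
            for o in self.observations
            for p in PERSPECTIVES
        ]
        return pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)


@dataclass
class BalanceReport:
    """Outcome of :func:`validate_balance`."""

    counts: dict[str, int]
    balanced: bool
    offending: list[str]
    empty: bool

    def __bool__(self) -> bool:  # truthiness == verdict
        return self.balanced


def validate_balance(manifest: DatasetManifest) -> BalanceReport:
    """Report per-species observation counts and a balance verdict.

    The verdict is true iff every species has the same number of
    observations.  An empty manifest is balanced by convention and flagged
    ``empty``.  Species whose count differs from the modal count are listed
    as offending.
    """
    counts: dict[str, int] = {}
    for o in manifest.observations:
        counts[o.species] = counts.get(o.species, 0) + 1
    if not counts:
        return BalanceReport(counts={}, balanced=True, offending=[], empty=True)
    values = list(counts.values())
    balanced = len(set(values)) == 1
    offending: list[str] = []
    if not balanced:
        modal = max(set(values), key=values.count)
        offending = sorted(s for s, c in counts.items() if c != modal)
    return BalanceReport(counts=counts, balanced=balanced, offending=offending, empty=False)


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a dataset manifest.

    Image paths are recorded verbatim, never opened.  Raises
    :class:`ManifestError` for malformed rows (naming the line) and
    :class:`IntegrityError` for duplicate ``(observation_id, perspective)``
    pairs or observations without exactly five perspectives.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ManifestError(f"{path}: empty manifest file")
    sep = _detect_sep(lines[0])
    header = [c.strip() for c in lines[0].split(sep)]
    if header != _MANIFEST_COLUMNS:
        raise ManifestError(
            f"{path}: line 1: header must be {','.join(_MANIFEST_COLUMNS)!r}, "
            f"got {','.join(header)!r}"
        )
    frame = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    return manifest_from_frame(frame, source=str(path))


def manifest_from_frame(frame: pd.DataFrame, source: str = "<frame>") -> DatasetManifest:
    """Build a :class:`DatasetManifest` from a long-form table (one row per
    image, columns as in the manifest file format)."""
    if list(frame.columns) != _MANIFEST_COLUMNS:
        raise ManifestError(f"{source}: columns must be {_MANIFEST_COLUMNS}")
    bad = ~frame["perspective"].isin(PERSPECTIVES)
    if bad.any():
        row = int(frame.index[bad][0])
        raise ManifestError(
            f"{source}: line {row + 2}: unknown perspective "
            f"{frame['perspective'].iloc[row]!r}"
        )
    dup = frame.duplicated(subset=["observation_id", "perspective"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise IntegrityError(
            f"{source}: duplicate (observation_id, perspective) = "
            f"({row['observation_id']!r}, {row['perspective']!r})"
        )
    observations: list[Observation] = []
    for obs_id, grp in frame.groupby("observation_id", sort=True):
        species = set(grp["species"])
        if len(species) > 1:
            raise IntegrityError(
                f"{source}: observation {obs_id!r} rows disagree on species: "
                f"{sorted(species)}"
            )
        group_labels = set(grp["group"])
        if len(group_labels) > 1:
            raise IntegrityError(
                f"{source}: observation {obs_id!r} rows disagree on group: "
                f"{sorted(group_labels)}"
            )
        images = dict(zip(grp["perspective"], grp["path"]))
        if set(images) != set(PERSPECTIVES):
            missing = sorted(set(PERSPECTIVES) - set(images))
            raise IntegrityError(
                f"{source}: observation {obs_id!r} lists perspectives "
                f"{sorted(images)} (missing {missing})"
            )
        observations.append(
            Observation(
                observation_id=str(obs_id),
                species=grp["species"].iloc[0],
                group=grp["group"].iloc[0],
                images=images,
            )
        )
    return DatasetManifest(observations=observations)


def write_manifest(manifest: DatasetManifest, path: str | Path, sep: str = ",") -> None:
    """Write a manifest as delimited text (round-trips with
    :func:`load_manifest`)."""
    frame = manifest.to_frame()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=sep, index=False)
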