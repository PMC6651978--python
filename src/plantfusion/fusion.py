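"""Sum-rule score-level fusion over perspective combinations.

The fused score of a species for one observation is the arithmetic mean of
that species' confidence scores across the perspectives in the combination,

    S = (1/n) Σ_p s_p ,

which keeps probability rows normalized and makes combinations of different
sizes directly comparable.  All 2⁵ − 1 = 31 non-empty perspective subsets
are enumerated for the standard five codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .backends import ScoreMatrix
from .errors import InputError, IntegrityError
from .observations import PERSPECTIVES


@dataclass(frozen=True)
class CombinationSpec:
    """A non-empty subset of perspective codes, canonically ordered."""

    perspectives: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.perspectives:
            raise InputError("a combination needs at least one perspective")
        if len(set(self.perspectives)) != len(self.perspectives):
            raise InputError(f"duplicate perspectives in {self.perspectives}")
        # normalize to canonical display order (EP, FF, FL, LT, LB)
        known = [p for p in PERSPECTIVES if p in self.perspectives]
        extra = [p for p in self.perspectives if p not in PERSPECTIVES]
        object.__setattr__(self, "perspectives", tuple(known + sorted(extra)))

    @property
    def n(self) -> int:
        return len(self.perspectives)

    @property
    def label(self) -> str:
        return "+".join(self.perspectives)

    def __str__(self) -> str:
        return self.label


def enumerate_combinations(
    perspectives: Sequence[str] = PERSPECTIVES,
) -> list[CombinationSpec]:
    """All non-empty subsets of the given perspective codes, ordered by
    (size ascending, label lexicographic).

    For the five standard codes this yields 31 combinations with size
    counts (5, 10, 10, 5, 1).
    """
    codes = list(dict.fromkeys(perspectives))
    if not codes:
        raise InputError("perspective set must be non-empty")
    out: list[CombinationSpec] = []
    for k in range(1, len(codes) + 1):
        specs = [CombinationSpec(tuple(c)) for c in _combinations(codes, k)]
        specs.sort(key=lambda s: s.label)
        out.extend(specs)
    return out


@dataclass
class FusedScoreMatrix:
    """Fused scores: one row per test observation, one column per species."""

    data: pd.DataFrame  # index observation_id × species columns
    combination: CombinationSpec
    provenance: dict = field(default_factory=dict)

    @property
    def species_list(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        flat = self.data.sort_index().reset_index()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# combination={self.combination.label}\n")
            flat.to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "FusedScoreMatrix":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().strip()
            if not first.startswith("# combination="):
                raise IntegrityError(f"{path}: missing combination header")
            label = first.split("=", 1)[1]
            frame = pd.read_csv(fh, dtype={"observation_id": str})
        frame = frame.set_index("observation_id")
        return cls(
            data=frame,
            combination=CombinationSpec(tuple(label.split("+"))),
            provenance={"source": str(path)},
        )


def fuse(
    matrices: Mapping[str, ScoreMatrix],
    combination: CombinationSpec,
) -> FusedScoreMatrix:
    """Average per-perspective score rows over a perspective combination.

    Every perspective in the combination must supply a score matrix with an
    identical species ordering and exactly one row per test observation;
    a missing row is a hard error (no renormalized partial fusion).
    """
    blocks: list[pd.DataFrame] = []
    species: list[str] | None = None
    obs_index: pd.Index | None = None
    for code in combination.perspectives:
        if code not in matrices:
            raise IntegrityError(f"no score matrix supplied for perspective {code!r}")
        sub = matrices[code].rows_for_perspective(code)
        if sub.index.has_duplicates:
            dup = sub.index[sub.index.duplicated()][0]
            raise IntegrityError(f"perspective {code}: duplicate rows for observation {dup!r}")
        if species is None:
            species = list(sub.columns)
            obs_index = sub.index.sort_values()
        else:
            if list(sub.columns) != species:
                raise IntegrityError(
                    f"species ordering of perspective {code} disagrees with "
                    f"{combination.perspectives[0]}"
                )
            missing = obs_index.difference(sub.index)
            extra = sub.index.difference(obs_index)
            if len(missing) or len(extra):
                name = (list(missing) + list(extra))[0]
                raise IntegrityError(
                    f"observation {name!r} lacks a row for every perspective of "
                    f"{combination.label}"
                )
        blocks.append(sub.loc[obs_index])
    assert species is not None and obs_index is not None
    stacked = np.stack([b.to_numpy(dtype=float) for b in blocks])
    fused = stacked.mean(axis=0)
    frame = pd.DataFrame(fused, index=obs_index, columns=species)
    frame.index.name = "observation_id"
    return FusedScoreMatrix(
        data=frame,
        combination=combination,
        provenance={"n_perspectives": combination.n},
    )
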