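"""Core containers: specimen landmark records, datasets, and study configuration.

A :class:`LandmarkDataset` is an ordered collection of specimens, each a
``k x d`` landmark configuration (in mm) annotated with species and sex.
All analyses are run per sex, on species meeting a minimum sample size,
so the dataset exposes cheap per-sex / per-species views.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

VALID_SEXES = ("F", "M")


def genus_of(species: str) -> str:
    """Genus component of a 'Genus_species' label (text before the first underscore)."""
    return species.split("_", 1)[0] if species else ""


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen: a landmark configuration plus taxonomic metadata.

    ``coords`` is a ``(k, d)`` float array in mm; ``species`` follows the
    'Genus_species' convention and ``genus`` is always derived from it.
    Metadata may be empty until joined from a table.
    """

    specimen_id: str
    coords: np.ndarray
    species: str = ""
    sex: str = ""
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError(
                f"specimen {self.specimen_id!r}: coords must be (k, 2) or (k, 3), "
                f"got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        if self.sex and self.sex not in VALID_SEXES:
            raise ValueError(
                f"specimen {self.specimen_id!r}: sex must be one of {VALID_SEXES}, got {self.sex!r}"
            )

    @property
    def genus(self) -> str:
        return genus_of(self.species)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


class LandmarkDataset:
    """Ordered collection of :class:`SpecimenRecord` sharing one (k, d)."""

    def __init__(self, records: Iterable[SpecimenRecord]):
        records = list(records)
        if not records:
            raise ValueError("dataset must contain at least one record")
        k, d = records[0].k, records[0].d
        for rec in records:
            if (rec.k, rec.d) != (k, d):
                raise ValueError(
                    f"mixed landmark dimensionality: specimen {rec.specimen_id!r} "
                    f"has ({rec.k}, {rec.d}), expected ({k}, {d})"
                )
        ids = [rec.specimen_id for rec in records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dupes = {i for i in ids if i in seen or seen.add(i)}
            raise ValueError(f"duplicate specimen ids: {sorted(dupes)}")
        self.records: list[SpecimenRecord] = records
        self.k: int = k
        self.d: int = d

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SpecimenRecord:
        return self.records[i]

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    @property
    def sexes(self) -> list[str]:
        return [r.sex for r in self.records]

    def coords_array(self) -> np.ndarray:
        """Stacked configurations, shape ``(n, k, d)``."""
        return np.stack([r.coords for r in self.records])

    def subset(self, indices: Sequence[int]) -> "LandmarkDataset":
        return LandmarkDataset([self.records[i] for i in indices])

    def species_counts(self, sex: str | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            if sex is not None and rec.sex != sex:
                continue
            counts[rec.species] = counts.get(rec.species, 0) + 1
        return counts


@dataclass
class StudyConfig:
    """Analysis-wide thresholds and experiment sizes.

    min_n
        Minimum per-sex species sample size for inclusion (10, 20 or 30).
    alpha
        Significance threshold for the multivariate regression (0.005).
    rsq_threshold
        Effect-size branch of the non-negligible rule (Rsq > 0.05).
    n_permutations
        Tip permutations for the phylogenetic-signal test (1000).
    n_bootstrap
        Replicates of the balanced bootstrapped subsampling experiment (100).
    magnification
        Exaggeration factor for rendered extreme allometric shapes (3.0).
    seed
        Master seed for every stochastic operation.
    """

    min_n: int = 10
    alpha: float = 0.005
    rsq_threshold: float = 0.05
    n_permutations: int = 1000
    n_bootstrap: int = 100
    magnification: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_n < 2:
            raise ValueError("min_n must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.rsq_threshold < 1:
            raise ValueError("rsq_threshold must be in [0, 1)")
        for name in ("n_permutations", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    def with_(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
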