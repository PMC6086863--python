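"""Shared domain types for the community-assembly pipeline.

All types validate their invariants on construction and raise
:class:`ValidationError` naming the offending label(s), so that malformed
field data never propagates silently into an analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

HABITATS = ("Arboreal", "Terrestrial")
ACTIVITIES = ("Diurnal", "Nocturnal")


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


def _check_unique(labels: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {kind} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Binary species x sites occupancy matrix.

    Every cell is 0/1; every species occurs on at least one site and every
    site holds at least one species (an all-zero row or column carries no
    information for co-occurrence and indicates a data error).
    """

    species_labels: tuple[str, ...]
    site_labels: tuple[str, ...]
    cells: np.ndarray  # shape (n_species, n_sites), dtype int8

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.shape != (len(self.species_labels), len(self.site_labels)):
            raise ValidationError(
                f"cell block shape {cells.shape} does not match "
                f"{len(self.species_labels)} species x {len(self.site_labels)} sites"
            )
        _check_unique(self.species_labels, "species")
        _check_unique(self.site_labels, "site")
        bad = ~np.isin(cells, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at species {self.species_labels[i]!r}, "
                f"site {self.site_labels[j]!r}: {cells[i, j]!r}"
            )
        empty_rows = [
            self.species_labels[i] for i in np.flatnonzero(cells.sum(axis=1) == 0)
        ]
        if empty_rows:
            raise ValidationError(f"species with no occurrences: {empty_rows}")
        empty_cols = [
            self.site_labels[j] for j in np.flatnonzero(cells.sum(axis=0) == 0)
        ]
        if empty_cols:
            raise ValidationError(f"sites with no species: {empty_cols}")
        object.__setattr__(self, "cells", cells.astype(np.int8))

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    def site_counts(self) -> dict[str, int]:
        """Number of occupied sites per species."""
        return dict(zip(self.species_labels, self.cells.sum(axis=1).tolist()))

    def richness_per_site(self) -> dict[str, int]:
        return dict(zip(self.site_labels, self.cells.sum(axis=0).tolist()))


@dataclass(frozen=True)
class GuildTable:
    """Species -> (habitat, diel activity) guild membership."""

    species: tuple[str, ...]
    habitat: tuple[str, ...]
    activity: tuple[str, ...]

    def __post_init__(self) -> None:
        if not len(self.species) == len(self.habitat) == len(self.activity):
            raise ValidationError("guild table columns have unequal lengths")
        _check_unique(self.species, "species")
        for sp, hab in zip(self.species, self.habitat):
            if hab not in HABITATS:
                raise ValidationError(
                    f"unknown habitat {hab!r} for species {sp!r}; allowed: {HABITATS}"
                )
        for sp, act in zip(self.species, self.activity):
            if act not in ACTIVITIES:
                raise ValidationError(
                    f"unknown activity {act!r} for species {sp!r}; allowed: {ACTIVITIES}"
                )


@dataclass(frozen=True)
class QuadratCounts:
    """Long-form individual counts per (community, quadrat, species).

    Counts are individuals per 100 m^2 bounded quadrat.
    """

    community: tuple[str, ...]
    quadrat: tuple[str, ...]
    species: tuple[str, ...]
    count: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.community)
        if not len(self.quadrat) == len(self.species) == len(self.count) == n:
            raise ValidationError("quadrat count columns have unequal lengths")
        keys = set()
        for com, q, sp, c in zip(self.community, self.quadrat, self.species, self.count):
            if c < 0 or int(c) != c:
                raise ValidationError(
                    f"negative or non-integer count {c!r} for "
                    f"({com!r}, {q!r}, {sp!r})"
                )
            key = (com, q, sp)
            if key in keys:
                raise ValidationError(f"duplicate quadrat record: {key}")
            keys.add(key)


@dataclass(frozen=True)
class BodyMassTable:
    """Species-level mean body mass in grams."""

    species: tuple[str, ...]
    mass: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.species) != len(self.mass):
            raise ValidationError("body-mass table columns have unequal lengths")
        _check_unique(self.species, "species")
        for sp, m in zip(self.species, self.mass):
            if not m > 0:
                raise ValidationError(f"non-positive mass {m!r} for species {sp!r}")

    def mass_of(self, species: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.species, self.mass))
        missing = [sp for sp in species if sp not in lookup]
        if missing:
            raise ValidationError(f"species without mass data: {missing}")
        return np.array([lookup[sp] for sp in species], dtype=float)


@dataclass(frozen=True)
class IslandAttributes:
    """Per-island area (km^2) and species richness."""

    island: tuple[str, ...]
    area: tuple[float, ...]
    richness: tuple[int, ...]

    def __post_init__(self) -> None:
        if not len(self.island) == len(self.area) == len(self.richness):
            raise ValidationError("island attribute columns have unequal lengths")
        _check_unique(self.island, "island")
        for isl, a in zip(self.island, self.area):
            if not a > 0:
                raise ValidationError(f"non-positive area {a!r} for island {isl!r}")
        for isl, s in zip(self.island, self.richness):
            if s < 1 or int(s) != s:
                raise ValidationError(f"invalid richness {s!r} for island {isl!r}")


@dataclass(frozen=True)
class AbundanceVector:
    """A community's per-species abundances, ranked descending.

    ``N`` is the total number of individuals, ``S`` the species richness.
    """

    community: str
    abundances: tuple[int, ...]
    species: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if any(a < 1 or int(a) != a for a in self.abundances):
            raise ValidationError(
                f"community {self.community!r}: abundances must be positive integers"
            )
        if list(self.abundances) != sorted(self.abundances, reverse=True):
            raise ValidationError(
                f"community {self.community!r}: abundances must be ranked descending"
            )
        if self.species and len(self.species) != len(self.abundances):
            raise ValidationError(
                f"community {self.community!r}: species labels do not match abundances"
            )

    @property
    def n_individuals(self) -> int:
        return int(sum(self.abundances))

    @property
    def n_species(self) -> int:
        return len(self.abundances)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.abundances, dtype=float)


@dataclass(frozen=True)
class SizeCommunity:
    """An island community with member species and their body masses (g)."""

    community: str
    members: tuple[str, ...]
    masses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.masses):
            raise ValidationError("members and masses have unequal lengths")
        if len(self.members) < 2:
            raise ValidationError(
                f"community {self.community!r} has fewer than 2 members"
            )
        for sp, m in zip(self.members, self.masses):
            if not m > 0:
                raise ValidationError(f"non-positive mass {m!r} for member {sp!r}")

    @property
    def richness(self) -> int:
        return len(self.members)
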