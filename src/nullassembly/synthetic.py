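"""Synthetic communities with the statistical structure each stage assumes.

Generators cover the study designs the pipeline is meant to detect:

* two-block *allopatric* metacommunities — two island groups with endemic
  species and a few shared ones, the structure a deep ocean channel creates;
* *nested* ("common history") archipelagos — poorer islands' faunas are
  subsets of richer islands';
* abundance vectors drawn from Pareto and broken-stick SADs;
* size assemblages drawn randomly or evenly spaced on the log-mass axis
  from a source pool.

Every generator is driven by a named substream derived from one global
integer seed (SeedSequence over (seed, crc32(scenario))), so stages can be
regenerated independently and bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .datatypes import AbundanceVector, PresenceAbsenceMatrix, SizeCommunity

_MAX_RETRIES = 1000


@dataclass(frozen=True)
class SynthSpec:
    """Provenance record for a generated dataset."""

    scenario: str
    parameters: Mapping[str, float | int | str]
    seed: int


def substream(seed: int, scenario: str) -> np.random.Generator:
    """Deterministic named RNG substream for one generator."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(scenario.encode())])
    )


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(v + 0.5).astype(int)


def gen_independent_matrix(
    n_species: int, n_islands: int, occupancy: float, seed: int
) -> PresenceAbsenceMatrix:
    """Null-structured matrix: every cell an independent Bernoulli(occupancy).

    The reference condition for type-I error checks of the co-occurrence
    classifier.  Redraws (bounded) until no species row or island column is
    empty.
    """
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    rng = substream(seed, "independent")
    for _ in range(_MAX_RETRIES):
        cells = (rng.random((n_species, n_islands)) < occupancy).astype(np.int8)
        if cells.sum(axis=1).all() and cells.sum(axis=0).all():
            return PresenceAbsenceMatrix(
                species_labels=tuple(f"sp{i:03d}" for i in range(n_species)),
                site_labels=tuple(f"isl{j:03d}" for j in range(n_islands)),
                cells=cells,
            )
    raise RuntimeError("could not draw a matrix without empty rows/columns")


def gen_allopatric_matrix(
    n_groups: int = 2,
    species_per_group: int = 8,
    islands_per_group: int = 10,
    shared_species: int = 1,
    occupancy: float = 0.6,
    seed: int = 0,
) -> PresenceAbsenceMatrix:
    """Block-structured metacommunity: each group's endemics occur only on
    that group's islands (independently with probability ``occupancy``);
    shared species range over all islands."""
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    n_species = n_groups * species_per_group + shared_species
    n_islands = n_groups * islands_per_group
    rng = substream(seed, "allopatric")
    for _ in range(_MAX_RETRIES):
        cells = np.zeros((n_species, n_islands), dtype=np.int8)
        for g in range(n_groups):
            r0, c0 = g * species_per_group, g * islands_per_group
            block = rng.random((species_per_group, islands_per_group)) < occupancy
            cells[r0 : r0 + species_per_group, c0 : c0 + islands_per_group] = block
        if shared_species:
            cells[n_groups * species_per_group :, :] = (
                rng.random((shared_species, n_islands)) < occupancy
            )
        if cells.sum(axis=1).all() and cells.sum(axis=0).all():
            labels = [
                f"g{g}sp{i:02d}" for g in range(n_groups) for i in range(species_per_group)
            ] + [f"shared{i:02d}" for i in range(shared_species)]
            return PresenceAbsenceMatrix(
                species_labels=tuple(labels),
                site_labels=tuple(
                    f"g{g}isl{j:02d}"
                    for g in range(n_groups)
                    for j in range(islands_per_group)
                ),
                cells=cells,
            )
    raise RuntimeError(
        "infeasible allopatric spec: occupancy too low to fill rows/columns"
    )


def species_group(label: str) -> str | None:
    """Group tag of an allopatric species label, None for shared species."""
    return label.split("sp")[0] if label.startswith("g") else None


def gen_common_history_matrix(
    n_species: int = 20,
    n_islands: int = 12,
    nestedness: float = 1.0,
    occupancy: float = 0.5,
    seed: int = 0,
) -> PresenceAbsenceMatrix:
    """Nested archipelago: islands are ordered richest-first and each
    species, with probability ``nestedness``, occupies a prefix of that
    order (so poorer islands hold subsets of richer islands' faunas); with
    the complementary probability its incidence is independent Bernoulli.
    At 1.0 the matrix is perfectly nested; at 0.0 occupancy is independent.
    """
    if not 0 <= nestedness <= 1:
        raise ValueError("nestedness must be in [0, 1]")
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    rng = substream(seed, "common_history")
    for _ in range(_MAX_RETRIES):
        cells = np.zeros((n_species, n_islands), dtype=np.int8)
        for i in range(n_species):
            n_i = max(1, rng.binomial(n_islands, occupancy))
            if rng.random() < nestedness:
                cells[i, :n_i] = 1
            else:
                cols = rng.choice(n_islands, size=n_i, replace=False)
                cells[i, cols] = 1
        if cells.sum(axis=1).all() and cells.sum(axis=0).all():
            return PresenceAbsenceMatrix(
                species_labels=tuple(f"sp{i:03d}" for i in range(n_species)),
                site_labels=tuple(f"isl{j:03d}" for j in range(n_islands)),
                cells=cells,
            )
    raise RuntimeError("could not draw a nested matrix without empty rows/columns")


def gen_pareto_sample(
    n_species: int, scale: float, shape: float, seed: int, community: str = "synthetic"
) -> AbundanceVector:
    """Abundances by inverse-CDF sampling of the Pareto(scale, shape) law,
    rounded half-up to integers; the minimum is never below the scale."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if shape <= 0:
        raise ValueError("shape must be positive")
    rng = substream(seed, "pareto")
    u = rng.random(n_species)
    x = _round_half_up(scale * u ** (-1.0 / shape))
    return AbundanceVector(
        community=community, abundances=tuple(sorted(x.tolist(), reverse=True))
    )


def gen_broken_stick_sample(
    n_individuals: int, n_species: int, seed: int, community: str = "synthetic"
) -> AbundanceVector:
    """Abundances as the S segments of a stick of length N cut at S-1
    uniform points, rounded to integers summing exactly to N by
    largest-remainder correction.  Rounded segments of 0 trigger a
    (bounded) redraw so the vector stays strictly positive.
    """
    if n_species < 2 or n_individuals < n_species:
        raise ValueError("need N >= S >= 2")
    rng = substream(seed, "broken_stick")
    for _ in range(_MAX_RETRIES):
        cuts = np.sort(rng.uniform(0, n_individuals, size=n_species - 1))
        seg = np.diff(np.concatenate(([0.0], cuts, [float(n_individuals)])))
        floors = np.floor(seg).astype(int)
        frac = seg - floors
        remainder = n_individuals - int(floors.sum())
        order = np.argsort(-frac)
        floors[order[:remainder]] += 1
        if (floors > 0).all():
            return AbundanceVector(
                community=community,
                abundances=tuple(sorted(floors.tolist(), reverse=True)),
            )
    raise RuntimeError("could not draw strictly positive broken-stick segments")


def broken_stick_expected_ranked(n_individuals: int, n_species: int) -> np.ndarray:
    """Analytic expected abundance of rank i (descending):
    (N/S) * sum_{k=i}^{S} 1/k."""
    s = n_species
    tail = np.cumsum(1.0 / np.arange(s, 0, -1))[::-1]
    return n_individuals / s * tail


def gen_size_community(
    pool_masses,
    richness: int,
    mode: str = "random",
    seed: int = 0,
    community: str = "synthetic",
) -> SizeCommunity:
    """Assemble a community of given richness from a mass pool.

    ``random`` draws without replacement (passive sampling); ``even_log_spaced``
    picks, for each point of an even grid on the log-mass axis, the nearest
    not-yet-used pool species — the constant-size-ratio construction.
    """
    pool = np.asarray(pool_masses, dtype=float)
    if pool.size < richness:
        raise ValueError("pool smaller than requested richness")
    if mode == "random":
        rng = substream(seed, "size_random")
        masses = rng.choice(pool, size=richness, replace=False)
    elif mode == "even_log_spaced":
        logm = np.log(np.sort(pool))
        grid = np.linspace(logm[0], logm[-1], richness)
        used: list[int] = []
        for g in grid:
            dist = np.abs(logm - g)
            dist[used] = np.inf
            used.append(int(np.argmin(dist)))
        masses = np.exp(logm[used])
    else:
        raise ValueError("mode must be 'random' or 'even_log_spaced'")
    masses = np.sort(masses)
    return SizeCommunity(
        community=community,
        members=tuple(f"sp{i:03d}" for i in range(richness)),
        masses=tuple(masses.tolist()),
    )
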