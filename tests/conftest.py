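from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from nullassembly import BodyMassTable, GuildTable, PresenceAbsenceMatrix


def enumerate_cooccurrence_pmf(n_sites: int, n_a: int, n_b: int) -> dict[int, Fraction]:
    """Brute-force co-occurrence law: enumerate every joint placement of the
    two species' occupied-site sets and count shared sites.  Independent of
    the hypergeometric formula under test."""
    sites = range(n_sites)
    counts: dict[int, int] = {}
    total = 0
    for occ_a in combinations(sites, n_a):
        set_a = set(occ_a)
        for occ_b in combinations(sites, n_b):
            j = len(set_a & set(occ_b))
            counts[j] = counts.get(j, 0) + 1
            total += 1
    return {j: Fraction(c, total) for j, c in counts.items()}


@pytest.fixture(scope="session")
def small_matrix() -> PresenceAbsenceMatrix:
    """3 species x 4 islands, hand-checkable."""
    return PresenceAbsenceMatrix(
        species_labels=("SPA", "SPB", "SPC"),
        site_labels=("i1", "i2", "i3", "i4"),
        cells=np.array([[1, 1, 0, 0], [1, 1, 1, 0], [0, 0, 1, 1]]),
    )


@pytest.fixture(scope="session")
def guild_table() -> GuildTable:
    return GuildTable(
        species=("SPM", "BRD", "GES", "CNS"),
        habitat=("Terrestrial", "Arboreal", "Arboreal", "Terrestrial"),
        activity=("Diurnal", "Diurnal", "Nocturnal", "Nocturnal"),
    )


@pytest.fixture(scope="session")
def archipelago_masses() -> BodyMassTable:
    """29-species mass table spanning the 0.5-84 g range of the study system."""
    rng = np.random.default_rng(20180810)
    masses = np.exp(rng.uniform(np.log(0.5), np.log(84.0), size=27))
    masses = np.concatenate([[0.5, 84.0], masses])
    return BodyMassTable(
        species=tuple(f"sp{i:02d}" for i in range(29)),
        mass=tuple(float(m) for m in masses),
    )
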