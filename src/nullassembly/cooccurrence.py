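"""Exact probabilistic pairwise species co-occurrence.

Given two species occupying ``n_a`` and ``n_b`` of ``N`` sites, the number of
shared sites ``j`` under random, independent placement follows the
hypergeometric law

    P(j) = C(n_a, j) C(N - n_a, n_b - j) / C(N, n_b),

on the support max(0, n_a + n_b - N) <= j <= min(n_a, n_b).  Comparing the
observed number of shared sites against the two inclusive tails of this
distribution classifies each pair as positive, negative, random, or
unclassifiable; pairs whose expected co-occurrence n_a*n_b/N falls below a
minimum threshold are removed from the analysis.

All probabilities are computed with exact integer combinatorics
(``fractions.Fraction`` over ``math.comb``), so tail sums are exact for any
matrix size encountered in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

from .datatypes import PresenceAbsenceMatrix

CLASSIFICATIONS = ("positive", "negative", "random", "unclassifiable", "removed")


@dataclass(frozen=True)
class PairResult:
    """Outcome of the exact co-occurrence test for one unordered species pair."""

    species_a: str
    species_b: str
    n_sites: int
    n_a: int
    n_b: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    classification: str
    ses: float


@dataclass(frozen=True)
class CooccurrenceSummary:
    n_species: int
    n_sites: int
    n_pairs_total: int
    n_removed: int
    n_positive: int
    n_negative: int
    n_random: int
    n_unclassifiable: int

    def __post_init__(self) -> None:
        parts = (
            self.n_removed
            + self.n_positive
            + self.n_negative
            + self.n_random
            + self.n_unclassifiable
        )
        if parts != self.n_pairs_total:
            raise ValueError("classification counts do not partition the pairs")


def support(n_sites: int, n_a: int, n_b: int) -> range:
    """Attainable values of the shared-site count."""
    return range(max(0, n_a + n_b - n_sites), min(n_a, n_b) + 1)


def cooccurrence_pmf(n_sites: int, n_a: int, n_b: int, j: int) -> Fraction:
    """Exact probability that two species share exactly ``j`` sites.

    Returns an exact rational; ``float()`` it for reporting.  Off-support
    ``j`` returns 0.
    """
    _check_counts(n_sites, n_a, n_b)
    if j not in support(n_sites, n_a, n_b):
        return Fraction(0)
    return Fraction(comb(n_a, j) * comb(n_sites - n_a, n_b - j), comb(n_sites, n_b))


def expected_cooccurrence(n_sites: int, n_a: int, n_b: int) -> Fraction:
    """Expected number of shared sites, n_a * n_b / N (the pmf mean)."""
    if n_sites == 0:
        raise ValueError("n_sites must be positive")
    _check_counts(n_sites, n_a, n_b)
    return Fraction(n_a * n_b, n_sites)


def tail_probabilities(n_sites: int, n_a: int, n_b: int, j_obs: int) -> tuple[Fraction, Fraction]:
    """Inclusive lower and upper tail probabilities at ``j_obs``.

    p_lt = P(j <= j_obs), p_gt = P(j >= j_obs); both include P(j_obs), so
    p_lt + p_gt - P(j_obs) = 1 exactly.
    """
    supp = support(n_sites, n_a, n_b)
    p_lt = sum(
        (cooccurrence_pmf(n_sites, n_a, n_b, j) for j in supp if j <= j_obs),
        Fraction(0),
    )
    p_gt = sum(
        (cooccurrence_pmf(n_sites, n_a, n_b, j) for j in supp if j >= j_obs),
        Fraction(0),
    )
    return p_lt, p_gt


def classify_pair(
    species_a: str,
    species_b: str,
    n_sites: int,
    n_a: int,
    n_b: int,
    j_obs: int,
    *,
    alpha: float = 0.05,
    random_band: float = 0.1,
    min_expected: float = 1.0,
) -> PairResult:
    """Classify one species pair from its occupancy counts.

    Decision order: pairs with expected co-occurrence below ``min_expected``
    are removed; a tail probability below ``alpha`` gives positive (upper) or
    negative (lower); otherwise a deviation within ``random_band * n_sites``
    shared sites of the expectation is random, and anything further is
    unclassifiable.  The standardized effect size (observed - expected) / N
    is bounded in [-1, 1] and reported for every pair.
    """
    _check_counts(n_sites, n_a, n_b)
    if j_obs not in support(n_sites, n_a, n_b):
        raise ValueError(
            f"observed co-occurrence {j_obs} outside the attainable range "
            f"{list(support(n_sites, n_a, n_b))} for ({n_sites}, {n_a}, {n_b})"
        )
    expected = expected_cooccurrence(n_sites, n_a, n_b)
    p_lt, p_gt = tail_probabilities(n_sites, n_a, n_b, j_obs)
    ses = float(Fraction(j_obs - expected, n_sites))

    if expected < min_expected:
        cls = "removed"
    elif p_gt < alpha:
        cls = "positive"
    elif p_lt < alpha:
        cls = "negative"
    elif abs(j_obs - expected) <= Fraction(random_band).limit_denominator(10**9) * n_sites:
        cls = "random"
    else:
        cls = "unclassifiable"

    return PairResult(
        species_a=species_a,
        species_b=species_b,
        n_sites=n_sites,
        n_a=n_a,
        n_b=n_b,
        j_obs=j_obs,
        expected=float(expected),
        p_lt=float(p_lt),
        p_gt=float(p_gt),
        classification=cls,
        ses=ses,
    )


def analyze_matrix(
    matrix: PresenceAbsenceMatrix,
    *,
    alpha: float = 0.05,
    random_band: float = 0.1,
    min_expected: float = 1.0,
) -> tuple[list[PairResult], CooccurrenceSummary]:
    """Run the exact co-occurrence test over every unordered species pair."""
    if matrix.n_species < 2:
        raise ValueError("co-occurrence analysis needs at least 2 species")
    cells = matrix.cells
    row_sums = cells.sum(axis=1)
    n_sites = matrix.n_sites
    results: list[PairResult] = []
    for ia, ib in combinations(range(matrix.n_species), 2):
        j_obs = int((cells[ia] & cells[ib]).sum())
        results.append(
            classify_pair(
                matrix.species_labels[ia],
                matrix.species_labels[ib],
                n_sites,
                int(row_sums[ia]),
                int(row_sums[ib]),
                j_obs,
                alpha=alpha,
                random_band=random_band,
                min_expected=min_expected,
            )
        )
    counts = {cls: 0 for cls in CLASSIFICATIONS}
    for r in results:
        counts[r.classification] += 1
    summary = CooccurrenceSummary(
        n_species=matrix.n_species,
        n_sites=n_sites,
        n_pairs_total=matrix.n_species * (matrix.n_species - 1) // 2,
        n_removed=counts["removed"],
        n_positive=counts["positive"],
        n_negative=counts["negative"],
        n_random=counts["random"],
        n_unclassifiable=counts["unclassifiable"],
    )
    return results, summary


def _check_counts(n_sites: int, n_a: int, n_b: int) -> None:
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    for name, n in (("n_a", n_a), ("n_b", n_b)):
        if not 0 <= n <= n_sites:
            raise ValueError(f"{name}={n} outside [0, {n_sites}]")
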