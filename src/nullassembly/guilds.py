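"""Guild co-occurrence and cross-classification against geography.

Species are assigned to guilds by habitat (Arboreal/Terrestrial) crossed
with diel activity (Diurnal/Nocturnal).  The guild matrix encodes the four
*categories* as columns, so every species row sums to 2 (one habitat, one
activity).  Running the same exact co-occurrence test on this species x 4
matrix asks whether ecologically similar species associate: with N = 4
"sites" and every species occupying exactly 2 of them, the smallest
attainable tail probability is 1/6 > 0.05, so the guild analysis can label
pairs random (share one category) or unclassifiable (share both or neither)
but never significant — a structural property, asserted in the test suite.

Cross-tabulating geographic against guild outcomes separates mechanism:
geographic segregation without guild association indicates historical
allopatry, geographic aggregation without guild structure indicates common
history, and geographic segregation *with* guild association is the pattern
competition would produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cooccurrence import (
    CLASSIFICATIONS,
    CooccurrenceSummary,
    PairResult,
    analyze_matrix,
)
from .datatypes import GuildTable, PresenceAbsenceMatrix, ValidationError

GUILD_CATEGORIES = ("Arboreal", "Terrestrial", "Diurnal", "Nocturnal")

INFERENCE_TAGS = (
    "historical allopatry",
    "common history",
    "competition-consistent",
    "uninformative",
)


def build_guild_matrix(guilds: GuildTable) -> PresenceAbsenceMatrix:
    """Species x 4 binary membership matrix over the guild categories."""
    cells = np.zeros((len(guilds.species), 4), dtype=np.int8)
    for i, (hab, act) in enumerate(zip(guilds.habitat, guilds.activity)):
        cells[i, GUILD_CATEGORIES.index(hab)] = 1
        cells[i, GUILD_CATEGORIES.index(act)] = 1
    try:
        return PresenceAbsenceMatrix(
            species_labels=tuple(guilds.species),
            site_labels=GUILD_CATEGORIES,
            cells=cells,
        )
    except ValidationError as err:
        # a category column can be empty if e.g. no species is nocturnal
        raise ValidationError(
            f"guild table does not populate all four categories: {err}"
        ) from err


def analyze_guild_matrix(
    gm: PresenceAbsenceMatrix,
    *,
    alpha: float = 0.05,
    random_band: float = 0.1,
    min_expected: float = 1.0,
) -> tuple[list[PairResult], CooccurrenceSummary]:
    """Exact co-occurrence over guild categories (N = 4 pseudo-sites)."""
    if tuple(gm.site_labels) != GUILD_CATEGORIES:
        raise ValueError(f"guild matrix columns must be {GUILD_CATEGORIES}")
    return analyze_matrix(
        gm, alpha=alpha, random_band=random_band, min_expected=min_expected
    )


@dataclass(frozen=True)
class InteractionCrossTab:
    """Pairs cross-tabulated by (geographic, guild) classification.

    ``counts[i][j]`` counts pairs with geographic class ``CLASSIFICATIONS[i]``
    and guild class ``CLASSIFICATIONS[j]``.  ``tags`` carries one mechanism
    label per pair present in both analyses.
    """

    counts: np.ndarray  # 5 x 5
    tags: dict[tuple[str, str], str]
    unmatched: tuple[tuple[str, str], ...]  # pairs present in only one analysis

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def tag_counts(self) -> dict[str, int]:
        out = {t: 0 for t in INFERENCE_TAGS}
        for tag in self.tags.values():
            out[tag] += 1
        return out


def _infer_tag(geo_cls: str, guild_cls: str) -> str:
    if geo_cls == "negative" and guild_cls == "positive":
        return "competition-consistent"
    if geo_cls == "negative" and guild_cls != "positive":
        return "historical allopatry"
    if geo_cls == "positive" and guild_cls in ("random", "unclassifiable"):
        return "common history"
    return "uninformative"


def cross_classify(
    geo: list[PairResult], guild: list[PairResult]
) -> InteractionCrossTab:
    """Join geographic and guild pair results on the unordered species pair."""

    def key(r: PairResult) -> tuple[str, str]:
        return tuple(sorted((r.species_a, r.species_b)))  # type: ignore[return-value]

    geo_map = {key(r): r for r in geo}
    guild_map = {key(r): r for r in guild}
    counts = np.zeros((len(CLASSIFICATIONS), len(CLASSIFICATIONS)), dtype=int)
    tags: dict[tuple[str, str], str] = {}
    for k in sorted(set(geo_map) & set(guild_map)):
        gcls = geo_map[k].classification
        ucls = guild_map[k].classification
        counts[CLASSIFICATIONS.index(gcls), CLASSIFICATIONS.index(ucls)] += 1
        tags[k] = _infer_tag(gcls, ucls)
    unmatched = tuple(sorted(set(geo_map) ^ set(guild_map)))
    return InteractionCrossTab(counts=counts, tags=tags, unmatched=unmatched)
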