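"""Power-law species-area regression.

Fits S = c * A^z by ordinary least squares of log richness on log island
area.  The slope z, R^2 and F statistic are invariant to the logarithm
base; base 10 is canonical here.  Used as a control for intrinsic
differences between island sets: similar z across sets argues against
systematic habitat or colonization differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import IslandAttributes, PresenceAbsenceMatrix


@dataclass(frozen=True)
class SpeciesAreaFit:
    slope_z: float
    intercept: float
    r_squared: float
    f_stat: float
    df_resid: int
    p_value: float


def fit_species_area(attrs: IslandAttributes) -> SpeciesAreaFit:
    """OLS of log10(richness) on log10(area); F = (n-2) R^2 / (1 - R^2)."""
    area = np.asarray(attrs.area, dtype=float)
    rich = np.asarray(attrs.richness, dtype=float)
    n = area.size
    if n < 3:
        raise ValueError("species-area fit needs at least 3 islands")
    log_a = np.log10(area)
    log_s = np.log10(rich)
    if np.var(log_a) == 0:
        raise ValueError("zero variance in log area")
    res = stats.linregress(log_a, log_s)
    r2 = res.rvalue**2
    df = n - 2
    f = df * r2 / (1 - r2) if r2 < 1 else np.inf
    return SpeciesAreaFit(
        slope_z=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        f_stat=float(f),
        df_resid=df,
        p_value=float(res.pvalue),
    )


def attributes_from_matrix(
    matrix: PresenceAbsenceMatrix, areas: dict[str, float]
) -> IslandAttributes:
    """Island attributes with richness taken from matrix column sums."""
    richness = matrix.richness_per_site()
    missing = [s for s in matrix.site_labels if s not in areas]
    if missing:
        raise ValueError(f"islands without area data: {missing}")
    return IslandAttributes(
        island=tuple(matrix.site_labels),
        area=tuple(float(areas[s]) for s in matrix.site_labels),
        richness=tuple(int(richness[s]) for s in matrix.site_labels),
    )
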