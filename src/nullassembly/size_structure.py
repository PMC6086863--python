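"""Body-size V-ratio and its randomization null model.

The V-ratio of a community is the variance of the gaps between adjacent
log-transformed body masses (equivalently, the variance of the logs of
adjacent size ratios) after sorting species by mass.  A community whose
species are spaced at a constant size ratio — the classical signature of
competitive size structuring — has V-ratio 0; random assemblages scatter.

Significance is judged against a Monte-Carlo null: a source pool is built
from the archipelago-wide mass table, truncated so the largest pool species
matches the focal community's largest species, padded with a few
hypothetical species of arbitrary (log-uniform) mass so the pool always
exceeds the community's richness; null communities of equal richness are
drawn from the pool without replacement and their V-ratios form the null
distribution.  Observed V is located in that distribution by inclusive tail
proportions and a standardized effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import BodyMassTable, SizeCommunity


@dataclass(frozen=True)
class VRatioResult:
    community: str
    richness: int
    observed_v: float
    null_mean: float
    null_var: float
    p_lower: float
    p_upper: float
    ses: float
    n_iter: int
    seed: int | None


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation between community richness and observed V-ratio."""

    r: float
    t: float
    df: int
    p_value: float
    n: int
    excluded: tuple[str, ...] = ()


def v_ratio(masses, *, ddof: int = 1) -> float:
    """Variance of adjacent log-mass gaps of the sorted masses.

    ``ddof=1`` (gaps minus one in the denominator) is the default sample
    variance; ``ddof=0`` gives the population convention.  Order-invariant
    and scale-invariant (a common mass factor shifts all logs equally).
    """
    m = np.asarray(masses, dtype=float)
    if m.size < 3:
        raise ValueError("V-ratio needs at least 3 masses (>= 2 adjacent ratios)")
    if (m <= 0).any():
        raise ValueError("masses must be positive")
    gaps = np.diff(np.log(np.sort(m)))
    return float(np.var(gaps, ddof=ddof))


def build_source_pool(
    all_masses: BodyMassTable,
    community: SizeCommunity,
    *,
    n_hypothetical: int = 5,
    seed: int | None = None,
) -> np.ndarray:
    """Mass pool for the null model of one community.

    All archipelago species with mass <= the community's maximum, plus
    ``n_hypothetical`` species with masses log-uniform on [pool min,
    community max].  The hypothetical masses are drawn once per pool, not
    per iterate.  The community's largest species is guaranteed present, so
    the pool and community maxima coincide.
    """
    com_max = max(community.masses)
    pool = [m for m in all_masses.mass if m <= com_max]
    if com_max not in pool:
        pool.append(com_max)
    rng = np.random.default_rng(seed)
    if n_hypothetical > 0:
        lo, hi = np.log(min(pool)), np.log(com_max)
        pool.extend(np.exp(rng.uniform(lo, hi, size=n_hypothetical)).tolist())
    pool_arr = np.sort(np.asarray(pool, dtype=float))
    if pool_arr.size <= community.richness:
        raise ValueError(
            f"source pool ({pool_arr.size}) not larger than community richness "
            f"({community.richness}); increase n_hypothetical"
        )
    return pool_arr


def null_distribution(
    pool: np.ndarray,
    richness: int,
    *,
    n_iter: int = 1000,
    seed: int | None = None,
    ddof: int = 1,
) -> np.ndarray:
    """V-ratios of ``n_iter`` equal-richness draws from the pool."""
    pool = np.asarray(pool, dtype=float)
    if richness < 3:
        raise ValueError("null communities need richness >= 3")
    if pool.size < richness:
        raise ValueError("pool smaller than community richness")
    if n_iter < 100:
        raise ValueError("use at least 100 null iterations")
    rng = np.random.default_rng(seed)
    out = np.empty(n_iter)
    for i in range(n_iter):
        draw = rng.choice(pool, size=richness, replace=False)
        out[i] = v_ratio(draw, ddof=ddof)
    return out


def ses_and_tails(
    community: str,
    observed_v: float,
    null_sample: np.ndarray,
    *,
    seed: int | None = None,
) -> VRatioResult:
    """Locate the observed V-ratio in the null sample.

    Tail proportions are inclusive (a null value equal to the observation
    counts in both tails), so p_lower + p_upper >= 1.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    null_mean = float(null_sample.mean())
    null_var = float(null_sample.var(ddof=1))
    if null_var == 0:
        raise ValueError(
            f"community {community!r}: null variance is 0, SES undefined"
        )
    ses = (observed_v - null_mean) / np.sqrt(null_var)
    return VRatioResult(
        community=community,
        richness=-1,
        observed_v=float(observed_v),
        null_mean=null_mean,
        null_var=null_var,
        p_lower=float((null_sample <= observed_v).mean()),
        p_upper=float((null_sample >= observed_v).mean()),
        ses=float(ses),
        n_iter=int(null_sample.size),
        seed=seed,
    )


def analyze_community(
    all_masses: BodyMassTable,
    community: SizeCommunity,
    *,
    n_hypothetical: int = 5,
    n_iter: int = 1000,
    seed: int | None = None,
    ddof: int = 1,
) -> VRatioResult:
    """Full pipeline for one community: pool, null sample, SES and tails."""
    obs = v_ratio(community.masses, ddof=ddof)
    pool = build_source_pool(
        all_masses, community, n_hypothetical=n_hypothetical, seed=seed
    )
    null = null_distribution(
        pool, community.richness, n_iter=n_iter,
        seed=None if seed is None else seed + 1, ddof=ddof,
    )
    res = ses_and_tails(community.community, obs, null, seed=seed)
    return VRatioResult(**{**res.__dict__, "richness": community.richness})


def richness_vratio_correlation(
    richness,
    observed_v,
    *,
    exclude_index=None,
    excluded_labels: tuple[str, ...] = (),
) -> CorrelationReport:
    """Pearson correlation of community richness against observed V-ratio,
    with its t statistic (df = n - 2) and two-sided P."""
    rich = np.asarray(richness, dtype=float)
    v = np.asarray(observed_v, dtype=float)
    if exclude_index is not None:
        keep = np.ones(rich.size, dtype=bool)
        keep[list(np.atleast_1d(exclude_index))] = False
        rich, v = rich[keep], v[keep]
    n = rich.size
    if n < 3:
        raise ValueError("correlation needs at least 3 communities")
    if np.var(rich) == 0 or np.var(v) == 0:
        raise ValueError("zero variance in richness or V-ratio")
    r, p = stats.pearsonr(rich, v)
    df = n - 2
    t = r * np.sqrt(df / (1 - r**2)) if abs(r) < 1 else math.copysign(math.inf, r)
    return CorrelationReport(
        r=float(r), t=float(t), df=df, p_value=float(p), n=n,
        excluded=excluded_labels,
    )
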