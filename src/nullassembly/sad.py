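"""Species-abundance-distribution (SAD) model fitting and AIC ranking.

A community's abundance vector (per-species counts ranked descending) is fit
by maximum likelihood to a registry of classical SAD and rank-abundance
models, and models are ranked by AIC.  Three fits have closed forms and are
exposed directly:

* Pareto (continuous power law, scale ``a`` fixed, shape ``b`` free):
  f(x) = b a^b / x^(b+1) for x >= a.  With the scale fixed at the smallest
  observed abundance, the shape MLE is b = S / sum(ln(x_i / a)).
* Broken stick (single-resource random partition, no free parameters):
  p(x) = (S-1)/N * (1 - x/N)^(S-2), determined entirely by the total count N
  and richness S.
* Lognormal: moments of ln(x), with the maximum-likelihood (divide-by-S)
  variance.

The rest of the registry (geometric series, log-series, Weibull, discrete
power, Zipf, Zipf-Mandelbrot, Poisson-lognormal, negative binomial, gamma)
is fit numerically with multi-start optimization; standard errors come from
the observed information (numerical Hessian).  Continuous densities are
evaluated at the integer abundances as densities, not discretized.  Species
models treat abundances as i.i.d. draws; rank models (geometric series,
Zipf, Zipf-Mandelbrot) use the multinomial likelihood of the ranked counts.

The zero-sum multinomial and the dispersal-limited neutral SAD are
registered as stubs raising ``NotImplementedError``: their likelihoods are
combinatorially heavy and the registry accepts their later addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .datatypes import AbundanceVector, QuadratCounts, ValidationError


class DegenerateSampleError(ValueError):
    """The sample admits no finite maximum-likelihood estimate."""


class FitError(RuntimeError):
    """Numerical fitting failed to converge."""


@dataclass(frozen=True)
class SADFit:
    """One model's maximum-likelihood fit to an abundance vector."""

    model: str
    fixed: dict[str, float]
    estimates: dict[str, tuple[float, float]]  # name -> (value, SE)
    loglik: float
    df: int
    aic: float = field(default=float("nan"))
    delta_aic: float = field(default=float("nan"))
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "aic", -2.0 * self.loglik + 2.0 * self.df)


# ---------------------------------------------------------------------------
# abundance aggregation


def aggregate_abundances(
    qc: QuadratCounts, pooling: dict[str, Sequence[str]] | None = None
) -> dict[str, AbundanceVector]:
    """Pool quadrat counts into per-community abundance vectors.

    ``pooling`` maps an output community name to the input community labels
    it pools (e.g. an archipelago community pooling several islands); by
    default each input community maps to itself.  Species with zero total
    count in a community are dropped; an empty community is an error.
    """
    communities = sorted(set(qc.community))
    if pooling is None:
        pooling = {c: [c] for c in communities}
    out: dict[str, AbundanceVector] = {}
    for name, members in pooling.items():
        unknown = sorted(set(members) - set(communities))
        if unknown:
            raise ValidationError(f"unknown communities in pooling: {unknown}")
        totals: dict[str, int] = {}
        for com, sp, c in zip(qc.community, qc.species, qc.count):
            if com in members:
                totals[sp] = totals.get(sp, 0) + int(c)
        totals = {sp: c for sp, c in totals.items() if c > 0}
        if not totals:
            raise ValidationError(f"community {name!r} has no individuals")
        ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
        out[name] = AbundanceVector(
            community=name,
            abundances=tuple(c for _, c in ranked),
            species=tuple(sp for sp, _ in ranked),
        )
    return out


# ---------------------------------------------------------------------------
# closed-form fits


def pareto_fit(x: AbundanceVector, scale: float | str = "min") -> SADFit:
    """Fixed-scale Pareto fit: shape MLE b = S / sum(ln x_i/a), SE = b/sqrt(S)."""
    arr = x.as_array()
    a = float(arr.min()) if scale == "min" else float(scale)
    if a <= 0:
        raise ValueError("scale must be positive")
    if (arr < a).any():
        raise ValueError(f"abundances below the scale {a} are outside the support")
    s = x.n_species
    log_ratio = np.log(arr / a).sum()
    if log_ratio <= 0:
        raise DegenerateSampleError(
            "all abundances equal the scale; the Pareto shape MLE diverges"
        )
    b = s / log_ratio
    loglik = float(np.sum(np.log(b) + b * np.log(a) - (b + 1) * np.log(arr)))
    return SADFit(
        model="pareto",
        fixed={"scale": a},
        estimates={"shape": (float(b), float(b / math.sqrt(s)))},
        loglik=loglik,
        df=1,
    )


def broken_stick_eval(x: AbundanceVector) -> SADFit:
    """Broken-stick log-likelihood; N and S are data-determined, df = 0."""
    arr = x.as_array()
    n, s = x.n_individuals, x.n_species
    if s < 2:
        raise ValueError("broken stick needs at least 2 species")
    if (arr >= n).any() and s > 2:
        raise DegenerateSampleError(
            "an abundance equals the community total; broken-stick density is 0"
        )
    loglik = float(
        np.sum(np.log(s - 1) - np.log(n) + (s - 2) * np.log1p(-arr / n))
    )
    return SADFit(
        model="broken-stick",
        fixed={"N": float(n), "S": float(s)},
        estimates={},
        loglik=loglik,
        df=0,
    )


def lognormal_fit(x: AbundanceVector) -> SADFit:
    """Lognormal fit via moments of ln x (ML variance, divide by S)."""
    arr = x.as_array()
    s = x.n_species
    if s < 2:
        raise ValueError("lognormal fit needs at least 2 species")
    logs = np.log(arr)
    meanlog = float(logs.mean())
    sdlog = float(logs.std(ddof=0))
    if sdlog == 0:
        raise DegenerateSampleError("all abundances equal; sdlog is 0")
    loglik = float(stats.lognorm.logpdf(arr, s=sdlog, scale=math.exp(meanlog)).sum())
    return SADFit(
        model="lognormal",
        fixed={},
        estimates={
            "meanlog": (meanlog, sdlog / math.sqrt(s)),
            "sdlog": (sdlog, sdlog / math.sqrt(2 * s)),
        },
        loglik=loglik,
        df=2,
    )


# ---------------------------------------------------------------------------
# model registry for numeric MLE


@dataclass(frozen=True)
class SADModel:
    """A registered SAD model: likelihood, parameter space, initials.

    ``kind`` is "continuous" (i.i.d. densities on x > 0), "discrete"
    (i.i.d. pmfs on x = 1, 2, ...), or "rank" (multinomial likelihood of the
    ranked counts with per-rank probabilities p_i(theta)).
    """

    name: str
    kind: str
    params: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    nll: Callable[[np.ndarray, np.ndarray], float]
    initial: Callable[[np.ndarray], np.ndarray]
    # pdf/pmf over x (continuous/discrete) or rank probabilities (rank)
    density: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def _rank_nll(logp: Callable[[int, np.ndarray], np.ndarray]):
    """Multinomial negative log-likelihood for ranked counts."""

    def nll(x: np.ndarray, theta: np.ndarray) -> float:
        s = len(x)
        lp = logp(s, theta)
        const = special.gammaln(x.sum() + 1) - special.gammaln(x + 1).sum()
        return -float(const + np.dot(x, lp))

    return nll


def _geom_logp(s: int, theta: np.ndarray) -> np.ndarray:
    (k,) = theta
    i = np.arange(1, s + 1)
    logp = np.log(k) + (i - 1) * np.log1p(-k) - np.log1p(-((1 - k) ** s))
    return logp


def _zipf_logp(s: int, theta: np.ndarray) -> np.ndarray:
    (g,) = theta
    i = np.arange(1, s + 1)
    w = -g * np.log(i)
    return w - special.logsumexp(w)


def _zm_logp(s: int, theta: np.ndarray) -> np.ndarray:
    g, q = theta
    i = np.arange(1, s + 1)
    w = -g * np.log(i + q)
    return w - special.logsumexp(w)


def _poilog_logpmf(x: np.ndarray, mu: float, sigma: float, order: int = 60) -> np.ndarray:
    """Zero-truncated Poisson-lognormal pmf via Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(order)
    lam = np.exp(mu + sigma * nodes)  # nodes of the mixing lognormal
    logw = np.log(weights) - 0.5 * math.log(2 * math.pi)
    xs = np.atleast_1d(x)[:, None]
    log_terms = stats.poisson.logpmf(xs, lam[None, :]) + logw[None, :]
    logpmf = special.logsumexp(log_terms, axis=1)
    log_p0 = special.logsumexp(stats.poisson.logpmf(0, lam) + logw)
    return logpmf - np.log1p(-np.exp(log_p0))


def _iid_nll(logpdf: Callable[[np.ndarray, np.ndarray], np.ndarray]):
    def nll(x: np.ndarray, theta: np.ndarray) -> float:
        lp = logpdf(x, theta)
        if not np.all(np.isfinite(lp)):
            return np.inf
        return -float(lp.sum())

    return nll


def _build_registry() -> dict[str, SADModel]:
    eps = 1e-9
    reg: dict[str, SADModel] = {}

    def add(model: SADModel) -> None:
        reg[model.name] = model

    # -- discrete species models ------------------------------------------
    add(
        SADModel(
            name="log-series",
            kind="discrete",
            params=("p",),
            bounds=((eps, 1 - 1e-12),),
            nll=_iid_nll(lambda x, th: stats.logser.logpmf(x, th[0])),
            initial=lambda x: np.array([1 - 1 / max(x.mean(), 1.01)]),
            density=lambda x, th, ctx: stats.logser.pmf(x, th[0]),
        )
    )
    add(
        SADModel(
            name="power-discrete",
            kind="discrete",
            params=("exponent",),
            bounds=((1 + 1e-6, 20.0),),
            nll=_iid_nll(lambda x, th: stats.zipf.logpmf(x, th[0])),
            initial=lambda x: np.array([1.5]),
            density=lambda x, th, ctx: stats.zipf.pmf(x, th[0]),
        )
    )

    def _nbinom_logpmf(x: np.ndarray, th: np.ndarray) -> np.ndarray:
        r, mu = th
        p = r / (r + mu)
        # zero-truncated on x >= 1
        return stats.nbinom.logpmf(x, r, p) - np.log1p(-stats.nbinom.pmf(0, r, p))

    add(
        SADModel(
            name="negative-binomial",
            kind="discrete",
            params=("size", "mu"),
            bounds=((1e-4, 1e4), (eps, 1e9)),
            nll=_iid_nll(_nbinom_logpmf),
            initial=lambda x: np.array(
                [max(x.mean() ** 2 / max(x.var() - x.mean(), 0.5), 0.05), x.mean()]
            ),
            density=lambda x, th, ctx: np.exp(_nbinom_logpmf(np.asarray(x, float), th)),
        )
    )
    add(
        SADModel(
            name="poisson-lognormal",
            kind="discrete",
            params=("mu", "sigma"),
            bounds=((-10.0, 20.0), (1e-3, 10.0)),
            nll=_iid_nll(lambda x, th: _poilog_logpmf(x, th[0], th[1])),
            initial=lambda x: np.array([np.log(x).mean(), max(np.log(x).std(), 0.2)]),
            density=lambda x, th, ctx: np.exp(
                _poilog_logpmf(np.asarray(x, float), th[0], th[1])
            ),
        )
    )

    # -- continuous species models ----------------------------------------
    def _pareto_logpdf(x: np.ndarray, th: np.ndarray) -> np.ndarray:
        (b,) = th
        a = x.min()
        return np.log(b) + b * np.log(a) - (b + 1) * np.log(x)

    add(
        SADModel(
            name="pareto",
            kind="continuous",
            params=("shape",),
            bounds=((1e-6, 1e3),),
            nll=_iid_nll(_pareto_logpdf),
            initial=lambda x: np.array(
                [len(x) / max(np.log(x / x.min()).sum(), 1e-6)]
            ),
            density=lambda x, th, ctx: stats.pareto.pdf(x, th[0], scale=ctx[0]),
        )
    )
    add(
        SADModel(
            name="lognormal",
            kind="continuous",
            params=("meanlog", "sdlog"),
            bounds=((-20.0, 30.0), (1e-6, 20.0)),
            nll=_iid_nll(
                lambda x, th: stats.lognorm.logpdf(x, s=th[1], scale=np.exp(th[0]))
            ),
            initial=lambda x: np.array([np.log(x).mean(), max(np.log(x).std(), 0.1)]),
            density=lambda x, th, ctx: stats.lognorm.pdf(
                x, s=th[1], scale=np.exp(th[0])
            ),
        )
    )
    add(
        SADModel(
            name="weibull",
            kind="continuous",
            params=("shape", "scale"),
            bounds=((1e-3, 50.0), (1e-6, 1e9)),
            nll=_iid_nll(
                lambda x, th: stats.weibull_min.logpdf(x, th[0], scale=th[1])
            ),
            initial=lambda x: np.array([1.0, x.mean()]),
            density=lambda x, th, ctx: stats.weibull_min.pdf(x, th[0], scale=th[1]),
        )
    )
    add(
        SADModel(
            name="gamma",
            kind="continuous",
            params=("shape", "scale"),
            bounds=((1e-3, 1e3), (1e-6, 1e9)),
            nll=_iid_nll(lambda x, th: stats.gamma.logpdf(x, th[0], scale=th[1])),
            initial=lambda x: np.array(
                [max(x.mean() ** 2 / max(x.var(), 0.5), 0.05), max(x.var(), 0.5) / x.mean()]
            ),
            density=lambda x, th, ctx: stats.gamma.pdf(x, th[0], scale=th[1]),
        )
    )

    # -- rank-abundance models (multinomial over ranks) --------------------
    add(
        SADModel(
            name="geometric-series",
            kind="rank",
            params=("k",),
            bounds=((eps, 1 - eps),),
            nll=_rank_nll(_geom_logp),
            initial=lambda x: np.array([min(max(x[0] / x.sum(), 0.01), 0.95)]),
            density=lambda x, th, ctx: np.exp(_geom_logp(int(ctx[0]), th)),
        )
    )
    add(
        SADModel(
            name="zipf",
            kind="rank",
            params=("exponent",),
            bounds=((0.0, 20.0),),
            nll=_rank_nll(_zipf_logp),
            initial=lambda x: np.array([1.0]),
            density=lambda x, th, ctx: np.exp(_zipf_logp(int(ctx[0]), th)),
        )
    )
    add(
        SADModel(
            name="zipf-mandelbrot",
            kind="rank",
            params=("exponent", "offset"),
            bounds=((0.0, 20.0), (0.0, 100.0)),
            nll=_rank_nll(_zm_logp),
            initial=lambda x: np.array([1.0, 0.5]),
            density=lambda x, th, ctx: np.exp(_zm_logp(int(ctx[0]), th)),
        )
    )
    return reg


_REGISTRY = _build_registry()

#: registered but deliberately unimplemented (combinatorially heavy likelihoods)
STUB_MODELS = ("zero-sum-multinomial", "neutral")


def registry() -> tuple[str, ...]:
    """Names accepted by :func:`generic_mle_fit`."""
    return tuple(sorted(_REGISTRY)) + STUB_MODELS


def get_model(name: str) -> SADModel:
    if name in STUB_MODELS:
        raise NotImplementedError(
            f"{name}: sampling-theory likelihood not implemented; the registry "
            "accepts its later addition"
        )
    if name not in _REGISTRY:
        raise ValueError(f"unknown model {name!r}; registry: {registry()}")
    return _REGISTRY[name]


def _numeric_hessian(f: Callable[[np.ndarray], float], theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian, step scaled to parameter magnitude."""
    k = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def generic_mle_fit(
    x: AbundanceVector,
    model: str,
    *,
    seed: int = 0,
    n_starts: int = 5,
    tol: float = 1e-8,
) -> SADFit:
    """Numeric maximum-likelihood fit of a registered model.

    Multi-start bounded optimization from a moment-based initial plus
    seeded perturbations; standard errors from the inverse observed
    information.  Non-convergence raises :class:`FitError`; a parameter
    pinned at its domain boundary is flagged in the returned fit by an
    infinite standard error.
    """
    m = get_model(model)
    arr = x.as_array()
    rng = np.random.default_rng(seed)
    base = np.clip(
        m.initial(arr), [lo for lo, _ in m.bounds], [hi for _, hi in m.bounds]
    )

    def obj(theta: np.ndarray) -> float:
        val = m.nll(arr, theta)
        return val if np.isfinite(val) else 1e12

    best = None
    for start in range(n_starts):
        theta0 = base if start == 0 else np.clip(
            base * np.exp(rng.normal(0, 0.3, size=len(base))),
            [lo for lo, _ in m.bounds],
            [hi for _, hi in m.bounds],
        )
        res = optimize.minimize(
            obj, theta0, method="L-BFGS-B", bounds=m.bounds,
            options={"ftol": tol, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise FitError(f"{model}: optimization failed to converge")

    theta = best.x
    hess = _numeric_hessian(obj, theta)
    ses = np.full(len(theta), np.inf)
    at_boundary = np.array(
        [
            th <= lo + 1e-7 * max(abs(lo), 1) or th >= hi - 1e-7 * max(abs(hi), 1)
            for th, (lo, hi) in zip(theta, m.bounds)
        ]
    )
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        ok = (diag > 0) & ~at_boundary
        ses[ok] = np.sqrt(diag[ok])
    except np.linalg.LinAlgError:
        pass

    fixed: dict[str, float] = {}
    if model == "pareto":
        fixed["scale"] = float(arr.min())
    if m.kind == "rank":
        fixed["S"] = float(x.n_species)
        fixed["N"] = float(x.n_individuals)
    return SADFit(
        model=model,
        fixed=fixed,
        estimates={
            name: (float(v), float(se)) for name, v, se in zip(m.params, theta, ses)
        },
        loglik=-float(best.fun),
        df=len(theta),
    )


def fit_all(
    x: AbundanceVector,
    models: Sequence[str] | None = None,
    *,
    seed: int = 0,
) -> list[SADFit]:
    """Fit every requested (default: every implemented) model; failures are
    returned as non-converged placeholder fits, never silently dropped."""
    names = list(models) if models is not None else sorted(_REGISTRY) + ["broken-stick"]
    fits: list[SADFit] = []
    for name in names:
        try:
            if name == "broken-stick":
                fits.append(broken_stick_eval(x))
            else:
                fits.append(generic_mle_fit(x, name, seed=seed))
        except NotImplementedError:
            raise
        except (FitError, DegenerateSampleError, ValueError):
            fits.append(
                SADFit(
                    model=name, fixed={}, estimates={},
                    loglik=-np.inf, df=0, converged=False,
                )
            )
    return fits


def rank_by_aic(fits: Sequence[SADFit]) -> list[SADFit]:
    """Ascending-AIC ranking with delta AIC; ties break by fewer df, then name."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise FitError("no converged fits to rank")
    ordered = sorted(ok, key=lambda f: (f.aic, f.df, f.model))
    best = ordered[0].aic
    ranked = [replace(f, delta_aic=f.aic - best) for f in ordered]
    ranked += [f for f in fits if not (f.converged and np.isfinite(f.aic))]
    return ranked
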