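"""SAD model fits: closed forms, numeric MLE, registry, AIC ranking."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from nullassembly import (
    AbundanceVector,
    QuadratCounts,
    ValidationError,
    aggregate_abundances,
    broken_stick_eval,
    generic_mle_fit,
    lognormal_fit,
    pareto_fit,
    rank_by_aic,
    registry,
)
from nullassembly.sad import (
    DegenerateSampleError,
    SADFit,
    _REGISTRY,
    fit_all,
    get_model,
)
from nullassembly.synthetic import gen_pareto_sample


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_pools_quadrats():
    qc = QuadratCounts(
        community=("c1", "c1", "c1"),
        quadrat=("q1", "q1", "q2"),
        species=("A", "B", "A"),
        count=(3, 1, 2),
    )
    vec = aggregate_abundances(qc)["c1"]
    assert vec.abundances == (5, 1)
    assert vec.species == ("A", "B")
    assert vec.n_individuals == 6 and vec.n_species == 2


def test_aggregate_pooling_and_errors():
    qc = QuadratCounts(
        community=("i1", "i2"), quadrat=("q", "q"), species=("A", "B"), count=(2, 3)
    )
    pooled = aggregate_abundances(qc, {"meta": ["i1", "i2"]})["meta"]
    assert pooled.abundances == (3, 2)
    with pytest.raises(ValidationError):
        aggregate_abundances(qc, {"meta": ["i1", "nowhere"]})


# ---------------------------------------------------------------------------
# closed forms against independent oracles


def test_pareto_shape_mle_matches_numeric_maximization():
    """x = {1, e} with scale 1: analytic MLE b = S/sum(ln x/a) = 2, and the
    likelihood maximized numerically over b agrees."""
    x = np.array([1.0, math.e])
    s = len(x)
    assert s / np.log(x).sum() == pytest.approx(2.0)

    def negll(b):
        return -np.sum(np.log(b) + b * np.log(1.0) - (b + 1) * np.log(x))

    res = optimize.minimize_scalar(negll, bounds=(0.01, 50), method="bounded")
    # integer abundances: check the fit itself on a real vector
    vec = AbundanceVector("t", (272, 100))  # ratio e, scale 100
    fit = pareto_fit(vec, scale=100)
    assert fit.estimates["shape"][0] == pytest.approx(
        2 / math.log(2.72), rel=1e-12
    )
    assert res.x == pytest.approx(2.0, rel=1e-4)


def test_pareto_fit_properties():
    vec = gen_pareto_sample(200, 20, 0.5, seed=7)
    fit = pareto_fit(vec)
    b, se = fit.estimates["shape"]
    assert fit.fixed["scale"] == min(vec.abundances)
    assert se == pytest.approx(b / math.sqrt(200))
    assert abs(b - 0.5) < 3 * se
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2, abs=1e-9)


def test_pareto_degenerate_sample():
    with pytest.raises(DegenerateSampleError):
        pareto_fit(AbundanceVector("t", (5, 5, 5)), scale=5)


def test_pareto_scale_above_minimum_rejected():
    with pytest.raises(ValueError):
        pareto_fit(AbundanceVector("t", (30, 10)), scale=20)


def test_broken_stick_uniform_at_s2():
    fit = broken_stick_eval(AbundanceVector("t", (7, 3)))
    assert fit.loglik == pytest.approx(2 * math.log(0.1))
    assert fit.df == 0
    assert fit.aic == pytest.approx(-2 * fit.loglik)


def test_broken_stick_density_normalizes():
    """p(x) = (S-1)/N (1-x/N)^(S-2) integrates to 1 on (0, N)."""
    n, s = 460, 5
    val, _ = integrate.quad(lambda x: (s - 1) / n * (1 - x / n) ** (s - 2), 0, n)
    assert val == pytest.approx(1.0, abs=1e-9)


def test_broken_stick_edge_cases():
    with pytest.raises(ValueError):
        broken_stick_eval(AbundanceVector("t", (5,)))
    # endpoint: p(N) = 0 whenever S > 2
    n, s = 100, 5
    assert (s - 1) / n * (1 - n / n) ** (s - 2) == 0.0


def test_lognormal_moments():
    x = (round(math.e**4), round(math.e**2))  # 55, 7: integers nearest e^4, e^2
    fit = lognormal_fit(AbundanceVector("t", x))
    meanlog, se_mean = fit.estimates["meanlog"]
    sdlog, se_sd = fit.estimates["sdlog"]
    assert meanlog == pytest.approx((math.log(55) + math.log(7)) / 2)
    assert meanlog == pytest.approx(3.0, abs=0.05)
    assert sdlog == pytest.approx(1.0, abs=0.05)
    assert se_mean == pytest.approx(sdlog / math.sqrt(2))
    assert se_sd == pytest.approx(sdlog / 2)
    assert fit.df == 2
    with pytest.raises(DegenerateSampleError):
        lognormal_fit(AbundanceVector("t", (4, 4, 4)))


# ---------------------------------------------------------------------------
# numeric registry


def test_closed_forms_agree_with_numeric_mle():
    vec = gen_pareto_sample(80, 20, 0.8, seed=3)
    closed = pareto_fit(vec)
    numeric = generic_mle_fit(vec, "pareto", seed=0)
    assert numeric.loglik == pytest.approx(closed.loglik, abs=1e-6)
    assert numeric.estimates["shape"][0] == pytest.approx(
        closed.estimates["shape"][0], abs=1e-5
    )
    closed_ln = lognormal_fit(vec)
    numeric_ln = generic_mle_fit(vec, "lognormal", seed=0)
    assert numeric_ln.loglik == pytest.approx(closed_ln.loglik, abs=1e-6)


def test_zipf_exponent_matches_grid_search():
    """Harmonic decay {100, 50, 33, 25}: the multinomial rank likelihood is
    maximized near exponent 1 (oracle: dense grid over the likelihood)."""
    vec = AbundanceVector("t", (100, 50, 33, 25))
    model = _REGISTRY["zipf"]
    x = vec.as_array()
    grid = np.linspace(0.2, 3.0, 2801)
    nlls = [model.nll(x, np.array([g])) for g in grid]
    g_star = grid[int(np.argmin(nlls))]
    fit = generic_mle_fit(vec, "zipf")
    assert fit.estimates["exponent"][0] == pytest.approx(g_star, abs=1e-3)
    assert fit.estimates["exponent"][0] == pytest.approx(1.0, abs=0.05)


def test_geometric_series_parameter_recovery():
    """Ranked counts drawn from the geometric-series composition with
    k = 0.5, S = 50 recover k within 3 SE."""
    from nullassembly.sad import _geom_logp

    rng = np.random.default_rng(12)
    p = np.exp(_geom_logp(50, np.array([0.5])))
    counts = rng.multinomial(5000, p)
    counts = np.sort(counts[counts > 0])[::-1]
    vec = AbundanceVector("t", tuple(int(c) for c in counts))
    fit = generic_mle_fit(vec, "geometric-series", seed=1)
    k, se = fit.estimates["k"]
    assert np.isfinite(se)
    assert abs(k - 0.5) < 3 * se


def test_registered_densities_normalize_at_fitted_parameters():
    """Continuous pdfs integrate to 1, discrete pmfs sum to 1 over x >= 1,
    rank probabilities sum to 1 over the S ranks (1e-6)."""
    vec = gen_pareto_sample(60, 5, 1.0, seed=9)
    ctx = np.array([float(vec.n_species), float(min(vec.abundances))])
    for name, model in sorted(_REGISTRY.items()):
        fit = generic_mle_fit(vec, name, seed=2)
        theta = np.array([v for v, _ in fit.estimates.values()])
        if model.kind == "continuous":
            lo = min(vec.abundances) if name == "pareto" else 0.0
            ctx_m = np.array([float(min(vec.abundances))])
            total, _ = integrate.quad(
                lambda x: model.density(np.array([x]), theta, ctx_m)[0],
                lo, np.inf, limit=200,
            )
        elif model.kind == "discrete":
            xs = np.arange(1, 200001)
            total = model.density(xs, theta, ctx).sum()
            if name == "power-discrete":
                # exact Hurwitz-zeta tail beyond the truncation point
                from scipy.special import zeta

                s_exp = theta[0]
                total += zeta(s_exp, xs[-1] + 1) / zeta(s_exp, 1)
        else:  # rank
            total = model.density(
                np.arange(1, vec.n_species + 1), theta,
                np.array([float(vec.n_species)]),
            ).sum()
        assert total == pytest.approx(1.0, abs=1e-4), name


def test_unknown_and_stub_models():
    with pytest.raises(ValueError, match="registry"):
        get_model("gaussian")
    for stub in ("zero-sum-multinomial", "neutral"):
        assert stub in registry()
        with pytest.raises(NotImplementedError):
            get_model(stub)


# ---------------------------------------------------------------------------
# ranking


def test_rank_by_aic_deltas():
    fits = [
        SADFit(model="a", fixed={}, estimates={}, loglik=-44.7, df=1),
        SADFit(model="b", fixed={}, estimates={}, loglik=-45.8, df=0),
        SADFit(model="c", fixed={}, estimates={}, loglik=-45.65, df=2),
    ]
    ranked = rank_by_aic(fits)
    assert [f.model for f in ranked] == ["a", "b", "c"]
    assert ranked[0].delta_aic == 0
    assert ranked[1].delta_aic == pytest.approx(ranked[1].aic - ranked[0].aic)
    single = rank_by_aic([fits[0]])
    assert single[0].delta_aic == 0


def test_zero_parameter_model_does_not_shift_other_aics():
    vec = gen_pareto_sample(40, 10, 0.9, seed=5)
    fits = fit_all(vec, ["pareto", "lognormal"], seed=0)
    with_const = fits + [broken_stick_eval(vec)]
    r1 = {f.model: f.aic for f in rank_by_aic(fits)}
    r2 = {f.model: f.aic for f in rank_by_aic(with_const)}
    assert r1["pareto"] == r2["pareto"] and r1["lognormal"] == r2["lognormal"]


def test_pareto_tops_ranking_on_pareto_data():
    """Fits of the main model family to a heavy-tailed power-law sample rank
    the generating model first."""
    vec = gen_pareto_sample(100, 20, 0.6, seed=21)
    ranked = rank_by_aic(
        fit_all(vec, ["pareto", "lognormal", "broken-stick"], seed=0)
    )
    assert ranked[0].model == "pareto"
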