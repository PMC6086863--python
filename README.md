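# nullassembly

Null-model inference for insular community assembly. The package asks, for a
finite community spread over an archipelago, whether interspecific
competition leaves detectable fingerprints in three classical patterns —
species co-occurrence, species-abundance distributions (SADs), and body-size
spacing — or whether history and chance suffice. It is written for community
ecologists and macroecologists working with presence–absence matrices,
quadrat counts, and trait tables.

## What it computes

**Exact pairwise co-occurrence.** For species occupying `n1` and `n2` of `N`
sites, the number of shared sites `j` under random placement is
hypergeometric:

    P(j) = C(n1, j) C(N - n1, n2 - j) / C(N, n2)

Each of the `S(S-1)/2` unordered pairs is classified against the inclusive
tails of this law: *positive* if `P(J >= j_obs) < α`, *negative* if
`P(J <= j_obs) < α`, *random* if `|j_obs − n1 n2/N| <= 0.1 N`, otherwise
*unclassifiable*; pairs with expectation `n1 n2/N < 1` are *removed*. A
standardized effect size `(j_obs − n1 n2/N)/N ∈ [−1, 1]` is reported for
every pair. All probabilities use exact integer arithmetic.

**Guild cross-classification.** The same test is run on a species × 4 matrix
over {Arboreal, Terrestrial} × {Diurnal, Nocturnal} categories (each row
sums to 2). With `N = 4` and all occupancies 2, no tail probability can fall
below 1/6, so guild pairs are never significant — which is the point: pairs
that segregate geographically but show no guild association are explained by
*historical allopatry*, geographically aggregated pairs without guild
structure by *common history*, and only geographic segregation combined with
guild association is *competition-consistent*.

**SAD model selection.** Abundance vectors are fit by maximum likelihood to
a registry of models — Pareto `f(x) = b a^b / x^(b+1)` with the scale `a`
fixed at the rarest species' abundance, the parameter-free broken stick
`p(x) = (S−1)/N (1 − x/N)^(S−2)`, lognormal, log-series, geometric series,
Weibull, gamma, discrete power, Zipf, Zipf–Mandelbrot, Poisson-lognormal and
negative binomial — and ranked by AIC.

**Body-size V-ratio.** The V-ratio is the variance of gaps between adjacent
log body masses; constant size ratios (the classical competitive-spacing
prediction) give 0. Observed values are placed in a Monte-Carlo null built
by drawing equal-richness communities from a source pool truncated at the
community's largest species and padded with five hypothetical species, with
inclusive tail proportions and SES `(V_obs − mean(V_null))/sd(V_null)`.

**Species–area regression** (`log10 S` on `log10 A`) as a control for
intrinsic island differences, and synthetic generators (allopatric blocks,
nested archipelagos, Pareto/broken-stick samplers, size assemblages) that
give every stage a testable ground truth.

## Worked example

```python
from nullassembly import analyze_matrix, fit_all, rank_by_aic
from nullassembly.synthetic import gen_allopatric_matrix, gen_pareto_sample
from nullassembly import io

m = gen_allopatric_matrix(n_groups=2, species_per_group=8, islands_per_group=10,
                          shared_species=1, occupancy=0.6, seed=1)
results, summary = analyze_matrix(m)
print(io.summary_frame({"geographic": summary}).to_string(index=False))

vec = gen_pareto_sample(50, 20, 0.6, seed=2)
ranked = rank_by_aic(fit_all(vec, ["pareto", "lognormal", "broken-stick"], seed=0))
print(io.sad_ranking_frame(ranked).to_string(index=False))
```

prints

```
  analysis  species  sites  pairs_total  removed  positive  negative  random  unclassifiable
geographic       17     20          136        1        17        14     104               0

       model         fixed                               coefficients      loglik  df        aic  delta_aic  converged
      pareto      scale=21                     shape=0.6744 (±0.0954) -296.063104   1 594.126208   0.000000       True
   lognormal          None meanlog=4.527 (±0.2); sdlog=1.416 (±0.142) -314.706315   2 633.412630  39.286423       True
broken-stick N=21982; S=50                                            -361.288098   0 722.576195 128.449988       True
```

The two-block metacommunity (two groups of 8 endemics on 10 islands each,
one shared species) yields 14 negative pairs, every one of them spanning the
two groups — the allopatry signature, with no competition involved. The
abundance sample drawn from a Pareto SAD (scale 20, shape 0.6) is correctly
ranked Pareto-first by AIC, with the shape recovered within one standard
error.

The same stages are available from a shell:

```sh
nullassembly synth --scenario allopatric --seed 1 --out data/
nullassembly cooccur data/matrix.csv --alpha 0.05 --out out/
nullassembly sad abundances.csv --out out/
nullassembly vratio masses.csv composition.csv --seed 1 --out out/
```

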