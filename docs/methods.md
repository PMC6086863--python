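# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions a maintainer would otherwise have
to reverse-engineer.

## Exact co-occurrence model

Two species occupying `n1` and `n2` of `N` equally likely sites, placed
independently, share a hypergeometric number of sites `J`:
`P(J = j) = C(n1, j) C(N−n1, n2−j) / C(N, n2)` on
`max(0, n1+n2−N) ≤ j ≤ min(n1, n2)`. The model is conditional on the
observed row totals; it does not condition on column totals (site richness),
which is the main structural assumption — site-quality gradients inflate
apparent positive association (see the nested-generator tests, which exploit
exactly this).

Probabilities are exact rationals (`fractions.Fraction` over `math.comb`),
so the pmf sums to 1 identically and the suite's normalization checks are
exact rather than toleranced. Runtime is negligible for `N` up to a few
hundred sites.

Classification defaults: `alpha = 0.05`, random band `0.1 × N` shared
sites, removal threshold `expected < 1`. Tails are inclusive
(`p_lt = P(J ≤ j_obs)`, `p_gt = P(J ≥ j_obs)`), so `p_lt + p_gt ≥ 1` and at
`alpha < 0.5` both tails can never be significant simultaneously — asserted
as a test, not assumed. Removed pairs are reported with
`classification = "removed"` rather than dropped, and are tallied separately
from unclassifiable pairs. The SES `(j_obs − E)/N` is bounded in `[−1, 1]`
and is *not* a z-score; it is comparable across pairs within a matrix, not
across matrices of different `N`.

## Guild encoding

The guild matrix uses the four *category* columns (Arboreal, Terrestrial,
Diurnal, Nocturnal) with every species row summing to 2. This is an
interpretation: an alternative encoding with four mutually exclusive guild
columns would give every pair expected co-occurrence 1/4 < 1 and remove all
of them, leaving nothing to classify, so the category encoding is the one
under which the analysis is informative. Under it the outcome space is
structural: pairs sharing one category are `random` (deviation 0 ≤ 0.4),
pairs sharing both or neither are `unclassifiable` (deviation 1 > 0.4), and
no pair can reach significance because the smallest attainable tail
probability at `N = 4`, `n1 = n2 = 2` is 1/6. The cross-classification
vocabulary (`historical allopatry`, `common history`,
`competition-consistent`, `uninformative`) is fixed so downstream reports
can cite it.

## SAD likelihoods

All continuous densities (Pareto, lognormal, broken stick, Weibull, gamma)
are evaluated at the integer abundances as densities, not discretized or
binned; discrete models (log-series, discrete power, zero-truncated negative
binomial, zero-truncated Poisson-lognormal) use pmfs on `x ≥ 1`; the
rank-abundance models (geometric series, Zipf, Zipf–Mandelbrot) use the
multinomial likelihood of the ranked counts with per-rank probabilities.
AIC values are therefore comparable within a kind and, following common
practice in SAD model selection, compared across kinds as well.

* Pareto scale defaults to `min(x)`: with a fixed scale the shape MLE is
  `b = S / Σ ln(x_i/a)` with asymptotic SE `b/√S`. A sample with all
  abundances at the scale has no finite MLE and raises a degenerate-sample
  error.
* Broken stick has `df = 0` (`N` and `S` are data), so `AIC = −2 logL`.
* Lognormal uses the ML (divide-by-`S`) variance; SEs are `sdlog/√S` and
  `sdlog/√(2S)`.
* Numeric fits run L-BFGS-B from a moment-based initial plus four seeded
  log-normal perturbations (5 starts), relative log-likelihood tolerance
  `1e-8`; SEs come from the inverse of a central-difference observed
  information. A parameter within `1e-7` (relative) of its bound is flagged
  by an infinite SE rather than a spurious Hessian-based one. Failures are
  returned as non-converged placeholder fits, never dropped silently.
* The Poisson-lognormal pmf is computed by 60-node Gauss–Hermite quadrature
  over the mixing lognormal and zero-truncated.
* The zero-sum multinomial and neutral-model SADs are registry stubs that
  raise `NotImplementedError`; their sampling-theory likelihoods are
  combinatorially heavy and the registry is designed to accept them later.

AIC ties break by fewer parameters, then model name, making rankings
deterministic.

## V-ratio null model

The V-ratio is the sample variance (denominator `n_gaps − 1` by default;
`ddof=0` behind a flag, since the literature is not unanimous on the
convention) of the differences between adjacent log body masses after
sorting. It is invariant to species order and to rescaling all masses, and
it is 0 exactly when size ratios are constant — the property the metric is
designed around.

The null pool for a community is: every archipelago species with mass not
exceeding the community's maximum (the community's largest species is
guaranteed present, so pool and community maxima coincide), plus 5
hypothetical species with masses drawn log-uniformly between the pool
minimum and the community maximum. Hypothetical masses are drawn once per
pool, not per iterate; they exist to keep the pool strictly larger than the
community. Null communities are equal-richness draws without replacement,
1000 iterates by default (configurable; the V-ratio's null distribution is
heavily right-skewed, so tail proportions — inclusive, hence
`p_lower + p_upper ≥ 1` — are reported alongside the SES).

The richness–V-ratio association is summarized by Pearson's `r` with
`t = r √(df/(1−r²))`, `df = n − 2`.

## Species–area control

Ordinary least squares of `log10(richness)` on `log10(area)`;
`F = (n−2) R²/(1−R²)`. Slope, `R²` and `F` are invariant to the logarithm
base (property-tested); base 10 is canonical. When no attribute table is
supplied, richness can be taken from presence–absence column sums.

## Synthetic generators

One global integer seed drives a named substream per generator
(`SeedSequence([seed, crc32(name)])`), so stages regenerate independently
and bit-identically.

* *Allopatric*: two (or more) island groups; endemics occur only within
  their group, independently with probability `occupancy` (default 0.6, a
  moderately occupied block); shared species range over all islands. The
  defaults (2 groups × 8 endemics × 10 islands, 1 shared species) mirror a
  two-archipelago system split by a dispersal barrier with one widespread
  species.
* *Nested ("common history")*: islands are ordered richest-first; each
  species occupies a prefix of that order with probability `nestedness`,
  otherwise an independent random set. At 1.0 every pair of islands is
  subset-comparable; at 0.0 occupancy is independent.
* *Pareto sampler*: inverse-CDF, `x = round(a U^(−1/b))`, half-up rounding,
  so the minimum never falls below the scale.
* *Broken-stick sampler*: `S−1` uniform cuts of a stick of length `N`,
  integerized by largest-remainder so totals are conserved exactly; a
  rounded-to-zero segment triggers a bounded redraw (a negligible-probability
  event at the sizes used, noted here because it slightly truncates the
  smallest-segment distribution).
* *Size assemblages*: random draws from a mass pool, or the `S` pool species
  nearest an even grid on the log-mass axis (the constant-ratio
  construction used for power checks).

What the generators do **not** emulate: spatial structure within island
groups, abundance–occupancy correlations, detection error, phylogenetic
signal in body mass, and site-richness gradients other than the nestedness
device. Passing tests therefore demonstrate correctness of the inference
machinery under its own assumptions, not robustness of the field method to
those complications.

## Problem sizes in the test suite

The suite's stochastic batteries use 200 replicates for type-I control
(12 species × 20 islands) and SES calibration (29-species pool, richness 7,
500 null iterates), 100 replicates for the power check, 200 replicates per
shape for Pareto recovery at `S = 200`, and 2000 draws for the
broken-stick distributional checks — sizes at which the Monte-Carlo error
of each assertion is several times smaller than the margin it tests, while
the whole suite stays interactive.

## Known limitations

* The exact test conditions on row totals only; strong site-suitability
  gradients are read as positive association (by design, this is what the
  nested scenario demonstrates).
* Cross-kind AIC comparisons (rank-multinomial vs i.i.d.-species
  likelihoods) inherit the usual caveat that the likelihoods are defined on
  different sample spaces.
* The V-ratio variance convention (`ddof`) changes observed values by a
  factor of up to 2 at small richness; both conventions are exposed, and
  comparisons against external values should confirm which one they use.
* SES for co-occurrence and SES for V-ratios are different quantities (one
  is bounded and site-normalized, the other a z-score); they share a name
  in the field but are not comparable.
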