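# Methods

## Data model and effect scale

All analyses operate on two-arm binary-outcome trial summaries
(events/total per arm). The effect scale is the log odds ratio: control
logit `mu_i = logit(p_C,i)`, treatment logit `mu_i + delta_i`. The
observed effect uses the cross-product ratio with the Woolf variance
`1/a + 1/b + 1/c + 1/d`; within-study variances are treated as known
everywhere downstream. Wald intervals and normal-theory p-values are
attached (z, not t). A continuity correction (+0.5 to all four cells) is
applied only when a cell is zero and only when explicitly enabled;
otherwise a zero cell raises an error naming the cell, since silently
correcting non-degenerate tables would change published estimates.

P-values default to two-sided; a one-sided option exists because some
published single-trial p-values follow the one-sided convention while
meta-analytic p-values are two-sided. Events are oriented as
harms/failures; datasets with beneficial events carry that orientation as
metadata and are excluded from noninferiority calls, which are only
meaningful for harm-oriented outcomes.

## Frequentist pooling

Fixed effect: inverse-variance weighting, variance `1/sum(w_i)`. Random
effects: the same with `w_i* = 1/(sigma_i^2 + tau^2)`. `tau^2` is
estimated by DerSimonian–Laird, `max(0, (Q - df) / (S1 - S2/S1))` with
`S1 = sum w`, `S2 = sum w^2` — chosen as the conventional moment default,
consistent with the behaviour that homogeneous examples give exactly
`tau^2 = 0` and identical fixed/random results. REML is available behind a
flag (bounded scalar optimization of the restricted likelihood) but is not
used by the worked examples. No Hartung–Knapp adjustment: intervals are
plain Wald at all levels. Cochran's Q uses the chi-square upper tail with
n−1 degrees of freedom.

## Heterogeneity priors and their interpretation

Three families: half-normal on `tau` (scale `s`), inverse-gamma on
`tau^2` (scale `a`, shape `b`; the density in `tau` carries the Jacobian
`2 tau`), and point masses (handled symbolically, never as densities).
The configuration syntax requires an explicit `on: tau | tau2` keyword so
the two parameterizations cannot be silently confused; fraction strings
("1/3") are accepted.

Each prior is summarized by a *nominal* heterogeneity: `(E tau)^2 =
2 s^2 / pi` for the half-normal, and `a/b` for the inverse-gamma. The
inverse-gamma mean is undefined at shape 1 (the shape used throughout),
so `a/b` is a representative value — the scale of the distribution — not
a moment; it reproduces the conventional translation table (0.33, 0.14,
0.001). The half-normal uses `(E tau)^2` rather than `E(tau^2)` for the
same reason of matching the standard table entry at scale 0.5 (0.16);
neither convention reproduces the commonly printed 0.61 for scale 1
exactly, which we document rather than chase. The interpretability
translation is `OR1/OR2 = exp(2 * 1.96 * sqrt(nominal tau^2))` — the
ratio of the 97.5th to the 2.5th percentile of trial-level odds ratios
under that heterogeneity — and reproduces the printed column
(10, 4, 1, 23, 5) to within its loose rounding.

## Bayesian meta-analysis: quadrature engine

The normal-normal hierarchical model is conjugate given `tau`, so no
sampling is needed:

1. `log m(data | tau)` with the overall effect integrated out
   analytically — a sequential (Kalman-style) product of one-step
   predictive normal densities for a proper `N(m0, v0)` effect prior, or
   the profile form `(1/2) sum log w* - (1/2) log sum w* - Q*/2` for the
   improper flat prior.
2. `p(tau | data)` = prior density × marginal likelihood, normalized by
   trapezoid rule on a uniform grid of 400 points from 0 to the prior's
   99.99% quantile (capped at 10 on the log OR scale — heterogeneity
   beyond that is meaningless for trial data).
3. `p(delta | data)` = mixture over the `tau` grid of the conditional
   conjugate normals, evaluated on a `delta` grid of 800 points.

The `delta` grid spans the **envelope** of all conditional means ± 8
conditional SDs rather than a fixed multiple of the pooled SD: with heavy
heterogeneity priors the conditional posteriors at large `tau` are far
wider than the fixed-effect pooled SD, and a grid sized by the pooled SD
alone would truncate them. The envelope keeps both tails below 1e-6 of
the peak for every mixture component. Doubling both grid resolutions
moves posterior means by less than 1e-4 on the worked examples.

Posteriors are carried as normalized grid densities. Summaries are the
numeric mean, the median, and equal-tailed credible intervals obtained by
inverse-CDF with linear interpolation; quantiles use the midpoint of the
generalized-inverse interval so they remain well defined across flat CDF
stretches (relevant for well-separated mixture components). Equal-tailed
intervals are the default to match standard forest-style displays;
posteriors under half-normal priors can be visibly skewed, in which case
the median is the reported point estimate.

Effect and control priors are read in **mean/variance** parameterization
(`N(0,10)`, `N(0,4)` defaults, the usual vague-prior convention); an
`NormalPrior.from_sd` constructor is the loudly-labelled alternative, and
`NormalPrior.flat()` gives the improper flat prior whose fixed-effect
posterior equals the frequentist result exactly.

## MCMC engine

The exact-likelihood engine targets the binomial-logit posterior
directly: per-study `mu_i` with `N(0,4)` priors, common `delta ~ N(0,10)`
(fixed model) or study effects `theta_i ~ N(delta, tau^2)` with `delta`
updated by an exact Gibbs step and `tau` by a reflected random walk under
its heterogeneity prior (random model). All Metropolis updates are
Gaussian random walks, vectorized across chains, with step sizes adapted
every 50 warmup iterations toward ~30% acceptance. Defaults: 4 chains,
10,000 iterations, first half discarded as warmup; the seed is mandatory.
Split R-hat and effective sample size (via arviz) are computed for all
scalar parameters; R-hat > 1.05 raises an error carrying the diagnostics
rather than returning silently bad chains. A point-mass heterogeneity
prior at 0 collapses the hierarchy, and the sampler delegates to the
fixed model in that case.

The two engines use different likelihoods (normal approximation vs exact
binomial), so their posterior means agree only up to the approximation
error of the Woolf variance — within 0.02 on the published tables (a few
hundred patients per arm) and within 0.01 at a few thousand per arm.

## MAP and MAC

The predictive prior for a new exchangeable study is
`p(delta_new | hist) = integral N(delta_new | theta, tau^2)
p(theta, tau | hist) dtheta dtau`: the inner integral is conjugate in
closed form given `tau`; the outer is the same `tau` grid as above using
the *historical data only*. Point-mass `tau` yields a closed normal
`N(m(tau), v(tau) + tau^2)`; for one historical study and a flat
overall-effect prior this is `N(delta_H, 2 tau^2 + sigma_H^2)` — the
between-trial variance counts once for the historical trial and once for
the new one. The update step multiplies the predictive prior by the new
study's normal likelihood pointwise and renormalizes; no heterogeneity
prior enters the update.

The construction defaults to a **flat prior on the overall effect**, so
the closed forms above hold exactly and the fixed-effect MAP prior is
precisely the pooled estimate with pooled variance. A proper normal prior
may be supplied and is then used consistently in both routes.

The central correctness property is sequential/joint equivalence: the
two-step MAP posterior is an exact factorization of the joint
hierarchical ("MAC") posterior of the new study's effect, because the new
study's likelihood does not depend on `tau` given `delta_new`. The joint
route is implemented independently (conditional
`delta_new | data, tau ~ N(a y_new + (1-a) B, 1/P + (1-a)^2 V)` mixed
over `p(tau | all data)`), and both agree within 7e-5 on every worked
example × prior combination — the tests enforce 5e-3.

Borrowing monotonicity (more assumed heterogeneity → posterior closer to
the new study) holds within each prior family. It does *not* hold across
families at matched nominal heterogeneity: half-normal priors retain mass
near `tau = 0`, so the historical data keep more weight than under an
inverse-gamma prior of similar nominal value, and the posterior is
visibly skewed. This is a genuine feature of the model, not a numerical
artifact, and the tests compare within families only.

## Decision rules and battery

`significant` means the two-sided interval excludes 0 strictly;
`noninferior` means events are harms and the upper bound of the two-sided
95% interval is strictly below the margin (one-sided 2.5% rule). The
default margin is 0.43 log OR, the translation of a 10-percentage-point
risk margin at a control event rate near 31%
(`ln[odds(p_C + 0.10)/odds(p_C)]`; the translation is evaluated at the
first adult trial's printed control rate, 61/196, which reproduces
0.44/OR 1.55 — the translation varies by about ±0.01 over plausible
control-rate choices).

The comparison battery emits rows in fixed order — individual studies,
frequentist fixed/random pool, Bayesian fixed effect, Bayesian random
effects under the five standard priors, then fixed-effect MAP and
random-effects MAP under four priors (the near-degenerate IG(1/1000,1)
is omitted from the MAP panel because it replicates the fixed-effect MAP
row). Method labels are a fixed controlled vocabulary; output CSV is
deterministic at fixed precision and byte-identical across runs.

## Synthetic programmes

The generator emulates the kidney-transplant extrapolation setting:
control failure rate 0.3, true log OR 0 (the adult evidence is null),
three adult trials of 195 per arm and a paediatric trial of 53 per arm —
the published design sizes. Study effects are drawn
`delta_i ~ N(delta, tau^2)` with the paediatric trial exchangeable with
the adults; `tau = 0` reproduces the homogeneous scenario, `tau` around
0.6 the discordant one. Per-study generators are split from one
`SeedSequence`, so enlarging a programme never perturbs earlier studies.

What the generator does **not** emulate: overdispersion beyond binomial
sampling, differential follow-up or dropout, non-exchangeable shifts
between populations (e.g. a systematic adult-vs-paediatric offset), and
composite-endpoint correlation structure. Passing calibration tests on
these simulations therefore demonstrates internal correctness of the
machinery under its own assumptions, not robustness of MAP borrowing on
real programmes — indeed the package's central point is that conclusions
under discordance are driven by the heterogeneity prior.

Simulation sizes used by the tests and the acceptance script (2,000
trials for interval coverage, 200 replicates for simulation-based
calibration and per-`tau` MAP coverage, 50 studies for `tau` recovery)
were chosen to bound Monte-Carlo error well below the tolerances being
asserted while keeping the default suite fast.

## Known limitations

* Log OR scale only; no risk-difference/risk-ratio analyses, no exact
  conditional inference, no individual-patient data.
* The quadrature engine inherits the normal approximation of study-level
  likelihoods; very small or zero-cell trials should use the MCMC engine
  (whose binomial likelihood needs no continuity correction).
* No power priors, commensurate priors, or robust mixture-MAP priors;
  no multiplicity control across the battery (none is intended — the
  battery is a sensitivity display, not a testing procedure).
* Heterogeneity priors are limited to half-normal, inverse-gamma and
  point masses; uniform/half-Cauchy variants and elicitation from
  external meta-analyses are out of scope.
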