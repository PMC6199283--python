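# Methods

## Model and assumptions

`mncount` implements the marked nest count (MNC) estimator for orang-utan
surveys as a three-layer hierarchical *N*-mixture model. Plots are the
sampling unit. On the first visit all nests in a plot are observed and new
nests are marked; on revisits only nests built since the first visit are
counted. This bypasses nest decay rates entirely — the single most
error-prone input of standing-crop nest counts — at the price of three
design assumptions: (1) all nests present are recorded on the first survey
(relaxed below via the double-observer component), (2) no nest built after
the first survey decays before the next, and (3) plots with no old or new
nest sign on the first survey are treated as unused for the whole survey
window, are not revisited, and enter the model as structural zeros.

Per site, with plots *i*:

* *z<sub>i</sub>* ~ Bernoulli(ψ) — suitability / habitat use, *z* observed;
* *n<sub>i</sub>* ~ Poisson(λ · *z<sub>i</sub>* · *a<sub>i</sub>* ·
  *t<sub>i</sub>*) — latent new nests built between first and last survey,
  with the plot-area × elapsed-days product as offset so λ is a rate in
  nests km⁻² day⁻¹;
* *y<sub>i</sub>* ~ Binomial(*n<sub>i</sub>*, *q*) — revisit detection.

The model is intercept-only: no covariates on ψ or λ, matching the survey
analysis it reimplements. ψ and λ are site-specific. *q* and the latent
first-survey nest total *x₀* are pooled across all sites, because the
detection process (two teams walking each strip in opposite directions) is
shared; a single pooled *q* row is what the original summary table prints.

The double-observer first survey treats *q* as a per-team, per-nest
Bernoulli probability: each of the *x₀* fresh nests is independently found
by team 1 and team 2, giving the multinomial pattern (q², q(1−q), (1−q)q,
(1−q)²) over (both, team-1-only, team-2-only, missed). This is the reading
consistent with a latent nest total slightly above the count actually found
together with a handful of single-team detections. The revisit layer uses
*q* directly as printed, i.e. `y ~ Binomial(n, q)`, not a two-team combined
probability.

## Priors and sampling

ψ, *q* ~ Uniform(0,1); λ ~ Uniform(0, 4) nests km⁻² day⁻¹; *x₀* flat on the
integers up to `x0_max` (default 10 × the distinct nests found, floored at
20 so a survey that found nothing still has support). Every full
conditional is then available in closed form, and the sampler is a
systematic-scan Gibbs with exact updates:

| block | full conditional |
|---|---|
| ψ (per site) | Beta(1 + Σz, 1 + N − Σz) |
| n_i (latent) | y_i + Poisson(λ a_i t_i (1 − q)) |
| λ (per site) | Gamma(1 + Σn, Σ a t) truncated to [0, 4]; the prior when no used plot was revisited |
| x₀ | m + NegBinomial(m + 1, 1 − (1−q)²) truncated at x0_max, m = distinct nests found |
| q | Beta(1 + S, 1 + F), S/F = per-nest detection successes/failures from revisits and the two-team first survey |

Truncated-gamma and truncated-negative-binomial draws use rejection from
the untruncated distribution (exact) with an inverse-CDF fallback after 64
misses, so the stationary distribution is never approximated. Defaults are
40,000 iterations with 5,000 burn-in, three chains independently seeded
from one `SeedSequence`; runs are bit-reproducible given the seed.
A split-chain R̂ is reported per parameter (advisory; the conjugate
structure mixes essentially instantly, and ψ's chain is i.i.d. because *z*
is fully observed).

Joint estimation of *q* with everything else is the default. A sequential
mode (`q_mode="plugin"`) first estimates *q* from the first-survey
double-observer data alone via a short (q, x₀) Gibbs run and then holds the
posterior mean fixed, mirroring a two-stage analysis in which the
first-survey estimate "is used for" the revisits; the joint default is
preferred because it propagates detection uncertainty into λ.

Degenerate inputs: a site with zero plots is an error; q = 0 alongside
positive counts is rejected as impossible data; a site with no used plot
keeps its λ at the prior and is flagged NA-eligible downstream.

## Derived quantities

Draw-wise, per site *M*: D = λψ (whole-site nest construction rate),
d = D/(p·r) with p = 0.85 (proportion of nest builders, from n = 92
followed individuals) and r = 1.00 nests builder⁻¹ day⁻¹ (602 dawn-to-dusk
follows), both treated as fixed constants; μ = d·A on the site's area.
Combination across sites is draw-wise assuming independence between sites
(they were surveyed and fitted independently): total μ sums the non-NA
sites, and the combined density is Σ d_M·A_M over non-NA sites divided by
the total area of **all** sites — the only convention that reproduces the
published combined density from the published per-site values. NA sites
still display their (prior-driven) density posterior but no population.

Two combined-HDI conventions exist and are both computed: the HDI of the
summed draws, and the sum (area-weighted mean, for density) of the per-site
HDI endpoints. The endpoint sum is the report default because it is the
arithmetic that reconciles the published per-site intervals with the
published combined interval; it is conservative (wider) relative to the
draw-sum HDI whenever site posteriors are not comonotone.

Display rounding follows the field's reporting style — densities to 4
decimals, populations and their HDI endpoints to whole individuals — and is
applied only at report time; draws are never rounded.

## Summaries and identifiability

**HDI.** The 95% highest density interval is computed by the sorted-window
scan: sort the draws, slide a window of ⌈0.95·n⌉ consecutive order
statistics, return the narrowest (ties to the smallest lower bound). This
is the standard shortest-interval estimator for unimodal posteriors; it is
cross-checked against `arviz.hdi` in the test suite.

**Overlap.** Identifiability is scored by τ = ∫ min(prior, posterior) dθ.
Densities are estimated by histograms on a fixed 512-cell grid spanning the
prior support union the data range; histograms rather than kernels because
kernels leak mass past bounded supports (ψ, q ∈ [0,1], λ ∈ [0,4]) and
inflate overlap there. The min-integral is the exact cell-sum of the
piecewise-constant densities. τ ≥ 0.35 flags the parameter weakly
identified. When both densities come from draws, the grid resolution scales
like √n (capped at 512) because the min of two noisy histograms is biased
low at low counts per cell.

**Induced reference for μ.** The population is a derived quantity, so its
"prior" for the overlap test has to be constructed. Pushing prior draws of
both (ψ, λ) through the derived chain cannot reproduce the behavior this
diagnostic is meant to capture: for a site whose three plots all lacked
nest sign, that construction yields τ ≈ 0.67 — mechanically, because the
fully observed *z* updates ψ to Beta(1,4) even though the counts carry no
abundance information at all, and an overlap of 0.67 would suggest partial
learning where there is none. `mncount` instead pairs the site's ψ
**posterior** (exact conjugacy on observed data, not an estimate at risk)
with **prior** λ draws and pushes both through the same code path as the
posterior. The μ overlap then isolates exactly what the nest counts taught
about abundance: a site with no count information scores τ ≈ 1 (its λ chain
is its prior), and well-counted sites fall below the 0.35 line. The
posterior mode reported alongside comes from the densest histogram cell
(meaningful for right-skewed posteriors whose "most probable value" is
zero).

## Synthetic data

The generator produces plot tables with precisely the structure the sampler
assumes, plus one nuisance component the model deliberately ignores: the
first-survey fresh-nest pool is Poisson(λ·a·`fresh_window_days`), with a
10-day default window during which a nest still classifies as "new". The
window only scales x₀ and the (team-1/team-2/both) split; it never enters
the fitted likelihood.

Defaults mirror the field design: 0.1471 km² plots (four 1-km × 36-m
strips), 42.7 days first-to-last survey, Bernoulli site use, Binomial
two-team first-survey detection. `paper_like_study()` builds seven sites
with the published areas (total 680.21 km²), three plots each for the first
five sites and six for the last two (27 designed plots; the original survey
visited 29 because reserve plots substituted for sign-free ones — the
substitution affects which plots exist, not the likelihood, and is not
simulated), per-team detection 0.8133, and per-site (ψ, λ) chosen so λ·ψ
matches the magnitude of each site's published nest construction rate; one
site is generated with ψ = 0 to reproduce the observed all-zero,
never-revisited pattern and exercise the NA path.

What the generator does **not** emulate — so what passing tests do not
certify about field data: spatial autocorrelation between plots, nest decay
classes and misclassification of "new", observer heterogeneity beyond the
single shared q, temporary emigration (false zeros from ranging behavior),
and any covariate structure on ψ or λ. Parameter recovery on these
synthetic studies demonstrates the estimator is correct under its own
assumptions, not that the assumptions hold in any forest.

## Numerical and scale choices

* Truncated-gamma inverse CDF uses `gammaincinv` on the renormalized mass;
  the empty-data case degenerates cleanly to the uniform prior.
* The λ prior upper bound (4 nests km⁻² day⁻¹) is far above any plausible
  orang-utan nest construction rate, and the truncation is inert in
  practice (posterior mass near the bound only for data-free sites).
* Recovery experiments in the test suite run 50 replicates of a 20-plot
  site at (ψ, λ, q) = (0.8, 1.0, 0.8) with 8,000 iterations — enough for
  an effectively exact posterior from a conjugate Gibbs sampler — and check
  95%-HDI coverage ≥ 90% plus centering of posterior means; at 20 plots the
  uniform priors visibly shrink means (the exact sampling expectation of
  the ψ posterior mean is (1+Nψ)/(N+2) = 0.773, not 0.80), so centering is
  asserted against finite-sample expectations, not raw truths.
* Identifiability experiments compare 3-, 6- and 12-plot designs at the
  same truth: mean μ-overlap declines monotonically, every 3-plot replicate
  is weakly identified, and a substantial share of 12-plot designs come out
  strong — the quantitative form of the design recommendation to survey six
  or more plots per site.

## Known limitations

* Uncertainty in the nest-to-individual conversion constants p and r is not
  propagated (they are treated as known, as in the analysis this package
  reimplements); density HDIs are therefore conditional on p·r.
* The pooled q assumes exchangeable detection across sites and teams.
* Estimates are a snapshot of plot use over the ~43-day survey window, not
  a steady-state density; extrapolation from plots to the full site area
  assumes plots are representative (they were placed at random in the
  design emulated here).
* The sampler is written for the scale this design implies (tens of plots,
  pooled q); it is a per-site loop in Python and is not tuned for
  thousands of sites.
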