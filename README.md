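# mncount — Bayesian marked nest count analysis

`mncount` estimates orang-utan density and population size from **marked
nest count (MNC)** plot surveys using a zero-inflated *N*-mixture model
fitted by an exact Gibbs sampler. It is written for wildlife biologists and
quantitative ecologists who survey great-ape nests in fixed plots, mark new
nests on a first visit, and count the nests built between revisits — and who
need defensible interval estimates even when new-nest counts are low.

## The model

For plot *i* of a site, with plot area *a&#8342;* (km²) and *t&#8342;* days
between the first and last survey:

```
z_i ~ Bernoulli(psi)                      suitability: any nest sign on first survey
n_i ~ Poisson(lambda * z_i * a_i * t_i)   new nests built between surveys (latent)
y_i ~ Binomial(n_i, q)                    new nests recorded on revisits
```

Plots without nest sign on the first survey (z = 0) are structural zeros and
are not revisited. The first survey is a double-observer pass: two teams
independently detect each of the `x0` fresh nests present with per-team
probability `q`, so the split of found nests into (team-1-only, team-2-only,
both) identifies `q`, and `x0` itself is latent. `psi` and `lambda` are
site-specific; `q` and `x0` are pooled across sites.

Posterior draws are converted draw-wise into the reported quantities:

```
D  = lambda * psi          whole-site nest construction rate (nests km^-2 day^-1)
d  = D / (p * r)           orang-utan density (individuals km^-2)
mu = d * A                 site population, A = site area (km^2)
```

with `p = 0.85` (proportion of nest builders) and `r = 1.00` (nests per
builder per day). Sites are combined by area-weighting densities and summing
populations; a site with no sign of use contributes its area to the
denominator but nothing to the numerators and reports `NA`. Each posterior
is summarized by its mean and 95% highest density interval (HDI), and the
reliability of every estimate is scored by the prior–posterior overlap
`tau = integral min(p(theta), pi(theta | Y)) dtheta`; `tau >= 35%` flags a
weakly identified parameter.

Under the uniform priors (`psi, q ~ U(0,1)`, `lambda ~ U(0,4)`, flat `x0`)
every full conditional is conjugate or closed-form — Beta for `psi` and `q`,
truncated Gamma for `lambda`, shifted Poisson for the latent counts, and a
truncated negative binomial for `x0` — so the Gibbs sampler is exact, with
no tuning and no rejection-based kernels.

## Worked example

Simulate a seven-site study with the survey geometry of the greater Batang
Ai–Lanjak-Entimau landscape (areas totalling 680.21 km², three plots per
site for five sites and six for two, one site with no nest sign anywhere),
fit it, and report:

```sh
mncount report --paper-like --seed 1 --iters 8000 --burnin 1000 --outdir out
```

The summary table (`out/report.csv`) looks like:

```
    site  area_km2  q_mean  ...  d_mean  d_hdi_lower  d_hdi_upper  mu_mean  mu_hdi_lower  mu_hdi_upper    na
      BA     58.28  0.9056  ...  0.7452       0.1427       1.4190     43.0           8.0          83.0 False
      UE     22.48  0.9056  ...  1.0508       0.4156       1.7143     24.0           9.0          39.0 False
      UN     69.40  0.9056  ...  0.4709       0.0000       1.5731      NaN           NaN           NaN  True
      UK     96.41  0.9056  ...  0.1242       0.0009       0.3257     12.0           0.0          31.0 False
      UP     45.84  0.9056  ...  0.9400       0.3715       1.5514     43.0          17.0          71.0 False
     USM    140.00  0.9056  ...  0.6540       0.2802       1.0361     92.0          39.0         145.0 False
      ET    247.80  0.9056  ...  0.1389       0.0113       0.3094     34.0           3.0          77.0 False
combined    680.21  0.9056  ...  0.3647       0.1129       0.6549    248.0          77.0         445.0 False
```

Reading it: each row gives a site's posterior-mean orang-utan density
(`d_mean`, individuals km⁻²) with its 95% HDI, and the implied population
(`mu_mean`) on its area. The all-zero site `UN` reports `NA` — there was no
evidence of use, so its population is not estimable from these data — yet
its 69.40 km² still dilutes the combined density. The combined row says this
synthetic landscape holds about 248 animals (95% HDI 77–445) at 0.36 km⁻².
The pooled detection probability `q_mean` shows nest detection is imperfect,
and `out/overlap.csv` scores each estimate: in this run the population
overlap for `UN` is 0.97 (hopelessly prior-driven), the three-plot sites sit
above the 0.35 weak-identifiability line, and the better-sampled `UK` and
`USM` fall below it (0.19 and 0.27) — the survey-design lesson being that
three plots per site are rarely enough.

The same pipeline runs on real data: `mncount fit --input plots.csv ...`
with a CSV of columns `site_id, plot_id, area_km2, elapsed_days, z,
x_t1_only, x_t2_only, x_both, y, revisited`, then `mncount summarize --areas
areas.json` and `mncount check-id`. Everything is also available as library
functions (`mncount.simulate_site`, `mncount.run_mcmc`,
`mncount.site_estimates`, `mncount.hdi`, ...).

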