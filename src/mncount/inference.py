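"""Gibbs sampler for the zero-inflated N-mixture nest-count model.

The hierarchy, per site M with plots i:

* suitability:  z_i ~ Bernoulli(psi_M)               (z observed)
* abundance:    n_i ~ Poisson(lambda_M * a_i * t_i)  for z_i = 1 (n latent)
* detection:    y_i ~ Binomial(n_i, q)               (y observed on revisits)

plus a double-observer first survey: each of the x0 fresh nests present is
detected independently by each of two teams with probability q, yielding the
observed (team-1-only, team-2-only, both) split of the x distinct nests
found; x0 itself is latent.

Under uniform priors — psi ~ U(0,1), lambda ~ U(0, lambda_max), q ~ U(0,1),
x0 flat on {m, ..., x0_max} — every full conditional is conjugate or
closed-form, so the sampler is a systematic-scan Gibbs with exact updates:

* psi_M    | z            ~ Beta(1 + sum z, 1 + N - sum z)
* lambda_M | n            ~ Gamma(1 + sum n, sum a*t) truncated to [0, lambda_max]
* n_i      | y_i, lam, q  =  y_i + Poisson(lam * a_i * t_i * (1 - q))
* q        | n, x0        ~ Beta(1 + S, 1 + F) with per-team success/failure
                            tallies from revisits and the first survey
* x0 - m   | q            ~ NegBinomial(m + 1, 1 - (1-q)^2) truncated at x0_max

psi and lambda are site-specific; q and x0 are pooled across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .synthetic import Study

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "TruncatedGamma",
    "ShiftedPoisson",
    "psi_full_conditional",
    "lambda_full_conditional",
    "n_full_conditional",
    "q_full_conditional",
    "x0_conditional_pmf",
    "x0_update",
    "run_mcmc",
]


@dataclass(frozen=True)
class PriorSpec:
    """Uninformative priors of the published analysis.

    psi ~ Uniform(0, 1); lambda ~ Uniform(0, lambda_max) in nests km^-2
    day^-1; q ~ Uniform(0, 1); x0 flat on the non-negative integers up to
    ``x0_max`` (default 10x the distinct nests found, floored at 20).
    """

    lambda_max: float = 4.0
    x0_max: int | None = None

    def validate(self) -> None:
        if not self.lambda_max > 0:
            raise ValueError(f"lambda_max must be > 0, got {self.lambda_max}")
        if self.x0_max is not None and self.x0_max < 0:
            raise ValueError(f"x0_max must be >= 0, got {self.x0_max}")

    def resolve_x0_max(self, distinct_found: int) -> int:
        if self.x0_max is not None:
            if self.x0_max < distinct_found:
                raise ValueError(
                    f"x0_max={self.x0_max} is below the {distinct_found} "
                    "distinct nests found"
                )
            return self.x0_max
        return max(10 * distinct_found, 20)


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 40_000
    burn_in: int = 5_000
    n_chains: int = 3
    thin: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError(
                f"burn_in ({self.burn_in}) must be < n_iter ({self.n_iter})"
            )
        if self.n_chains < 1:
            raise ValueError(f"n_chains must be >= 1, got {self.n_chains}")
        if self.thin < 1:
            raise ValueError(f"thin must be >= 1, got {self.thin}")

    @property
    def n_draws(self) -> int:
        """Retained draws per chain."""
        return (self.n_iter - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# Full conditionals
# ---------------------------------------------------------------------------


def psi_full_conditional(n_plots: int, n_used: int) -> tuple[float, float]:
    """Beta(1 + sum z, 1 + N - sum z): exact conjugate update of psi.

    With a uniform prior the all-used six-plot site gives Beta(7, 1),
    posterior mean 7/8 = 0.875.
    """
    if n_plots < 0 or n_used < 0 or n_used > n_plots:
        raise ValueError(
            f"need 0 <= n_used <= n_plots, got n_used={n_used}, n_plots={n_plots}"
        )
    return (1.0 + n_used, 1.0 + n_plots - n_used)


@dataclass(frozen=True)
class TruncatedGamma:
    """Gamma(shape, rate) truncated to [0, upper].

    ``rate == 0`` with ``shape == 1`` degenerates to Uniform(0, upper), the
    prior fallback when no revisited used plot contributes exposure.
    """

    shape: float
    rate: float
    upper: float

    @property
    def _mass(self) -> float:
        # P(Gamma(shape, rate) <= upper)
        return float(special.gammainc(self.shape, self.rate * self.upper))

    def mean(self) -> float:
        if self.rate == 0.0:
            return self.upper * self.shape / (self.shape + 1.0)
        num = special.gammainc(self.shape + 1.0, self.rate * self.upper)
        return float(self.shape / self.rate * num / self._mass)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.rate == 0.0:
            # flat on [0, upper] when shape == 1
            out = np.where(
                (x >= 0) & (x <= self.upper),
                x ** (self.shape - 1.0) * self.shape / self.upper**self.shape,
                0.0,
            )
            return out
        base = stats.gamma.pdf(x, self.shape, scale=1.0 / self.rate) / self._mass
        return np.where((x >= 0) & (x <= self.upper), base, 0.0)

    def cdf(self, x):
        x = np.clip(np.asarray(x, dtype=float), 0.0, self.upper)
        if self.rate == 0.0:
            return (x / self.upper) ** self.shape
        return special.gammainc(self.shape, self.rate * x) / self._mass

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        if self.rate == 0.0:
            return self.upper * u ** (1.0 / self.shape)
        return special.gammaincinv(self.shape, u * self._mass) / self.rate

    def rvs(self, rng: np.random.Generator, size=None):
        """Exact draw: rejection from the untruncated gamma, inverse-CDF
        fallback when the acceptance region holds little mass."""
        if self.rate == 0.0:
            return self.ppf(rng.random(size))
        if size is None:
            for _ in range(64):
                x = rng.gamma(self.shape, 1.0 / self.rate)
                if x <= self.upper:
                    return float(x)
            return float(self.ppf(rng.random()))
        return self.ppf(rng.random(size))


def lambda_full_conditional(
    n, exposure, lambda_max: float = 4.0
) -> TruncatedGamma:
    """Truncated-Gamma full conditional of the nest construction rate.

    ``n`` are the current latent nest counts and ``exposure`` the matching
    a_i * t_i products over revisited used plots. An empty exposure set
    returns the Uniform(0, lambda_max) prior.
    """
    n = np.asarray(n, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if n.shape != exposure.shape:
        raise ValueError("n and exposure must have matching lengths")
    if n.size == 0:
        return TruncatedGamma(1.0, 0.0, lambda_max)
    if np.any(exposure <= 0):
        raise ValueError("exposures must be strictly positive")
    if np.any(n < 0):
        raise ValueError("latent counts must be non-negative")
    return TruncatedGamma(1.0 + float(n.sum()), float(exposure.sum()), lambda_max)


@dataclass(frozen=True)
class ShiftedPoisson:
    """Distribution of n given y: n = y + Poisson(rate).

    The exact conditional of a Poisson total given its binomially thinned
    observation; rate = lambda * a * t * (1 - q).
    """

    y: int
    rate: float

    def pmf(self, n):
        n = np.asarray(n)
        return np.where(n >= self.y, stats.poisson.pmf(n - self.y, self.rate), 0.0)

    def rvs(self, rng: np.random.Generator, size=None):
        return self.y + rng.poisson(self.rate, size)


def n_full_conditional(
    y: int, lam: float, q: float, a: float, t: float
) -> ShiftedPoisson:
    """Exact conditional of the latent nest count at one revisited plot."""
    if y < 0:
        raise ValueError(f"y must be non-negative, got {y}")
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if q == 0.0 and y > 0:
        raise ValueError("impossible data: y > 0 observed with detection q = 0")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    return ShiftedPoisson(int(y), lam * a * t * (1.0 - q))


def q_full_conditional(
    sum_y: int,
    sum_n_minus_y: int,
    x_both: int = 0,
    x_t1_only: int = 0,
    x_t2_only: int = 0,
    x0: int | None = None,
) -> tuple[float, float]:
    """Beta parameters of the pooled detection probability.

    Successes: every nest recorded on revisits plus per-team first-survey
    detections (a both-teams nest counts twice). Failures: latent revisit
    misses (n - y) plus per-team first-survey misses — one per single-team
    nest, two per nest missed outright (x0 - distinct found).
    """
    for name, v in (
        ("sum_y", sum_y),
        ("sum_n_minus_y", sum_n_minus_y),
        ("x_both", x_both),
        ("x_t1_only", x_t1_only),
        ("x_t2_only", x_t2_only),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    successes = sum_y + 2 * x_both + x_t1_only + x_t2_only
    failures = sum_n_minus_y + x_t1_only + x_t2_only
    if x0 is not None:
        m = x_both + x_t1_only + x_t2_only
        if x0 < m:
            raise ValueError(f"x0 ({x0}) below the {m} distinct nests found")
        failures += 2 * (x0 - m)
    return (1.0 + successes, 1.0 + failures)


def x0_conditional_pmf(
    distinct_found: int, q: float, x0_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of x0 | q: m + NegBinomial(m + 1, s) truncated at
    x0_max, where s = 1 - (1-q)^2 is the chance at least one team finds a
    nest."""
    m = distinct_found
    if m < 0:
        raise ValueError(f"distinct_found must be non-negative, got {m}")
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    if x0_max < m:
        raise ValueError(f"x0_max ({x0_max}) below distinct_found ({m})")
    s = 1.0 - (1.0 - q) ** 2
    support = np.arange(m, x0_max + 1)
    if s == 1.0:
        pmf = np.zeros(support.size)
        pmf[0] = 1.0
        return support, pmf
    pmf = stats.nbinom.pmf(support - m, m + 1, s)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("x0 conditional has no mass on the truncated support")
    return support, pmf / total


def x0_update(
    distinct_found: int, q: float, x0_max: int, rng: np.random.Generator
) -> int:
    """Exact draw of the latent first-survey nest total."""
    m = distinct_found
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    s = 1.0 - (1.0 - q) ** 2
    if s == 1.0:
        return m
    cap = x0_max - m
    for _ in range(64):  # rejection from the untruncated negative binomial
        k = int(rng.negative_binomial(m + 1, s))
        if k <= cap:
            return m + k
    support, pmf = x0_conditional_pmf(m, q, x0_max)
    return int(rng.choice(support, p=pmf))


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


@dataclass
class _SiteData:
    site_id: str
    n_plots: int
    n_used: int
    y: np.ndarray         # revisit counts at used, revisited plots
    exposure: np.ndarray  # a_i * t_i for the same plots

    @property
    def has_exposure(self) -> bool:
        return self.y.size > 0


def _prepare_sites(study: Study) -> list[_SiteData]:
    study.validate()
    sites = []
    for site_id, plots in study.by_site().items():
        used = [p for p in plots if p.z == 1]
        revisited = [p for p in used if p.revisited and p.elapsed_days > 0]
        sites.append(
            _SiteData(
                site_id=site_id,
                n_plots=len(plots),
                n_used=len(used),
                y=np.array([p.y for p in revisited], dtype=np.int64),
                exposure=np.array(
                    [p.area * p.elapsed_days for p in revisited], dtype=float
                ),
            )
        )
    return sites


def _first_survey_tallies(study: Study) -> tuple[int, int, int]:
    xb = sum(p.x_both for p in study.plots)
    x1 = sum(p.x_t1_only for p in study.plots)
    x2 = sum(p.x_t2_only for p in study.plots)
    return xb, x1, x2


@dataclass
class PosteriorSamples:
    """Post-burn-in draws, shaped (n_chains, n_draws) per parameter.

    ``psi`` and ``lam`` are per-site; ``q`` and ``x0`` are pooled across
    sites. ``n_used``/``n_plots`` record the observed suitability data so
    downstream reporting can flag sites with no evidence of use (NA).
    """

    site_ids: list[str]
    psi: dict[str, np.ndarray]
    lam: dict[str, np.ndarray]
    q: np.ndarray
    x0: np.ndarray
    config: MCMCConfig
    priors: PriorSpec
    n_used: dict[str, int]
    n_plots: dict[str, int]

    @property
    def n_draws_total(self) -> int:
        return int(self.q.size)

    def flat(self, name: str, site: str | None = None) -> np.ndarray:
        """Draws pooled across chains, chain-major order."""
        if name == "q":
            return self.q.reshape(-1)
        if name == "x0":
            return self.x0.reshape(-1)
        if site is None:
            raise ValueError(f"parameter {name!r} is site-specific; pass site=")
        return {"psi": self.psi, "lam": self.lam}[name][site].reshape(-1)

    def na_eligible(self, site: str) -> bool:
        """True when the site had no plot with nest sign, so abundance is
        prior-driven and the population estimate should be reported NA."""
        return self.n_used[site] == 0

    # -- persistence ------------------------------------------------------

    def to_frame(self):
        import pandas as pd

        n_chains, n_draws = self.q.shape
        data = {
            "chain": np.repeat(np.arange(n_chains), n_draws),
            "draw": np.tile(np.arange(n_draws), n_chains),
        }
        for s in self.site_ids:
            data[f"psi_{s}"] = self.psi[s].reshape(-1)
            data[f"lam_{s}"] = self.lam[s].reshape(-1)
        data["q"] = self.q.reshape(-1)
        data["x0"] = self.x0.reshape(-1)
        return pd.DataFrame(data)

    def save(self, prefix) -> None:
        """Write ``<prefix>.draws.csv`` and ``<prefix>.meta.json``."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(f"{prefix}.draws.csv", index=False)
        meta = {
            "site_ids": self.site_ids,
            "n_used": self.n_used,
            "n_plots": self.n_plots,
            "config": {
                "n_iter": self.config.n_iter,
                "burn_in": self.config.burn_in,
                "n_chains": self.config.n_chains,
                "thin": self.config.thin,
                "seed": self.config.seed,
            },
            "priors": {"lambda_max": self.priors.lambda_max,
                       "x0_max": self.priors.x0_max},
        }
        Path(f"{prefix}.meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "PosteriorSamples":
        import json
        from pathlib import Path

        import pandas as pd

        meta = json.loads(Path(f"{prefix}.meta.json").read_text())
        df = pd.read_csv(f"{prefix}.draws.csv")
        cfg = MCMCConfig(**meta["config"])
        n_chains = int(df["chain"].max()) + 1
        shape = (n_chains, len(df) // n_chains)

        def grab(col):
            return df[col].to_numpy().reshape(shape)

        return cls(
            site_ids=list(meta["site_ids"]),
            psi={s: grab(f"psi_{s}") for s in meta["site_ids"]},
            lam={s: grab(f"lam_{s}") for s in meta["site_ids"]},
            q=grab("q"),
            x0=grab("x0").astype(np.int64),
            config=cfg,
            priors=PriorSpec(**meta["priors"]),
            n_used={k: int(v) for k, v in meta["n_used"].items()},
            n_plots={k: int(v) for k, v in meta["n_plots"].items()},
        )


def _fit_q_first_survey(
    xb: int, x1: int, x2: int, x0_max: int, rng: np.random.Generator,
    n_iter: int = 4000, burn_in: int = 500,
) -> float:
    """Posterior-mean q from the first-survey double-observer data alone,
    via a short (q, x0) Gibbs run. Used by the sequential ('plugin') mode."""
    m = xb + x1 + x2
    q = 0.5
    total = 0.0
    kept = 0
    for it in range(n_iter):
        x0 = x0_update(m, q, x0_max, rng)
        alpha, beta = q_full_conditional(0, 0, xb, x1, x2, x0=x0)
        q = rng.beta(alpha, beta)
        if it >= burn_in:
            total += q
            kept += 1
    return total / kept


def run_mcmc(
    study: Study,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    q_mode: str = "joint",
) -> PosteriorSamples:
    """Fit the N-mixture model by systematic-scan Gibbs.

    psi and lambda are sampled per site; q and x0 are pooled across sites.
    ``q_mode='joint'`` (default) samples q from the revisit and first-survey
    likelihoods jointly; ``q_mode='plugin'`` first estimates q from the
    first-survey double-observer data alone and holds it fixed, mirroring a
    two-stage analysis. Chains are independently seeded from ``config.seed``
    and runs are exactly reproducible.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    priors.validate()
    config.validate()
    if q_mode not in ("joint", "plugin"):
        raise ValueError(f"q_mode must be 'joint' or 'plugin', got {q_mode!r}")

    sites = _prepare_sites(study)
    xb, x1, x2 = _first_survey_tallies(study)
    m = xb + x1 + x2
    x0_max = priors.resolve_x0_max(m)
    sum_y = int(sum(s.y.sum() for s in sites))

    n_draws = config.n_draws
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains + 1)

    q_fixed = None
    if q_mode == "plugin":
        q_fixed = _fit_q_first_survey(
            xb, x1, x2, x0_max, np.random.default_rng(seeds[-1])
        )

    psi_out = {s.site_id: np.empty((config.n_chains, n_draws)) for s in sites}
    lam_out = {s.site_id: np.empty((config.n_chains, n_draws)) for s in sites}
    q_out = np.empty((config.n_chains, n_draws))
    x0_out = np.empty((config.n_chains, n_draws), dtype=np.int64)

    for chain in range(config.n_chains):
        rng = np.random.default_rng(seeds[chain])
        # initial state: prior means / observed minima
        q = q_fixed if q_fixed is not None else 0.5
        lam = {s.site_id: priors.lambda_max / 2.0 for s in sites}
        n_latent = {s.site_id: s.y.copy() for s in sites}
        x0 = m
        kept = 0
        for it in range(config.n_iter):
            for s in sites:
                a, b = psi_full_conditional(s.n_plots, s.n_used)
                psi_draw = rng.beta(a, b)
                if s.has_exposure:
                    # latent counts, then the rate they imply
                    extra = rng.poisson(lam[s.site_id] * s.exposure * (1.0 - q))
                    n_latent[s.site_id] = s.y + extra
                dist = lambda_full_conditional(
                    n_latent[s.site_id] if s.has_exposure else [],
                    s.exposure if s.has_exposure else [],
                    priors.lambda_max,
                )
                lam[s.site_id] = dist.rvs(rng)
                if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                    psi_out[s.site_id][chain, kept] = psi_draw
                    lam_out[s.site_id][chain, kept] = lam[s.site_id]
            x0 = x0_update(m, q, x0_max, rng) if q > 0 else x0
            if q_fixed is None:
                sum_n_minus_y = int(
                    sum(n_latent[s.site_id].sum() - s.y.sum() for s in sites)
                )
                alpha, beta = q_full_conditional(
                    sum_y, sum_n_minus_y, xb, x1, x2, x0=x0
                )
                q = rng.beta(alpha, beta)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                q_out[chain, kept] = q
                x0_out[chain, kept] = x0
                kept += 1

    return PosteriorSamples(
        site_ids=[s.site_id for s in sites],
        psi=psi_out,
        lam=lam_out,
        q=q_out,
        x0=x0_out,
        config=config,
        priors=priors,
        n_used={s.site_id: s.n_used for s in sites},
        n_plots={s.site_id: s.n_plots for s in sites},
    )
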