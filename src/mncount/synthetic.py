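"""Forward simulation of marked nest count (MNC) plot surveys.

The generator reproduces the statistical structure the inference module
assumes: Bernoulli plot use (suitability), Poisson nest construction with an
area x time offset at used plots, Binomial revisit detection, and a
double-observer first survey in which each of two teams independently detects
each fresh nest with per-team probability ``q``.

A simulated study mirrors the field design: plots of four 1-km strips 36 m
wide (0.1471 km^2), roughly 42.7 days between the first and last survey, and
plots with no nest sign on the first survey treated as unused and never
revisited (a structural zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference

__all__ = [
    "SiteParams",
    "PlotObservation",
    "Study",
    "simulate_site",
    "paper_like_study",
    "PLOT_AREA_KM2",
    "INTERSURVEY_DAYS",
]

#: Mean surveyed plot area: four 1 km x 36 m strips.
PLOT_AREA_KM2 = 0.1471
#: Mean days between the first and the last (third) survey.
INTERSURVEY_DAYS = 42.7


@dataclass(frozen=True)
class SiteParams:
    """True generating parameters for one study site.

    ``psi_true`` is the probability a plot shows sign of orang-utan use
    (old or new nest), ``lambda_true`` the nest construction rate at used
    plots in nests km^-2 day^-1, and ``q_true`` the per-team, per-nest
    detection probability. ``fresh_window_days`` is how long a nest remains
    classifiable as "new" on the first survey; it scales the first-survey
    nest pool but never enters the fitted model.
    """

    site_id: str
    site_area: float
    n_plots: int
    psi_true: float
    lambda_true: float
    q_true: float
    plot_area: float = PLOT_AREA_KM2
    intersurvey_days: float = INTERSURVEY_DAYS
    fresh_window_days: float = 10.0

    def validate(self) -> None:
        if not 0.0 <= self.psi_true <= 1.0:
            raise ValueError(f"psi_true must be in [0, 1], got {self.psi_true}")
        if self.lambda_true < 0.0:
            raise ValueError(f"lambda_true must be >= 0, got {self.lambda_true}")
        if not 0.0 < self.q_true <= 1.0:
            raise ValueError(f"q_true must be in (0, 1], got {self.q_true}")
        for name in ("site_area", "plot_area", "intersurvey_days", "fresh_window_days"):
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.n_plots < 1:
            raise ValueError(f"n_plots must be a positive integer, got {self.n_plots}")


@dataclass(frozen=True)
class PlotObservation:
    """One surveyed plot's design values and counts.

    ``z`` is the old-or-new nest sign on the first survey; the first-survey
    new-nest count is split by detection pattern into team-1-only,
    team-2-only, and both-teams; ``y`` is the total of new nests recorded on
    the revisits. Unused plots (z = 0) carry all-zero counts and are not
    revisited.
    """

    site_id: str
    plot_id: str
    area: float
    elapsed_days: float
    z: int
    x_t1_only: int
    x_t2_only: int
    x_both: int
    y: int
    revisited: bool

    @property
    def x(self) -> int:
        """Distinct new nests found on the first survey (x)."""
        return self.x_t1_only + self.x_t2_only + self.x_both

    def validate(self) -> None:
        if self.z not in (0, 1):
            raise ValueError(f"plot {self.plot_id}: z must be 0 or 1, got {self.z}")
        for name in ("x_t1_only", "x_t2_only", "x_both", "y"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"plot {self.plot_id}: {name} must be non-negative, "
                    f"got {getattr(self, name)}"
                )
        if not self.area > 0.0:
            raise ValueError(f"plot {self.plot_id}: area must be > 0, got {self.area}")
        if self.z == 0 and (self.y > 0 or self.revisited or self.x > 0):
            raise ValueError(
                f"plot {self.plot_id}: unused plots (z=0) must have zero counts "
                "and no revisit (plots without nest sign are not revisited)"
            )
        if self.revisited and not self.elapsed_days > 0.0:
            raise ValueError(
                f"plot {self.plot_id}: revisited plots need elapsed_days > 0, "
                f"got {self.elapsed_days}"
            )


@dataclass
class Study:
    """A multi-site plot-survey dataset."""

    plots: list[PlotObservation]
    site_areas: dict[str, float] | None = None
    true_params: dict[str, SiteParams] = field(default_factory=dict)

    @property
    def site_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.plots:
            seen.setdefault(p.site_id, None)
        return list(seen)

    def by_site(self) -> dict[str, list[PlotObservation]]:
        grouped: dict[str, list[PlotObservation]] = {}
        for p in self.plots:
            grouped.setdefault(p.site_id, []).append(p)
        return grouped

    def validate(self) -> None:
        if not self.plots:
            raise ValueError("study contains no plots")
        for p in self.plots:
            p.validate()


def _detection_pattern_probs(q: float) -> np.ndarray:
    # (both, team-1 only, team-2 only, missed) under independent per-team
    # Bernoulli(q) detection of every fresh nest.
    miss = 1.0 - q
    return np.array([q * q, q * miss, miss * q, miss * miss])


def simulate_site(params: SiteParams, seed: int) -> list[PlotObservation]:
    """Simulate every plot of one site forward through the hierarchy.

    For each plot: use indicator ``z ~ Bernoulli(psi)``; at used plots the
    nests built between surveys are ``n ~ Poisson(lambda * a * t)`` of which
    ``y ~ Binomial(n, q)`` are recorded on revisits, and the fresh first-survey
    pool ``n0 ~ Poisson(lambda * a * fresh_window)`` is split multinomially
    over the two-team detection patterns. Deterministic given ``seed``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    pattern = _detection_pattern_probs(params.q_true)
    a, t = params.plot_area, params.intersurvey_days

    plots: list[PlotObservation] = []
    for j in range(params.n_plots):
        plot_id = f"{params.site_id}-p{j + 1}"
        z = int(rng.random() < params.psi_true)
        if z == 0:
            plots.append(
                PlotObservation(params.site_id, plot_id, a, 0.0, 0, 0, 0, 0, 0, False)
            )
            continue
        n_new = int(rng.poisson(params.lambda_true * a * t))
        y = int(rng.binomial(n_new, params.q_true)) if n_new else 0
        n0 = int(rng.poisson(params.lambda_true * a * params.fresh_window_days))
        both, t1_only, t2_only, _missed = (
            rng.multinomial(n0, pattern) if n0 else (0, 0, 0, 0)
        )
        plots.append(
            PlotObservation(
                params.site_id,
                plot_id,
                a,
                t,
                1,
                int(t1_only),
                int(t2_only),
                int(both),
                y,
                True,
            )
        )
    return plots


def _paper_like_params() -> list[SiteParams]:
    """Site configurations emulating the Batang Ai-Lanjak-Entimau survey.

    Areas and plot counts follow the published design (three plots per site
    for the first five sites, six for the last two). True (psi, lambda) pairs
    are fixed so that lambda * psi matches the magnitude of each site's
    published nest construction rate; Ulu Ngemah is generated with psi = 0 to
    reproduce its observed all-zero, never-revisited pattern.
    """
    q = reference.Q_HAT
    # (acronym, psi, lambda): lambda * psi ~= published d_hat * p * r.
    shapes = {
        "BA": (0.90, 1.33),
        "UE": (0.90, 1.69),
        "UN": (0.00, 0.40),
        "UK": (0.60, 0.24),
        "UP": (0.90, 0.96),
        "USM": (0.90, 0.78),
        "ET": (0.60, 0.32),
    }
    out = []
    for acronym, area in reference.SITE_AREAS_KM2.items():
        psi, lam = shapes[acronym]
        out.append(
            SiteParams(
                site_id=acronym,
                site_area=area,
                n_plots=reference.PLOTS_PER_SITE[acronym],
                psi_true=psi,
                lambda_true=lam,
                q_true=q,
            )
        )
    return out


def paper_like_study(seed: int) -> Study:
    """Generate a seven-site study with the published survey geometry.

    Site areas sum to 680.21 km^2; the designed plot count is 27
    (3 x 5 + 6 x 2). One site (Ulu Ngemah) is simulated with psi = 0 so that
    all its plots are structural zeros, exercising the NA reporting path.
    """
    site_params = _paper_like_params()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(site_params))
    plots: list[PlotObservation] = []
    for params, child in zip(site_params, child_seeds):
        site_plots = simulate_site(params, int(child))
        if params.psi_true == 0.0:
            # Bernoulli(0) is degenerate; keep the draw stream aligned anyway.
            assert all(p.z == 0 for p in site_plots)
        plots.extend(site_plots)
    return Study(
        plots=plots,
        site_areas=dict(reference.SITE_AREAS_KM2),
        true_params={p.site_id: p for p in site_params},
    )
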