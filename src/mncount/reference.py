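"""Published reference values from the greater Batang Ai-Lanjak-Entimau
(BALE) orang-utan survey, Sarawak.

These are the printed study-design constants and posterior summaries of the
original seven-site marked nest count analysis. They serve two purposes:
as the design template for :func:`mncount.synthetic.paper_like_study`, and as
inputs to desk cross-checks of the derived-estimate arithmetic (area-weighted
density, summed population).

Sites are keyed by acronym in chronological survey order: Batang Ai (BA),
Ulu Engkari (UE), Ulu Ngemah (UN), Ulu Katibas (UK), Ulu Pasin (UP),
Ulu Sungai Menyang (USM), Engkari-Telaus (ET).
"""

from __future__ import annotations

import math

#: Study-site areas in km^2; they total 680.21 km^2.
SITE_AREAS_KM2: dict[str, float] = {
    "BA": 58.28,
    "UE": 22.48,
    "UN": 69.40,
    "UK": 96.41,
    "UP": 45.84,
    "USM": 140.00,
    "ET": 247.80,
}

#: Designed plots per site: three for the first five sites, six for the last
#: two (the survey itself visited 29 plots because reserve plots replaced
#: plots without nest sign; that substitution does not affect the likelihood).
PLOTS_PER_SITE: dict[str, int] = {
    "BA": 3,
    "UE": 3,
    "UN": 3,
    "UK": 3,
    "UP": 3,
    "USM": 6,
    "ET": 6,
}

#: Plots actually surveyed and their mean area (km^2).
N_PLOTS_SURVEYED = 29
MEAN_PLOT_AREA_KM2 = 0.1471

#: Posterior-mean orang-utan density (individuals km^-2) per site. Ulu Ngemah
#: showed no nest sign at any plot; its density posterior is prior-driven and
#: its population estimate was reported as NA.
DENSITY_PER_SITE: dict[str, float] = {
    "BA": 1.4050,
    "UE": 1.7890,
    "UN": 0.4681,
    "UK": 0.1719,
    "UP": 1.0174,
    "USM": 0.8245,
    "ET": 0.2273,
}

#: Posterior-mean population per site (individuals, rounded); None marks the
#: site without evidence of use.
POPULATION_PER_SITE: dict[str, int | None] = {
    "BA": 82,
    "UE": 40,
    "UN": None,
    "UK": 16,
    "UP": 46,
    "USM": 115,
    "ET": 56,
}

#: Sites excluded from combined numerators (no sign of use).
NA_SITES: tuple[str, ...] = ("UN",)

#: Pooled detection probability of a new nest per team on the first survey
#: (also used for revisit detection).
Q_HAT = 0.8133

#: Nest-to-individual conversion: proportion of nest builders and nests
#: built per builder per day (Kinabatangan follow data).
P_BUILDERS = 0.85
R_NESTS_PER_DAY = 1.00

#: Prior upper bound for the nest construction rate (nests km^-2 day^-1).
LAMBDA_MAX = 4.0


def total_area_km2() -> float:
    """Sum of the seven study-site areas."""
    return math.fsum(SITE_AREAS_KM2.values())


def plot_coverage_percent(
    n_plots: int = N_PLOTS_SURVEYED, plot_area: float = MEAN_PLOT_AREA_KM2
) -> float:
    """Surveyed plot area as a percentage of the combined study area."""
    return 100.0 * n_plots * plot_area / total_area_km2()
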