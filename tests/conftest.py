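import numpy as np
import pytest

from mncount.inference import MCMCConfig, run_mcmc
from mncount.synthetic import SiteParams, Study, paper_like_study, simulate_site


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def paper_study():
    return paper_like_study(seed=7)


@pytest.fixture(scope="session")
def six_plot_used_study():
    """A single site whose six plots all show nest sign (the Ulu Sungai
    Menyang design), built with perfect suitability so z = 1 is guaranteed."""
    params = SiteParams(
        site_id="USM",
        site_area=140.0,
        n_plots=6,
        psi_true=1.0,
        lambda_true=0.8,
        q_true=0.81,
    )
    return Study(plots=simulate_site(params, seed=11))


@pytest.fixture(scope="session")
def small_fit(paper_study):
    """A short but converged fit of the seven-site synthetic study, shared by
    the diagnostics and reporting tests."""
    return run_mcmc(
        paper_study,
        config=MCMCConfig(n_iter=2500, burn_in=500, n_chains=2, seed=5),
    )
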