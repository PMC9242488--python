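import numpy as np
import pytest
from hypothesis import settings

from lsirm import LSIRM, SimConfig, match_maps, simulate_paired
from lsirm.alignment import FittedModel, posterior_summary
from lsirm.sampler import Hyperparameters, PosteriorChain, SamplerConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_chain(
    rng: np.random.Generator,
    n_draws: int = 50,
    n_items: int = 6,
    n_respondents: int = 8,
    d: int = 2,
    spread: float = 0.1,
) -> PosteriorChain:
    """A synthetic posterior chain (draws jittered around one configuration)."""
    W0 = rng.standard_normal((n_items, d))
    Z0 = rng.standard_normal((n_respondents, d))
    return PosteriorChain(
        beta=rng.standard_normal(n_items)[None, :]
        + spread * rng.standard_normal((n_draws, n_items)),
        theta=rng.standard_normal(n_respondents)[None, :]
        + spread * rng.standard_normal((n_draws, n_respondents)),
        sigma_sq=1.0 + 0.1 * rng.random(n_draws),
        W=W0[None] + spread * rng.standard_normal((n_draws, n_items, d)),
        Z=Z0[None] + spread * rng.standard_normal((n_draws, n_respondents, d)),
        log_posterior=rng.standard_normal(n_draws),
        imputed=np.empty((n_draws, 0)),
        missing_indices=(np.array([], dtype=int), np.array([], dtype=int)),
        acceptance_rates={b: 0.3 for b in ("beta", "theta", "w", "z")},
        hyper=Hyperparameters(d=d),
        config=SamplerConfig(n_iterations=n_draws + 1, burn_in=1, thin=1, seed=0),
    )


def make_fitted_from_params(beta, theta, W, Z, informant="other") -> FittedModel:
    """A one-draw FittedModel with exactly the given parameters."""
    beta = np.asarray(beta, float)
    theta = np.asarray(theta, float)
    W = np.asarray(W, float)
    Z = np.asarray(Z, float)
    chain = PosteriorChain(
        beta=beta[None], theta=theta[None], sigma_sq=np.array([1.0]),
        W=W[None], Z=Z[None], log_posterior=np.array([0.0]),
        imputed=np.empty((1, 0)),
        missing_indices=(np.array([], dtype=int), np.array([], dtype=int)),
        acceptance_rates={b: 0.3 for b in ("beta", "theta", "w", "z")},
        hyper=Hyperparameters(d=W.shape[1]),
        config=SamplerConfig(n_iterations=2, burn_in=1, thin=1, seed=0),
        aligned=True,
    )
    return posterior_summary(chain, informant=informant, align=False)


@pytest.fixture(scope="session")
def small_sim():
    """A small paired simulation with known discrepancy structure."""
    cfg = SimConfig(
        n_respondents=150, n_items=32, items_per_syndrome=3,
        n_shifted_items=4, beta_shift=1.5,
        displaced_cluster_size=3, respondent_jitter=0.1,
        seed=7,
    )
    return simulate_paired(cfg)


@pytest.fixture(scope="session")
def small_fits(small_sim):
    """Both instruments of the small simulation fitted with short chains."""
    paired, truth = small_sim
    fit_a = (
        LSIRM(n_iterations=3000, burn_in=1000, thin=2, random_state=11)
        .fit(paired.a)
        .fitted_model_
    )
    fit_b = (
        LSIRM(n_iterations=3000, burn_in=1000, thin=2, random_state=12)
        .fit(paired.b)
        .fitted_model_
    )
    return fit_a, match_maps(fit_a, fit_b)
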