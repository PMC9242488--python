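"""LSIRM likelihood, posterior density, and a scikit-learn style estimator.

The model for a binary response of respondent k to item i is

    logit P(y_ki = 1) = beta_i + theta_k - ||w_i - z_k||    (distance weight 1)

:class:`LSIRM` wraps the MCMC sampler (:mod:`lsirm.sampler`), the
Procrustes post-processing (:mod:`lsirm.alignment`) and posterior
summaries behind a ``fit`` / ``predict_proba`` / ``score`` interface, so
the model composes with scikit-learn tooling.  The module-level functions
are thin, stateless counterparts used throughout the test oracles.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .alignment import FittedModel, pool_chains, posterior_summary
from .data import ResponseMatrix
from .sampler import (
    Hyperparameters,
    ParameterDraw,
    PosteriorChain,
    SamplerConfig,
    run_sampler,
)

__all__ = [
    "success_probability",
    "log_likelihood",
    "log_posterior",
    "fit_lsirm",
    "LSIRM",
    "effective_sample_size",
]


def success_probability(
    beta_i: np.ndarray | float,
    theta_k: np.ndarray | float,
    w_i: np.ndarray,
    z_k: np.ndarray,
) -> np.ndarray | float:
    """P(y=1) = expit(beta_i + theta_k - ||w_i - z_k||).

    Strictly increasing in ``beta_i`` and ``theta_k``, strictly decreasing
    in the item–respondent distance.
    """
    w_i = np.asarray(w_i, dtype=float)
    z_k = np.asarray(z_k, dtype=float)
    if w_i.shape[-1] != z_k.shape[-1]:
        raise ValueError(
            f"latent dimensions differ: {w_i.shape[-1]} vs {z_k.shape[-1]}"
        )
    dist = np.linalg.norm(w_i - z_k, axis=-1)
    out = expit(np.asarray(beta_i) + np.asarray(theta_k) - dist)
    return float(out) if np.ndim(out) == 0 else out


def _probability_matrix(
    beta: np.ndarray, theta: np.ndarray, W: np.ndarray, Z: np.ndarray
) -> np.ndarray:
    """N x P matrix of success probabilities at one parameter value."""
    dist = np.linalg.norm(Z[:, None, :] - W[None, :, :], axis=-1)
    return expit(beta[None, :] + theta[:, None] - dist)


def _response_values(data: ResponseMatrix | np.ndarray) -> np.ndarray:
    if isinstance(data, ResponseMatrix):
        return data.values
    return np.asarray(data, dtype=float)


def log_likelihood(
    draw: ParameterDraw,
    data: ResponseMatrix | np.ndarray,
    include_imputed: bool = False,
    missing_indices: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Bernoulli log likelihood of the data under one parameter draw.

    Missing cells contribute zero unless ``include_imputed`` is set, in
    which case the draw's imputed values stand in for them (the augmented
    likelihood the sampler itself conditions on).
    """
    y = _response_values(data)
    if y.shape != (draw.theta.size, draw.beta.size):
        raise ValueError("data shape inconsistent with the draw")
    observed = ~np.isnan(y)
    bad = observed & ~np.isin(y, (0.0, 1.0))
    if bad.any():
        raise ValueError("observed responses must be 0 or 1")
    if include_imputed and draw.imputed.size:
        if missing_indices is None:
            missing_indices = np.nonzero(np.isnan(y))
        y = y.copy()
        y[missing_indices] = draw.imputed
        observed = ~np.isnan(y)
    prob = _probability_matrix(draw.beta, draw.theta, draw.W, draw.Z)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell = np.where(y == 1.0, np.log(prob), np.log1p(-prob))
    return float(cell[observed].sum())


def log_prior(draw: ParameterDraw, hyper: Hyperparameters) -> float:
    """Joint log prior density with all normalizing constants."""
    if draw.sigma_sq <= 0:
        raise ValueError("sigma_sq must be positive")
    beta, theta = draw.beta, draw.theta
    p, n = beta.size, theta.size
    tau = hyper.tau_beta_sq
    lp = -0.5 * p * math.log(2 * math.pi * tau) - float(beta @ beta) / (2 * tau)
    lp += (
        -0.5 * n * math.log(2 * math.pi * draw.sigma_sq)
        - float(theta @ theta) / (2 * draw.sigma_sq)
    )
    a, b = hyper.a_sigma, hyper.b_sigma
    lp += (
        a * math.log(b) - math.lgamma(a)
        - (a + 1) * math.log(draw.sigma_sq) - b / draw.sigma_sq
    )
    d = draw.W.shape[1]
    lp += -0.5 * (p + n) * d * math.log(2 * math.pi)
    lp += -0.5 * (float(np.sum(draw.W**2)) + float(np.sum(draw.Z**2)))
    return lp


def log_posterior(
    draw: ParameterDraw,
    data: ResponseMatrix | np.ndarray,
    hyper: Hyperparameters,
    include_imputed: bool = False,
) -> float:
    """Unnormalized log posterior (likelihood + priors, constants kept)."""
    return log_likelihood(draw, data, include_imputed=include_imputed) + log_prior(
        draw, hyper
    )


def fit_lsirm(
    data: ResponseMatrix | np.ndarray,
    hyper: Hyperparameters | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorChain:
    """Run the MH-within-Gibbs sampler on a response matrix."""
    return run_sampler(_response_values(data), hyper, config)


def effective_sample_size(x: np.ndarray) -> float:
    """Bulk effective sample size of a 1-d chain (convergence diagnostic)."""
    import arviz as az

    return float(az.ess(np.asarray(x, dtype=float)[None, :]))


class LSIRM(BaseEstimator):
    """Bayesian latent space item response model.

    Fits item easiness ``beta_i``, respondent traits ``theta_k`` and latent
    positions ``w_i`` (items), ``z_k`` (respondents) in a shared
    ``n_dims``-dimensional interaction map by Metropolis–Hastings-within-
    Gibbs sampling, then resolves rotational/reflective/translational
    non-identifiability by Procrustes alignment onto the MAP draw.

    Parameters
    ----------
    n_dims : int, default 2
        Latent space dimension.
    tau_beta_sq : float, default 4.0
        Prior variance of the item easiness parameters.
    a_sigma, b_sigma : float, default 1.0
        Inverse-Gamma prior shape/scale of the trait variance.
    n_iterations, burn_in, thin : int
        MCMC schedule; defaults retain (30000 - 5000) / 5 = 5000 draws.
    scale_beta, scale_theta, scale_w, scale_z : float
        Initial random-walk proposal scales (adapted during burn-in when
        ``adapt_during_burn_in`` is set, then frozen).
    n_chains : int, default 1
        Number of independent chains; chains are Procrustes-aligned into a
        common frame and their retained draws pooled.
    informant : {"parent", "self", "other"}
        Label carried into reports.
    random_state : int, default 0
        Seed; identical seeds give bit-identical chains.

    Attributes
    ----------
    beta_, theta_ : posterior means of easiness and trait parameters.
    W_, Z_ : posterior-mean latent positions (from the aligned chain).
    sigma_sq_ : posterior mean of the trait variance.
    chain_ : aligned :class:`~lsirm.sampler.PosteriorChain`.
    fitted_model_ : :class:`~lsirm.alignment.FittedModel` summary.
    acceptance_rates_ : per-block MH acceptance rates after burn-in.
    map_index_ : index of the maximum-a-posteriori retained draw.
    """

    def __init__(
        self,
        n_dims: int = 2,
        tau_beta_sq: float = 4.0,
        a_sigma: float = 1.0,
        b_sigma: float = 1.0,
        n_iterations: int = 30000,
        burn_in: int = 5000,
        thin: int = 5,
        scale_beta: float = 0.3,
        scale_theta: float = 0.3,
        scale_w: float = 0.2,
        scale_z: float = 0.2,
        adapt_during_burn_in: bool = True,
        align: bool = True,
        n_chains: int = 1,
        informant: str = "other",
        random_state: int = 0,
    ) -> None:
        self.n_dims = n_dims
        self.tau_beta_sq = tau_beta_sq
        self.a_sigma = a_sigma
        self.b_sigma = b_sigma
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.scale_beta = scale_beta
        self.scale_theta = scale_theta
        self.scale_w = scale_w
        self.scale_z = scale_z
        self.adapt_during_burn_in = adapt_during_burn_in
        self.align = align
        self.n_chains = n_chains
        self.informant = informant
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------
    def _hyper(self) -> Hyperparameters:
        return Hyperparameters(
            d=self.n_dims,
            tau_beta_sq=self.tau_beta_sq,
            a_sigma=self.a_sigma,
            b_sigma=self.b_sigma,
        )

    def _config(self, seed_offset: int = 0) -> SamplerConfig:
        return SamplerConfig(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            scale_beta=self.scale_beta,
            scale_theta=self.scale_theta,
            scale_w=self.scale_w,
            scale_z=self.scale_z,
            adapt_during_burn_in=self.adapt_during_burn_in,
            seed=(self.random_state + 100003 * seed_offset) % (2**31),
        )

    def fit(self, X: ResponseMatrix | np.ndarray, y=None) -> "LSIRM":
        """Fit the model to an N x P binary matrix (NaN marks missing)."""
        informant = self.informant
        item_ids = respondent_ids = None
        if isinstance(X, ResponseMatrix):
            informant = X.informant if self.informant == "other" else self.informant
            item_ids, respondent_ids = X.item_ids, X.respondent_ids
        values = _response_values(X)
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_chains == 1:
            chain = run_sampler(values, self._hyper(), self._config())
        else:
            # independent chains pooled in a common frame: better coverage
            # of minor posterior modes at the same total cost
            chain = pool_chains(
                [
                    run_sampler(values, self._hyper(), self._config(c))
                    for c in range(self.n_chains)
                ]
            )
        fitted = posterior_summary(
            chain,
            informant=informant,
            item_ids=item_ids,
            respondent_ids=respondent_ids,
            align=self.align,
        )
        self.fitted_model_: FittedModel = fitted
        self.chain_ = fitted.chain
        self.beta_ = fitted.beta_mean
        self.theta_ = fitted.theta_mean
        self.W_ = fitted.W_mean
        self.Z_ = fitted.Z_mean
        self.sigma_sq_ = float(fitted.chain.sigma_sq.mean())
        self.acceptance_rates_ = dict(fitted.chain.acceptance_rates)
        self.map_index_ = fitted.map_index
        self.n_features_in_ = values.shape[1]
        self._train_values = values
        return self

    # -- prediction --------------------------------------------------------
    def predict_proba(self, X=None, average_draws: bool = False) -> np.ndarray:
        """In-sample N x P success probabilities.

        Plug-in at the posterior means by default; with ``average_draws``
        the per-draw probabilities are averaged over the retained chain.
        """
        self._check_fitted()
        if X is not None:
            values = _response_values(X)
            if values.shape != self._train_values.shape:
                raise ValueError("X must match the shape of the fitted data")
        if average_draws:
            chain = self.chain_
            out = np.zeros((chain.n_respondents, chain.n_items))
            for s in range(len(chain)):
                out += _probability_matrix(
                    chain.beta[s], chain.theta[s], chain.W[s], chain.Z[s]
                )
            return out / len(chain)
        return _probability_matrix(self.beta_, self.theta_, self.W_, self.Z_)

    def predict(self, X=None, threshold: float = 0.5, average_draws: bool = False) -> np.ndarray:
        """Thresholded in-sample predictions (0/1)."""
        return (self.predict_proba(X, average_draws=average_draws) >= threshold).astype(float)

    def score(self, X=None, y=None) -> float:
        """In-sample classification accuracy over non-missing cells."""
        self._check_fitted()
        values = self._train_values if X is None else _response_values(X)
        observed = ~np.isnan(values)
        pred = self.predict()
        return float((pred[observed] == values[observed]).mean())

    def _check_fitted(self) -> None:
        if not hasattr(self, "chain_"):
            raise RuntimeError("this LSIRM instance is not fitted yet")
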