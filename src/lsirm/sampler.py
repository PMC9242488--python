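"""Metropolis–Hastings-within-Gibbs sampler for the latent space item
response model (LSIRM).

Model
-----
For respondent k and item i with binary response ``y_ki``,

    logit P(y_ki = 1) = beta_i + theta_k - ||w_i - z_k||,

where ``beta_i`` is the item easiness, ``theta_k`` the respondent's latent
trait, and ``w_i``, ``z_k`` are positions in a shared d-dimensional latent
space (the *interaction map*).  The distance weight is fixed at one.

Priors:  beta_i ~ N(0, tau_beta_sq);  theta_k ~ N(0, sigma_sq);
sigma_sq ~ Inv-Gamma(a_sigma, b_sigma);  w_i, z_k ~ N(0, I_d).

Sampler
-------
beta, theta, W-rows and Z-rows are updated with componentwise Gaussian
random walks (valid jointly because the full conditional of each block
factorizes over its components); sigma_sq is drawn exactly from its
conjugate inverse-Gamma full conditional.  Missing responses are treated by
Bayesian data augmentation: at the start of every sweep each missing cell
is redrawn as Bernoulli at the current parameters and then conditioned on
like observed data.  Proposal scales are adapted during burn-in toward a
componentwise acceptance rate of ~0.35 and frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Hyperparameters",
    "SamplerConfig",
    "ParameterDraw",
    "PosteriorChain",
    "run_sampler",
    "sample_sigma_sq",
    "DegenerateDataError",
    "SamplerDiagnosticsError",
]

_BLOCKS = ("beta", "theta", "w", "z")
_ADAPT_TARGET = 0.35  # inside the 0.23-0.44 band aimed for during burn-in
_ADAPT_BATCH = 50


class DegenerateDataError(ValueError):
    """A partially observed matrix has a fully missing row or column."""


class SamplerDiagnosticsError(RuntimeError):
    """The sampler produced a non-finite log posterior."""


@dataclass(frozen=True)
class Hyperparameters:
    """Prior settings of the LSIRM.

    d : latent dimension.
    tau_beta_sq : prior variance of the item easiness parameters.
    a_sigma, b_sigma : inverse-Gamma shape and scale of the trait variance.
    """

    d: int = 2
    tau_beta_sq: float = 4.0
    a_sigma: float = 1.0
    b_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("latent dimension d must be >= 1")
        if min(self.tau_beta_sq, self.a_sigma, self.b_sigma) <= 0:
            raise ValueError("tau_beta_sq, a_sigma, b_sigma must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """Run-length and proposal settings of the MCMC."""

    n_iterations: int = 30000
    burn_in: int = 5000
    thin: int = 5
    scale_beta: float = 0.3
    scale_theta: float = 0.3
    scale_w: float = 0.2
    scale_z: float = 0.2
    adapt_during_burn_in: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for name in ("scale_beta", "scale_theta", "scale_w", "scale_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class ParameterDraw:
    """One retained MCMC draw."""

    beta: np.ndarray        # (P,)
    theta: np.ndarray       # (N,)
    sigma_sq: float
    W: np.ndarray           # (P, d) item positions
    Z: np.ndarray           # (N, d) respondent positions
    log_posterior: float
    imputed: np.ndarray     # values imputed at the missing cells, (n_missing,)


@dataclass
class PosteriorChain:
    """Retained, thinned draws of one LSIRM fit, stored columnarly."""

    beta: np.ndarray          # (S, P)
    theta: np.ndarray         # (S, N)
    sigma_sq: np.ndarray      # (S,)
    W: np.ndarray             # (S, P, d)
    Z: np.ndarray             # (S, N, d)
    log_posterior: np.ndarray  # (S,)
    imputed: np.ndarray       # (S, n_missing)
    missing_indices: tuple[np.ndarray, np.ndarray]  # (rows, cols) of missing cells
    acceptance_rates: dict[str, float]
    hyper: Hyperparameters
    config: SamplerConfig
    aligned: bool = False

    def __len__(self) -> int:
        return self.beta.shape[0]

    @property
    def n_items(self) -> int:
        return self.beta.shape[1]

    @property
    def n_respondents(self) -> int:
        return self.theta.shape[1]

    def draw(self, s: int) -> ParameterDraw:
        return ParameterDraw(
            beta=self.beta[s], theta=self.theta[s], sigma_sq=float(self.sigma_sq[s]),
            W=self.W[s], Z=self.Z[s], log_posterior=float(self.log_posterior[s]),
            imputed=self.imputed[s],
        )

    def __iter__(self) -> Iterator[ParameterDraw]:
        return (self.draw(s) for s in range(len(self)))

    @property
    def map_index(self) -> int:
        # argmax returns the first maximizer: ties break to the earliest draw
        return int(np.argmax(self.log_posterior))


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def sample_sigma_sq(
    theta: np.ndarray, a_sigma: float, b_sigma: float, rng: np.random.Generator
) -> float:
    """Exact Gibbs draw of the trait variance from its full conditional.

    With theta_k ~ N(0, sigma_sq) and sigma_sq ~ Inv-Gamma(a, b), the full
    conditional is Inv-Gamma(a + N/2, b + sum(theta^2)/2).
    """
    shape = a_sigma + theta.size / 2.0
    scale = b_sigma + 0.5 * float(theta @ theta)
    return scale / rng.gamma(shape)


def _full_log_posterior(
    y: np.ndarray, eta: np.ndarray, l1pe: np.ndarray,
    beta: np.ndarray, theta: np.ndarray, sigma_sq: float,
    W: np.ndarray, Z: np.ndarray, hyper: Hyperparameters,
) -> float:
    """Augmented-data log posterior with all normalizing constants."""
    ll = float(np.sum(y * eta - l1pe))
    p, n = beta.size, theta.size
    tau = hyper.tau_beta_sq
    lp = ll
    lp += -0.5 * p * math.log(2 * math.pi * tau) - float(beta @ beta) / (2 * tau)
    lp += -0.5 * n * math.log(2 * math.pi * sigma_sq) - float(theta @ theta) / (2 * sigma_sq)
    a, b = hyper.a_sigma, hyper.b_sigma
    lp += a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(sigma_sq) - b / sigma_sq
    d = W.shape[1]
    lp += -0.5 * (p + n) * d * math.log(2 * math.pi)
    lp += -0.5 * (float(np.sum(W * W)) + float(np.sum(Z * Z)))
    return lp


def run_sampler(
    values: np.ndarray,
    hyper: Hyperparameters | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorChain:
    """Fit the LSIRM to a binary matrix (NaN = missing) by MCMC.

    An entirely missing matrix is accepted and yields draws from the prior
    (the data-augmentation target then marginalizes to the prior exactly);
    a partially observed matrix with an empty row or column raises
    :class:`DegenerateDataError`.
    """
    hyper = hyper or Hyperparameters()
    config = config or SamplerConfig()
    y_obs = np.asarray(values, dtype=float)
    if y_obs.ndim != 2 or min(y_obs.shape) < 2:
        raise DegenerateDataError("need an N x P matrix with N >= 2 and P >= 2")
    n, p = y_obs.shape
    d = hyper.d
    miss = np.isnan(y_obs)
    obs = ~miss
    all_missing = not obs.any()
    if not all_missing:
        if (~obs.any(axis=1)).any() or (~obs.any(axis=0)).any():
            raise DegenerateDataError(
                "a row or column has no observed responses; drop it before fitting"
            )
        bad = obs & ~np.isin(y_obs, (0.0, 1.0))
        if bad.any():
            raise ValueError("observed entries must be 0 or 1")
    miss_idx = np.nonzero(miss)
    n_miss = miss_idx[0].size

    rng = np.random.Generator(np.random.PCG64(config.seed))

    # --- initialization (deterministic given the seed) ---
    if all_missing:
        beta = np.zeros(p)
    else:
        with np.errstate(invalid="ignore"):
            rate = np.nanmean(y_obs, axis=0)
        rate = np.clip(rate, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
        beta = np.clip(np.log(rate / (1.0 - rate)), -3.0, 3.0)
    theta = np.zeros(n)
    sigma_sq = 1.0
    pos_scale = math.sqrt(0.1)
    W = pos_scale * rng.standard_normal((p, d))
    Z = pos_scale * rng.standard_normal((n, d))

    y = y_obs.copy()
    y[miss_idx] = 0.0

    scales = {
        "beta": config.scale_beta, "theta": config.scale_theta,
        "w": config.scale_w, "z": config.scale_z,
    }

    D = cdist(Z, W)
    eta = beta[None, :] + theta[:, None] - D
    l1pe = _log1pexp(eta)

    n_ret = config.n_retained
    store = {
        "beta": np.empty((n_ret, p)), "theta": np.empty((n_ret, n)),
        "sigma_sq": np.empty(n_ret), "W": np.empty((n_ret, p, d)),
        "Z": np.empty((n_ret, n, d)), "log_posterior": np.empty(n_ret),
        "imputed": np.empty((n_ret, n_miss)),
    }
    acc_total = {b: 0.0 for b in _BLOCKS}   # post-burn-in, for reporting
    acc_batch = {b: 0.0 for b in _BLOCKS}   # burn-in batches, for adaptation
    n_post = 0
    batch_no = 0
    s_out = 0

    for it in range(1, config.n_iterations + 1):
        # --- data augmentation: redraw missing responses ---
        if n_miss:
            pm = 1.0 / (1.0 + np.exp(-eta[miss_idx]))
            y[miss_idx] = (rng.random(n_miss) < pm).astype(float)
        col_y = y.sum(axis=0)
        row_y = y.sum(axis=1)

        # --- beta block: componentwise random walk over items ---
        prop = scales["beta"] * rng.standard_normal(p)
        eta_p = eta + prop[None, :]
        l1pe_p = _log1pexp(eta_p)
        delta = prop * col_y - (l1pe_p - l1pe).sum(axis=0)
        beta_p = beta + prop
        delta += (beta * beta - beta_p * beta_p) / (2 * hyper.tau_beta_sq)
        acc = np.log(rng.random(p)) < delta
        beta[acc] = beta_p[acc]
        eta[:, acc] = eta_p[:, acc]
        l1pe[:, acc] = l1pe_p[:, acc]
        rate_beta = acc.mean()

        # --- theta block: componentwise random walk over respondents ---
        prop = scales["theta"] * rng.standard_normal(n)
        eta_p = eta + prop[:, None]
        l1pe_p = _log1pexp(eta_p)
        delta = prop * row_y - (l1pe_p - l1pe).sum(axis=1)
        theta_p = theta + prop
        delta += (theta * theta - theta_p * theta_p) / (2 * sigma_sq)
        acc = np.log(rng.random(n)) < delta
        theta[acc] = theta_p[acc]
        eta[acc, :] = eta_p[acc, :]
        l1pe[acc, :] = l1pe_p[acc, :]
        rate_theta = acc.mean()

        # --- item positions: random walk on rows of W, accepted per item ---
        W_p = W + scales["w"] * rng.standard_normal((p, d))
        D_p = cdist(Z, W_p)
        eta_p = eta + (D - D_p)
        l1pe_p = _log1pexp(eta_p)
        delta = (y * (eta_p - eta) - (l1pe_p - l1pe)).sum(axis=0)
        delta += 0.5 * ((W * W).sum(axis=1) - (W_p * W_p).sum(axis=1))
        acc = np.log(rng.random(p)) < delta
        W[acc] = W_p[acc]
        D[:, acc] = D_p[:, acc]
        eta[:, acc] = eta_p[:, acc]
        l1pe[:, acc] = l1pe_p[:, acc]
        rate_w = acc.mean()

        # --- respondent positions: random walk on rows of Z ---
        Z_p = Z + scales["z"] * rng.standard_normal((n, d))
        D_p = cdist(Z_p, W)
        eta_p = eta + (D - D_p)
        l1pe_p = _log1pexp(eta_p)
        delta = (y * (eta_p - eta) - (l1pe_p - l1pe)).sum(axis=1)
        delta += 0.5 * ((Z * Z).sum(axis=1) - (Z_p * Z_p).sum(axis=1))
        acc = np.log(rng.random(n)) < delta
        Z[acc] = Z_p[acc]
        D[acc, :] = D_p[acc, :]
        eta[acc, :] = eta_p[acc, :]
        l1pe[acc, :] = l1pe_p[acc, :]
        rate_z = acc.mean()

        # --- trait variance: exact conjugate Gibbs draw ---
        sigma_sq = sample_sigma_sq(theta, hyper.a_sigma, hyper.b_sigma, rng)

        rates = {"beta": rate_beta, "theta": rate_theta, "w": rate_w, "z": rate_z}
        if it <= config.burn_in and config.adapt_during_burn_in:
            for b in _BLOCKS:
                acc_batch[b] += rates[b]
            if it % _ADAPT_BATCH == 0:
                batch_no += 1
                step = min(0.5, 1.0 / math.sqrt(batch_no))
                for b in _BLOCKS:
                    mean_rate = acc_batch[b] / _ADAPT_BATCH
                    scales[b] *= math.exp(step * (mean_rate - _ADAPT_TARGET))
                    acc_batch[b] = 0.0
        elif it > config.burn_in:
            n_post += 1
            for b in _BLOCKS:
                acc_total[b] += rates[b]

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            lp = _full_log_posterior(y, eta, l1pe, beta, theta, sigma_sq, W, Z, hyper)
            if not np.isfinite(lp):
                raise SamplerDiagnosticsError(
                    f"non-finite log posterior at iteration {it}"
                )
            store["beta"][s_out] = beta
            store["theta"][s_out] = theta
            store["sigma_sq"][s_out] = sigma_sq
            store["W"][s_out] = W
            store["Z"][s_out] = Z
            store["log_posterior"][s_out] = lp
            if n_miss:
                store["imputed"][s_out] = y[miss_idx]
            s_out += 1
            if s_out == n_ret:
                break

    acceptance = {b: (acc_total[b] / n_post if n_post else float("nan")) for b in _BLOCKS}
    return PosteriorChain(
        beta=store["beta"][:s_out], theta=store["theta"][:s_out],
        sigma_sq=store["sigma_sq"][:s_out], W=store["W"][:s_out], Z=store["Z"][:s_out],
        log_posterior=store["log_posterior"][:s_out], imputed=store["imputed"][:s_out],
        missing_indices=(miss_idx[0].copy(), miss_idx[1].copy()),
        acceptance_rates=acceptance, hyper=hyper, config=config,
    )
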