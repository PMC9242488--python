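"""Identifiability post-processing for latent positions.

The LSIRM likelihood depends on latent positions only through Euclidean
distances, so any rotation, reflection or translation of a configuration
leaves the posterior unchanged.  Two consequences are handled here:

* within a chain, retained draws wander over that equivalence class; each
  draw's stacked positions (items and respondents together) are mapped by
  an orthogonal Procrustes transform onto the maximum-a-posteriori draw;
* across two independently fitted instruments, the two interaction maps
  live in arbitrary frames; :func:`match_maps` puts them into a common
  frame using the posterior-mean *item* positions as anchors (items are
  the objects shared verbatim between instruments) and broadcasts the
  transform to respondents and to every retained draw.

Scaling is never estimated — only distance-preserving motions are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .sampler import PosteriorChain

__all__ = [
    "RigidTransform",
    "FittedModel",
    "procrustes_fit",
    "procrustes_align_chain",
    "posterior_summary",
    "match_maps",
]


@dataclass(frozen=True)
class RigidTransform:
    """x -> x @ rotation + translation, with rotation orthogonal (det ±1)."""

    rotation: np.ndarray     # (d, d)
    translation: np.ndarray  # (d,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if not np.allclose(r.T @ r, np.eye(r.shape[0]), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.rotation + self.translation

    @property
    def is_reflection(self) -> bool:
        return bool(np.linalg.det(self.rotation) < 0)

    @classmethod
    def identity(cls, d: int) -> "RigidTransform":
        return cls(np.eye(d), np.zeros(d))


def procrustes_fit(
    Z: np.ndarray, Z0: np.ndarray
) -> tuple[RigidTransform, float]:
    """Rigid motion (rotation/reflection + translation) taking Z closest to Z0.

    Minimizes ``||Z0 - (Z R + t)||_F^2`` over orthogonal R and translations
    t; no scaling.  Returns the transform and the minimized squared
    residual.  The rotation is unique when the centered cross-product
    matrix has full rank; otherwise a degeneracy warning is emitted and the
    SVD-based solution (a valid minimizer) is returned.
    """
    Z = np.asarray(Z, dtype=float)
    Z0 = np.asarray(Z0, dtype=float)
    if Z.shape != Z0.shape:
        raise ValueError(f"shape mismatch {Z.shape} vs {Z0.shape}")
    mu, mu0 = Z.mean(axis=0), Z0.mean(axis=0)
    Zc, Z0c = Z - mu, Z0 - mu0
    cross = Zc.T @ Z0c
    if np.linalg.matrix_rank(cross) < cross.shape[0]:
        warnings.warn(
            "rank-deficient cross-product: the Procrustes rotation is not "
            "unique; returning an SVD minimizer",
            RuntimeWarning,
            stacklevel=2,
        )
    R, _ = orthogonal_procrustes(Zc, Z0c)
    t = mu0 - mu @ R
    transform = RigidTransform(R, t)
    residual = float(np.sum((Z0 - transform.apply(Z)) ** 2))
    return transform, residual


def procrustes_align_chain(
    chain: PosteriorChain, target: np.ndarray | None = None
) -> PosteriorChain:
    """Map every retained draw's positions onto a reference configuration.

    The default target is the stacked item+respondent configuration of the
    draw with maximal stored log posterior (ties to the earliest draw).
    beta, theta and sigma_sq are untouched; pairwise distances within each
    draw are invariant under the applied rigid motions.
    """
    if len(chain) == 0:
        raise ValueError("cannot align an empty chain")
    if target is None:
        m = chain.map_index
        target = np.vstack([chain.W[m], chain.Z[m]])
    p = chain.n_items
    W_al = np.empty_like(chain.W)
    Z_al = np.empty_like(chain.Z)
    for s in range(len(chain)):
        stacked = np.vstack([chain.W[s], chain.Z[s]])
        transform, _ = procrustes_fit(stacked, target)
        moved = transform.apply(stacked)
        W_al[s] = moved[:p]
        Z_al[s] = moved[p:]
    return replace(chain, W=W_al, Z=Z_al, aligned=True)


def pool_chains(chains: list[PosteriorChain]) -> PosteriorChain:
    """Concatenate independent chains into one aligned chain.

    Every chain is Procrustes-aligned onto the first chain's MAP
    configuration, so pooled draws share one frame; running several
    shorter chains and pooling covers minor posterior modes that a single
    chain of the same total length may miss.
    """
    if not chains:
        raise ValueError("need at least one chain")
    first = procrustes_align_chain(chains[0])
    m = first.map_index
    target = np.vstack([first.W[m], first.Z[m]])
    aligned = [first] + [procrustes_align_chain(c, target=target) for c in chains[1:]]
    rates = {
        b: float(np.mean([c.acceptance_rates[b] for c in aligned]))
        for b in aligned[0].acceptance_rates
    }
    return replace(
        first,
        beta=np.concatenate([c.beta for c in aligned]),
        theta=np.concatenate([c.theta for c in aligned]),
        sigma_sq=np.concatenate([c.sigma_sq for c in aligned]),
        W=np.concatenate([c.W for c in aligned]),
        Z=np.concatenate([c.Z for c in aligned]),
        log_posterior=np.concatenate([c.log_posterior for c in aligned]),
        imputed=np.concatenate([c.imputed for c in aligned]),
        acceptance_rates=rates,
        aligned=True,
    )


@dataclass
class FittedModel:
    """Aligned chain plus posterior-mean and MAP summaries for one instrument."""

    chain: PosteriorChain
    beta_mean: np.ndarray
    theta_mean: np.ndarray
    W_mean: np.ndarray
    Z_mean: np.ndarray
    map_index: int
    informant: str = "other"
    item_ids: list[str] | None = None
    respondent_ids: list[str] | None = None
    match_transform: RigidTransform | None = None

    @property
    def n_items(self) -> int:
        return self.W_mean.shape[0]

    @property
    def n_respondents(self) -> int:
        return self.Z_mean.shape[0]

    @property
    def map_draw(self):
        return self.chain.draw(self.map_index)


def posterior_summary(
    chain: PosteriorChain,
    informant: str = "other",
    item_ids: list[str] | None = None,
    respondent_ids: list[str] | None = None,
    align: bool = True,
) -> FittedModel:
    """Summarize a chain into a :class:`FittedModel` (aligning it first)."""
    if len(chain) == 0:
        raise ValueError("cannot summarize an empty chain")
    if align and not chain.aligned:
        chain = procrustes_align_chain(chain)
    return FittedModel(
        chain=chain,
        beta_mean=chain.beta.mean(axis=0),
        theta_mean=chain.theta.mean(axis=0),
        W_mean=chain.W.mean(axis=0),
        Z_mean=chain.Z.mean(axis=0),
        map_index=chain.map_index,
        informant=informant,
        item_ids=item_ids,
        respondent_ids=respondent_ids,
    )


def match_maps(reference: FittedModel, other: FittedModel) -> FittedModel:
    """Bring ``other``'s interaction map into ``reference``'s frame.

    The rigid transform is estimated on posterior-mean item positions only
    and then applied to all of ``other``'s positions (means and every
    retained draw).  Within-instrument distances are unchanged.
    """
    if reference.item_ids is not None and other.item_ids is not None:
        if reference.item_ids != other.item_ids:
            raise ValueError("item ids of the two fits differ; cannot match maps")
    if reference.n_items != other.n_items:
        raise ValueError("item counts differ; cannot match maps")
    transform, _ = procrustes_fit(other.W_mean, reference.W_mean)
    chain = replace(
        other.chain,
        W=np.einsum("spd,de->spe", other.chain.W, transform.rotation) + transform.translation,
        Z=np.einsum("snd,de->sne", other.chain.Z, transform.rotation) + transform.translation,
    )
    return FittedModel(
        chain=chain,
        beta_mean=other.beta_mean.copy(),
        theta_mean=other.theta_mean.copy(),
        W_mean=transform.apply(other.W_mean),
        Z_mean=transform.apply(other.Z_mean),
        map_index=other.map_index,
        informant=other.informant,
        item_ids=other.item_ids,
        respondent_ids=other.respondent_ids,
        match_transform=transform,
    )
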