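"""Cross-informant discrepancy statistics on two matched interaction maps.

Given two fitted and map-matched LSIRMs (e.g. parent report vs. self
report on the same children and items), this module quantifies where the
two instruments disagree:

* item easiness comparison — Pearson correlation of the two posterior-mean
  ``beta`` vectors, an OLS trend line, and outlier items flagged by
  studentized residual;
* item-pair dependency — the posterior distribution of ``||w_i - w_j||``
  per instrument, compared via the overlap statistic
  ``R = ∫ min(f_a, f_b) dx`` (``R <= 0.05`` flags a pair as different),
  Kullback–Leibler divergence, and the two-sample Kolmogorov–Smirnov test;
* syndrome geometry — syndrome centroids, their pairwise cosine
  similarities per instrument;
* respondent profiles — distances from each respondent to each syndrome
  centroid, and K-means clustering of respondents on those profiles.

All distance-based quantities are invariant to the rigid motions used for
alignment and matching.  The per-pair ``R <= 0.05`` rule is applied
without any multiplicity correction, as is conventional for this
statistic; treat the flagged set as descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gaussian_kde, ks_2samp
from sklearn.cluster import KMeans

from .alignment import FittedModel
from .data import NO_SYNDROME, SyndromeMap

__all__ = [
    "DistanceDistribution",
    "OverlapResult",
    "KLResult",
    "BetaComparison",
    "OverlapHeatmap",
    "beta_compare",
    "distance_samples",
    "overlap_R",
    "kl_distance_divergence",
    "ks_compare",
    "overlap_heatmap",
    "syndrome_centroids",
    "cosine_similarity",
    "syndrome_similarity_matrices",
    "respondent_syndrome_distances",
    "cluster_respondents",
    "rank_discrepant_pairs",
]

FLAG_THRESHOLD = 0.05
_KDE_GRID = 512
_KDE_PAD = 3.0  # union support padded by this many bandwidths
_KL_FLOOR = 1e-12


class UndefinedDensityError(ValueError):
    """A kernel density cannot be formed (zero-variance samples)."""


# ---------------------------------------------------------------------------
# item easiness comparison


@dataclass
class BetaComparison:
    """Comparison of posterior-mean item easiness between two instruments."""

    pearson_r: float
    slope: float
    intercept: float
    studentized_residuals: np.ndarray  # externally studentized OLS residuals
    robust_z: np.ndarray               # robust-line residuals on a MAD scale
    flagged: np.ndarray                # boolean per item, from robust_z
    item_ids: list[str]
    threshold: float = 2.5

    @property
    def flagged_items(self) -> list[str]:
        return [i for i, f in zip(self.item_ids, self.flagged) if f]

    def to_frame(self, beta_a: np.ndarray, beta_b: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "beta_a": beta_a,
                "beta_b": beta_b,
                "studentized_residual": self.studentized_residuals,
                "robust_z": self.robust_z,
                "flagged": self.flagged,
            }
        )


def beta_compare(
    fit_a: FittedModel, fit_b: FittedModel, threshold: float = 2.5
) -> BetaComparison:
    """Correlate the two beta vectors and flag off-trend items.

    Reports the Pearson correlation and the OLS line of ``beta_b`` on
    ``beta_a`` (with externally studentized residuals).  Outlier flagging
    uses a masking-resistant rule: residuals from a Huber robust
    regression, standardized by their MAD, flagged beyond ``threshold`` in
    absolute value.  A plain studentized-OLS cut is blind to a moderately
    sized shifted subset — the off-trend items themselves inflate the OLS
    residual scale — whereas the robust scale is set by the on-trend
    majority.
    """
    beta_a, beta_b = fit_a.beta_mean, fit_b.beta_mean
    if beta_a.size != beta_b.size:
        raise ValueError("item counts differ between fits")
    if beta_a.size < 3:
        raise ValueError("need at least 3 items to compare easiness")
    r = float(np.corrcoef(beta_a, beta_b)[0, 1])
    X = sm.add_constant(beta_a)
    ols = sm.OLS(beta_b, X).fit()
    student = ols.get_influence().resid_studentized_external
    with warnings.catch_warnings():
        # a perfect linear relation gives zero robust scale; handled below
        warnings.simplefilter("ignore")
        rlm = sm.RLM(beta_b, X, M=sm.robust.norms.HuberT()).fit()
    resid = np.asarray(rlm.resid, dtype=float)
    scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if scale < 1e-12:
        robust_z = np.zeros_like(resid)
    else:
        robust_z = resid / scale
    flagged = np.abs(robust_z) > threshold
    item_ids = fit_a.item_ids or [str(i) for i in range(beta_a.size)]
    return BetaComparison(
        pearson_r=r,
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        studentized_residuals=np.asarray(student, dtype=float),
        robust_z=robust_z,
        flagged=flagged,
        item_ids=list(item_ids),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# item-pair distance distributions


@dataclass
class DistanceDistribution:
    """Posterior samples of ``||w_i - w_j||`` for one item pair."""

    item_pair: tuple[int, int]
    samples: np.ndarray
    instrument: str = "other"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty vector")
        if (self.samples < 0).any():
            raise ValueError("distances must be non-negative")


def distance_samples(fit: FittedModel, i: int, j: int) -> DistanceDistribution:
    """Per-draw Euclidean distance between items i and j."""
    if i == j:
        warnings.warn("i == j gives a degenerate zero-distance distribution",
                      RuntimeWarning, stacklevel=2)
    d = np.linalg.norm(fit.chain.W[:, i, :] - fit.chain.W[:, j, :], axis=1)
    return DistanceDistribution((i, j), d, fit.informant)


@dataclass(frozen=True)
class OverlapResult:
    item_pair: tuple[int, int]
    R: float
    flag_different: bool


def _kde_pair_grid(
    xa: np.ndarray, xb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Silverman-bandwidth Gaussian KDEs of both samples on a shared grid."""
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise UndefinedDensityError(
            "zero-variance samples: kernel density estimate is undefined"
        )
    ka = gaussian_kde(xa, bw_method="silverman")
    kb = gaussian_kde(xb, bw_method="silverman")
    bwa = float(np.sqrt(ka.covariance[0, 0]))
    bwb = float(np.sqrt(kb.covariance[0, 0]))
    lo = min(xa.min() - _KDE_PAD * bwa, xb.min() - _KDE_PAD * bwb)
    hi = max(xa.max() + _KDE_PAD * bwa, xb.max() + _KDE_PAD * bwb)
    grid = np.linspace(lo, hi, _KDE_GRID)
    return grid, ka(grid), kb(grid)


def overlap_R(da: DistanceDistribution, db: DistanceDistribution) -> OverlapResult:
    """Overlap statistic R = ∫ min(f_a, f_b) dx of the two distance densities.

    Densities are Gaussian KDEs with per-sample Silverman bandwidths,
    integrated by the trapezoid rule over the padded union support; the
    result is clamped to [0, 1].  ``R <= 0.05`` flags the pair's dependency
    as different between instruments.
    """
    grid, fa, fb = _kde_pair_grid(da.samples, db.samples)
    r = float(np.clip(np.trapezoid(np.minimum(fa, fb), grid), 0.0, 1.0))
    return OverlapResult(da.item_pair, r, r <= FLAG_THRESHOLD)


@dataclass(frozen=True)
class KLResult:
    """Directed and symmetrized KL divergence between distance densities."""

    kl_ab: float
    kl_ba: float

    @property
    def symmetric(self) -> float:
        return 0.5 * (self.kl_ab + self.kl_ba)


def kl_distance_divergence(
    da: DistanceDistribution, db: DistanceDistribution
) -> KLResult:
    """KL(f_a || f_b) (and the reverse) on the shared KDE grid.

    Densities are renormalized on the grid and floored at 1e-12; tiny
    negative quadrature error is clamped to zero so Gibbs' inequality
    holds numerically.
    """
    grid, fa, fb = _kde_pair_grid(da.samples, db.samples)
    fa = np.maximum(fa, _KL_FLOOR)
    fb = np.maximum(fb, _KL_FLOOR)
    fa = fa / np.trapezoid(fa, grid)
    fb = fb / np.trapezoid(fb, grid)
    kl_ab = max(0.0, float(np.trapezoid(fa * np.log(fa / fb), grid)))
    kl_ba = max(0.0, float(np.trapezoid(fb * np.log(fb / fa), grid)))
    return KLResult(kl_ab, kl_ba)


def ks_compare(
    da: DistanceDistribution, db: DistanceDistribution
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value.

    Caveat: posterior samples are autocorrelated, so the nominal p-value
    overstates the effective sample size; use it descriptively.
    """
    res = ks_2samp(da.samples, db.samples, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class OverlapHeatmap:
    """Symmetric matrix of overlap statistics R for all item pairs."""

    R: np.ndarray                 # (P, P), NaN on the diagonal
    flagged: np.ndarray           # boolean, R <= threshold off-diagonal
    item_ids: list[str]
    threshold: float = FLAG_THRESHOLD

    @property
    def flagged_proportion(self) -> float:
        iu = np.triu_indices_from(self.R, k=1)
        return float(self.flagged[iu].mean())

    def flagged_pairs(self) -> list[tuple[int, int]]:
        iu = np.triu_indices_from(self.R, k=1)
        return [
            (int(i), int(j))
            for i, j, f in zip(iu[0], iu[1], self.flagged[iu])
            if f
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.item_ids, columns=self.item_ids)


def _pairwise_distance_draws(fit: FittedModel, max_draws: int | None) -> np.ndarray:
    W = fit.chain.W
    if max_draws is not None and len(fit.chain) > max_draws:
        idx = np.linspace(0, len(fit.chain) - 1, max_draws).round().astype(int)
        W = W[idx]
    # (S, P, P) distance tensor
    return np.linalg.norm(W[:, :, None, :] - W[:, None, :, :], axis=-1)


def overlap_heatmap(
    fit_a: FittedModel,
    fit_b: FittedModel,
    threshold: float = FLAG_THRESHOLD,
    max_draws: int | None = None,
) -> OverlapHeatmap:
    """Overlap statistic R for every item pair of two matched fits."""
    if fit_a.n_items != fit_b.n_items:
        raise ValueError("item counts differ between fits")
    p = fit_a.n_items
    dist_a = _pairwise_distance_draws(fit_a, max_draws)
    dist_b = _pairwise_distance_draws(fit_b, max_draws)
    R = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(i + 1, p):
            da = DistanceDistribution((i, j), dist_a[:, i, j], fit_a.informant)
            db = DistanceDistribution((i, j), dist_b[:, i, j], fit_b.informant)
            R[i, j] = R[j, i] = overlap_R(da, db).R
    flagged = np.zeros((p, p), dtype=bool)
    off = ~np.isnan(R)
    flagged[off] = R[off] <= threshold
    item_ids = list(fit_a.item_ids or [str(i) for i in range(p)])
    return OverlapHeatmap(R, flagged, item_ids, threshold)


# ---------------------------------------------------------------------------
# syndrome-level geometry


def syndrome_centroids(
    fit: FittedModel,
    syndromes: SyndromeMap,
    per_draw: bool = False,
) -> dict[str, np.ndarray]:
    """Centroid of member-item positions per syndrome.

    Centroids are means of posterior-mean item positions; with
    ``per_draw`` each value is an (S, d) array of per-draw centroids
    instead (for uncertainty bands).  Items assigned ``"none"`` never
    contribute; empty syndromes are skipped with a warning.
    """
    item_ids = fit.item_ids or [str(i) for i in range(fit.n_items)]
    index = {iid: k for k, iid in enumerate(item_ids)}
    out: dict[str, np.ndarray] = {}
    for syn in syndromes.syndrome_order:
        members = [index[i] for i in syndromes.members(syn) if i in index]
        if not members:
            warnings.warn(f"syndrome {syn!r} has no member items; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        if per_draw:
            out[syn] = fit.chain.W[:, members, :].mean(axis=1)
        else:
            out[syn] = fit.W_mean[members].mean(axis=0)
    return out


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(phi) = a.b / (||a|| ||b||), in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def syndrome_similarity_matrices(
    fit_a: FittedModel, fit_b: FittedModel, syndromes: SyndromeMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise cosine-similarity matrix of syndrome centroids per instrument."""

    def one(fit: FittedModel) -> pd.DataFrame:
        cents = syndrome_centroids(fit, syndromes)
        labels = [s for s in syndromes.syndrome_order if s in cents]
        m = np.eye(len(labels))
        for x in range(len(labels)):
            for y in range(x + 1, len(labels)):
                m[x, y] = m[y, x] = cosine_similarity(cents[labels[x]], cents[labels[y]])
        return pd.DataFrame(m, index=labels, columns=labels)

    return one(fit_a), one(fit_b)


def respondent_syndrome_distances(
    fit: FittedModel, centroids: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Euclidean distance from each respondent position to each centroid."""
    labels = list(centroids)
    cents = np.stack([centroids[s] for s in labels])
    dist = np.linalg.norm(fit.Z_mean[:, None, :] - cents[None, :, :], axis=-1)
    index = fit.respondent_ids or [str(k) for k in range(fit.n_respondents)]
    return pd.DataFrame(dist, index=index, columns=labels)


@dataclass
class RespondentClusters:
    labels: np.ndarray
    profile: pd.DataFrame  # cluster x syndrome mean distances
    inertia: float


def cluster_respondents(
    dist_matrix: pd.DataFrame | np.ndarray, k: int = 4, seed: int = 0
) -> RespondentClusters:
    """K-means clustering of respondents on their syndrome-distance profiles.

    k-means++ initialization with 25 restarts; the per-cluster mean
    distance to each syndrome is reported as the cluster profile.
    """
    X = dist_matrix.to_numpy() if isinstance(dist_matrix, pd.DataFrame) else np.asarray(dist_matrix)
    if not 2 <= k <= X.shape[0]:
        raise ValueError(f"k must be in [2, {X.shape[0]}]")
    km = KMeans(n_clusters=k, init="k-means++", n_init=25, random_state=seed)
    labels = km.fit_predict(X)
    cols = (
        list(dist_matrix.columns)
        if isinstance(dist_matrix, pd.DataFrame)
        else [str(j) for j in range(X.shape[1])]
    )
    profile = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in range(k)],
        index=[f"cluster_{c}" for c in range(k)],
        columns=cols,
    )
    return RespondentClusters(labels, profile, float(km.inertia_))


# ---------------------------------------------------------------------------
# ranked pair tables


def rank_discrepant_pairs(
    fit_a: FittedModel,
    fit_b: FittedModel,
    heatmap: OverlapHeatmap,
    top_k: int = 12,
) -> pd.DataFrame:
    """Item pairs ranked by dependency discrepancy between instruments.

    Emits, per pair, the MAP-draw and posterior-mean distances in both
    instruments, the overlap statistic R, and two ranks: by R ascending
    (most distributionally different first) and by absolute MAP-distance
    difference descending.  The top ``top_k`` pairs under either ranking
    are returned.
    """
    p = fit_a.n_items
    map_a = fit_a.chain.W[fit_a.map_index]
    map_b = fit_b.chain.W[fit_b.map_index]
    mean_da = np.linalg.norm(fit_a.W_mean[:, None] - fit_a.W_mean[None, :], axis=-1)
    mean_db = np.linalg.norm(fit_b.W_mean[:, None] - fit_b.W_mean[None, :], axis=-1)
    mda = np.linalg.norm(map_a[:, None] - map_a[None, :], axis=-1)
    mdb = np.linalg.norm(map_b[:, None] - map_b[None, :], axis=-1)
    ids = heatmap.item_ids
    iu = np.triu_indices(p, k=1)
    df = pd.DataFrame(
        {
            "item_i": [ids[i] for i in iu[0]],
            "item_j": [ids[j] for j in iu[1]],
            "R": heatmap.R[iu],
            "map_dist_a": mda[iu],
            "map_dist_b": mdb[iu],
            "mean_dist_a": mean_da[iu],
            "mean_dist_b": mean_db[iu],
        }
    )
    df["abs_map_dist_diff"] = (df["map_dist_b"] - df["map_dist_a"]).abs()
    df["rank_by_R"] = df["R"].rank(method="first").astype(int)
    df["rank_by_map_diff"] = (
        (-df["abs_map_dist_diff"]).rank(method="first").astype(int)
    )
    keep = (df["rank_by_R"] <= top_k) | (df["rank_by_map_diff"] <= top_k)
    return df[keep].sort_values("rank_by_R").reset_index(drop=True)
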