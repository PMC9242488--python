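"""Conventional direct-comparison analyses used as references.

Three classical ways to compare two informants' reports on the same
respondents and items, without any latent structure:

* syndrome-level Pearson correlations of sum scores,
* item-level Cohen's kappa (with syndrome means of the item coefficients),
* item-pair Jaccard similarity within each instrument, differenced
  between instruments and ranked.

Missing handling: pairwise-complete deletion for kappa and correlations;
missing treated as 0 (not endorsed) for Jaccard, with the affected-cell
count reported.  Missingness in the target data is ~0.2%, so these
choices are immaterial there, but they are explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import NO_SYNDROME, ResponseMatrix, SyndromeMap

__all__ = [
    "SyndromeScores",
    "syndrome_sum_scores",
    "syndrome_correlations",
    "item_kappa",
    "jaccard_difference",
    "JaccardComparison",
]


@dataclass
class SyndromeScores:
    """Respondent × syndrome sum scores with per-cell item availability."""

    scores: pd.DataFrame       # sums over non-missing member items
    n_available: pd.DataFrame  # count of non-missing member items per cell
    informant: str = "other"


def syndrome_sum_scores(m: ResponseMatrix, syndromes: SyndromeMap) -> SyndromeScores:
    """Per-respondent sum of non-missing member items for each syndrome."""
    labels = syndromes.labels_with_members()
    index = {iid: k for k, iid in enumerate(m.item_ids)}
    scores = {}
    avail = {}
    for syn in labels:
        cols = [index[i] for i in syndromes.members(syn) if i in index]
        if not cols:
            continue
        block = m.values[:, cols]
        scores[syn] = np.nansum(block, axis=1)
        avail[syn] = (~np.isnan(block)).sum(axis=1)
    return SyndromeScores(
        pd.DataFrame(scores, index=m.respondent_ids),
        pd.DataFrame(avail, index=m.respondent_ids),
        m.informant,
    )


def syndrome_correlations(
    scores_a: SyndromeScores, scores_b: SyndromeScores
) -> pd.Series:
    """Pearson correlation of the two instruments' sum scores per syndrome.

    A syndrome where either instrument has zero score variance yields NaN
    (undefined correlation) rather than an arbitrary number.
    """
    common = [s for s in scores_a.scores.columns if s in scores_b.scores.columns]
    out = {}
    for syn in common:
        x = scores_a.scores[syn].to_numpy(dtype=float)
        y = scores_b.scores[syn].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[syn] = np.nan
        else:
            out[syn] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r")


def _kappa_from_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's kappa of two binary vectors; NaN when chance agreement is 1."""
    n = x.size
    po = float((x == y).mean())
    px, py = float(x.mean()), float(y.mean())
    pe = px * py + (1 - px) * (1 - py)
    if pe >= 1.0:
        return np.nan
    return (po - pe) / (1 - pe)


def item_kappa(
    a: ResponseMatrix, b: ResponseMatrix, syndromes: SyndromeMap | None = None
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Per-item Cohen's kappa between informants, plus syndrome means.

    Each item's 2×2 agreement table uses only respondents with both
    entries observed (pairwise-complete).  Degenerate marginals (expected
    agreement 1) yield NaN with the count of usable respondents reported.
    """
    if a.item_ids != b.item_ids:
        raise ValueError("item ids differ between instruments")
    rows = []
    for i, item in enumerate(a.item_ids):
        xa, xb = a.values[:, i], b.values[:, i]
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        kappa = _kappa_from_pair(xa[ok], xb[ok]) if ok.any() else np.nan
        rows.append(
            {
                "item_id": item,
                "kappa": kappa,
                "n_complete": int(ok.sum()),
                "syndrome": syndromes.syndrome_of(item) if syndromes else NO_SYNDROME,
            }
        )
    table = pd.DataFrame(rows).set_index("item_id")
    means = None
    if syndromes is not None:
        by_syn = table[table["syndrome"] != NO_SYNDROME]
        means = (
            by_syn.groupby("syndrome")["kappa"].mean()
            .reindex(syndromes.labels_with_members())
            .rename("mean_kappa")
        )
    return table, means


@dataclass
class JaccardComparison:
    """Within-instrument item-pair Jaccard matrices and their difference."""

    J_a: np.ndarray
    J_b: np.ndarray
    difference: np.ndarray       # J_b - J_a
    item_ids: list[str]
    n_missing_as_zero: int       # missing cells coerced to 0 before counting
    top_pairs: pd.DataFrame      # ranked by |difference|, undefined excluded


def _jaccard_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard J(A,B) = |A∩B| / |A∪B| between item columns."""
    y = values.astype(float)
    inter = y.T @ y
    counts = y.sum(axis=0)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / union, np.nan)
    return J


def jaccard_difference(
    a: ResponseMatrix, b: ResponseMatrix, top_k: int = 12
) -> JaccardComparison:
    """Jaccard similarity per item pair in each instrument, differenced.

    Missing responses count as not endorsed.  Pairs whose union is empty
    in either instrument have undefined similarity and are excluded from
    the ranking.  ``difference = J_b - J_a`` (self minus parent in the
    canonical orientation).
    """
    if a.item_ids != b.item_ids:
        raise ValueError("item ids differ between instruments")
    n_coerced = int(a.missing_mask.sum() + b.missing_mask.sum())
    ya = np.nan_to_num(a.values, nan=0.0)
    yb = np.nan_to_num(b.values, nan=0.0)
    J_a = _jaccard_matrix(ya)
    J_b = _jaccard_matrix(yb)
    diff = J_b - J_a
    p = len(a.item_ids)
    iu = np.triu_indices(p, k=1)
    table = pd.DataFrame(
        {
            "item_i": [a.item_ids[i] for i in iu[0]],
            "item_j": [a.item_ids[j] for j in iu[1]],
            "J_a": J_a[iu],
            "J_b": J_b[iu],
            "difference": diff[iu],
        }
    )
    table = table.dropna(subset=["difference"])
    table["abs_difference"] = table["difference"].abs()
    table = (
        table.sort_values("abs_difference", ascending=False)
        .head(top_k)
        .reset_index(drop=True)
    )
    return JaccardComparison(J_a, J_b, diff, list(a.item_ids), n_coerced, table)
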