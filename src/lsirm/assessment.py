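"""Goodness of fit of a fitted LSIRM by in-sample classification.

Predicted success probabilities (plug-in at posterior means, or averaged
over retained draws) are thresholded and compared against the observed
binary responses; sensitivity, specificity and overall accuracy are
reported.  Evaluation is in-sample by design — the question is adequacy
of fit, not out-of-sample prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .alignment import FittedModel
from .data import ResponseMatrix

__all__ = [
    "ConfusionCounts",
    "GofMetrics",
    "predict_probabilities",
    "confusion",
    "gof_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class GofMetrics:
    """Specificity, sensitivity, accuracy; NaN + a flag when undefined."""

    specificity: float
    sensitivity: float
    overall_accuracy: float
    undefined: tuple[str, ...] = ()


def _prob_matrix(beta, theta, W, Z) -> np.ndarray:
    dist = np.linalg.norm(Z[:, None, :] - W[None, :, :], axis=-1)
    return expit(beta[None, :] + theta[:, None] - dist)


def predict_probabilities(
    fit: FittedModel,
    data: ResponseMatrix | np.ndarray | None = None,
    average_draws: bool = False,
) -> np.ndarray:
    """N x P success probabilities under the fitted model.

    Plug-in at posterior means by default; ``average_draws`` averages the
    per-draw probability matrices over the retained chain instead.
    """
    if data is not None:
        values = data.values if isinstance(data, ResponseMatrix) else np.asarray(data)
        if values.shape != (fit.n_respondents, fit.n_items):
            raise ValueError(
                f"data shape {values.shape} does not match fit "
                f"({fit.n_respondents}, {fit.n_items})"
            )
    if average_draws:
        chain = fit.chain
        out = np.zeros((fit.n_respondents, fit.n_items))
        for s in range(len(chain)):
            out += _prob_matrix(chain.beta[s], chain.theta[s], chain.W[s], chain.Z[s])
        return out / len(chain)
    return _prob_matrix(fit.beta_mean, fit.theta_mean, fit.W_mean, fit.Z_mean)


def confusion(
    fit: FittedModel,
    data: ResponseMatrix | np.ndarray,
    threshold: float = 0.5,
    average_draws: bool = False,
) -> ConfusionCounts:
    """Tally predictions (probability >= threshold) against observations.

    Missing cells are excluded from every count.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    values = data.values if isinstance(data, ResponseMatrix) else np.asarray(data, float)
    prob = predict_probabilities(fit, values, average_draws=average_draws)
    observed = ~np.isnan(values)
    pred = prob >= threshold
    y = values == 1.0
    return ConfusionCounts(
        TP=int((observed & y & pred).sum()),
        TN=int((observed & ~y & ~pred).sum()),
        FP=int((observed & ~y & pred).sum()),
        FN=int((observed & y & ~pred).sum()),
    )


def gof_metrics(c: ConfusionCounts) -> GofMetrics:
    """Specificity TN/(TN+FP), sensitivity TP/(TP+FN), accuracy (TP+TN)/total.

    A zero denominator makes the corresponding metric NaN and lists it in
    ``undefined`` — never a silent 0.
    """
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    spec = ratio(c.TN, c.TN + c.FP, "specificity")
    sens = ratio(c.TP, c.TP + c.FN, "sensitivity")
    acc = ratio(c.TP + c.TN, c.total, "overall_accuracy")
    return GofMetrics(spec, sens, acc, tuple(undefined))
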