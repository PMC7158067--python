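"""Decision rules turning posterior draws into per-area anomaly flags.

Two families are provided.  Exceedance-threshold rules flag an area when the
posterior probability that a risk quantity exceeds its reference (relative
risk above 1, i.e. positive on the log scale) is high enough at one or more
time points.  The Bayesian false-discovery-rate rule flags the largest group
of areas whose average posterior probability of following the common-trend
model stays within the FDR budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DetectionResult:
    """Per-area flags with the scores and rule that produced them.

    ``scores`` lie in [0, 1] and are oriented so that larger means more
    unusual (max exceedance probability, rule statistic, or one minus the
    posterior probability of the common model).
    """

    flags: np.ndarray
    scores: np.ndarray
    rule: str
    threshold: float

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        scores = np.asarray(self.scores, dtype=float)
        if flags.shape != scores.shape or flags.ndim != 1:
            raise ValueError("flags and scores must be 1-d arrays of equal length")
        if scores.min() < 0 or scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "scores", scores)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def flagged_areas(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area": np.arange(len(self.flags)),
                "score": self.scores,
                "flagged": self.flags,
                "rule": self.rule,
                "threshold": self.threshold,
            }
        )


def exceedance_probability(draws) -> float:
    """Fraction of posterior draws strictly above the reference value 0.

    For a log relative-risk (or interaction) quantity this is the posterior
    probability that the risk ratio exceeds 1.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one retained draw")
    return float(np.mean(draws > 0.0))


def exceedance_matrix(draws: np.ndarray) -> np.ndarray:
    """Per-unit exceedance probabilities from draws of shape (n_draws, A, T)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.shape[0] == 0:
        raise ValueError("expected non-empty draws of shape (n_draws, areas, times)")
    return np.mean(draws > 0.0, axis=0)


def _check_probs(exceed) -> np.ndarray:
    p = np.asarray(exceed, dtype=float)
    if p.ndim != 2:
        raise ValueError("expected an area x time probability matrix")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("exceedance probabilities must lie in [0, 1]")
    return p


def dm_rule(exceed, threshold: float) -> DetectionResult:
    """Flag areas whose exceedance probability passes ``threshold`` anywhere.

    An area is flagged iff at least one time point has exceedance probability
    strictly greater than ``threshold`` (conventionally 0.8, or 0.9 for a
    conservative variant).  The per-area score is the maximum probability
    over time.
    """
    p = _check_probs(exceed)
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    scores = p.max(axis=1)
    return DetectionResult(
        flags=scores > threshold,
        scores=scores,
        rule=f"dm({threshold:g})",
        threshold=threshold,
    )


def stmix_rule1(exceed) -> DetectionResult:
    """Interaction-mixture rule 1: any single time point above 0.8.

    Flags an area when, for at least one time point, the space-time
    interaction has probability greater than 0.8 of being above 1 on the
    risk-ratio scale.  Identical to :func:`dm_rule` at threshold 0.8 applied
    to the interaction exceedance matrix.
    """
    res = dm_rule(exceed, threshold=0.8)
    return DetectionResult(
        flags=res.flags, scores=res.scores, rule="stmix1", threshold=0.8
    )


def stmix_rule2(exceed, consecutive: bool = False) -> DetectionResult:
    """Interaction-mixture rule 2: three time points averaging above 0.8.

    Flags an area when at least three time points' interaction exceedance
    probabilities average more than 0.8.  The default reading takes the three
    largest per-time probabilities (the most favourable triple, so the rule
    is "there exist three time points whose average exceeds 0.8");
    ``consecutive=True`` instead requires some window of three consecutive
    time points to average above 0.8.
    """
    p = _check_probs(exceed)
    n_times = p.shape[1]
    if n_times < 3:
        raise ValueError(f"rule needs at least 3 time points, got {n_times}")
    if consecutive:
        windows = np.stack(
            [p[:, t : t + 3].mean(axis=1) for t in range(n_times - 2)], axis=1
        )
        scores = windows.max(axis=1)
    else:
        top3 = np.sort(p, axis=1)[:, -3:]
        scores = top3.mean(axis=1)
    return DetectionResult(
        flags=scores > 0.8, scores=scores, rule="stmix2", threshold=0.8
    )


def bayes_fdr_flags(model_probs, alpha: float = 0.05) -> DetectionResult:
    """Bayesian FDR control from posterior common-model probabilities.

    ``model_probs[i]`` is the posterior probability that area i follows the
    common-trend model; small values signal anomalies.  Sorting ascending,
    the rule flags the largest prefix whose running mean stays at or below
    ``alpha`` — so the expected share of truly-common areas among the flags,
    under the model's own posterior, does not exceed the budget.  Areas tied
    at the cutoff probability are flagged together.
    """
    p = np.asarray(model_probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("model_probs must be a vector")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("model probabilities must lie in [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    order = np.argsort(p, kind="stable")
    srt = p[order]
    running_mean = np.cumsum(srt) / np.arange(1, p.size + 1)
    # a prefix may not split a group of tied probabilities
    tie_closed = np.ones(p.size, dtype=bool)
    tie_closed[:-1] = srt[:-1] < srt[1:]
    # tiny slack so exact-boundary cases are not lost to float accumulation
    admissible = np.flatnonzero((running_mean <= alpha + 1e-12) & tie_closed)
    flags = np.zeros(p.size, dtype=bool)
    if admissible.size:
        flags = p <= srt[admissible[-1]]
    return DetectionResult(
        flags=flags, scores=1.0 - p, rule=f"bayes_fdr({alpha:g})", threshold=alpha
    )
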