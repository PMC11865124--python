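"""Participant-level exclusion rules applied before any analysis.

Two rules: (1) discrete responders, who used only the labeled anchor points
of the slider (0, 50, 100) on at least 75/90 of their trials, and (2)
participants whose ratings correlate poorly (r < .5) with the true relative
tempo of the stimulus on a log2 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "ScreeningReport",
    "is_discrete_responder",
    "truth_correlation",
    "screen_participant",
    "screen_study",
    "DISCRETE_NUMERATOR",
    "DISCRETE_DENOMINATOR",
    "MIN_TRUTH_CORRELATION",
    "ANCHOR_VALUES",
]

DISCRETE_NUMERATOR = 75
DISCRETE_DENOMINATOR = 90
MIN_TRUTH_CORRELATION = 0.5
ANCHOR_VALUES = frozenset({0.0, 50.0, 100.0})


@dataclass(frozen=True)
class ScreeningReport:
    participant: object
    n_trials: int
    n_discrete_responses: int
    truth_correlation: float  # NaN when undefined
    excluded: bool
    reason: str  # "none" | "discrete" | "low_correlation"


def is_discrete_responder(
    ratings,
    threshold_count: int | None = None,
    anchor_values=ANCHOR_VALUES,
) -> bool:
    """True iff the participant used anchor values on >= the threshold count.

    The 75-out-of-90 rule scales pro rata to other trial counts:
    ceil(75/90 * n_trials), unless an explicit ``threshold_count`` is given.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size == 0:
        raise InvalidArgumentError("empty rating list")
    if threshold_count is None:
        threshold_count = math.ceil(
            DISCRETE_NUMERATOR / DISCRETE_DENOMINATOR * ratings.size
        )
    n_anchor = int(np.isin(ratings, sorted(anchor_values)).sum())
    return n_anchor >= threshold_count


def truth_correlation(ratings, iois_ms, ref_ioi_ms: float) -> float:
    """Pearson r between ratings and log2 relative tempo (ref_ioi / ioi).

    Returns NaN when either variable has zero variance.
    """
    ratings = np.asarray(ratings, dtype=float)
    iois = np.asarray(iois_ms, dtype=float)
    if ratings.size < 3:
        raise InvalidArgumentError("need at least 3 trials")
    x = np.log2(ref_ioi_ms / iois)
    if np.ptp(x) == 0:
        raise InvalidArgumentError("tempo must vary across trials")
    if np.ptp(ratings) == 0:
        return float("nan")
    from scipy import stats

    return float(stats.pearsonr(ratings, x).statistic)


def screen_participant(
    participant,
    ratings,
    iois_ms,
    ref_ioi_ms: float,
    discrete_rule: bool = True,
    min_r: float = MIN_TRUTH_CORRELATION,
) -> ScreeningReport:
    """Apply both exclusion rules; the discrete rule takes priority."""
    ratings = np.asarray(ratings, dtype=float)
    n_anchor = int(np.isin(ratings, sorted(ANCHOR_VALUES)).sum())
    discrete = discrete_rule and is_discrete_responder(ratings)
    r = truth_correlation(ratings, iois_ms, ref_ioi_ms)
    if discrete:
        excluded, reason = True, "discrete"
    elif math.isnan(r) or r < min_r:
        # constant-rating participants (undefined r) fall under this rule
        excluded, reason = True, "low_correlation"
    else:
        excluded, reason = False, "none"
    return ScreeningReport(
        participant=participant,
        n_trials=int(ratings.size),
        n_discrete_responses=n_anchor,
        truth_correlation=r,
        excluded=excluded,
        reason=reason,
    )


def screen_study(trials, ref_ioi_ms: float, **kwargs) -> "list[ScreeningReport]":
    """Screen every participant in a trial table (pandas DataFrame)."""
    reports = []
    for pid, grp in trials.groupby("participant_id", sort=True):
        reports.append(
            screen_participant(
                pid,
                grp["rating"].to_numpy(),
                grp["ioi_ms"].to_numpy(),
                ref_ioi_ms,
                **kwargs,
            )
        )
    return reports
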