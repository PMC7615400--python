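"""Daily composite ordinal angina symptom score.

Each patient-day is scored from the number of angina episodes and the
units of antianginal medication in use: more episodes and more
medication give a higher score, and a day with no angina and no
antianginal medication scores zero.  Three clinical events override the
symptom-derived value and occupy the top of the ordinal scale, in
increasing severity: unblinding for intolerable angina, acute coronary
syndrome, and death.  Missing daily values are filled by carrying the
last observed value forward; override days are never overwritten.

Scores are plain floats; override categories are the strings in
:data:`OVERRIDES`.  :func:`score_sort_key` defines the global ordinal
comparator (every override ranks above every numeric value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: override categories in increasing severity
OVERRIDES = ("unblinding", "acs", "death")

_OVERRIDE_RANK = {name: i for i, name in enumerate(OVERRIDES)}


def is_override(value) -> bool:
    return isinstance(value, str) and value in _OVERRIDE_RANK


def score_sort_key(value) -> tuple[int, float]:
    """Sort key placing numeric scores below all override categories."""
    if is_override(value):
        return (1, float(_OVERRIDE_RANK[value]))
    return (0, float(value))


def worst_override(categories) -> str:
    """Most severe override among those present (ties: worst wins)."""
    cats = [c for c in categories if is_override(c)]
    if not cats:
        raise ValueError("no override categories present")
    return max(cats, key=lambda c: _OVERRIDE_RANK[c])


@dataclass(frozen=True)
class ScoreConfig:
    """Weights and windows defining the composite score.

    The published scale's exact level table lives in trial supplementary
    material; these defaults (one point per episode capped at
    ``daily_cap``, one point per antianginal unit) reproduce its
    structure — monotone in both inputs, zero iff symptom- and
    medication-free — and every weight is replaceable without code
    change.

    Parameters
    ----------
    episode_weight : float
        Score units per angina episode.
    med_unit_weight : float
        Score units per standardized antianginal unit (one unit is half
        a guideline maximum daily dose of one agent).
    daily_cap : float
        Maximum symptom-derived contribution per day.
    summary_window_days : int
        Trailing window over which the follow-up summary averages the
        daily score.
    """

    episode_weight: float = 1.0
    med_unit_weight: float = 1.0
    daily_cap: float = 6.0
    summary_window_days: int = 7

    def __post_init__(self) -> None:
        if self.episode_weight <= 0 or self.med_unit_weight <= 0:
            raise ValueError("score weights must be positive")
        if self.daily_cap < self.episode_weight:
            raise ValueError("daily_cap must be at least episode_weight")
        if self.summary_window_days < 1:
            raise ValueError("summary_window_days must be >= 1")


def daily_score(episodes, med_units: float, override: str = "none",
                config: ScoreConfig | None = None):
    """Composite score for one patient-day.

    An override category supersedes the symptom-derived value entirely;
    otherwise the score is
    ``min(daily_cap, episode_weight * episodes) + med_unit_weight * med_units``.
    Missing episode counts (None/NaN) yield a missing score (NaN) unless
    an override is present.
    """
    config = config or ScoreConfig()
    if override != "none":
        if not is_override(override):
            raise ValueError(f"unknown override category: {override!r}")
        return override
    if med_units < 0:
        raise ValueError("med_units must be nonnegative")
    if episodes is None or (isinstance(episodes, float) and math.isnan(episodes)):
        return float("nan")
    if episodes < 0:
        raise ValueError("episodes must be nonnegative")
    symptom = min(config.daily_cap, config.episode_weight * episodes)
    return float(symptom + config.med_unit_weight * med_units)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def locf_fill(values):
    """Fill missing daily values with the last observed value.

    Override entries are observed values and are never overwritten.
    Days missing before the first observation take the first observed
    value, so the filled sequence is total; a fully missing sequence is
    rejected.
    """
    values = list(values)
    observed = [v for v in values if not _is_missing(v)]
    if not observed:
        raise ValueError("cannot carry forward: all values missing")
    filled = []
    last = observed[0]
    for v in values:
        if _is_missing(v):
            filled.append(last)
        else:
            last = v
            filled.append(v)
    return filled


def _daily_scores(diary: pd.DataFrame, config: ScoreConfig) -> list:
    return [
        daily_score(row.episodes, row.med_units, row.override, config)
        for row in diary.itertuples()
    ]


def followup_summary(diary: pd.DataFrame, config: ScoreConfig | None = None):
    """Per-patient follow-up score: override category or windowed mean.

    If any override occurred during follow-up the summary is the worst
    override category.  Otherwise daily scores are computed, gaps filled
    by carrying the last value forward, and the summary is the mean over
    the final ``summary_window_days`` days — a real number on the
    daily-score scale.

    ``diary`` holds one patient's records with columns ``day`` (>= 1 for
    follow-up), ``episodes``, ``med_units``, ``override``.
    """
    config = config or ScoreConfig()
    fu = diary[diary["day"] >= 1].sort_values("day")
    if fu.empty:
        raise ValueError("follow-up diary is empty")
    if (fu["override"] != "none").any():
        return worst_override(fu.loc[fu["override"] != "none", "override"])
    filled = locf_fill(_daily_scores(fu, config))
    window = filled[-config.summary_window_days:]
    return float(np.mean(window))


def prerandomization_summary(diary: pd.DataFrame,
                             config: ScoreConfig | None = None) -> float:
    """Mean daily score over the pre-randomization phase (days < 0)."""
    config = config or ScoreConfig()
    pre = diary[diary["day"] < 0].sort_values("day")
    if pre.empty:
        raise ValueError("pre-randomization diary is empty")
    filled = locf_fill(_daily_scores(pre, config))
    return float(np.mean(filled))


def score_trial(diary: pd.DataFrame,
                config: ScoreConfig | None = None) -> pd.DataFrame:
    """Per-patient score table for a whole trial diary.

    Returns one row per patient: ``patient_id``, ``pre_score`` (float),
    ``followup_score`` (float or override category), ``override`` (the
    category, or "none").
    """
    config = config or ScoreConfig()
    rows = []
    for pid, sub in diary.groupby("patient_id", sort=True):
        fu_score = followup_summary(sub, config)
        rows.append(
            {
                "patient_id": pid,
                "pre_score": prerandomization_summary(sub, config),
                "followup_score": fu_score,
                "override": fu_score if is_override(fu_score) else "none",
            }
        )
    return pd.DataFrame(rows)
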