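"""Arm-specific blinding index from treatment-guess tables.

After a sham-controlled procedure, each patient (and each blinded staff
member) is asked which arm they believe the patient was assigned to, on
a five-level certainty scale.  For one true-arm stratum the index is

    BI = (n_correct - n_incorrect) / n,

equivalently ``(2 * P(correct | guessed) - 1) * P(guessed)``: 0 under
random guessing (ideal blinding), 1 under complete unblinding, negative
when guesses run opposite to assignment.  The confidence interval is a
Wald interval from the multinomial variance of the linear contrast,
truncated to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: canonical guess categories, from "guessed own arm, sure" to
#: "guessed other arm, sure"
GUESS_CATEGORIES = (
    "correct_sure",
    "correct_unsure",
    "dont_know",
    "incorrect_unsure",
    "incorrect_sure",
)


@dataclass(frozen=True)
class BlindingTable:
    """Guess counts for one true-arm stratum.

    Certainty sub-levels are retained so tables can be reported in full,
    but the index collapses them to correct / don't know / incorrect.
    Three-category data can be entered with the ``*_sure`` fields at 0.
    """

    correct_sure: int = 0
    correct_unsure: int = 0
    dont_know: int = 0
    incorrect_unsure: int = 0
    incorrect_sure: int = 0

    def __post_init__(self) -> None:
        for name in GUESS_CATEGORIES:
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be nonnegative")

    @property
    def n(self) -> int:
        return sum(getattr(self, name) for name in GUESS_CATEGORIES)

    @property
    def n_correct(self) -> int:
        return self.correct_sure + self.correct_unsure

    @property
    def n_incorrect(self) -> int:
        return self.incorrect_sure + self.incorrect_unsure

    def swapped(self) -> "BlindingTable":
        """Table with correct and incorrect guesses exchanged."""
        return BlindingTable(
            correct_sure=self.incorrect_sure,
            correct_unsure=self.incorrect_unsure,
            dont_know=self.dont_know,
            incorrect_unsure=self.correct_unsure,
            incorrect_sure=self.correct_sure,
        )


def blinding_index(
    table: BlindingTable, conf_level: float = 0.95
) -> tuple[float, float, float]:
    """Blinding index with Wald confidence interval for one arm.

    Each guess contributes +1 (correct), 0 (don't know) or -1
    (incorrect); the index is the mean of these scores and its variance
    is ``(p_correct + p_incorrect - BI^2) / n``.  Degenerate tables
    (e.g. all "don't know", or all correct-sure) have zero variance and
    return a width-zero interval.

    Returns
    -------
    (index, lower, upper) with all three in [-1, 1].
    """
    n = table.n
    if n < 1:
        raise ValueError("blinding table is empty")
    pc = table.n_correct / n
    pi = table.n_incorrect / n
    bi = pc - pi
    var = (pc + pi - bi**2) / n
    z = stats.norm.ppf(0.5 + conf_level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return (
        float(bi),
        float(max(bi - half, -1.0)),
        float(min(bi + half, 1.0)),
    )
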