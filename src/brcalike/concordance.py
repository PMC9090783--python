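"""Marginal-matched concordance between two continuous biomarker scores.

When only one of two scores has an established decision cutoff, the second
is dichotomized at the percentile that the first score's cutoff occupies in
the data, so that both binary calls have (nearly) the same marginal positive
fraction; agreement is then tabulated as a 2x2 table.  The percentile is
defined by strict below-counting and the matching quantile by linear
interpolation, which makes the marginal match exact to within 1/n on
tie-free data; ties at either cutoff resolve to the high class (>=).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConcordanceResult:
    n: int
    cutoff_a: float
    percentile_used: float       # in [0, 100]
    cutoff_b: float
    both_high: int
    both_low: int
    a_high_b_low: int
    a_low_b_high: int

    @property
    def table(self) -> np.ndarray:
        """2x2 counts, rows = score_a call (high, low), cols = score_b call."""
        return np.array([[self.both_high, self.a_high_b_low],
                         [self.a_low_b_high, self.both_low]])

    @property
    def concordant_fraction(self) -> float:
        return (self.both_high + self.both_low) / self.n

    @property
    def discordant_fraction(self) -> float:
        return 1.0 - self.concordant_fraction

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "cutoff_a": self.cutoff_a,
            "percentile_used": self.percentile_used,
            "cutoff_b": self.cutoff_b,
            "table": self.table.tolist(),
            "concordant_fraction": self.concordant_fraction,
            "concordant_pct": 100.0 * self.concordant_fraction,
        }


def percentile_of_cutoff(scores_a, cutoff: float) -> float:
    """Percentile occupied by a cutoff: 100 * (#scores strictly below it) / n."""
    scores_a = np.asarray(scores_a, dtype=float)
    if len(scores_a) < 2:
        raise ValueError("need at least 2 scores")
    return 100.0 * float((scores_a < cutoff).sum()) / len(scores_a)


def dichotomize_at_percentile(scores_b, percentile: float):
    """Cut a score at an empirical percentile (linear interpolation).

    Returns (labels_high, cutoff_b): labels_high[i] is True iff
    scores_b[i] >= cutoff_b.  The proportion labeled low equals
    percentile/100 to within 1/n on tie-free data.
    """
    if not (0.0 <= percentile <= 100.0):
        raise ValueError("percentile must lie in [0, 100]")
    scores_b = np.asarray(scores_b, dtype=float)
    if percentile == 100.0:
        # everything sits below the matched cutoff: the cut falls just above
        # the maximum, so all calls are low
        cutoff_b = float(np.nextafter(scores_b.max(), np.inf))
    else:
        cutoff_b = float(np.percentile(scores_b, percentile))
    return scores_b >= cutoff_b, cutoff_b


def concordance(paired: pd.DataFrame, cutoff_a: float = 0.63) -> ConcordanceResult:
    """Tabulate 2x2 agreement of two scores after marginal-matched cuts.

    `paired` needs columns score_a (the cutoff-bearing score, in [0, 1]) and
    score_b (arbitrary scale); pairs must be complete and ids unique.
    """
    if len(paired) < 2:
        raise ValueError("need at least 2 paired scores")
    if paired[["score_a", "score_b"]].isna().any().any():
        raise ValueError("paired scores must have no missing values")
    if "sample_id" in paired.columns and paired["sample_id"].duplicated().any():
        raise ValueError("sample ids must be unique")
    a = paired["score_a"].to_numpy(dtype=float)
    b = paired["score_b"].to_numpy(dtype=float)
    high_a = a >= cutoff_a
    pct = percentile_of_cutoff(a, cutoff_a)
    high_b, cutoff_b = dichotomize_at_percentile(b, pct)
    return ConcordanceResult(
        n=len(a),
        cutoff_a=cutoff_a,
        percentile_used=pct,
        cutoff_b=cutoff_b,
        both_high=int((high_a & high_b).sum()),
        both_low=int((~high_a & ~high_b).sum()),
        a_high_b_low=int((high_a & ~high_b).sum()),
        a_low_b_high=int((~high_a & high_b).sum()),
    )
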