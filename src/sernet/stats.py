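"""Rank-based significance layer for goodness-of-fit tables.

A ``ScoreBlockTable`` holds scores in a complete block design (blocks x
treatments). ``friedman`` tests for a treatment effect on within-block
ranks (mid-ranks for ties, with the standard tie correction);
``tukey_kramer_posthoc`` compares all treatment pairs on mean ranks
using studentized-range critical values, as in the usual follow-up to a
significant Friedman test.

For a signed-threshold sweep the crossed design is used: to test the
positive-cost effect, blocks are the negative-cost levels (and vice
versa); ``score_table_from_sweep`` builds the table from a sweep CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScoreBlockTable",
    "TestResult",
    "friedman",
    "tukey_kramer_posthoc",
    "score_table_from_sweep",
]


@dataclass
class ScoreBlockTable:
    """Complete blocks x treatments score matrix."""

    values: np.ndarray
    treatment_labels: list[str]
    block_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("score table must be 2-D (blocks x treatments)")
        b, k = self.values.shape
        if len(self.treatment_labels) != k:
            raise ValueError("treatment label count mismatch")
        if len(self.block_labels) != b:
            raise ValueError("block label count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score table has missing cells (incomplete design)")

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_treatments(self) -> int:
        return self.values.shape[1]

    def ranks(self) -> np.ndarray:
        """Within-block mid-ranks."""
        return sps.rankdata(self.values, axis=1)


@dataclass
class TestResult:
    chi2: float
    df: int
    p: float
    rank_means: np.ndarray
    posthoc: pd.DataFrame | None = None


def friedman(table: ScoreBlockTable) -> TestResult:
    """Friedman rank test across treatments within blocks.

    Uses mid-ranks for ties and divides the statistic by the tie
    correction factor. Fully tied data (every block constant) yields
    statistic 0 and p = 1.
    """
    b, k = table.n_blocks, table.n_treatments
    if k < 2 or b < 2:
        raise ValueError("need at least 2 treatments and 2 blocks")
    ranks = table.ranks()
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (b * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * b * (k + 1)

    # tie correction: 1 - sum over blocks of (t^3 - t) / (b k (k^2 - 1))
    ties = 0.0
    for row in table.values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (b * k * (k * k - 1))
    if correction <= 0.0:
        return TestResult(chi2=0.0, df=k - 1, p=1.0,
                          rank_means=ranks.mean(axis=0))
    chi2 /= correction
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return TestResult(chi2=float(chi2), df=df, p=p, rank_means=ranks.mean(axis=0))


def tukey_kramer_posthoc(table: ScoreBlockTable, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs comparison of treatment mean ranks.

    A pair (i, j) is flagged when |rank_mean_i - rank_mean_j| exceeds
    q_{1-alpha}(k, inf) / sqrt(2) * sqrt(k (k+1) / (6 b)), the
    studentized-range critical difference for Friedman mean ranks.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    b, k = table.n_blocks, table.n_treatments
    rank_means = table.ranks().mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * b))
    q = sps.studentized_range.ppf(1.0 - alpha, k, np.inf)
    if not np.isfinite(q):  # older scipy: no df = inf support
        q = sps.studentized_range.ppf(1.0 - alpha, k, 1e6)
    critical = q / np.sqrt(2.0) * se
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = rank_means[i] - rank_means[j]
            rows.append({
                "treatment_a": table.treatment_labels[i],
                "treatment_b": table.treatment_labels[j],
                "rank_mean_a": rank_means[i],
                "rank_mean_b": rank_means[j],
                "difference": diff,
                "critical_difference": critical,
                "significant": bool(abs(diff) > critical),
            })
    return pd.DataFrame(rows)


def score_table_from_sweep(
    sweep_table: pd.DataFrame,
    treatment: str = "positive_cost",
    blocks: str = "negative_cost",
    value: str = "mean_r",
) -> ScoreBlockTable:
    """Pivot a tidy sweep table into a blocks x treatments score matrix."""
    for col in (treatment, blocks, value):
        if col not in sweep_table.columns:
            raise ValueError(f"sweep table lacks column {col!r}")
    pivot = sweep_table.pivot_table(index=blocks, columns=treatment,
                                    values=value, aggfunc="mean")
    if pivot.isna().any().any():
        raise ValueError("incomplete block design after pivoting sweep table")
    return ScoreBlockTable(
        values=pivot.to_numpy(),
        treatment_labels=[str(c) for c in pivot.columns],
        block_labels=[str(i) for i in pivot.index],
    )
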