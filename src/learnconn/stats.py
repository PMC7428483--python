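"""Nonparametric group statistics for the repeated-measures design.

Every subject contributes one value per condition (a behavioral score or a
connectivity statistic).  Paired two-condition contrasts use the Wilcoxon
signed-rank test; three-condition families (rest vs. the two learning or the
two test states) use the Friedman omnibus test followed by pairwise Wilcoxon
comparisons with Bonferroni correction; brain-behavior coupling uses the
Spearman rank correlation.  Significance threshold is p < .05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class PairComparison:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_corrected: float


@dataclass
class TestResult:
    """Outcome of one statistical test.

    ``degenerate`` marks inputs where the statistic is undefined or trivially
    null (all differences zero, constant input); callers should not interpret
    ``statistic`` in that case.
    """

    test: str
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False
    comparisons: list[PairComparison] = field(default_factory=list)


@dataclass
class CohortTable:
    """Subjects x conditions matrix of one metric, complete by construction."""

    data: pd.DataFrame  # index: subject ids, columns: condition labels

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("cohort table has missing cells")
        if len(self.data) < 2:
            raise ValueError("at least 2 subjects required")
        if self.data.shape[1] < 2:
            raise ValueError("at least 2 conditions required")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def column(self, condition: str) -> np.ndarray:
        return self.data[condition].to_numpy(dtype=float)

    @classmethod
    def from_metrics(
        cls,
        metrics: pd.DataFrame,
        value: str,
        conditions: Sequence[str],
    ) -> "CohortTable":
        wide = metrics.pivot(index="subject", columns="condition", values=value)
        missing = [c for c in conditions if c not in wide.columns]
        if missing:
            raise ValueError(f"conditions absent from metrics: {missing}")
        wide = wide[list(conditions)]
        if wide.isna().any().any():
            bad = wide[wide.isna().any(axis=1)].index.tolist()
            raise ValueError(f"incomplete design for subjects {bad}")
        return cls(wide)


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Paired Wilcoxon signed-rank test, two-sided normal approximation.

    Zero differences are handled Pratt-style (ranked, then dropped); the
    reported statistic is the signed rank sum T+ - T-.  If every difference
    is zero the result is degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    d = x - y
    if np.all(d == 0):
        return TestResult("wilcoxon", 0.0, 1.0, len(x), degenerate=True)
    res = sps.wilcoxon(x, y, zero_method="pratt", method="approx")
    # signed rank sum over nonzero differences, zeros ranked Pratt-style
    ranks = sps.rankdata(np.abs(d))
    nz = d != 0
    t_plus = ranks[nz & (d > 0)].sum()
    t_minus = ranks[nz & (d < 0)].sum()
    return TestResult(
        "wilcoxon", float(t_plus - t_minus), float(res.pvalue), len(x)
    )


def friedman_test(table: CohortTable) -> TestResult:
    """Friedman rank test across matched conditions (chi-square, tie-corrected)."""
    if table.data.shape[1] < 3:
        raise ValueError("the Friedman design needs at least 3 conditions")
    columns = [table.column(c) for c in table.conditions]
    if all(np.ptp(row) == 0 for row in table.data.to_numpy()):
        return TestResult("friedman", 0.0, 1.0, table.n_subjects, degenerate=True)
    stat, p = sps.friedmanchisquare(*columns)
    if not np.isfinite(stat):
        return TestResult("friedman", 0.0, 1.0, table.n_subjects, degenerate=True)
    return TestResult("friedman", float(stat), float(p), table.n_subjects)


def posthoc_pairwise(table: CohortTable) -> TestResult:
    """Friedman omnibus plus Bonferroni-corrected pairwise Wilcoxon tests.

    Every condition pair is compared; raw p-values are multiplied by the
    number of pairs and capped at 1.
    """
    omnibus = friedman_test(table)
    pairs = list(combinations(table.conditions, 2))
    k = len(pairs)
    comparisons = []
    for a, b in pairs:
        res = wilcoxon_signed_rank(table.column(a), table.column(b))
        comparisons.append(
            PairComparison(
                pair=(a, b),
                statistic=res.statistic,
                p_raw=res.p_value,
                p_corrected=min(1.0, res.p_value * k),
            )
        )
    omnibus.comparisons = comparisons
    return omnibus


def spearman_correlation(x, y) -> TestResult:
    """Tie-corrected Spearman rho with the two-sided t approximation (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if len(x) < 5:
        raise ValueError("at least 5 pairs required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("spearman", float("nan"), 1.0, len(x), degenerate=True)
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), len(x))


def brain_behavior_analysis(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    value: str = "between_DMN_FPN",
    condition_a: str = "TE-learn",
    condition_b: str = "EL-learn",
) -> tuple[pd.DataFrame, TestResult]:
    """Correlate connectivity differences with score differences.

    Both differences are taken trial-and-error minus errorless per subject:
    ``score_diff = TE score - EL score`` and ``connectivity_diff`` as the
    ``value`` column in ``condition_a`` minus ``condition_b``.  Returns the
    per-subject difference table and the Spearman result.
    """
    wide = metrics.pivot(index="subject", columns="condition", values=value)
    for cond in (condition_a, condition_b):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} missing from metrics")
        bad = wide.index[wide[cond].isna()].tolist()
        if bad:
            raise ValueError(f"subjects missing {cond!r} metrics: {bad}")
    scores = scores.set_index("subject") if "subject" in scores.columns else scores
    missing = [s for s in wide.index if s not in scores.index]
    if missing:
        raise ValueError(f"subjects missing scores: {missing}")
    scores = scores.loc[wide.index]
    diffs = pd.DataFrame(
        {
            "score_diff": scores["score_TE"] - scores["score_EL"],
            "connectivity_diff": wide[condition_a] - wide[condition_b],
        }
    )
    result = spearman_correlation(
        diffs["connectivity_diff"].to_numpy(), diffs["score_diff"].to_numpy()
    )
    return diffs, result


def pattern_summary(
    tables: dict[str, CohortTable], alpha: float = ALPHA
) -> pd.DataFrame:
    """Ordered-relation table over condition pairs for several metric families.

    For each metric family (a named cohort table) and each condition pair,
    the cell reads ``"A > B"`` when the Bonferroni-corrected pairwise p-value
    is below ``alpha`` and A's mean exceeds B's, ``"B > A"`` for the reverse,
    and ``"A ~ B"`` when the comparison is not significant.
    """
    rows = []
    for metric, table in tables.items():
        result = posthoc_pairwise(table)
        for comp in result.comparisons:
            a, b = comp.pair
            if comp.p_corrected < alpha:
                mean_a = table.column(a).mean()
                mean_b = table.column(b).mean()
                relation = f"{a} > {b}" if mean_a > mean_b else f"{b} > {a}"
            else:
                relation = f"{a} ~ {b}"
            rows.append(
                {
                    "metric": metric,
                    "pair": f"{a} vs {b}",
                    "statistic": comp.statistic,
                    "p_raw": comp.p_raw,
                    "p_corrected": comp.p_corrected,
                    "relation": relation,
                }
            )
    return pd.DataFrame(rows)
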