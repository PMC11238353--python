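"""Inferential toolkit: trial summaries, t-based CIs, paired t-tests with
Bonferroni correction, and Pearson correlation.

Conventions follow the study's analysis: two-sided tests, α = 0.05,
confidence intervals from the Student-t quantile with n−1 degrees of
freedom, and pairing by participant (the n=25 per-rater means, not the
individual Monte-Carlo trials, are the paired observations when protocols
are compared).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrialSummary",
    "ComparisonReport",
    "summarize_trials",
    "paired_t_bonferroni",
    "pearson",
    "summaries_to_frame",
]


@dataclass(frozen=True)
class TrialSummary:
    """Mean, sd and t-based confidence interval of a sample of F1 scores."""

    rater_id: str
    protocol: str
    mean_f1: float
    sd_f1: float
    n_trials: int
    ci_low: float
    ci_high: float
    level: float = 0.95

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass(frozen=True)
class PairResult:
    group_a: str
    group_b: str
    t_statistic: float
    raw_p: float
    adjusted_p: float


@dataclass(frozen=True)
class ComparisonReport:
    """All pairwise paired t-tests among named groups, Bonferroni-adjusted.

    ``adjusted_p = min(1, raw_p × m)`` with m the number of pairs tested.
    """

    pairs: tuple[PairResult, ...]
    correction: str
    alpha: float

    def flagged(self) -> list[PairResult]:
        """Pairs significant at ``alpha`` after correction."""
        return [p for p in self.pairs if p.adjusted_p < self.alpha]

    def to_json(self) -> str:
        return json.dumps(
            {
                "correction": self.correction,
                "alpha": self.alpha,
                "pairs": [asdict(p) for p in self.pairs],
            }
        )


def summarize_trials(
    per_trial_f1: Sequence[float],
    level: float = 0.95,
    rater_id: str = "",
    protocol: str = "",
) -> TrialSummary:
    """Sample mean, sd (n−1 denominator) and t-interval of a score sample.

    A single observation (or a constant sample) yields sd 0 and a degenerate
    interval at the mean.
    """
    x = np.asarray(per_trial_f1, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(sps.t.ppf(0.5 + level / 2, df=n - 1)) * sd / math.sqrt(n)
    else:
        half = 0.0
    return TrialSummary(
        rater_id=rater_id,
        protocol=protocol,
        mean_f1=mean,
        sd_f1=sd,
        n_trials=n,
        ci_low=mean - half,
        ci_high=mean + half,
        level=level,
    )


def paired_t_bonferroni(
    samples: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonReport:
    """Two-sided paired t-tests for every pair of groups, Bonferroni-corrected.

    Observations are paired by index (participant). A pair whose differences
    are all exactly zero is degenerate — no evidence of any difference — and
    is reported with t = 0, p = 1.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    vectors = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    n = {k: v.size for k, v in vectors.items()}
    if len(set(n.values())) != 1:
        raise ValueError(f"groups must have equal lengths, got {n}")
    combos = list(itertools.combinations(names, 2))
    m = len(combos)
    pairs = []
    for a, b in combos:
        diff = vectors[a] - vectors[b]
        if np.all(diff == 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = sps.ttest_rel(vectors[a], vectors[b])
            t_stat, p = float(t_stat), float(p)
        pairs.append(
            PairResult(
                group_a=a,
                group_b=b,
                t_statistic=t_stat,
                raw_p=p,
                adjusted_p=min(1.0, p * m),
            )
        )
    return ComparisonReport(pairs=tuple(pairs), correction="bonferroni", alpha=alpha)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input (undefined)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("vectors must have equal length")
    if xa.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    return float(sps.pearsonr(xa, ya).statistic)


def summaries_to_frame(
    baseline: Mapping[str, float],
    second_opinion: Mapping[str, TrialSummary],
    majority: Mapping[str, TrialSummary] | None = None,
) -> pd.DataFrame:
    """Arrange per-participant results as a table shaped like the study's
    published comparison (one row per participant, sorted by baseline F1)."""
    rows = []
    for rid in baseline:
        so = second_opinion[rid]
        row = {
            "participant": rid,
            "student": baseline[rid],
            "second_opinion_mean": so.mean_f1,
            "second_opinion_sd": so.sd_f1,
        }
        if majority is not None:
            mv = majority[rid]
            row["majority_mean"] = mv.mean_f1
            row["majority_sd"] = mv.sd_f1
        rows.append(row)
    return (
        pd.DataFrame(rows).sort_values("student", kind="stable").reset_index(drop=True)
    )
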