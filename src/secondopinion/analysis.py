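"""Downstream analyses of the second-opinion framework.

Covers the study's follow-up questions:

* how does the hybrid protocol's performance scale with the AI's operating
  point (:func:`sensitivity_sweep`, parameterised by balanced accuracy up to
  the perfect-classifier ceiling);
* are cases where panel and AI tend to agree systematically different from
  those where they disagree (:func:`stratify_agreement` at the 70% agreement
  threshold, :func:`compare_groups` for covariate and AI-accuracy contrasts);
* how often does consulting a second rater actually change — and correctly
  change — the initial decision (:func:`switch_analysis`);
* do the published per-participant results aggregate to the printed summary
  statistics (:func:`reproduce_table2` on the packaged fixture).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import balanced_accuracy
from .protocols import ProtocolResult, run_simulation
from .stats import TrialSummary, pearson, summarize_trials
from .synthetic import Cohort, RaterProfile, ResponseMatrix, generate_ai_predictions

__all__ = [
    "AgreementGroups",
    "SwitchReport",
    "sensitivity_sweep",
    "stratify_agreement",
    "compare_groups",
    "switch_analysis",
    "load_table2",
    "reproduce_table2",
    "Table2Summary",
]


@dataclass(frozen=True)
class AgreementGroups:
    """Partition of cases into high-agreement (HA) and low-agreement (LA).

    A case is HA when strictly more than ``threshold`` of the panel gave the
    same diagnosis as the AI; ``per_case_agreement`` holds that fraction for
    every case, indexed like the response matrix.
    """

    ha_cases: np.ndarray  # case indices
    la_cases: np.ndarray
    per_case_agreement: np.ndarray
    threshold: float


@dataclass(frozen=True)
class SwitchReport:
    """How often second opinions altered the primary rater's decisions.

    All fractions share the denominator named in ``denominator``:
    ``"consulted"`` (cases that went to a second opinion — the default) or
    ``"predicted_positive"`` (cases the primary rater initially called
    exposures). A switch is *correct* when the final answer matches the
    truth and the initial one did not, *incorrect* in the opposite case;
    correct + incorrect ≤ altered always holds under the consulted
    denominator.
    """

    altered_fraction: float
    correct_switch_fraction: float
    incorrect_switch_fraction: float
    denominator: str
    n_denominator: int


def sensitivity_sweep(
    matrix: ResponseMatrix,
    cohort: Cohort,
    targets: list[float],
    n_trials: int = 1000,
    seed: int = 0,
) -> list[TrialSummary]:
    """Re-run the second-opinion simulation across AI operating points.

    Each target ``b`` is a balanced accuracy in [0.5, 1]; the AI vector is
    replaced by a fresh draw with sensitivity = specificity = b (``b = 1``
    means the AI equals the truth exactly), the simulation is re-run, and
    the pool mean F1 (mean of per-rater means, t-interval across raters) is
    reported. Worse-than-chance AIs (b < 0.5) are rejected.
    """
    for b in targets:
        if not 0.5 <= b <= 1.0:
            raise ValueError(f"balanced-accuracy target {b} outside [0.5, 1.0]")
    out = []
    for k, b in enumerate(targets):
        if b == 1.0:
            ai = matrix.truth.copy()
        else:
            ai = generate_ai_predictions(
                cohort, RaterProfile("ai", b, b), seed=seed + 7919 * (k + 1)
            )
        swept = replace(matrix, ai=ai)
        per_rater = run_simulation(swept, "second_opinion", n_trials, seed=seed)
        rater_means = [float(v.mean()) for v in per_rater.values()]
        summary = summarize_trials(rater_means, protocol="second_opinion")
        out.append(replace(summary, rater_id=f"pool@b={b:g}"))
    return out


def stratify_agreement(
    matrix: ResponseMatrix, threshold: float = 0.70
) -> AgreementGroups:
    """Split cases by panel-AI agreement: HA strictly above the threshold."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    agreement = (matrix.responses == matrix.ai[:, None]).mean(axis=1)
    ha = np.flatnonzero(agreement > threshold)
    la = np.flatnonzero(agreement <= threshold)
    return AgreementGroups(
        ha_cases=ha, la_cases=la, per_case_agreement=agreement, threshold=threshold
    )


def _two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-proportion z-test (pooled)."""
    p_pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (k1 / n1 - k2 / n2) / se
    return float(2 * sps.norm.sf(abs(z)))


def compare_groups(
    groups: AgreementGroups,
    cohort: Cohort,
    matrix: ResponseMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Contrast HA vs LA cases on covariates and AI accuracy.

    Age is compared with a two-sample Welch t-test (t-based 95% CIs per
    group); the categorical shares (female, stepwise-excavation arm,
    preoperative pain) and the AI's per-group accuracy with two-sided
    two-proportion z-tests. Returns one row per factor with per-group
    values, the p-value and a significance flag at ``alpha``.
    """
    ha, la = groups.ha_cases, groups.la_cases
    if ha.size == 0 or la.size == 0:
        raise ValueError("both agreement groups must be non-empty to compare")
    rows = []

    def ci(x: np.ndarray) -> tuple[float, float]:
        s = summarize_trials(x)
        return s.ci_low, s.ci_high

    age_ha, age_la = cohort.age[ha].astype(float), cohort.age[la].astype(float)
    t, p = sps.ttest_ind(age_ha, age_la, equal_var=False)
    rows.append(
        {
            "factor": "age_mean",
            "ha": float(age_ha.mean()),
            "la": float(age_la.mean()),
            "ha_ci": ci(age_ha),
            "la_ci": ci(age_la),
            "p_value": float(p),
        }
    )

    for name, values in (
        ("female", cohort.female),
        ("arm_sw", (cohort.arm == "SW").astype(int)),
        ("pain", cohort.pain),
        ("ai_correct", (matrix.ai == cohort.truth).astype(int)),
    ):
        k1, k2 = int(values[ha].sum()), int(values[la].sum())
        rows.append(
            {
                "factor": f"{name}_share",
                "ha": k1 / ha.size,
                "la": k2 / la.size,
                "ha_ci": None,
                "la_ci": None,
                "p_value": _two_proportion_p(k1, ha.size, k2, la.size),
            }
        )
    df = pd.DataFrame(rows)
    df["significant"] = df["p_value"] < alpha
    return df


def switch_analysis(
    baseline: np.ndarray,
    result: ProtocolResult,
    truth: np.ndarray,
    denominator: str = "consulted",
) -> SwitchReport:
    """Quantify decision switches induced by the second-opinion protocol.

    ``altered`` counts consulted cases whose final answer differs from the
    primary rater's initial one; correct/incorrect switches additionally
    compare both answers with the truth. ``denominator`` selects the base
    of the reported fractions (see :class:`SwitchReport`); fractions of an
    empty denominator are 0.
    """
    baseline = np.asarray(baseline)
    truth = np.asarray(truth)
    final = result.final_predictions
    consulted = np.array([len(c) > 0 for c in result.consulted])
    altered = consulted & (final != baseline)
    correct = altered & (final == truth) & (baseline != truth)
    incorrect = altered & (baseline == truth) & (final != truth)

    if denominator == "consulted":
        denom = int(consulted.sum())
    elif denominator == "predicted_positive":
        denom = int((baseline == 1).sum())
    else:
        raise ValueError(
            "denominator must be 'consulted' or 'predicted_positive', "
            f"got {denominator!r}"
        )
    if denom == 0:
        return SwitchReport(0.0, 0.0, 0.0, denominator, 0)
    return SwitchReport(
        altered_fraction=float(altered.sum() / denom),
        correct_switch_fraction=float(correct.sum() / denom),
        incorrect_switch_fraction=float(incorrect.sum() / denom),
        denominator=denominator,
        n_denominator=denom,
    )


# ---------------------------------------------------------------------------
# published per-participant table


@dataclass(frozen=True)
class Table2Summary:
    """Aggregates recomputed from the published per-participant table."""

    baseline_mean: float
    second_opinion_mean: float
    majority_mean: float
    baseline_ci: tuple[float, float]
    second_opinion_ci: tuple[float, float]
    majority_ci: tuple[float, float]
    improvement_correlation: float
    n_participants: int


def load_table2() -> pd.DataFrame:
    """Load the packaged per-participant results table.

    25 rows: baseline macro-F1 of each dental student, plus the mean ± sd
    macro-F1 of the second-opinion and majority-vote protocols over 1000
    simulation trials, exactly as published (rows sorted by baseline F1).
    """
    with resources.files("secondopinion.data").joinpath("table2.csv").open() as fh:
        df = pd.read_csv(fh)
    if not df["baseline_f1"].is_monotonic_increasing:
        raise ValueError("fixture rows must be sorted by baseline F1")
    return df


def reproduce_table2(fixture: pd.DataFrame | None = None) -> Table2Summary:
    """Recompute the summary statistics from the per-participant table:
    column means, the t-based 95% CI of each column mean, and the Pearson
    correlation between baseline F1 and second-opinion improvement."""
    df = load_table2() if fixture is None else fixture
    b = df["baseline_f1"].to_numpy(float)
    so = df["second_opinion_mean"].to_numpy(float)
    mv = df["majority_mean"].to_numpy(float)
    sb, sso, smv = (summarize_trials(x) for x in (b, so, mv))
    return Table2Summary(
        baseline_mean=sb.mean_f1,
        second_opinion_mean=sso.mean_f1,
        majority_mean=smv.mean_f1,
        baseline_ci=(sb.ci_low, sb.ci_high),
        second_opinion_ci=(sso.ci_low, sso.ci_high),
        majority_ci=(smv.ci_low, smv.ci_high),
        improvement_correlation=pearson(b, so - b),
        n_participants=len(df),
    )
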