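"""Independent correctness oracles for the decision protocols.

Two kinds of oracle validate the Monte-Carlo engine:

* closed-form expected response rates under the conditional-independence
  rater model (raters err independently given the true outcome), and
* exhaustive enumeration of every possible second-opinion / majority-vote
  outcome for tiny response matrices, with exact probabilities.

The conditional-independence assumption is a modelling choice on the oracle
side only, used for validation; the protocol engine itself never assumes it
and works on arbitrary recorded response matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HybridRates",
    "expected_second_opinion_rates",
    "expected_majority_rate",
    "plugin_macro_f1",
    "EnumeratedDistribution",
    "enumerate_second_opinion",
    "enumerate_majority_vote",
]


def _check_prob(name: str, v: float) -> float:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
    return float(v)


@dataclass(frozen=True)
class HybridRates:
    """Per-class response rates of a (possibly hybrid) decision process.

    ``rate_pos`` = P(final = 1 | truth = 1) and ``rate_neg`` =
    P(final = 1 | truth = 0); together with the prevalence these determine
    the expected confusion rates and hence the large-n macro-F1.
    """

    rate_pos: float
    rate_neg: float

    def __post_init__(self):
        _check_prob("rate_pos", self.rate_pos)
        _check_prob("rate_neg", self.rate_neg)


def expected_second_opinion_rates(
    sA: float, cA: float, sM: float, cM: float, sB: float, cB: float
) -> HybridRates:
    """Exact response rates of the second-opinion protocol under conditional
    independence.

    Primary rater A has sensitivity ``sA`` / specificity ``cA``, the hidden
    AI trigger ``sM``/``cM``, and the consulted second rater ``sB``/``cB``
    (for a heterogeneous pool use the arithmetic mean of the other raters'
    parameters — exact here because the final response is linear in B's
    response probability). On a truly positive case the final answer is 1
    when A and the AI both say 1, or when they disagree and B says 1:

        rate_pos = sA*sM + [sA(1-sM) + (1-sA)sM] * sB

    and symmetrically on a truly negative case

        rate_neg = (1-cA)(1-cM) + [(1-cA)cM + cA(1-cM)] * (1-cB).
    """
    for name, v in (("sA", sA), ("cA", cA), ("sM", sM), ("cM", cM),
                    ("sB", sB), ("cB", cB)):
        _check_prob(name, v)
    rate_pos = sA * sM + (sA * (1 - sM) + (1 - sA) * sM) * sB
    rate_neg = (1 - cA) * (1 - cM) + ((1 - cA) * cM + cA * (1 - cM)) * (1 - cB)
    return HybridRates(rate_pos=rate_pos, rate_neg=rate_neg)


def expected_majority_rate(a: float, b: float) -> float:
    """P(majority of three votes = 1) when the primary voter votes 1 with
    probability ``a`` and each of the two co-voters independently with
    probability ``b``: a·(1-(1-b)²) + (1-a)·b²."""
    _check_prob("a", a)
    _check_prob("b", b)
    return a * (1.0 - (1.0 - b) ** 2) + (1.0 - a) * b**2


def plugin_macro_f1(rates: HybridRates, prevalence: float, n: int = 1) -> float:
    """Macro-F1 evaluated on the *expected* confusion counts.

    With prevalence π, E[TP] = nπ·rate_pos, E[FP] = n(1-π)·rate_neg,
    E[FN] = nπ(1-rate_pos), E[TN] = n(1-π)(1-rate_neg). Because macro-F1 is
    scale-free in the counts the result is independent of ``n``; it is the
    large-n limit of the mean Monte-Carlo macro-F1, not the finite-n
    expectation (macro-F1 is a nonlinear function of the counts, so at small
    n the simulated mean carries an O(1/n) bias relative to this value).
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    pi = prevalence
    tp = n * pi * rates.rate_pos
    fp = n * (1 - pi) * rates.rate_neg
    fn = n * pi * (1 - rates.rate_pos)
    tn = n * (1 - pi) * (1 - rates.rate_neg)

    def f1(tp_, fp_, fn_):
        prec = tp_ / (tp_ + fp_) if tp_ + fp_ > 0 else 0.0
        rec = tp_ / (tp_ + fn_) if tp_ + fn_ > 0 else 0.0
        return 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0

    return 0.5 * (f1(tp, fp, fn) + f1(tn, fn, fp))


@dataclass(frozen=True)
class EnumeratedDistribution:
    """Exact outcome distribution of a protocol on one small matrix.

    ``outcomes`` maps each reachable final-prediction vector (as a tuple) to
    its probability; ``f1_values`` holds the macro-F1 of each outcome in the
    same order as ``outcomes`` iteration.
    """

    outcomes: dict[tuple[int, ...], float]
    f1_values: dict[tuple[int, ...], float]
    mean_f1: float


_MAX_ASSIGNMENTS = 10**6


def _enumerate(
    truth: np.ndarray,
    base: np.ndarray,
    open_cases: np.ndarray,
    n_choices: int,
    combine,
) -> EnumeratedDistribution:
    """Shared enumeration core: iterate the product of per-case choices,
    each of the ``n_choices`` options per open case being equally likely."""
    from .metrics import macro_f1

    outcomes: dict[tuple[int, ...], float] = {}
    k = len(open_cases)
    prob = (1.0 / n_choices) ** k
    for picks in itertools.product(range(n_choices), repeat=k):
        final = base.copy()
        for case, pick in zip(open_cases, picks):
            final[case] = combine(case, pick)
        key = tuple(int(v) for v in final)
        outcomes[key] = outcomes.get(key, 0.0) + prob
    f1s = {k_: macro_f1(np.array(k_), truth) for k_ in outcomes}
    mean = sum(p * f1s[k_] for k_, p in outcomes.items())
    return EnumeratedDistribution(outcomes=outcomes, f1_values=f1s, mean_f1=mean)


def enumerate_second_opinion(matrix, primary: str) -> EnumeratedDistribution:
    """Exact second-opinion outcome distribution by exhaustive enumeration.

    Every assignment of a second rater to each case where the primary
    disagrees with the AI is enumerated with probability (1/(|D|-1))^k.
    Only feasible for tiny instances: raises ``ValueError`` when the number
    of assignments (|D|-1)^k exceeds 10^6 — use the Monte-Carlo engine then.
    """
    a = matrix.rater_index(primary)
    m = matrix.n_raters - 1
    if m < 1:
        raise ValueError("second-opinion protocol needs at least 2 raters")
    others = [i for i in range(matrix.n_raters) if i != a]
    base = matrix.responses[:, a].copy()
    open_cases = np.flatnonzero(base != matrix.ai)
    if m ** len(open_cases) > _MAX_ASSIGNMENTS:
        raise ValueError(
            f"{m}^{len(open_cases)} assignments exceed the enumeration limit; "
            "use the Monte-Carlo engine for this instance"
        )
    def combine(case_row, pick):
        return matrix.responses[case_row, others[pick]]

    return _enumerate(matrix.truth, base, open_cases, m, combine)


def enumerate_majority_vote(matrix, primary: str) -> EnumeratedDistribution:
    """Exact majority-vote outcome distribution over all unordered co-voter
    pairs per case (each of the C(|D|-1, 2) pairs equally likely)."""
    a = matrix.rater_index(primary)
    if matrix.n_raters < 3:
        raise ValueError("majority vote needs at least 3 raters")
    others = [i for i in range(matrix.n_raters) if i != a]
    pairs = list(itertools.combinations(others, 2))
    base = matrix.responses[:, a].copy()
    open_cases = np.arange(matrix.n_cases)
    if len(pairs) ** matrix.n_cases > _MAX_ASSIGNMENTS:
        raise ValueError(
            f"{len(pairs)}^{matrix.n_cases} assignments exceed the enumeration "
            "limit; use the Monte-Carlo engine for this instance"
        )
    def combine(case_row, pick):
        i, j = pairs[pick]
        votes = base[case_row] + matrix.responses[case_row, i] + matrix.responses[case_row, j]
        return 1 if votes >= 2 else 0

    return _enumerate(matrix.truth, base, open_cases, len(pairs), combine)
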