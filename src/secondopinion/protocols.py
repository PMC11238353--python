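"""Decision protocols and the Monte-Carlo trial engine.

Three ways of turning a panel's recorded answers into final decisions:

* **baseline** — the primary rater's own answer stands;
* **second opinion** — a hidden AI prediction is compared with the primary
  rater's; on disagreement a second rater B, drawn uniformly from the rest
  of the panel, gives the final answer. The AI's prediction itself is never
  a final response — it only triggers the consultation;
* **majority vote** — every case is decided by the primary rater plus two
  additional raters drawn without replacement from the rest of the panel,
  majority of the three (no ties are possible).

Because the consulted raters are random, protocol performance is a
distribution; :func:`run_simulation` estimates it by repeated trials,
scoring each trial's final predictions with macro-F1 against the truth.

Seeding: one master seed; every (protocol, primary-rater) pair gets an
independent child stream via ``numpy`` seed-sequence spawning, and all of a
rater's trials are drawn from that stream in a fixed order. Adding raters or
protocols therefore never perturbs another rater's trial results, and a run
with fewer trials is a prefix of a longer run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import macro_f1_batch
from .synthetic import ResponseMatrix

__all__ = [
    "ProtocolResult",
    "ProtocolError",
    "second_opinion_trial",
    "majority_vote_trial",
    "run_simulation",
    "PROTOCOLS",
]

PROTOCOLS = ("second_opinion", "majority_vote")

_PROTOCOL_STREAM = {"second_opinion": 100, "majority_vote": 200}


class ProtocolError(RuntimeError):
    """Raised when a protocol's panel-size precondition is not met."""


@dataclass(frozen=True)
class ProtocolResult:
    """Outcome of one protocol trial for one primary rater.

    ``consulted[j]`` lists the ids of the additional raters used on case j
    (empty tuple where the primary's answer stood alone — for the
    second-opinion protocol, exactly the cases where primary and AI agreed).
    """

    primary_rater: str
    trial_index: int
    final_predictions: np.ndarray
    consulted: tuple[tuple[str, ...], ...]


def _others(matrix: ResponseMatrix, a: int) -> np.ndarray:
    return np.array([i for i in range(matrix.n_raters) if i != a], dtype=np.int64)


def second_opinion_trial(
    matrix: ResponseMatrix,
    primary: str,
    rng: np.random.Generator,
    trial_index: int = 0,
    b_per_trial: bool = False,
) -> ProtocolResult:
    """Run one AI-triggered second-opinion trial.

    Where the primary rater agrees with the (hidden) AI their answer is
    final; elsewhere a second rater is drawn uniformly from the rest of the
    panel — independently per case by default, or once per trial with
    ``b_per_trial=True`` — and that rater's recorded answer becomes final.
    """
    a = matrix.rater_index(primary)
    if matrix.n_raters < 2:
        raise ProtocolError("second-opinion protocol needs at least 2 raters")
    others = _others(matrix, a)
    final = matrix.responses[:, a].copy()
    disagree = np.flatnonzero(final != matrix.ai)
    consulted: list[tuple[str, ...]] = [()] * matrix.n_cases
    if disagree.size:
        if b_per_trial:
            b_idx = np.full(disagree.size, rng.integers(others.size))
        else:
            b_idx = rng.integers(others.size, size=disagree.size)
        b = others[b_idx]
        final[disagree] = matrix.responses[disagree, b]
        for j, bi in zip(disagree, b):
            consulted[j] = (matrix.rater_ids[bi],)
    return ProtocolResult(
        primary_rater=primary,
        trial_index=trial_index,
        final_predictions=final,
        consulted=tuple(consulted),
    )


def majority_vote_trial(
    matrix: ResponseMatrix,
    primary: str,
    rng: np.random.Generator,
    trial_index: int = 0,
) -> ProtocolResult:
    """Run one majority-vote trial: each case decided by the primary rater
    plus two distinct co-voters drawn uniformly from the rest of the panel."""
    a = matrix.rater_index(primary)
    if matrix.n_raters < 3:
        raise ProtocolError("majority vote needs at least 3 raters")
    others = _others(matrix, a)
    m = others.size
    n = matrix.n_cases
    i1 = rng.integers(m, size=n)
    i2 = rng.integers(m - 1, size=n)
    i2 = i2 + (i2 >= i1)  # second voter distinct from the first
    v1 = matrix.responses[np.arange(n), others[i1]]
    v2 = matrix.responses[np.arange(n), others[i2]]
    final = ((matrix.responses[:, a] + v1 + v2) >= 2).astype(np.int64)
    consulted = tuple(
        (matrix.rater_ids[others[p]], matrix.rater_ids[others[q]])
        for p, q in zip(i1, i2)
    )
    return ProtocolResult(
        primary_rater=primary,
        trial_index=trial_index,
        final_predictions=final,
        consulted=consulted,
    )


def _rater_stream(seed: int, protocol: str, rater_idx: int) -> np.random.Generator:
    key = (_PROTOCOL_STREAM[protocol], rater_idx)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _simulate_second_opinion(
    matrix: ResponseMatrix, a: int, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    others = _others(matrix, a)
    base = matrix.responses[:, a]
    disagree = np.flatnonzero(base != matrix.ai)
    finals = np.broadcast_to(base, (n_trials, matrix.n_cases)).copy()
    if disagree.size:
        b_idx = rng.integers(others.size, size=(n_trials, disagree.size))
        finals[:, disagree] = matrix.responses[disagree, others[b_idx]]
    return finals


def _simulate_majority(
    matrix: ResponseMatrix, a: int, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    others = _others(matrix, a)
    m = others.size
    n = matrix.n_cases
    i1 = rng.integers(m, size=(n_trials, n))
    i2 = rng.integers(m - 1, size=(n_trials, n))
    i2 = i2 + (i2 >= i1)
    v1 = matrix.responses[np.arange(n)[None, :], others[i1]]
    v2 = matrix.responses[np.arange(n)[None, :], others[i2]]
    return ((matrix.responses[:, a][None, :] + v1 + v2) >= 2).astype(np.int64)


def run_simulation(
    matrix: ResponseMatrix,
    protocol: str,
    n_trials: int = 1000,
    seed: int = 0,
    primaries: tuple[str, ...] | None = None,
    case_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Monte-Carlo protocol simulation over the panel.

    For every rater in D as primary (or the subset ``primaries``), runs
    ``n_trials`` independent trials of ``protocol`` and scores each trial's
    final predictions with macro-F1 against the truth. Returns
    ``{rater_id: array of n_trials macro-F1 values}``.

    ``case_mask`` (boolean, n_cases × n_raters) optionally restricts each
    primary rater's *scored* case universe to their own reading subset —
    consultations still draw on the full panel's recorded answers.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    min_raters = 2 if protocol == "second_opinion" else 3
    if matrix.n_raters < min_raters:
        raise ProtocolError(
            f"{protocol} needs at least {min_raters} raters, got {matrix.n_raters}"
        )
    if case_mask is not None and case_mask.shape != (matrix.n_cases, matrix.n_raters):
        raise ValueError("case_mask must have shape (n_cases, n_raters)")
    ids = matrix.rater_ids if primaries is None else tuple(primaries)
    simulate = (
        _simulate_second_opinion if protocol == "second_opinion" else _simulate_majority
    )
    out: dict[str, np.ndarray] = {}
    for rid in ids:
        a = matrix.rater_index(rid)
        rng = _rater_stream(seed, protocol, a)
        finals = simulate(matrix, a, n_trials, rng)
        if case_mask is not None:
            scored = np.flatnonzero(case_mask[:, a])
            out[rid] = macro_f1_batch(finals[:, scored], matrix.truth[scored])
        else:
            out[rid] = macro_f1_batch(finals, matrix.truth)
    return out
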