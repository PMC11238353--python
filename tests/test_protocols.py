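"""Decision protocols and the Monte-Carlo engine: deterministic edge cases,
agreement with the exact enumeration oracle, and structural invariants."""

import numpy as np
import pytest

import secondopinion as so
from secondopinion import (
    ProtocolError,
    enumerate_majority_vote,
    enumerate_second_opinion,
    majority_vote_trial,
    run_simulation,
    second_opinion_trial,
)
from conftest import random_tiny_matrix


def make_matrix(truth, responses, ai):
    responses = np.asarray(responses)
    return so.ResponseMatrix(
        case_id=np.array([f"c{i}" for i in range(len(truth))], dtype=object),
        truth=np.asarray(truth),
        rater_ids=tuple(f"r{a}" for a in range(responses.shape[1])),
        responses=responses,
        ai=np.asarray(ai),
    )


class TestSecondOpinionTrial:
    def test_full_agreement_keeps_primary_answers(self):
        m = make_matrix([1, 0, 1], [[1, 0], [0, 1], [1, 1]], ai=[1, 0, 1])
        res = second_opinion_trial(m, "r0", np.random.default_rng(0))
        assert np.array_equal(res.final_predictions, m.responses[:, 0])
        assert all(c == () for c in res.consulted)

    def test_homogeneous_pool_echoes_primary(self):
        # every rater identical, AI disagrees everywhere: B always echoes A
        resp = np.tile([[1], [0], [1], [0]], (1, 4))
        m = make_matrix([1, 0, 0, 1], resp, ai=[0, 1, 0, 1])
        res = second_opinion_trial(m, "r0", np.random.default_rng(1))
        assert np.array_equal(res.final_predictions, resp[:, 0])
        # consulted exactly where primary and AI disagreed
        disagree = resp[:, 0] != m.ai
        assert [len(c) > 0 for c in res.consulted] == disagree.tolist()

    def test_single_rater_pool_rejected(self):
        m = make_matrix([1, 0], [[1], [0]], ai=[0, 1])
        with pytest.raises(ProtocolError):
            second_opinion_trial(m, "r0", np.random.default_rng(0))

    def test_ai_value_never_final(self):
        """Hidden-AI invariant: the final response per case is always drawn
        from the panel's recorded answers, never from the AI vector."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = random_tiny_matrix(rng)
            res = second_opinion_trial(m, m.rater_ids[0], rng)
            for j in range(m.n_cases):
                assert res.final_predictions[j] in set(m.responses[j, :])
        # pointed version: unanimous panel, AI opposite -> panel answer stands
        resp = np.ones((5, 3), dtype=int)
        m = make_matrix([1, 1, 0, 0, 1], resp, ai=[0] * 5)
        res = second_opinion_trial(m, "r0", np.random.default_rng(3))
        assert res.final_predictions.tolist() == [1] * 5


class TestMajorityVoteTrial:
    def test_unanimous_panel(self):
        resp = np.tile([[1], [0], [1]], (1, 5))
        m = make_matrix([1, 0, 1], resp, ai=[0, 0, 0])
        res = majority_vote_trial(m, "r0", np.random.default_rng(0))
        assert np.array_equal(res.final_predictions, resp[:, 0])

    def test_two_versus_one_forced_outcome(self):
        # primary always correct, both co-voters always wrong
        truth = np.array([1, 0, 1, 0])
        resp = np.column_stack([truth, 1 - truth, 1 - truth])
        m = make_matrix(truth, resp, ai=[0, 0, 0, 0])
        res = majority_vote_trial(m, "r0", np.random.default_rng(0))
        assert np.array_equal(res.final_predictions, 1 - truth)
        assert all(len(c) == 2 for c in res.consulted)

    def test_co_voters_distinct_and_exclude_primary(self):
        rng = np.random.default_rng(5)
        m = random_tiny_matrix(rng, n_cases=6, n_raters=4)
        res = majority_vote_trial(m, "r1", rng)
        for pair in res.consulted:
            assert len(set(pair)) == 2 and "r1" not in pair

    def test_pool_too_small_rejected(self):
        m = make_matrix([1, 0], [[1, 0], [0, 1]], ai=[0, 0])
        with pytest.raises(ProtocolError):
            majority_vote_trial(m, "r0", np.random.default_rng(0))


class TestRunSimulation:
    def test_unknown_protocol(self, study):
        _, matrix = study
        with pytest.raises(ValueError, match="unknown protocol"):
            run_simulation(matrix, "coin_flip", 1)

    def test_single_trial_with_agreeing_ai_equals_baseline(self):
        rng = np.random.default_rng(11)
        m = random_tiny_matrix(rng, n_cases=6, n_raters=3)
        m2 = so.ResponseMatrix(
            case_id=m.case_id, truth=m.truth, rater_ids=m.rater_ids,
            responses=m.responses, ai=m.responses[:, 1].copy(),
        )
        (f1,) = run_simulation(m2, "second_opinion", 1, seed=0, primaries=("r1",))["r1"]
        assert f1 == pytest.approx(m2.baseline_f1("r1"))

    def test_agreement_identity_across_trials(self, study):
        """AI identical to the primary's answers => hybrid == baseline in
        every trial."""
        _, matrix = study
        rid = matrix.rater_ids[3]
        m2 = so.ResponseMatrix(
            case_id=matrix.case_id, truth=matrix.truth, rater_ids=matrix.rater_ids,
            responses=matrix.responses, ai=matrix.column(rid).copy(),
        )
        f1s = run_simulation(m2, "second_opinion", 50, seed=2, primaries=(rid,))[rid]
        assert np.allclose(f1s, m2.baseline_f1(rid))

    def test_seed_determinism_and_trial_prefix(self, study):
        _, matrix = study
        rid = matrix.rater_ids[0]
        a = run_simulation(matrix, "second_opinion", 200, seed=3, primaries=(rid,))[rid]
        b = run_simulation(matrix, "second_opinion", 200, seed=3, primaries=(rid,))[rid]
        c = run_simulation(matrix, "second_opinion", 100, seed=3, primaries=(rid,))[rid]
        assert np.array_equal(a, b)
        assert np.array_equal(a[:100], c)

    def test_adding_raters_does_not_perturb_existing_streams(self, study):
        _, matrix = study
        rid = matrix.rater_ids[2]
        full = run_simulation(matrix, "second_opinion", 100, seed=4)[rid]
        alone = run_simulation(matrix, "second_opinion", 100, seed=4, primaries=(rid,))[rid]
        assert np.array_equal(full, alone)

    @pytest.mark.parametrize("protocol", ["second_opinion", "majority_vote"])
    def test_engine_matches_enumeration_oracle(self, protocol):
        """Monte-Carlo mean macro-F1 vs exhaustive enumeration on a fixed
        small matrix, within 3 standard errors."""
        rng = np.random.default_rng(99)
        m = random_tiny_matrix(rng, n_cases=4, n_raters=3)
        enum = (
            enumerate_second_opinion if protocol == "second_opinion"
            else enumerate_majority_vote
        )(m, "r0")
        f1s = run_simulation(m, protocol, 10_000, seed=17, primaries=("r0",))["r0"]
        se = f1s.std(ddof=1) / np.sqrt(f1s.size)
        assert abs(f1s.mean() - enum.mean_f1) <= max(3 * se, 1e-12)

    def test_per_case_final_frequencies_match_enumeration(self):
        """Distribution check: per-case frequency of final=1 over 10^4 trials
        vs the exact enumeration probabilities, within 3 binomial SE."""
        rng = np.random.default_rng(7)
        m = random_tiny_matrix(rng, n_cases=4, n_raters=3)
        dist = enumerate_second_opinion(m, "r0")
        exact = np.zeros(m.n_cases)
        for final, p in dist.outcomes.items():
            exact += p * np.array(final)
        n_trials = 10_000
        counts = np.zeros(m.n_cases)
        trial_rng = np.random.default_rng(8)
        for t in range(n_trials):
            counts += second_opinion_trial(m, "r0", trial_rng, t).final_predictions
        freq = counts / n_trials
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n_trials)
        assert (np.abs(freq - exact) <= 3 * se + 1e-9).all()

    def test_case_mask_restricts_scoring_universe(self, study):
        _, matrix = study
        rid = matrix.rater_ids[0]
        mask = so.readings_mask(matrix.n_cases, matrix.n_raters, 100, seed=5)
        masked = run_simulation(
            matrix, "second_opinion", 20, seed=6, primaries=(rid,), case_mask=mask
        )[rid]
        full = run_simulation(matrix, "second_opinion", 20, seed=6, primaries=(rid,))[rid]
        assert masked.shape == full.shape
        assert not np.allclose(masked, full)


class TestDirectionalBehaviour:
    def test_second_opinion_improves_calibrated_pool(self, study):
        """Study-shaped panel (pool F1 ~0.586, AI F1 ~0.71): the hybrid
        protocol's pool-mean F1 exceeds the baseline pool mean."""
        _, matrix = study
        res = run_simulation(matrix, "second_opinion", 300, seed=9)
        hybrid = np.mean([v.mean() for v in res.values()])
        baseline = np.mean([matrix.baseline_f1(r) for r in matrix.rater_ids])
        assert hybrid > baseline

    def test_better_ai_helps_more(self, study):
        """Perfect AI beats a balanced-accuracy-0.6 AI on the same panel."""
        cohort, matrix = study
        from dataclasses import replace

        perfect = replace(matrix, ai=matrix.truth.copy())
        weak_ai = so.generate_ai_predictions(
            cohort, so.RaterProfile("ai", 0.6, 0.6), seed=10
        )
        weak = replace(matrix, ai=weak_ai)
        f_perfect = np.mean(
            [v.mean() for v in run_simulation(perfect, "second_opinion", 300, seed=11).values()]
        )
        f_weak = np.mean(
            [v.mean() for v in run_simulation(weak, "second_opinion", 300, seed=11).values()]
        )
        assert f_perfect > f_weak

    def test_majority_vote_regresses_to_pool_mean(self, study):
        """Raters above the pool mean lose under majority vote, those below
        gain: the per-rater gain correlates negatively with baseline F1, the
        best rater loses and the worst gains."""
        _, matrix = study
        res = run_simulation(matrix, "majority_vote", 300, seed=12)
        base = np.array([matrix.baseline_f1(r) for r in matrix.rater_ids])
        gain = np.array([res[r].mean() for r in matrix.rater_ids]) - base
        assert so.pearson(base, gain) < -0.5
        assert gain[np.argmax(base)] < 0
        assert gain[np.argmin(base)] > 0
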