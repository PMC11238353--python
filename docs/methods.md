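# Methods

## The decision protocols

All three protocols act on a recorded response matrix: binary predictions
q<sub>J</sub><sup>A</sup> of every panel member A ∈ D on every case J, plus
one hidden AI prediction vector q<sup>AI</sup>. The protocols never
re-elicit answers; a consulted rater's recorded answer is taken as what they
would have said, which matches how the original reader experiment was run
(all answers were collected blind, before any arbitration).

- **Baseline** — the primary rater's answer is final.
- **Second opinion** — where q<sub>J</sub><sup>A</sup> =
  q<sub>J</sub><sup>AI</sup> the primary's answer is final; elsewhere a
  second rater B is drawn uniformly from D∖{A}, independently per case, and
  q<sub>J</sub><sup>B</sup> is final. The AI's value is never itself a
  final answer. A per-trial fixed-B variant (one B reused for all of a
  trial's consultations) exists behind the `b_per_trial` flag for study; the
  per-case draw is the default because the arbitration is defined case by
  case.
- **Majority vote** — every case is decided by the primary plus two
  co-voters drawn uniformly *without replacement* from D∖{A}; with three
  distinct voters no ties are possible. Drawing with replacement could
  duplicate a voter and silently turn the committee into two raters, so it
  is not offered.

Each (protocol, primary) pair is scored over `n_trials` Monte-Carlo trials
with macro-averaged F1 against the ground truth. Scoring treats both
classes equally: the F1 of the no-exposure class is computed by swapping
the class labels, and the two F1 values are averaged.

**Zero-division convention.** Precision or recall with an empty denominator
is 0, and a class F1 is 0 when precision + recall = 0. This keeps
degenerate trials scoreable. One consequence worth knowing: on a cohort
containing only one class, even perfect predictions score macro-F1 0.5 (the
absent class contributes 0), so "macro-F1 = 1 iff predictions equal truth"
holds only when both classes occur.

**Seeding.** One master seed; every (protocol, primary-rater) pair derives
an independent child stream by numpy seed-sequence spawning, and a rater's
trials are drawn from that stream in a fixed order. Consequences: results
are bit-reproducible, adding raters or protocols never perturbs another
rater's results, and a shorter run is a prefix of a longer one. Trials are
drawn in one vectorised block per rater rather than from per-trial
sub-streams; the block layout is part of the reproducibility contract.

## The synthetic study

No response data from the original experiment is available, so the
generator emulates its design:

| parameter | default | why |
|---|---|---|
| arm sizes (SW/NSE) | 142 / 148 | published cohort split |
| pulp exposures per arm | 24 / 42 | published outcome tallies |
| panel size | 25 | published reader panel |
| pool target macro-F1 | 0.586 | published student mean |
| AI target macro-F1 | 0.71 | published classifier score |
| rater heterogeneity (`spread`) | 0.06 | gives a baseline-F1 spread comparable to the published per-participant range (~0.48–0.67) |
| age | 18 + discretised lognormal, median 29, clipped at 89 | published median and range; right-skewed |
| preoperative pain | Bernoulli 103/290 | published prevalence |
| tooth class | multinomial 161/118/8/3 | published counts |
| female | Bernoulli 122/290 | published counts |

Outcome labels are assigned by **exact count per arm** (a random subset of
each arm of exactly the requested size), not by Bernoulli draws: the study's
outcome margins are fixed, and exact-count assignment reproduces them for
every seed. The published sources disagree internally about the exposure
tallies (24/42 in the cohort table vs 25/43 in the running text); the
defaults follow the table, and either is reachable through `StudyConfig`.

The published reading counts (2539 + 3624-2539 readings over 25 raters and
290 cases) imply each participant read a subset of the cohort; the subset
size is not derivable, so it is exposed as an explicit parameter
(`readings_mask`) rather than guessed, and the default simulation scores
all cases.

**Rater model.** Each rater answers 1 with probability equal to their
sensitivity on truly exposed cases, and 0 with probability equal to their
specificity otherwise, independently across cases and raters given the
truth. Real readers are *not* conditionally independent — hard cases are
hard for everyone — and that correlation is exactly what the high/low-
agreement stratification of the original study reflects. An optional shared
per-case difficulty (a latent normal shift on every rater's log-odds of
answering correctly, `difficulty_sd`) can induce such correlation; it
defaults off because no published quantity pins down its size. Consequence
for interpretation: with independent errors a consulted second reader is
more corrective than a real colleague would be, so the synthetic
second-opinion gains (~0.12 F1) overshoot the real ones (~0.06), and the
improvement-vs-baseline correlation is more strongly negative. Passing
tests therefore demonstrate directional and structural behaviour, not real-
data magnitudes — which is also why only directions are asserted.

**Pool calibration.** `calibrate_pool` draws per-rater sensitivity and
specificity offsets once from the seed, then finds a common operating level
by bisection so that the pool's expected macro-F1 — the plug-in score on
expected confusion rates at the cohort's prevalence — hits the target.
The plug-in is the large-n limit of the mean simulated macro-F1; at n = 290
the finite-n bias is well inside the default 0.02 tolerance. Unreachable
targets (outside the range spanned by operating levels 0.5–1.0, or any
target below ~0.4 at the study prevalence) raise `CalibrationError` with
the reachable range. A target of exactly 1.0 short-circuits to perfect
raters.

## Oracles

Two independent routes validate the Monte-Carlo engine:

1. **Closed form.** Under conditional independence the hybrid protocol's
   per-class response rates factor into the agreement and disagreement
   branches (formulas in the README); the plug-in macro-F1 converts rates
   into the large-n score. For a heterogeneous pool the consulted rater's
   parameters are the arithmetic mean over D∖{A} — exact, because the final
   response is linear in B's response probability.
2. **Exhaustive enumeration.** For tiny matrices every assignment of second
   raters to disagreement cases (or co-voter pairs to cases) is enumerated
   with its exact probability, giving the exact outcome distribution and
   mean macro-F1. Enumeration refuses instances above 10<sup>6</sup>
   assignments and points to the engine instead.

The engine is required to agree with enumeration within 3 Monte-Carlo
standard errors on random tiny instances, and the closed-form rates with a
10<sup>6</sup>-draw direct simulation within 0.01.

## Inference

Confidence intervals use the Student-t quantile with n−1 degrees of
freedom on the sample at hand. This choice reproduces the published
baseline-column interval (0.567, 0.605) from the 25 per-participant values,
which is how it was validated. Protocol comparisons operate on per-rater
mean F1 (n = 25 pairs, paired by participant), not on individual trials:
trials within a rater share a response matrix and are not independent
replicates of the participant-level question. All tests are two-sided at
α = 0.05 with Bonferroni correction over the number of pairwise
comparisons; a pair with identically zero differences is reported
degenerate with p = 1. Pearson correlation refuses constant input rather
than returning NaN.

For the high/low-agreement contrast, age uses a Welch two-sample t-test
and the categorical shares (female, arm, pain) and per-group AI accuracy
use a two-sided pooled two-proportion z-test — the published analysis
names only "Student's t-test", so the proportion-test choice is ours.
High agreement is *strictly* more than 70% of the panel matching the AI.

Decision-switch fractions are reported over the consulted cases by
default; the alternative denominator (cases initially called exposures) is
selectable because published switch rates are quotable against either
base. Under the consulted denominator, correct + incorrect ≤ altered holds
by construction.

## Problem sizes and numerical choices

The shipped simulations use the study's own sizes — 290 cases, 25 raters,
1000 trials per rater and protocol — which run in about a second thanks to
the vectorised engine; the engine-vs-oracle checks use 10<sup>5</sup>
trials on ≤6-case matrices and the rate checks 10<sup>6</sup> draws.
Bisection in the calibrator runs 60 halvings (level resolution ~10⁻¹⁸,
far below the 0.02 tolerance). The sensitivity sweep draws a fresh AI
vector per target from a target-indexed sub-seed, so sweeps are
reproducible and extendable without re-randomising earlier targets;
balanced-accuracy targets below 0.5 (worse than chance) are rejected.

## Known limitations

- Conditionally independent raters overstate second-opinion benefit
  relative to correlated human panels (see above); the difficulty effect is
  provided but uncalibrated.
- The AI is a (sensitivity, specificity) process, not an image model; no
  radiographs are synthesised or read.
- The enumeration oracle is exponential by design and only serves tiny
  instances.
- Covariates are generated independently of the outcome and of each other;
  they carry no planted signal unless a test plants one, so
  `compare_groups` on default synthetic data should find nothing.
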