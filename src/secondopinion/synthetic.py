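"""Synthetic cohorts and rater panels for the pulp-exposure study design.

The real study — 290 deep-caries patients randomised 1:1 between stepwise
excavation (SW, two visits) and non-selective excavation (NSE, one visit),
read by a panel of 25 dental students plus a hidden AI classifier — released
no response data, so every downstream stage of this package is exercised on
synthetic data with the same statistical structure:

* a :class:`Cohort` with *exact* per-arm pulp-exposure counts (the study's
  fixed margins: 24 exposures among 142 SW cases, 42 among 148 NSE cases)
  and covariates drawn from distributions matched to the published cohort
  composition;
* a panel of simulated raters, each a :class:`RaterProfile` with its own
  sensitivity/specificity, answering each case independently given the true
  outcome;
* an AI rater modelled the same way, so its operating point can be dialled
  for sensitivity sweeps.

:func:`calibrate_pool` searches sensitivity/specificity space so the panel's
mean macro-F1 matches a target (e.g. the students' published 0.586), which is
how study-shaped response matrices are produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import macro_f1
from .oracle import plugin_macro_f1, HybridRates

__all__ = [
    "Cohort",
    "RaterProfile",
    "ResponseMatrix",
    "CovariateConfig",
    "generate_cohort",
    "generate_rater_responses",
    "generate_ai_predictions",
    "calibrate_pool",
    "CalibrationError",
    "readings_mask",
    "write_study_csv",
    "read_study_csv",
    "StudyConfig",
    "generate_study",
]

ARMS = ("SW", "NSE")
TOOTH_CLASSES = ("molar", "premolar", "incisor", "canine")


class CalibrationError(RuntimeError):
    """Raised when no sensitivity/specificity pool can reach the target F1."""


@dataclass(frozen=True)
class CovariateConfig:
    """Distribution parameters for the simulated patient covariates.

    Defaults match the published cohort composition: median age 29 within
    18-89 (right-skewed), 103/290 with mild/moderate preoperative pain,
    tooth classes 161/118/8/3 (molar/premolar/incisor/canine) and 122/290
    female patients.
    """

    age_median: float = 29.0
    age_log_sd: float = 0.8
    age_min: int = 18
    age_max: int = 89
    pain_prob: float = 103 / 290
    tooth_probs: tuple[float, ...] = (161 / 290, 118 / 290, 8 / 290, 3 / 290)
    female_prob: float = 122 / 290


@dataclass(frozen=True)
class RaterProfile:
    """A simulated rater: answers 1 with probability ``sensitivity`` on truly
    exposed cases and 0 with probability ``specificity`` on unexposed ones."""

    rater_id: str
    sensitivity: float
    specificity: float

    def __post_init__(self):
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class Cohort:
    """A simulated patient population with ground-truth outcomes."""

    case_id: np.ndarray  # str
    truth: np.ndarray  # 0/1, 1 = pulp exposure
    arm: np.ndarray  # "SW" / "NSE"
    age: np.ndarray  # int years
    pain: np.ndarray  # 0/1 preoperative pain
    tooth_class: np.ndarray  # str
    female: np.ndarray  # 0/1

    @property
    def n_cases(self) -> int:
        return self.case_id.size

    @property
    def prevalence(self) -> float:
        return float(self.truth.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": self.case_id,
                "truth": self.truth,
                "arm": self.arm,
                "age": self.age,
                "pain": self.pain,
                "tooth_class": self.tooth_class,
                "female": self.female,
            }
        )


@dataclass(frozen=True)
class ResponseMatrix:
    """Binary predictions of every rater in the panel D plus the hidden AI.

    ``responses[j, a]`` is rater ``a``'s prediction for case ``j``; ``ai[j]``
    is the AI's. The AI is *not* a member of D: its predictions only ever
    trigger second opinions, they are never final responses.
    """

    case_id: np.ndarray
    truth: np.ndarray
    rater_ids: tuple[str, ...]
    responses: np.ndarray  # (n_cases, n_raters) in {0,1}
    ai: np.ndarray  # (n_cases,) in {0,1}

    def __post_init__(self):
        n, m = self.responses.shape
        if n != self.case_id.size or m != len(self.rater_ids):
            raise ValueError("responses shape inconsistent with cases/raters")
        if self.ai.shape != (n,):
            raise ValueError("ai vector length must equal the case count")
        for arr, name in ((self.responses, "responses"), (self.ai, "ai")):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must contain only 0/1 values")

    @property
    def n_cases(self) -> int:
        return self.case_id.size

    @property
    def n_raters(self) -> int:
        return len(self.rater_ids)

    def rater_index(self, rater_id: str) -> int:
        try:
            return self.rater_ids.index(rater_id)
        except ValueError:
            raise KeyError(f"unknown rater {rater_id!r}") from None

    def column(self, rater_id: str) -> np.ndarray:
        return self.responses[:, self.rater_index(rater_id)]

    def baseline_f1(self, rater_id: str) -> float:
        return macro_f1(self.column(rater_id), self.truth)


# ---------------------------------------------------------------------------
# generation


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_cohort(
    n_sw: int,
    n_nse: int,
    exposures_sw: int,
    exposures_nse: int,
    covariates: CovariateConfig | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a two-arm cohort with exact per-arm exposure counts.

    Exposure labels are assigned by exact count per arm (a random subset of
    each arm's cases of the requested size) rather than by Bernoulli draws:
    this reproduces the study's fixed outcome margins for every seed.
    """
    if exposures_sw > n_sw or exposures_nse > n_nse:
        raise ValueError("exposure count cannot exceed its arm size")
    if min(n_sw, n_nse, exposures_sw, exposures_nse) < 0:
        raise ValueError("counts must be non-negative")
    cov = covariates or CovariateConfig()
    rng = _rng(seed, 0)

    n = n_sw + n_nse
    arm = np.array(["SW"] * n_sw + ["NSE"] * n_nse, dtype=object)
    truth = np.zeros(n, dtype=np.int64)
    truth[rng.choice(n_sw, size=exposures_sw, replace=False)] = 1
    truth[n_sw + rng.choice(n_nse, size=exposures_nse, replace=False)] = 1

    # age: shifted discretised lognormal, median = age_median, clipped to range
    mu = np.log(cov.age_median - cov.age_min + 1)
    raw = cov.age_min - 1 + np.exp(rng.normal(mu, cov.age_log_sd, size=n))
    age = np.clip(np.floor(raw), cov.age_min, cov.age_max).astype(np.int64)

    pain = (rng.random(n) < cov.pain_prob).astype(np.int64)
    tooth = rng.choice(TOOTH_CLASSES, size=n, p=np.asarray(cov.tooth_probs))
    female = (rng.random(n) < cov.female_prob).astype(np.int64)

    case_id = np.array([f"case{i:04d}" for i in range(n)], dtype=object)
    order = rng.permutation(n)  # interleave the arms
    return Cohort(
        case_id=case_id,
        truth=truth[order],
        arm=arm[order],
        age=age[order],
        pain=pain[order],
        tooth_class=np.asarray(tooth, dtype=object)[order],
        female=female[order],
    )


def _simulate_responses(
    truth: np.ndarray,
    sens: np.ndarray,
    spec: np.ndarray,
    rng: np.random.Generator,
    difficulty_sd: float = 0.0,
) -> np.ndarray:
    """Draw a (n_cases, n_raters) response matrix given truth.

    Raters are conditionally independent given the true outcome. With
    ``difficulty_sd > 0`` a per-case latent difficulty, shared across raters,
    shifts every rater's log-odds of answering correctly — an optional
    mechanism for the case-level difficulty the high/low-agreement analysis
    implies; it defaults off.
    """
    n = truth.size
    m = sens.size
    p_correct = np.where(truth[:, None] == 1, sens[None, :], spec[None, :])
    if difficulty_sd > 0:
        shift = rng.normal(0.0, difficulty_sd, size=n)[:, None]
        eps = 1e-12
        logit = np.log(p_correct + eps) - np.log1p(-p_correct + eps)
        p_correct = 1.0 / (1.0 + np.exp(-(logit - shift)))
    correct = rng.random((n, m)) < p_correct
    return np.where(correct, truth[:, None], 1 - truth[:, None]).astype(np.int64)


def generate_rater_responses(
    cohort: Cohort,
    profiles: Sequence[RaterProfile],
    seed: int = 0,
    difficulty_sd: float = 0.0,
    ai_profile: RaterProfile | None = None,
    ai_seed_offset: int = 10_000,
) -> ResponseMatrix:
    """Simulate the panel's answers (and optionally the AI's) for a cohort."""
    if not profiles:
        raise ValueError("at least one rater profile is required")
    if cohort.n_cases == 0:
        raise ValueError("cohort is empty")
    sens = np.array([p.sensitivity for p in profiles])
    spec = np.array([p.specificity for p in profiles])
    responses = _simulate_responses(
        cohort.truth, sens, spec, _rng(seed, 1), difficulty_sd
    )
    if ai_profile is not None:
        ai = generate_ai_predictions(cohort, ai_profile, seed=seed + ai_seed_offset)
    else:
        ai = np.zeros(cohort.n_cases, dtype=np.int64)
    return ResponseMatrix(
        case_id=cohort.case_id,
        truth=cohort.truth,
        rater_ids=tuple(p.rater_id for p in profiles),
        responses=responses,
        ai=ai,
    )


def generate_ai_predictions(
    cohort: Cohort, ai_profile: RaterProfile, seed: int = 0
) -> np.ndarray:
    """Simulate the hidden AI's predictions from its sensitivity/specificity.

    ``RaterProfile("ai", 1.0, 1.0)`` yields predictions identical to the
    truth — the perfect-classifier ceiling experiment.
    """
    if cohort.n_cases == 0:
        raise ValueError("cohort is empty")
    out = _simulate_responses(
        cohort.truth,
        np.array([ai_profile.sensitivity]),
        np.array([ai_profile.specificity]),
        _rng(seed, 2),
    )
    return out[:, 0]


def readings_mask(
    n_cases: int, n_raters: int, readings_per_rater: int, seed: int = 0
) -> np.ndarray:
    """Boolean (n_cases, n_raters) mask selecting each rater's case load.

    The published reading counts imply each participant read a subset of the
    cohort rather than all cases; the subset size is therefore an explicit
    parameter here. Each rater's subset is drawn uniformly without
    replacement, independently across raters.
    """
    if not 1 <= readings_per_rater <= n_cases:
        raise ValueError("readings_per_rater must be in [1, n_cases]")
    rng = _rng(seed, 3)
    mask = np.zeros((n_cases, n_raters), dtype=bool)
    for a in range(n_raters):
        mask[rng.choice(n_cases, size=readings_per_rater, replace=False), a] = True
    return mask


# ---------------------------------------------------------------------------
# pool calibration


def _expected_pool_f1(
    sens: np.ndarray, spec: np.ndarray, prevalence: float
) -> float:
    rates = [HybridRates(rate_pos=s, rate_neg=1.0 - c) for s, c in zip(sens, spec)]
    return float(np.mean([plugin_macro_f1(r, prevalence) for r in rates]))


def calibrate_pool(
    target_mean_f1: float,
    n_raters: int,
    cohort: Cohort,
    seed: int = 0,
    spread: float = 0.06,
    tolerance: float = 0.02,
) -> list[RaterProfile]:
    """Find rater profiles whose pool-mean macro-F1 matches a target.

    Procedure: per-rater sensitivity/specificity offsets (heterogeneity of
    scale ``spread``) are drawn once from the seed, then a common operating
    level is found by coarse grid search plus bisection so that the pool's
    expected macro-F1 — the large-n confusion-rate plug-in evaluated at the
    cohort's prevalence — hits ``target_mean_f1``. A pool whose expected F1
    cannot be brought within ``tolerance`` of the target at the cohort's
    prevalence raises :class:`CalibrationError` (e.g. very low targets are
    unreachable because even a coin-flip rater scores well above them on a
    balanced class mix).

    ``target_mean_f1 == 1.0`` short-circuits to perfect profiles.
    """
    if not 0.0 < target_mean_f1 <= 1.0:
        raise ValueError("target_mean_f1 must be in (0, 1]")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    ids = [f"rater{a:02d}" for a in range(n_raters)]
    if target_mean_f1 == 1.0:
        return [RaterProfile(i, 1.0, 1.0) for i in ids]

    pi = cohort.prevalence
    if not 0.0 < pi < 1.0:
        raise CalibrationError(
            f"cohort prevalence {pi} is degenerate; macro-F1 targets other than "
            "1.0 cannot be calibrated with a single-class cohort"
        )
    rng = _rng(seed, 4)
    d_sens = rng.normal(0.0, spread, size=n_raters)
    d_spec = rng.normal(0.0, spread, size=n_raters)

    def pool_f1(level: float) -> float:
        sens = np.clip(level + d_sens, 0.0, 1.0)
        spec = np.clip(level + d_spec, 0.0, 1.0)
        return _expected_pool_f1(sens, spec, pi)

    # expected pool F1 is monotone increasing in the common level
    lo, hi = 0.5, 1.0
    f_lo, f_hi = pool_f1(lo), pool_f1(hi)
    if not f_lo - tolerance <= target_mean_f1 <= f_hi + tolerance:
        raise CalibrationError(
            f"target {target_mean_f1:.3f} outside reachable pool-F1 range "
            f"[{f_lo:.3f}, {f_hi:.3f}] at prevalence {pi:.3f}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if pool_f1(mid) < target_mean_f1:
            lo = mid
        else:
            hi = mid
    level = 0.5 * (lo + hi)
    achieved = pool_f1(level)
    if abs(achieved - target_mean_f1) > tolerance:
        raise CalibrationError(
            f"calibration stalled at pool F1 {achieved:.3f} for target "
            f"{target_mean_f1:.3f}"
        )
    sens = np.clip(level + d_sens, 0.0, 1.0)
    spec = np.clip(level + d_spec, 0.0, 1.0)
    return [RaterProfile(i, float(s), float(c)) for i, s, c in zip(ids, sens, spec)]


# ---------------------------------------------------------------------------
# serialization

_COHORT_COLS = ["case_id", "truth", "arm", "age", "pain", "tooth_class", "female"]


def write_study_csv(path, cohort: Cohort, matrix: ResponseMatrix | None = None) -> None:
    """Write a cohort (and optionally its response matrix) to a single CSV.

    Columns: case_id, truth, arm, age, pain, tooth_class, female, one
    ``rater_<id>`` column per panel member, and ``ai``.
    """
    df = cohort.to_frame()
    if matrix is not None:
        if not np.array_equal(matrix.case_id, cohort.case_id):
            raise ValueError("matrix and cohort case_ids do not match")
        for a, rid in enumerate(matrix.rater_ids):
            df[f"rater_{rid}"] = matrix.responses[:, a]
        df["ai"] = matrix.ai
    df.to_csv(path, index=False)


def read_study_csv(path) -> tuple[Cohort, ResponseMatrix | None]:
    """Read a study CSV written by :func:`write_study_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"study CSV is missing columns: {missing}")
    cohort = Cohort(
        case_id=df["case_id"].to_numpy(dtype=object),
        truth=df["truth"].to_numpy(dtype=np.int64),
        arm=df["arm"].to_numpy(dtype=object),
        age=df["age"].to_numpy(dtype=np.int64),
        pain=df["pain"].to_numpy(dtype=np.int64),
        tooth_class=df["tooth_class"].to_numpy(dtype=object),
        female=df["female"].to_numpy(dtype=np.int64),
    )
    rater_cols = [c for c in df.columns if c.startswith("rater_")]
    if not rater_cols or "ai" not in df.columns:
        return cohort, None
    matrix = ResponseMatrix(
        case_id=cohort.case_id,
        truth=cohort.truth,
        rater_ids=tuple(c[len("rater_"):] for c in rater_cols),
        responses=df[rater_cols].to_numpy(dtype=np.int64),
        ai=df["ai"].to_numpy(dtype=np.int64),
    )
    return cohort, matrix


@dataclass
class StudyConfig:
    """JSON-serialisable recipe for a full synthetic study.

    Defaults reproduce the published study design: 142/148 cases per arm with
    24/42 pulp exposures, a 25-student panel calibrated to pool-mean macro-F1
    0.586, and an AI rater calibrated to macro-F1 0.71.
    """

    n_sw: int = 142
    n_nse: int = 148
    exposures_sw: int = 24
    exposures_nse: int = 42
    n_raters: int = 25
    target_pool_f1: float = 0.586
    target_ai_f1: float = 0.71
    seed: int = 0
    difficulty_sd: float = 0.0
    covariates: CovariateConfig = field(default_factory=CovariateConfig)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "covariates"}
        d["covariates"] = vars(self.covariates) | {
            "tooth_probs": list(self.covariates.tooth_probs)
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        d = json.loads(text)
        cov = d.pop("covariates", None)
        if cov is not None:
            cov["tooth_probs"] = tuple(cov["tooth_probs"])
            d["covariates"] = CovariateConfig(**cov)
        return cls(**d)


def generate_study(config: StudyConfig | None = None) -> tuple[Cohort, ResponseMatrix]:
    """Generate a complete study-shaped cohort + response matrix.

    The panel is calibrated to ``target_pool_f1`` and the AI to
    ``target_ai_f1`` (as a single-rater pool with no heterogeneity) before
    responses are drawn.
    """
    cfg = config or StudyConfig()
    cohort = generate_cohort(
        cfg.n_sw, cfg.n_nse, cfg.exposures_sw, cfg.exposures_nse,
        cfg.covariates, seed=cfg.seed,
    )
    profiles = calibrate_pool(cfg.target_pool_f1, cfg.n_raters, cohort, seed=cfg.seed)
    ai_profile = calibrate_pool(
        cfg.target_ai_f1, 1, cohort, seed=cfg.seed + 1, spread=0.0
    )[0]
    ai_profile = RaterProfile("ai", ai_profile.sensitivity, ai_profile.specificity)
    matrix = generate_rater_responses(
        cohort, profiles, seed=cfg.seed, difficulty_sd=cfg.difficulty_sd,
        ai_profile=ai_profile,
    )
    return cohort, matrix
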