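"""Contextualisation statistics for deterministic pair classifiers.

F1 and accuracy from confusion counts, the analytic fair-coin expectation,
a Monte-Carlo random-choice baseline, chi-square goodness-of-fit against
chance, and one-sided paired t-tests of per-construction F1 vectors
against the random baseline.

The fair-coin analytics matter because F1 misbehaves on imbalanced data:
with n_c critical-occurred and n_b baseline-occurred pairs, a coin expects
the fractional confusion matrix (tp, fp, fn, tn) = (n_c/2, n_b/2, n_c/2,
n_b/2), whose F1 exceeds 0.5 whenever n_c > n_b.  The simulation makes the
sampling spread of that quantity visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy import stats as sps

from .classify import ConfusionMatrix
from .errors import DegenerateTestError, InvalidInputError, ValidationError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    sidedness: str  # "one" | "two"
    degenerate: bool = False


@dataclass(frozen=True)
class SimulationResult:
    """F1 distribution over repeated fair-coin classification runs."""

    construction: str
    n_reps: int
    f1_values: np.ndarray
    seed: int

    @property
    def median(self) -> float:
        return float(np.quantile(self.f1_values, 0.5))

    @property
    def q1(self) -> float:
        return float(np.quantile(self.f1_values, 0.25))

    @property
    def q3(self) -> float:
        return float(np.quantile(self.f1_values, 0.75))

    @property
    def mean(self) -> float:
        return float(np.mean(self.f1_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.f1_values, ddof=1))


def _check_counts(cm: ConfusionMatrix) -> None:
    for name in ("tp", "fp", "fn", "tn"):
        if getattr(cm, name) < 0:
            raise ValidationError(f"negative confusion count {name}")


def f1_from_confusion(cm: ConfusionMatrix) -> float:
    """F1 = 2PR/(P+R) with precision tp/(tp+fp), recall tp/(tp+fn).

    Any 0/0 sub-expression is taken as 0, so a classifier that never finds
    a true positive scores 0.  Fractional counts are accepted.
    """
    _check_counts(cm)
    if cm.total <= 0:
        raise InvalidInputError("confusion matrix is empty")
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def accuracy_from_confusion(cm: ConfusionMatrix) -> float:
    """(tp + tn) / total."""
    _check_counts(cm)
    if cm.total <= 0:
        raise InvalidInputError("confusion matrix is empty")
    return cm.n_correct / cm.total


def expected_fair_coin_confusion(n_critical: float, n_baseline: float) -> ConfusionMatrix:
    """Expected (fractional) confusion of a fair coin on given occurred counts.

    Half the critical-occurred pairs land as true positives and half as
    false negatives; likewise for baseline-occurred pairs as false
    positives / true negatives.
    """
    if n_critical < 0 or n_baseline < 0:
        raise ValidationError("occurred counts must be non-negative")
    if n_critical + n_baseline < 1:
        raise InvalidInputError("need at least one pair")
    return ConfusionMatrix(
        tp=n_critical / 2,
        fn=n_critical / 2,
        fp=n_baseline / 2,
        tn=n_baseline / 2,
        metric="fair_coin",
    )


def simulate_random_model(
    n_critical: int,
    n_baseline: int,
    n_reps: int = 1000,
    seed: int | None = None,
    construction: str = "",
) -> SimulationResult:
    """Monte-Carlo F1 distribution of a fair-coin classifier.

    Each repetition flips an independent fair coin for every pair (n_critical
    critical-occurred + n_baseline baseline-occurred), tabulates the confusion
    matrix, and records its F1.  Fully reproducible given the seed.
    """
    if n_reps < 1:
        raise InvalidInputError(f"n_reps must be >= 1, got {n_reps}")
    if n_critical < 0 or n_baseline < 0 or n_critical + n_baseline < 1:
        raise InvalidInputError("occurred counts must be >= 0 with a positive total")
    if seed is None:
        raise InvalidInputError("simulate_random_model requires an explicit seed")
    rng = np.random.default_rng(seed)
    tp = rng.binomial(n_critical, 0.5, size=n_reps).astype(float)
    fp = rng.binomial(n_baseline, 0.5, size=n_reps).astype(float)
    fn = n_critical - tp
    denom = 2 * tp + fp + fn  # == 2PR/(P+R) denominator, counts form
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return SimulationResult(
        construction=construction, n_reps=n_reps, f1_values=f1, seed=seed
    )


def simulated_confusion_means(sim_counts: tuple[int, int], n_reps: int, seed: int) -> ConfusionMatrix:
    """Mean tp/fp/fn/tn over fair-coin repetitions (for calibration checks)."""
    n_critical, n_baseline = sim_counts
    rng = np.random.default_rng(seed)
    tp = rng.binomial(n_critical, 0.5, size=n_reps).astype(float)
    fp = rng.binomial(n_baseline, 0.5, size=n_reps).astype(float)
    return ConfusionMatrix(
        tp=float(tp.mean()),
        fn=float(n_critical - tp.mean()),
        fp=float(fp.mean()),
        tn=float(n_baseline - fp.mean()),
        metric="fair_coin_mc",
    )


def chisq_vs_chance(n_correct: float, n_total: float) -> TestResult:
    """Goodness-of-fit of (correct, incorrect) against the 50/50 chance split.

    Pearson chi-square with expected counts (N/2, N/2), df = 1, no
    continuity correction; two-sided p from the chi-square distribution.
    """
    if n_total < 1:
        raise ValidationError(f"n_total must be >= 1, got {n_total}")
    if not (0 <= n_correct <= n_total):
        raise ValidationError(f"n_correct must lie in [0, {n_total}], got {n_correct}")
    expected = n_total / 2
    stat = (n_correct - expected) ** 2 / expected + ((n_total - n_correct) - expected) ** 2 / expected
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=float(stat), df=1, p_value=p, sidedness="two")


def paired_one_sided_t(
    model_f1: Sequence[float], random_f1: Sequence[float]
) -> TestResult:
    """One-sided paired t-test of model F1 > random-baseline F1.

    Input vectors hold one value per construction, paired positionally.
    All-zero differences are a degenerate no-signal case, reported with
    t = 0, p = 0.5; zero-variance but nonzero differences (infinite t)
    raise :class:`DegenerateTestError`.
    """
    model = np.asarray(model_f1, dtype=float)
    random = np.asarray(random_f1, dtype=float)
    if model.shape != random.shape or model.ndim != 1:
        raise InvalidInputError("model and random F1 vectors must be 1-d and equal length")
    n = model.size
    if n < 2:
        raise InvalidInputError("paired t-test needs at least 2 paired values")
    diffs = model - random
    if np.all(diffs == 0):
        return TestResult(statistic=0.0, df=n - 1, p_value=0.5, sidedness="one", degenerate=True)
    sd = float(np.std(diffs, ddof=1))
    if sd == 0:
        raise DegenerateTestError(
            f"differences are constant ({diffs[0]:+.6g}) with zero variance; "
            "t statistic is unbounded"
        )
    t = float(np.mean(diffs) / (sd / math.sqrt(n)))
    p = float(sps.t.sf(t, df=n - 1))
    return TestResult(statistic=t, df=n - 1, p_value=p, sidedness="one")
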