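"""Two-alternative forced-choice classification of sentence pairs.

Each hypothesis metric acts as a deterministic classifier: presented with
the two variants of a syntactic minimal pair — the *critical* variant
realising the phenomenon (e.g. raising, sluicing) and its canonical
*baseline* counterpart — it "predicts" that the variant with the lower
score is the one that actually occurred.  Tabulating predictions against
which variant really occurred gives a confusion matrix per construction,
with critical-occurrence as the positive class:

* TP — critical occurred, classifier preferred critical
* FN — critical occurred, classifier preferred baseline
* FP — baseline occurred, classifier preferred critical
* TN — baseline occurred, classifier preferred baseline

Exact ties (within 1e-9 bits) predict baseline and are flagged; counts
are stored as reals so analytic expectations (fair-coin half-counts) can
reuse the same container.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

from .errors import InvalidInputError, ValidationError
from .metrics import MetricConfig, score_profile
from .surprisal import SurprisalProfile

TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class SentencePair:
    """A critical/baseline variant pair plus which variant actually occurred."""

    pair_id: str
    construction: str
    critical: SurprisalProfile
    baseline: SurprisalProfile
    occurred: str  # "critical" | "baseline"

    def __post_init__(self) -> None:
        if self.occurred not in ("critical", "baseline"):
            raise ValidationError(
                f"pair {self.pair_id}: occurred must be 'critical' or 'baseline', "
                f"got {self.occurred!r}"
            )
        if self.critical.variant_role != "critical":
            raise ValidationError(
                f"pair {self.pair_id}: critical profile has role {self.critical.variant_role!r}"
            )
        if self.baseline.variant_role != "baseline":
            raise ValidationError(
                f"pair {self.pair_id}: baseline profile has role {self.baseline.variant_role!r}"
            )
        for prof in (self.critical, self.baseline):
            if prof.construction and prof.construction != self.construction:
                raise ValidationError(
                    f"pair {self.pair_id}: profile construction {prof.construction!r} "
                    f"does not match pair construction {self.construction!r}"
                )
        occ_flags = (self.critical.occurred, self.baseline.occurred)
        if occ_flags != (self.occurred == "critical", self.occurred == "baseline"):
            raise ValidationError(
                f"pair {self.pair_id}: profile occurred flags {occ_flags} conflict "
                f"with occurred={self.occurred!r}"
            )


@dataclass(frozen=True)
class Prediction:
    pair_id: str
    predicted: str  # "critical" | "baseline"
    tie: bool
    score_critical: float
    score_baseline: float


@dataclass
class ConfusionMatrix:
    """TP/FP/FN/TN counts; reals, so fractional analytic expectations fit too."""

    tp: float = 0.0
    fp: float = 0.0
    fn: float = 0.0
    tn: float = 0.0
    construction: str = ""
    metric: str = ""

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"confusion count {name} must be finite and >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_correct(self) -> float:
        return self.tp + self.tn

    def add(self, occurred: str, predicted: str, weight: float = 1.0) -> None:
        if occurred == "critical":
            if predicted == "critical":
                self.tp += weight
            else:
                self.fn += weight
        else:
            if predicted == "critical":
                self.fp += weight
            else:
                self.tn += weight


@dataclass
class MetricEvaluation:
    """Per-construction and pooled confusion matrices plus the raw predictions."""

    metric: str
    per_construction: dict[str, ConfusionMatrix] = field(default_factory=dict)
    pooled: ConfusionMatrix = field(default_factory=ConfusionMatrix)
    predictions: list[Prediction] = field(default_factory=list)


def classify_pair(pair: SentencePair, config: MetricConfig) -> Prediction:
    """Predict the occurred variant: the one with the strictly lower metric score.

    On an exact tie (within 1e-9 bits) the prediction defaults to baseline
    — conservative against the critical construction — and is flagged.
    """
    sc = score_profile(pair.critical, config).value
    sb = score_profile(pair.baseline, config).value
    tie = abs(sc - sb) <= TIE_TOLERANCE
    predicted = "critical" if (not tie and sc < sb) else "baseline"
    return Prediction(
        pair_id=pair.pair_id,
        predicted=predicted,
        tie=tie,
        score_critical=sc,
        score_baseline=sb,
    )


def evaluate_metric(pairs: Sequence[SentencePair], config: MetricConfig) -> MetricEvaluation:
    """Classify every pair and tabulate confusion counts per construction and pooled."""
    if len(pairs) == 0:
        raise InvalidInputError("evaluate_metric needs at least one pair")
    result = MetricEvaluation(metric=config.metric)
    result.pooled = ConfusionMatrix(construction="pooled", metric=config.metric)
    for pair in pairs:
        pred = classify_pair(pair, config)
        result.predictions.append(pred)
        cm = result.per_construction.setdefault(
            pair.construction,
            ConfusionMatrix(construction=pair.construction, metric=config.metric),
        )
        cm.add(pair.occurred, pred.predicted)
        result.pooled.add(pair.occurred, pred.predicted)
    return result


@dataclass(frozen=True)
class MajorityBaseline:
    """The frequency-majority predictor for one construction."""

    construction: str
    predicted: str
    n_critical: int
    n_baseline: int
    accuracy: float


def majority_predictions(
    pairs: Sequence[SentencePair],
) -> tuple[list[Prediction], dict[str, MajorityBaseline]]:
    """Majority-class baseline: always predict the construction's more frequent variant.

    A frequency tie predicts baseline, giving accuracy 0.5.  Returns the
    per-pair predictions and, per construction, the majority label with
    its accuracy max(n_critical, n_baseline) / N.
    """
    if len(pairs) == 0:
        raise InvalidInputError("majority_predictions needs at least one pair")
    counts: dict[str, list[int]] = {}
    for pair in pairs:
        c = counts.setdefault(pair.construction, [0, 0])
        c[0 if pair.occurred == "critical" else 1] += 1

    baselines: dict[str, MajorityBaseline] = {}
    for cons, (n_crit, n_base) in counts.items():
        predicted = "critical" if n_crit > n_base else "baseline"
        baselines[cons] = MajorityBaseline(
            construction=cons,
            predicted=predicted,
            n_critical=n_crit,
            n_baseline=n_base,
            accuracy=max(n_crit, n_base) / (n_crit + n_base),
        )

    predictions = [
        Prediction(
            pair_id=pair.pair_id,
            predicted=baselines[pair.construction].predicted,
            tie=False,
            score_critical=float("nan"),
            score_baseline=float("nan"),
        )
        for pair in pairs
    ]
    return predictions, baselines


def construction_counts(pairs: Iterable[SentencePair]) -> dict[str, tuple[int, int]]:
    """(n_critical_occurred, n_baseline_occurred) per construction."""
    counts: dict[str, list[int]] = {}
    for pair in pairs:
        c = counts.setdefault(pair.construction, [0, 0])
        c[0 if pair.occurred == "critical" else 1] += 1
    return {cons: (c[0], c[1]) for cons, c in counts.items()}
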