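"""The four information-density hypotheses as scores over a surprisal profile.

Each metric condenses a per-token surprisal sequence s(w_1..n) into a single
non-negative number, where *lower is better* (the preferred variant):

``delta_uid``
    Smoothness as the mean absolute difference between adjacent tokens,
    sum_{i=2..n} |s(w_i) - s(w_{i-1})| over the n-1 transitions.  Penalises
    local peaks and troughs, but tolerates gradual drift to extremes.

``mu_uid``
    Mean absolute deviation from the sequence's *own* mean surprisal.
    Prefers internally uniform signatures, even uniformly extreme ones.

``rtm``
    Regression to the mean: mean absolute deviation from a *global* mean
    word-surprisal (default 4.70 bits, within the 4-5 bits/word typically
    measured for human text).  Prefers sequences hugging the species-level
    information rate.

``low_ic``
    Low information content baseline: the plain mean surprisal.  Prefers
    the cheaper variant outright.

Normalisation (division by the number of transitions for ``delta_uid``,
by the number of tokens for ``mu_uid``/``rtm``) is on by default, which
makes scores comparable across sentences of different length; the raw
sums remain available with ``normalize=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import InvalidInputError
from .surprisal import SurprisalProfile

#: canonical metric names, in the conventional reporting order
METRIC_NAMES = ("delta_uid", "mu_uid", "rtm", "low_ic")

#: default global mean word surprisal in bits, used by the rtm metric
DEFAULT_GLOBAL_MEAN = 4.70


@dataclass(frozen=True)
class MetricConfig:
    """Which metric to run and with which knobs."""

    metric: str
    normalize: bool = True
    global_mean: float = DEFAULT_GLOBAL_MEAN

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise InvalidInputError(
                f"metric must be one of {METRIC_NAMES}, got {self.metric!r}"
            )
        if self.global_mean <= 0:
            raise InvalidInputError(f"global_mean must be > 0, got {self.global_mean}")


@dataclass(frozen=True)
class MetricScore:
    metric: str
    value: float
    n_tokens: int
    normalized: bool


def delta_uid(profile: SurprisalProfile, normalize: bool = True) -> MetricScore:
    """Sum (or mean, when normalised) of absolute adjacent surprisal differences.

    A single-token profile has no transitions; its fluctuation is defined
    as 0 and a degenerate-input warning is emitted.
    """
    s = profile.surprisal
    n = len(s)
    if n == 1:
        warnings.warn(
            f"{profile.sentence_id or 'profile'}: single token, no transitions; "
            "delta_uid defined as 0",
            stacklevel=2,
        )
        return MetricScore("delta_uid", 0.0, 1, normalize)
    total = sum(abs(s[i] - s[i - 1]) for i in range(1, n))
    value = total / (n - 1) if normalize else total
    return MetricScore("delta_uid", value, n, normalize)


def mu_uid(profile: SurprisalProfile, normalize: bool = True) -> MetricScore:
    """Sum (or mean) of absolute deviations from the profile's own mean."""
    s = profile.surprisal
    n = len(s)
    mean = sum(s) / n
    total = sum(abs(mean - x) for x in s)
    value = total / n if normalize else total
    return MetricScore("mu_uid", value, n, normalize)


def rtm_score(
    profile: SurprisalProfile,
    global_mean: float = DEFAULT_GLOBAL_MEAN,
    normalize: bool = True,
) -> MetricScore:
    """Sum (or mean) of absolute deviations from a global mean surprisal."""
    if global_mean <= 0:
        raise InvalidInputError(f"global_mean must be > 0, got {global_mean}")
    s = profile.surprisal
    n = len(s)
    total = sum(abs(global_mean - x) for x in s)
    value = total / n if normalize else total
    return MetricScore("rtm", value, n, normalize)


def low_ic(profile: SurprisalProfile) -> MetricScore:
    """Mean surprisal of the profile (already length-normalised by definition)."""
    s = profile.surprisal
    return MetricScore("low_ic", sum(s) / len(s), len(s), True)


def score_profile(profile: SurprisalProfile, config: MetricConfig) -> MetricScore:
    """Dispatch to the configured metric."""
    if config.metric == "delta_uid":
        return delta_uid(profile, config.normalize)
    if config.metric == "mu_uid":
        return mu_uid(profile, config.normalize)
    if config.metric == "rtm":
        return rtm_score(profile, config.global_mean, config.normalize)
    return low_ic(profile)
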