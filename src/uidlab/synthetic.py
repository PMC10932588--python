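"""Synthetic inputs for every pipeline stage: signatures, pair datasets, corpora.

Nothing here imitates natural language.  The generators produce the
*statistical shape* of the real inputs — per-token surprisal signatures
with controllable mean and fluctuation, labelled alternation-pair datasets
with controllable class balance and metric-occurrence association, and
Zipf-distributed token corpora for exercising the n-gram backend — so the
whole pipeline is testable without any downloaded data.

The key dial is ``discriminability``: the probability that a generated
pair's occurred variant is the one preferred by a designated generating
metric.  At 1.0 the generating metric classifies perfectly; at 0.5 the
occurred label is independent of the metric and every classifier is at
chance.  Measured accuracy of the generating metric's classifier is an
unbiased estimate of this dial, which is the module's core calibration
property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import SentencePair
from .errors import InvalidInputError
from .metrics import MetricConfig, score_profile
from .surprisal import Corpus, SurprisalProfile

SHAPES = ("flat", "ramp", "alternating", "spike")


@dataclass(frozen=True)
class SignatureSpec:
    """Recipe for one synthetic surprisal signature.

    ``amplitude`` controls the deterministic shape component (ramp span,
    alternation half-height, spike height) in bits; ``fluctuation`` is the
    SD of Gaussian token-level noise added on top.  Values are clipped at
    zero since surprisal is non-negative.
    """

    n_tokens: int
    mean: float = 4.70
    fluctuation: float = 0.0
    shape: str = "flat"
    amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tokens < 1:
            raise InvalidInputError(f"n_tokens must be >= 1, got {self.n_tokens}")
        if self.fluctuation < 0:
            raise InvalidInputError(f"fluctuation must be >= 0, got {self.fluctuation}")
        if self.shape not in SHAPES:
            raise InvalidInputError(f"shape must be one of {SHAPES}, got {self.shape!r}")


@dataclass(frozen=True)
class PairDatasetSpec:
    """Recipe for a labelled alternation-pair dataset.

    Occurred-variant counts are honoured exactly: n_critical pairs where
    the critical variant occurred and n_baseline where the baseline did,
    mirroring the per-construction bookkeeping of a real pair corpus.
    """

    construction: str
    n_critical: int
    n_baseline: int
    discriminability: float = 1.0
    length_range: tuple[int, int] = (10, 35)
    shape: str = "spike"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_critical < 0 or self.n_baseline < 0:
            raise InvalidInputError("occurred counts must be non-negative")
        if self.n_critical + self.n_baseline < 1:
            raise InvalidInputError("need at least one pair")
        if not (0.0 <= self.discriminability <= 1.0):
            raise InvalidInputError(
                f"discriminability must be in [0, 1], got {self.discriminability}"
            )
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise InvalidInputError(f"invalid length_range {self.length_range}")
        if self.shape not in SHAPES:
            raise InvalidInputError(f"shape must be one of {SHAPES}, got {self.shape!r}")


def _signature_values(
    rng: np.random.Generator,
    n: int,
    mean: float,
    fluctuation: float,
    shape: str,
    amplitude: float,
) -> np.ndarray:
    if shape == "flat":
        base = np.full(n, mean)
    elif shape == "ramp":
        base = np.linspace(mean - amplitude, mean + amplitude, n)
    elif shape == "alternating":
        base = mean + amplitude * np.where(np.arange(n) % 2 == 0, -1.0, 1.0)
    else:  # spike
        base = np.full(n, mean)
        base[n // 2] += amplitude
    if fluctuation > 0:
        base = base + rng.normal(0.0, fluctuation, size=n)
    return np.clip(base, 0.0, None)


def generate_signature(spec: SignatureSpec) -> SurprisalProfile:
    """Generate one seeded synthetic surprisal profile."""
    rng = np.random.default_rng(spec.seed)
    values = _signature_values(
        rng, spec.n_tokens, spec.mean, spec.fluctuation, spec.shape, spec.amplitude
    )
    return SurprisalProfile(
        sentence_id=f"sig-{spec.shape}-{spec.seed}",
        construction="synthetic",
        variant_role="critical",
        occurred=False,
        tokens=tuple(f"w{i}" for i in range(spec.n_tokens)),
        surprisal=tuple(float(v) for v in values),
    )


def generate_pair_dataset(
    spec: PairDatasetSpec, generating_metric: MetricConfig
) -> list[SentencePair]:
    """Generate a labelled pair dataset with a controlled metric-occurrence link.

    For each pair two signatures are drawn (random mean, amplitude, noise
    and length; shape per the spec) and scored under the generating
    metric; with probability ``discriminability`` the occurred variant is
    the metric-preferred (lower-scoring) one.  Score ties are redrawn so
    the preference is always well defined.
    """
    rng = np.random.default_rng(spec.seed)
    occurred_labels = ["critical"] * spec.n_critical + ["baseline"] * spec.n_baseline
    rng.shuffle(occurred_labels)
    lo, hi = spec.length_range

    pairs: list[SentencePair] = []
    for i, occurred in enumerate(occurred_labels):
        for _ in range(100):  # redraw on score ties
            drawn = []
            for _variant in range(2):
                n = int(rng.integers(lo, hi + 1))
                vals = _signature_values(
                    rng,
                    n,
                    mean=float(rng.uniform(3.0, 8.0)),
                    fluctuation=float(rng.uniform(0.5, 2.0)),
                    shape=spec.shape,
                    amplitude=float(rng.uniform(1.0, 5.0)),
                )
                drawn.append(vals)
            scores = [
                score_profile(_bare_profile(v), generating_metric).value for v in drawn
            ]
            if abs(scores[0] - scores[1]) > 1e-6:
                break
        else:  # pragma: no cover - virtually impossible with continuous draws
            raise RuntimeError("could not draw distinguishable signatures")

        preferred, other = (0, 1) if scores[0] < scores[1] else (1, 0)
        occurred_gets_preferred = rng.random() < spec.discriminability
        if occurred == "critical":
            crit_vals = drawn[preferred] if occurred_gets_preferred else drawn[other]
            base_vals = drawn[other] if occurred_gets_preferred else drawn[preferred]
        else:
            base_vals = drawn[preferred] if occurred_gets_preferred else drawn[other]
            crit_vals = drawn[other] if occurred_gets_preferred else drawn[preferred]

        pair_id = f"{spec.construction}-{i:04d}"
        pairs.append(
            SentencePair(
                pair_id=pair_id,
                construction=spec.construction,
                critical=_role_profile(pair_id, spec.construction, "critical",
                                       occurred == "critical", crit_vals),
                baseline=_role_profile(pair_id, spec.construction, "baseline",
                                       occurred == "baseline", base_vals),
                occurred=occurred,
            )
        )
    return pairs


def _bare_profile(values: np.ndarray) -> SurprisalProfile:
    return SurprisalProfile(
        sentence_id="tmp",
        construction="",
        variant_role="critical",
        occurred=False,
        tokens=tuple(f"w{i}" for i in range(len(values))),
        surprisal=tuple(float(v) for v in values),
    )


def _role_profile(
    pair_id: str, construction: str, role: str, occurred: bool, values: np.ndarray
) -> SurprisalProfile:
    return SurprisalProfile(
        sentence_id=pair_id,
        construction=construction,
        variant_role=role,
        occurred=occurred,
        tokens=tuple(f"w{i}" for i in range(len(values))),
        surprisal=tuple(float(v) for v in values),
    )


def generate_zipf_corpus(
    vocab_size: int,
    exponent: float = 1.0,
    n_sentences: int = 500,
    length_range: tuple[int, int] = (3, 12),
    seed: int = 0,
) -> Corpus:
    """Corpus whose token frequencies follow a Zipf rank distribution.

    P(rank r) proportional to r^-exponent over ``vocab_size`` types
    w001, w002, ...; sentence lengths uniform over ``length_range``.
    """
    if vocab_size < 2:
        raise InvalidInputError(f"vocab_size must be >= 2, got {vocab_size}")
    if exponent <= 0:
        raise InvalidInputError(f"exponent must be > 0, got {exponent}")
    if n_sentences < 1:
        raise InvalidInputError(f"n_sentences must be >= 1, got {n_sentences}")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise InvalidInputError(f"invalid length_range {length_range}")

    rng = np.random.default_rng(seed)
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    probs = ranks ** -exponent
    probs /= probs.sum()
    width = len(str(vocab_size))
    types = [f"w{r:0{width}d}" for r in range(1, vocab_size + 1)]

    sentences = []
    for _ in range(n_sentences):
        n = int(rng.integers(lo, hi + 1))
        idx = rng.choice(vocab_size, size=n, p=probs)
        sentences.append(tuple(types[j] for j in idx))
    return Corpus(sentences=tuple(sentences), label=f"zipf-{vocab_size}-{seed}")


def zipf_rank_probability(vocab_size: int, exponent: float, rank: int) -> float:
    """Analytic share of the given rank under the truncated Zipf law."""
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    probs = ranks ** -exponent
    return float(probs[rank - 1] / probs.sum())
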