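import pytest
from hypothesis import HealthCheck, settings

from uidlab import SentencePair, SurprisalProfile

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

# The tough-raising worked example: per-word surprisal in bits for the
# actually-occurred raised variant and its constructed unraised counterpart.
SEQ15_TOKENS = ("It", "is", "tough", "to", "score")
SEQ15_BITS = (5.33, 1.93, 7.47, 0.30, 8.14)
SEQ16_TOKENS = ("To", "score", "is", "tough")
SEQ16_BITS = (6.76, 9.48, 6.45, 9.72)


def make_profile(
    values,
    tokens=None,
    sentence_id="s",
    construction="",
    role="critical",
    occurred=False,
):
    values = tuple(float(v) for v in values)
    if tokens is None:
        tokens = tuple(f"w{i}" for i in range(len(values)))
    return SurprisalProfile(
        sentence_id=sentence_id,
        construction=construction,
        variant_role=role,
        occurred=occurred,
        tokens=tuple(tokens),
        surprisal=values,
    )


@pytest.fixture
def seq15():
    return make_profile(
        SEQ15_BITS, SEQ15_TOKENS, sentence_id="seq15",
        construction="tough-raising", role="critical", occurred=True,
    )


@pytest.fixture
def seq16():
    return make_profile(
        SEQ16_BITS, SEQ16_TOKENS, sentence_id="seq16",
        construction="tough-raising", role="baseline", occurred=False,
    )


@pytest.fixture
def tough_pair(seq15, seq16):
    """The worked-example pair: the raised (critical) variant occurred."""
    return SentencePair(
        pair_id="tough-0001",
        construction="tough-raising",
        critical=seq15,
        baseline=seq16,
        occurred="critical",
    )


def make_constant_pair(
    pair_id,
    construction,
    occurred,
    critical_level,
    baseline_level,
    n=4,
):
    """Pair of flat profiles at fixed surprisal levels; handy for forcing scores."""
    crit = make_profile(
        [critical_level] * n, sentence_id=pair_id, construction=construction,
        role="critical", occurred=occurred == "critical",
    )
    base = make_profile(
        [baseline_level] * n, sentence_id=pair_id, construction=construction,
        role="baseline", occurred=occurred == "baseline",
    )
    return SentencePair(
        pair_id=pair_id, construction=construction,
        critical=crit, baseline=base, occurred=occurred,
    )
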