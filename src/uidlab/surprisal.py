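"""Per-token surprisal profiles from an n-gram backend or precomputed tables.

Surprisal is the information-theoretic cost of a token in context,

    s(w_i) = -log2 P(w_i | w_{i-k+1} ... w_{i-1})        [bits]

The conditional probability comes either from an internally trained
order-``k`` n-gram model with add-k (Lidstone) or maximum-likelihood
estimation, or from an external table of precomputed per-token surprisal
values (the route used when surprisal is produced by a large language
model outside this package).  Downstream metrics are agnostic about the
backend: they only see a :class:`SurprisalProfile`.

Conventions
-----------
* log base 2 throughout; all surprisal values are in bits.
* Sentence starts are padded with ``order - 1`` BOS markers, so every
  visible word receives a surprisal value.
* An end-of-sentence event is counted at training time (it keeps the
  conditional distributions properly normalised) but is not scored by
  default, so a profile has exactly one value per visible token.
* Out-of-vocabulary tokens map to a single reserved UNK type that is
  added to the vocabulary at training time.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, InfiniteSurprisalError, InvalidInputError, ValidationError

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"

#: column order of the on-disk profile-table dialect (TSV, header row)
PROFILE_COLUMNS = (
    "sentence_id",
    "construction",
    "variant_role",
    "occurred",
    "position",
    "token",
    "surprisal_bits",
)


@dataclass(frozen=True)
class Corpus:
    """A tokenised training corpus: one token sequence per sentence."""

    sentences: tuple[tuple[str, ...], ...]
    label: str = "corpus"

    def __post_init__(self) -> None:
        if len(self.sentences) == 0:
            raise InvalidInputError("corpus must contain at least one sentence")
        for sent in self.sentences:
            if len(sent) == 0:
                raise InvalidInputError("every corpus sentence needs at least one token")
            if any(not tok for tok in sent):
                raise InvalidInputError("corpus tokens must be non-empty strings")

    @classmethod
    def from_lines(cls, lines: Iterable[str], label: str = "corpus") -> "Corpus":
        """Build a corpus from one-sentence-per-line text, whitespace tokenised."""
        sentences = tuple(tuple(line.split()) for line in lines if line.strip())
        return cls(sentences=sentences, label=label)

    @classmethod
    def from_file(cls, path: str | Path) -> "Corpus":
        path = Path(path)
        return cls.from_lines(path.read_text(encoding="utf-8").splitlines(), label=path.name)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class SurprisalProfile:
    """An ordered sequence of (token, surprisal-in-bits) for one sentence variant."""

    sentence_id: str
    construction: str
    variant_role: str  # "critical" | "baseline"
    occurred: bool
    tokens: tuple[str, ...]
    surprisal: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.variant_role not in ("critical", "baseline"):
            raise ValidationError(
                f"variant_role must be 'critical' or 'baseline', got {self.variant_role!r}"
            )
        if len(self.tokens) != len(self.surprisal):
            raise ValidationError(
                f"{self.sentence_id}: {len(self.tokens)} tokens but "
                f"{len(self.surprisal)} surprisal values"
            )
        if len(self.tokens) == 0:
            raise ValidationError(f"{self.sentence_id}: profile must have at least one token")
        for s in self.surprisal:
            if not math.isfinite(s) or s < 0:
                raise ValidationError(
                    f"{self.sentence_id}: surprisal values must be finite and >= 0, got {s}"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def values(self) -> tuple[float, ...]:
        return self.surprisal


@dataclass
class NgramModel:
    """Order-``k`` conditional token model with MLE or add-k smoothing.

    The vocabulary contains every training token plus the reserved EOS and
    UNK markers (BOS is a context-only symbol and never predicted).  With
    add-k smoothing every conditional probability is strictly positive:

        P(w | ctx) = (c(ctx, w) + k) / (c(ctx) + k * V)
    """

    order: int
    smoothing: str = "add_k"  # "mle" | "add_k"
    k: float = 0.01
    vocabulary: frozenset[str] = field(default_factory=frozenset)
    _ngram_counts: dict[tuple[str, ...], Counter] = field(default_factory=dict, repr=False)
    _context_totals: dict[tuple[str, ...], int] = field(default_factory=dict, repr=False)

    def contexts(self) -> tuple[tuple[str, ...], ...]:
        """All conditioning contexts observed during training."""
        return tuple(self._ngram_counts.keys())

    def _map(self, token: str) -> str:
        if token == BOS:
            return token
        return token if token in self.vocabulary else UNK

    def prob(self, token: str, context: Sequence[str]) -> float:
        """P(token | context); the context is truncated to the last order-1 tokens."""
        w = self._map(token)
        ctx = tuple(self._map(t) for t in context)[-(self.order - 1):] if self.order > 1 else ()
        counts = self._ngram_counts.get(ctx)
        c = counts[w] if counts is not None else 0
        n = self._context_totals.get(ctx, 0)
        if self.smoothing == "mle":
            return c / n if n > 0 else 0.0
        v = len(self.vocabulary)
        return (c + self.k) / (n + self.k * v)

    def surprisal(self, token: str, context: Sequence[str]) -> float:
        """-log2 P(token | context) in bits; raises on a zero-probability MLE event."""
        p = self.prob(token, context)
        if p <= 0.0:
            ctx = tuple(context)[-(self.order - 1):] if self.order > 1 else ()
            raise InfiniteSurprisalError(token, ctx)
        return -math.log2(p)


def train_ngram(
    corpus: Corpus,
    order: int = 3,
    smoothing: str = "add_k",
    k: float = 0.01,
) -> NgramModel:
    """Train an order-``order`` n-gram model on a tokenised corpus.

    Each sentence is padded with ``order - 1`` BOS markers and terminated
    with one EOS event, so for every observed context the conditional
    distribution over the vocabulary (training tokens + EOS + UNK) sums
    to one.
    """
    if order < 1:
        raise InvalidInputError(f"order must be >= 1, got {order}")
    if smoothing not in ("mle", "add_k"):
        raise InvalidInputError(f"smoothing must be 'mle' or 'add_k', got {smoothing!r}")
    if smoothing == "add_k" and k <= 0:
        raise InvalidInputError(f"add_k smoothing needs k > 0, got {k}")

    vocab = {tok for sent in corpus.sentences for tok in sent}
    vocab |= {EOS, UNK}

    ngram_counts: dict[tuple[str, ...], Counter] = {}
    context_totals: dict[tuple[str, ...], int] = {}
    pad = (BOS,) * (order - 1)
    for sent in corpus.sentences:
        seq = pad + tuple(sent) + (EOS,)
        for i in range(order - 1, len(seq)):
            ctx = seq[i - order + 1 : i]
            ngram_counts.setdefault(ctx, Counter())[seq[i]] += 1
            context_totals[ctx] = context_totals.get(ctx, 0) + 1

    return NgramModel(
        order=order,
        smoothing=smoothing,
        k=k,
        vocabulary=frozenset(vocab),
        _ngram_counts=ngram_counts,
        _context_totals=context_totals,
    )


def sequence_surprisal(
    model: NgramModel,
    sentence: Sequence[str],
    *,
    sentence_id: str = "",
    construction: str = "",
    variant_role: str = "critical",
    occurred: bool = False,
    include_eos: bool = False,
) -> SurprisalProfile:
    """Score a token sequence, producing one surprisal value per token.

    Initial tokens are conditioned on BOS padding.  With ``include_eos``
    an extra EOS value is appended (useful for whole-sequence probability
    audits; off by default so profiles have one value per visible word).
    """
    tokens = tuple(sentence)
    if len(tokens) == 0:
        raise InvalidInputError("cannot score an empty sentence")
    pad = (BOS,) * (model.order - 1)
    seq = pad + tokens + ((EOS,) if include_eos else ())
    out_tokens: list[str] = []
    values: list[float] = []
    for i in range(model.order - 1, len(seq)):
        out_tokens.append(seq[i])
        values.append(model.surprisal(seq[i], seq[i - model.order + 1 : i]))
    return SurprisalProfile(
        sentence_id=sentence_id or " ".join(tokens),
        construction=construction,
        variant_role=variant_role,
        occurred=occurred,
        tokens=tuple(out_tokens),
        surprisal=tuple(values),
    )


def corpus_mean_surprisal(profiles: Iterable[SurprisalProfile]) -> float:
    """Token-weighted mean surprisal over a profile collection, in bits.

    Every token counts once, so long sentences weigh more than short ones;
    this is the empirical stand-in for the global per-word information
    rate (roughly 4-5 bits for human language) used by the
    regression-to-the-mean metric.
    """
    total = 0.0
    n = 0
    for prof in profiles:
        total += sum(prof.surprisal)
        n += len(prof)
    if n == 0:
        raise InvalidInputError("corpus_mean_surprisal needs at least one profile")
    return total / n


def read_profile_table(path: str | Path) -> list[SurprisalProfile]:
    """Read per-token surprisal profiles from the TSV profile dialect.

    Rows are grouped by (sentence_id, variant_role) — so the two members
    of a sentence pair may share a sentence_id — ordered by the 0-based,
    contiguous ``position`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sentence_id": str, "token": str})
    for col in PROFILE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"profile table is missing required column {col!r}")
    if (df["surprisal_bits"] < 0).any():
        bad = df.loc[df["surprisal_bits"] < 0, "sentence_id"].iloc[0]
        raise ValidationError(f"negative surprisal in profile table for sentence {bad!r}")

    profiles: list[SurprisalProfile] = []
    for (sid, role), group in df.groupby(["sentence_id", "variant_role"], sort=False):
        group = group.sort_values("position")
        positions = group["position"].to_numpy()
        if list(positions) != list(range(len(group))):
            raise ValidationError(
                f"positions for sentence {sid!r} ({role}) must be contiguous from 0"
            )
        occ = set(group["occurred"].astype(bool))
        if len(occ) != 1:
            raise ValidationError(f"inconsistent occurred flags for sentence {sid!r} ({role})")
        cons = set(group["construction"])
        if len(cons) != 1:
            raise ValidationError(f"inconsistent construction labels for sentence {sid!r}")
        profiles.append(
            SurprisalProfile(
                sentence_id=str(sid),
                construction=group["construction"].iloc[0],
                variant_role=str(role),
                occurred=bool(group["occurred"].iloc[0]),
                tokens=tuple(group["token"].astype(str)),
                surprisal=tuple(float(s) for s in group["surprisal_bits"]),
            )
        )
    return profiles


def write_profile_table(profiles: Iterable[SurprisalProfile], path: str | Path) -> None:
    """Write profiles in the TSV dialect read back by :func:`read_profile_table`."""
    rows = []
    for prof in profiles:
        for pos, (tok, s) in enumerate(zip(prof.tokens, prof.surprisal)):
            rows.append(
                {
                    "sentence_id": prof.sentence_id,
                    "construction": prof.construction,
                    "variant_role": prof.variant_role,
                    "occurred": prof.occurred,
                    "position": pos,
                    "token": tok,
                    "surprisal_bits": s,
                }
            )
    pd.DataFrame(rows, columns=list(PROFILE_COLUMNS)).to_csv(path, sep="\t", index=False)
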