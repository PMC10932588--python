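import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from uidlab import (
    Corpus,
    FormatError,
    InfiniteSurprisalError,
    InvalidInputError,
    ValidationError,
    corpus_mean_surprisal,
    read_profile_table,
    sequence_surprisal,
    train_ngram,
    write_profile_table,
)
from uidlab.surprisal import EOS, UNK

from conftest import SEQ15_BITS, SEQ16_BITS, make_profile


def corpus_of(*texts):
    return Corpus.from_lines(texts)


class TestTrainNgram:
    def test_deterministic_corpus_forces_unit_probabilities(self):
        model = train_ngram(corpus_of("a b c"), order=2, smoothing="mle")
        assert model.prob("b", ("a",)) == 1.0
        assert model.prob("c", ("b",)) == 1.0

    def test_split_continuation_gives_half(self):
        model = train_ngram(corpus_of("a b", "a c"), order=2, smoothing="mle")
        assert model.prob("b", ("a",)) == 0.5

    def test_add_k_matches_lidstone_formula(self):
        # vocab = {a, b, EOS, UNK} -> V = 4; P(b|a) = (1 + 1) / (1 + V)
        model = train_ngram(corpus_of("a b"), order=2, smoothing="add_k", k=1.0)
        v = len(model.vocabulary)
        assert model.prob("b", ("a",)) == pytest.approx(2 / (1 + v))
        assert EOS in model.vocabulary and UNK in model.vocabulary

    @pytest.mark.parametrize(
        "kwargs, exc",
        [
            (dict(order=0), InvalidInputError),
            (dict(smoothing="add_k", k=0.0), InvalidInputError),
            (dict(smoothing="add_k", k=-1.0), InvalidInputError),
            (dict(smoothing="kneser_ney"), InvalidInputError),
        ],
    )
    def test_invalid_training_arguments(self, kwargs, exc):
        with pytest.raises(exc):
            train_ngram(corpus_of("a b"), **kwargs)

    def test_empty_corpus_rejected(self):
        with pytest.raises(InvalidInputError):
            Corpus(sentences=())
        with pytest.raises(InvalidInputError):
            Corpus(sentences=((),))

    @pytest.mark.parametrize("smoothing", ["mle", "add_k"])
    @given(
        sents=st.lists(
            st.lists(st.sampled_from("abcd"), min_size=1, max_size=5),
            min_size=1,
            max_size=6,
        ),
        order=st.integers(1, 3),
    )
    def test_conditional_distributions_normalize(self, sents, order, smoothing):
        """Every observed context's distribution over the vocabulary sums to 1."""
        model = train_ngram(
            Corpus(tuple(tuple(s) for s in sents)), order=order, smoothing=smoothing
        )
        for ctx in model.contexts():
            total = sum(model.prob(w, ctx) for w in model.vocabulary)
            assert total == pytest.approx(1.0, abs=1e-9)


class TestSequenceSurprisal:
    def test_deterministic_corpus_gives_zero_bits(self):
        model = train_ngram(corpus_of("a b c"), order=2, smoothing="mle")
        prof = sequence_surprisal(model, ["a", "b", "c"])
        assert prof.surprisal[1] == 0.0
        assert prof.surprisal[2] == 0.0

    def test_half_probability_is_one_bit(self):
        model = train_ngram(corpus_of("a b", "a c"), order=2, smoothing="mle")
        prof = sequence_surprisal(model, ["a", "b"])
        assert prof.surprisal[1] == pytest.approx(1.0)

    def test_empty_sentence_rejected(self):
        model = train_ngram(corpus_of("a b"), order=2)
        with pytest.raises(InvalidInputError):
            sequence_surprisal(model, [])

    def test_mle_zero_probability_event_raises_with_diagnostic(self):
        model = train_ngram(corpus_of("a b"), order=2, smoothing="mle")
        with pytest.raises(InfiniteSurprisalError, match="zero probability"):
            sequence_surprisal(model, ["a", "d"])

    @given(
        sents=st.lists(
            st.lists(st.sampled_from("abc"), min_size=1, max_size=4),
            min_size=1,
            max_size=5,
        ),
        order=st.integers(1, 3),
    )
    def test_training_sentences_stay_finite_under_mle(self, sents, order):
        corpus = Corpus(tuple(tuple(s) for s in sents))
        model = train_ngram(corpus, order=order, smoothing="mle")
        for sent in corpus.sentences:
            prof = sequence_surprisal(model, sent)
            assert all(math.isfinite(v) for v in prof.surprisal)

    @given(
        sents=st.lists(
            st.lists(st.sampled_from("abc"), min_size=1, max_size=4),
            min_size=2,
            max_size=5,
        ),
        order=st.integers(1, 3),
    )
    def test_profile_sum_equals_chain_rule_log_probability(self, sents, order):
        """Summed per-token surprisal is -log2 of the whole-sequence probability."""
        corpus = Corpus(tuple(tuple(s) for s in sents))
        model = train_ngram(corpus, order=order, smoothing="add_k", k=0.5)
        sent = corpus.sentences[0]
        prof = sequence_surprisal(model, sent)
        padded = ("<s>",) * (order - 1) + sent
        logp = 0.0
        for i in range(order - 1, len(padded)):
            logp += math.log2(model.prob(padded[i], padded[i - order + 1 : i]))
        assert sum(prof.surprisal) == pytest.approx(-logp, abs=1e-9)


class TestProfileTable:
    def test_nine_row_table_groups_into_two_profiles(self, tmp_path, seq15, seq16):
        path = tmp_path / "profiles.tsv"
        write_profile_table([seq15, seq16], path)
        profiles = read_profile_table(path)
        assert sorted(len(p) for p in profiles) == [4, 5]

    def test_worked_example_profile_mean(self, tmp_path, seq15):
        path = tmp_path / "profiles.tsv"
        write_profile_table([seq15], path)
        (prof,) = read_profile_table(path)
        assert round(sum(prof.surprisal) / len(prof), 2) == 4.63

    def test_roundtrip_is_identity(self, tmp_path, seq15, seq16):
        path = tmp_path / "profiles.tsv"
        write_profile_table([seq15, seq16], path)
        assert read_profile_table(path) == [seq15, seq16]

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sentence_id\ttoken\n" "s1\thello\n")
        with pytest.raises(FormatError, match="construction"):
            read_profile_table(path)

    def test_negative_surprisal_rejected(self, tmp_path, seq15):
        path = tmp_path / "neg.tsv"
        write_profile_table([seq15], path)
        path.write_text(path.read_text().replace("5.33", "-5.33"))
        with pytest.raises(ValidationError, match="negative surprisal"):
            read_profile_table(path)

    def test_noncontiguous_positions_rejected(self, tmp_path, seq15):
        path = tmp_path / "gap.tsv"
        write_profile_table([seq15], path)
        lines = path.read_text().splitlines()
        del lines[2]  # drop position 1, leaving a gap
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="contiguous"):
            read_profile_table(path)


class TestCorpusMeanSurprisal:
    def test_constant_profiles(self):
        prof = make_profile([4.7, 4.7, 4.7])
        assert corpus_mean_surprisal([prof]) == pytest.approx(4.7)

    def test_token_weighted_not_profile_weighted(self):
        profs = [make_profile([2.0, 2.0]), make_profile([6.0])]
        assert corpus_mean_surprisal(profs) == pytest.approx(10 / 3)

    def test_worked_example_token_pool(self, seq15, seq16):
        # nine printed values pooled: 55.58 / 9
        mean = corpus_mean_surprisal([seq15, seq16])
        assert mean == pytest.approx(sum(SEQ15_BITS + SEQ16_BITS) / 9)
        assert round(mean, 2) == 6.18

    def test_empty_collection_rejected(self):
        with pytest.raises(InvalidInputError):
            corpus_mean_surprisal([])
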