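from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stutterkit as sk
from stutterkit.linguistic import (
    LINGUISTIC_NAMES,
    AsrChunk,
    AsrDecoding,
    MockAsrErrorModel,
    aggregate_decodings,
    base_feature_vector,
    decodings_from_jsonl,
    decodings_to_jsonl,
    mock_asr_decode,
    nonsequential_ngram_repetition,
    normalize_text,
    probability_features,
    segmental_repetition_scan,
    sequential_ngram_repetition,
    temporal_features,
)

tokens_strategy = st.lists(st.sampled_from(["das", "buch", "nicht", "a", "b"]),
                           max_size=12)


def chunk(text="x", t0=0.0, t1=1.0, pt=0.9, pn=0.1):
    return AsrChunk(text, t0, t1, pt, pn)


class TestNormalizeText:
    def test_lowercase_and_punctuation(self):
        tokens, chars = normalize_text("Das, das Buch.")
        assert tokens == ["das", "das", "buch"]
        assert chars == "dasdasbuch"

    def test_empty(self):
        assert normalize_text("") == ([], "")

    def test_token_count(self):
        tokens, _ = normalize_text("The cat sat sat on the mmmat")
        assert len(tokens) == 7


class TestNgramRepetition:
    # the counting conventions are fixed by worked phrases: an adjacent
    # duplicated word is one sequential event; repeated types anywhere
    # count once each for the non-sequential variant
    @pytest.mark.parametrize("text,n,expected", [
        ("das das buch", 1, 1),
        ("das buch das buch", 2, 1),
        ("a a a", 1, 2),
        ("a b c", 1, 0),
    ])
    def test_sequential(self, text, n, expected):
        assert sequential_ngram_repetition(text.split(), n) == expected

    @pytest.mark.parametrize("text,n,expected", [
        ("das buch nicht das buch", 1, 2),
        ("das buch nicht das buch", 2, 1),
        ("a b c", 1, 0),
    ])
    def test_nonsequential(self, text, n, expected):
        assert nonsequential_ngram_repetition(text.split(), n) == expected

    @settings(max_examples=300, derandomize=True)
    @given(tokens_strategy)
    def test_sequential_matches_bruteforce(self, tokens):
        for n in (1, 2):
            brute = sum(
                1 for i in range(len(tokens) - 2 * n + 1)
                if tuple(tokens[i:i + n]) == tuple(tokens[i + n:i + 2 * n])
            )
            assert sequential_ngram_repetition(tokens, n) == brute

    @settings(max_examples=300, derandomize=True)
    @given(tokens_strategy)
    def test_adjacent_repeats_imply_repeated_types(self, tokens):
        seq = sequential_ngram_repetition(tokens, 1)
        repeated_occurrences = sum(
            c for c in Counter(tokens).values() if c >= 2
        )
        assert seq <= repeated_occurrences


class TestSegmentalScan:
    @pytest.mark.parametrize("chars,expected", [
        ("abcdabcd", 1),   # stops at n=4: "abcd" repeats
        ("abcabc", 1),     # nothing longer repeats; n=3 finds "abc"
        ("abc", 0),        # below the 4-character minimum
        ("aaaa", 1),       # "aaa" occurs at two overlapping positions
        ("wxyz", 0),
    ])
    def test_examples(self, chars, expected):
        assert segmental_repetition_scan(chars) == expected

    def test_matches_exhaustive_tabulation(self):
        # oracle: tabulate every n-gram length top-down and emulate the
        # stopping rule independently
        rng = np.random.default_rng(0)
        alphabet = "abcd"
        for _ in range(500):
            length = int(rng.integers(0, 31))
            chars = "".join(rng.choice(list(alphabet), length))
            expected = 0
            if len(chars) >= 4:
                for n in range(len(chars) - 1, 2, -1):
                    grams = Counter(chars[i:i + n]
                                    for i in range(len(chars) - n + 1))
                    count = sum(1 for c in grams.values() if c >= 2)
                    if count > 0 or n == 3:
                        expected = count
                        break
            assert segmental_repetition_scan(chars) == expected


class TestTemporalAndProbability:
    def test_two_durations(self):
        dec = AsrDecoding([chunk(t0=0, t1=1.0), chunk(t0=1, t1=3.0)])
        sums = temporal_features(dec)
        np.testing.assert_allclose(
            sums, [3.0, 2.0, 1.0, 1.5, 1.5, 0.5, 1.25, 1.75, 0.5])

    def test_single_chunk_degenerate_stats(self):
        dec = AsrDecoding([chunk(t0=0, t1=2.5)])
        out = temporal_features(dec)
        assert out[0] == out[1] == out[2] == out[3] == out[4] == 2.5
        assert out[5] == 0.0 and out[8] == 0.0

    def test_matches_numpy_recomputation(self):
        durations = [1.0, 2.0, 3.0, 4.0]
        dec = AsrDecoding([chunk(t0=0, t1=d) for d in durations])
        d = np.array(durations)
        expected = [d.sum(), d.max(), d.min(), d.mean(), np.median(d),
                    d.std(), *np.percentile(d, [25, 75]),
                    np.subtract(*np.percentile(d, [75, 25]))]
        np.testing.assert_allclose(temporal_features(dec), expected)

    def test_empty_decoding_flagged_zero(self):
        with pytest.warns(UserWarning):
            assert not temporal_features(AsrDecoding([])).any()

    def test_probability_means(self):
        dec = AsrDecoding([chunk(pt=0.8, pn=0.1), chunk(pt=0.6, pn=0.1)])
        np.testing.assert_allclose(probability_features(dec), [0.7, 0.1])


class TestAggregation:
    def test_triple_1_2_3(self):
        per_dec = np.tile([1.0], (3, 16)) * np.array([[1.0], [2.0], [3.0]])
        out = aggregate_decodings(per_dec)
        assert out.shape == (80,)
        np.testing.assert_allclose(out[:5], [6, 2, 3, 1, np.sqrt(2 / 3)])

    def test_identical_decodings_have_zero_sd(self):
        out = aggregate_decodings(np.full((3, 16), 2.5))
        sds = out[4::5]
        assert not sds.any()
        np.testing.assert_allclose(out[0::5], 7.5)

    def test_wrong_decoding_count_rejected(self):
        with pytest.raises(ValueError, match="3"):
            aggregate_decodings(np.ones((2, 16)))

    def test_vector_always_80_named_values(self):
        decs = mock_asr_decode(["ba", "ba", "du"], window=3.0, seed=4)
        vec = sk.linguistic_vector(decs)
        assert vec.shape == (80,)
        assert len(LINGUISTIC_NAMES) == 80


class TestMockAsr:
    def test_zero_error_reproduces_reference(self):
        model = MockAsrErrorModel(0.0, 0.0, 0.0)
        for dec in mock_asr_decode(["das", "das", "buch"], 3.0, model, seed=1):
            assert normalize_text(dec.text)[0] == ["das", "das", "buch"]

    def test_certain_repeat_deletion(self):
        model = MockAsrErrorModel(p_delete_repeat=1.0, p_delete_any=0.0,
                                  jitter_sd=0.0)
        for dec in mock_asr_decode(["das", "das", "buch"], 3.0, model, seed=1):
            assert normalize_text(dec.text)[0] == ["das", "buch"]

    def test_seeded_runs_identical(self):
        a = mock_asr_decode(["a", "b", "c", "c"], 2.0, seed=7)
        b = mock_asr_decode(["a", "b", "c", "c"], 2.0, seed=7)
        assert decodings_to_jsonl(a) == decodings_to_jsonl(b)

    def test_chunks_span_window(self):
        for dec in mock_asr_decode(["a", "b", "c"], 4.0, seed=2):
            assert dec.chunks[0].t_start == 0.0
            assert dec.chunks[-1].t_end == pytest.approx(4.0)

    def test_deletion_lowers_repetition_counts_on_wwr_transcripts(self):
        # ASR deletion errors collapse stuttered repetitions, so measured
        # sequential unigram counts must drop (Monte-Carlo, seeded)
        reference = ["ba", "ba", "ba", "du", "du", "ne"]
        def mean_count(p):
            model = MockAsrErrorModel(p_delete_repeat=p, p_delete_any=0.0,
                                      jitter_sd=0.0)
            counts = []
            for seed in range(60):
                for dec in mock_asr_decode(reference, 3.0, model, seed=seed):
                    counts.append(
                        sequential_ngram_repetition(normalize_text(dec.text)[0], 1))
            return np.mean(counts)
        assert mean_count(0.0) > mean_count(0.5) > mean_count(1.0)

    def test_jsonl_roundtrip(self):
        decs = mock_asr_decode(["xy", "zw"], 2.0, seed=3)
        back = decodings_from_jsonl(decodings_to_jsonl(decs))
        assert [d.text for d in back] == [d.text for d in decs]


def test_base_vector_is_16_values():
    dec = AsrDecoding([chunk("das das buch", 0, 2.0)])
    assert base_feature_vector(dec).shape == (16,)
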