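"""Language-based features from ASR decodings of a segment's context window.

Each segment's lookback window is decoded three times by an ASR system
(Whisper in production; the built-in mock ASR in tests).  From each
decoding, 16 base values are computed: five orthographic repetition
counts (sequential word uni/bigram repetitions, non-sequential word
uni/bigram repetition types, and a character-level segmental repetition
scan), two probability means, and nine summary statistics of chunk
durations.  Five aggregators (sum, mean, max, min, population SD) over
the three decodings yield the final (5 + 2 + 9) x 5 = 80-value vector.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

ORTHOGRAPHIC_NAMES = [
    "seq_unigram_rep",
    "seq_bigram_rep",
    "nonseq_unigram_rep",
    "nonseq_bigram_rep",
    "segmental_rep",
]
PROBABILITY_NAMES = ["mean_p_transcription", "mean_p_nospeech"]
TEMPORAL_NAMES = [
    "dur_sum", "dur_max", "dur_min", "dur_mean", "dur_median",
    "dur_sd", "dur_q25", "dur_q75", "dur_iqr",
]
BASE_NAMES = ORTHOGRAPHIC_NAMES + PROBABILITY_NAMES + TEMPORAL_NAMES
AGGREGATOR_NAMES = ["sum", "mean", "max", "min", "sd"]
LINGUISTIC_NAMES = [
    f"ling_{base}_{agg}" for base in BASE_NAMES for agg in AGGREGATOR_NAMES
]
N_LINGUISTIC = len(LINGUISTIC_NAMES)  # 80


@dataclass(frozen=True)
class AsrChunk:
    """One decoded transcription chunk with timestamps and probabilities."""

    text: str
    t_start: float
    t_end: float
    p_transcription: float
    p_nospeech: float

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValueError("chunk t_end must be >= t_start")
        for name in ("p_transcription", "p_nospeech"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class AsrDecoding:
    """One full decoding: chunks ordered by start time."""

    chunks: list[AsrChunk] = field(default_factory=list)

    def __post_init__(self):
        self.chunks = sorted(self.chunks, key=lambda c: c.t_start)

    @property
    def text(self) -> str:
        return " ".join(c.text for c in self.chunks)

    def clipped_to(self, t0: float, t1: float) -> "AsrDecoding":
        """Keep the chunks whose midpoint falls inside [t0, t1]."""
        return AsrDecoding(
            [c for c in self.chunks if t0 <= (c.t_start + c.t_end) / 2.0 <= t1]
        )


_PUNCT = re.compile(r"[^\w\s]|_", flags=re.UNICODE)


def normalize_text(text: str) -> tuple[list[str], str]:
    """Lowercase, strip punctuation, split on whitespace.

    Returns (tokens, character string): the character string joins the
    tokens without spaces, feeding the segmental scan that is robust to
    ASR word-boundary errors.
    """
    cleaned = _PUNCT.sub(" ", text.lower())
    tokens = cleaned.split()
    return tokens, "".join(tokens)


def sequential_ngram_repetition(tokens: list[str], n: int) -> int:
    """Count immediately-repeated word n-grams (e.g. 'das das Buch' -> 1).

    Overlapping scan over positions i, counting those where the n-gram
    at i equals the n-gram at i + n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return sum(
        1
        for i in range(len(tokens) - 2 * n + 1)
        if tokens[i:i + n] == tokens[i + n:i + 2 * n]
    )


def nonsequential_ngram_repetition(tokens: list[str], n: int) -> int:
    """Count distinct word n-gram types occurring at least twice anywhere."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grams = Counter(
        tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1)
    )
    return sum(1 for count in grams.values() if count >= 2)


def segmental_repetition_scan(chars: str) -> int:
    """Character n-gram repetition count with a longest-first early stop.

    Scans n from len(chars) - 1 downward counting character n-gram types
    that occur at least twice (overlapping positions count separately).
    Stops at the first n > 3 with a repetition; otherwise returns the
    count at n = 3 (the floor that avoids flagging ordinary repeated
    syllables and inflectional morphemes).  Strings shorter than 4
    characters return 0.
    """
    if len(chars) < 4:
        return 0
    for n in range(len(chars) - 1, 2, -1):
        grams = Counter(chars[i:i + n] for i in range(len(chars) - n + 1))
        count = sum(1 for c in grams.values() if c >= 2)
        if count > 0 or n == 3:
            return count
    return 0


def orthographic_features(decoding: AsrDecoding) -> np.ndarray:
    """The five repetition counts over the decoding's concatenated text."""
    tokens, chars = normalize_text(decoding.text)
    return np.array(
        [
            sequential_ngram_repetition(tokens, 1),
            sequential_ngram_repetition(tokens, 2),
            nonsequential_ngram_repetition(tokens, 1),
            nonsequential_ngram_repetition(tokens, 2),
            segmental_repetition_scan(chars),
        ],
        dtype=float,
    )


def probability_features(decoding: AsrDecoding) -> np.ndarray:
    """Mean transcription probability and mean no-speech probability."""
    if not decoding.chunks:
        warnings.warn("empty decoding: probability features set to 0")
        return np.zeros(2)
    return np.array(
        [
            float(np.mean([c.p_transcription for c in decoding.chunks])),
            float(np.mean([c.p_nospeech for c in decoding.chunks])),
        ]
    )


def temporal_features(decoding: AsrDecoding) -> np.ndarray:
    """Nine summary statistics of chunk durations.

    Sum, max, min, mean, median, population SD, lower/upper quartile
    (linear interpolation) and interquartile range.  An empty decoding
    yields zeros with a warning.
    """
    if not decoding.chunks:
        warnings.warn("empty decoding: temporal features set to 0")
        return np.zeros(len(TEMPORAL_NAMES))
    d = np.array([c.duration for c in decoding.chunks], dtype=float)
    q25, q75 = np.percentile(d, [25, 75])
    return np.array(
        [d.sum(), d.max(), d.min(), d.mean(), float(np.median(d)),
         d.std(ddof=0), q25, q75, q75 - q25]
    )


def base_feature_vector(decoding: AsrDecoding) -> np.ndarray:
    """The 16 per-decoding base values in canonical order."""
    return np.concatenate(
        [
            orthographic_features(decoding),
            probability_features(decoding),
            temporal_features(decoding),
        ]
    )


def aggregate_decodings(
    per_decoding: np.ndarray | list[np.ndarray], n_expected: int = 3
) -> np.ndarray:
    """Aggregate the base values of the decodings into the 80-value vector.

    For each of the 16 base features, emits sum, mean, max, min and
    population SD over its values across decodings, in the column order
    of ``LINGUISTIC_NAMES``.
    """
    mat = np.atleast_2d(np.asarray(per_decoding, dtype=float))
    if mat.shape[0] != n_expected:
        raise ValueError(f"expected {n_expected} decodings, got {mat.shape[0]}")
    if mat.shape[1] != len(BASE_NAMES):
        raise ValueError(f"expected {len(BASE_NAMES)} base values per decoding")
    aggs = np.stack(
        [mat.sum(axis=0), mat.mean(axis=0), mat.max(axis=0),
         mat.min(axis=0), mat.std(axis=0, ddof=0)],
        axis=1,
    )  # (16, 5): row-major flatten matches base-major column order
    return aggs.ravel()


def linguistic_vector(decodings: list[AsrDecoding]) -> np.ndarray:
    """The 80-value linguistic vector for one segment's decodings."""
    return aggregate_decodings([base_feature_vector(d) for d in decodings],
                               n_expected=len(decodings) or 3)


@dataclass(frozen=True)
class MockAsrErrorModel:
    """Deletion-dominated corruption model for the mock ASR.

    ``p_delete_repeat`` removes tokens identical to their predecessor
    (ASR systems tend to collapse stuttered repetitions), ``p_delete_any``
    removes any token, ``jitter_sd`` perturbs chunk boundaries (seconds).
    """

    p_delete_repeat: float = 0.5
    p_delete_any: float = 0.05
    jitter_sd: float = 0.05

    def __post_init__(self):
        for name in ("p_delete_repeat", "p_delete_any"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


def mock_asr_decode(
    reference_tokens: list[str],
    window: float,
    error_model: MockAsrErrorModel | None = None,
    seed: int = 0,
    n_decodings: int = 3,
) -> list[AsrDecoding]:
    """Simulate repeated ASR decodings of a window of reference speech.

    Each decoding independently corrupts the reference token sequence
    (deletion-dominated, mimicking how ASR systems swallow stuttered
    words), splits the survivors into 1-3 chunks whose timestamps span
    the window (with boundary jitter), and draws per-chunk transcription
    and no-speech probabilities from Beta distributions.  Deterministic
    per (seed, decoding index).
    """
    error_model = error_model or MockAsrErrorModel()
    decodings = []
    for d in range(n_decodings):
        rng = np.random.default_rng([int(seed) % (2 ** 31), d])
        kept = []
        for i, tok in enumerate(reference_tokens):
            p_del = (
                error_model.p_delete_repeat
                if i > 0 and tok == reference_tokens[i - 1]
                else error_model.p_delete_any
            )
            if rng.random() >= p_del:
                kept.append(tok)
        n_chunks = int(rng.integers(1, 4)) if kept else 1
        n_chunks = min(n_chunks, max(len(kept), 1))
        bounds = np.linspace(0.0, window, n_chunks + 1)
        if error_model.jitter_sd > 0 and n_chunks > 1:
            bounds[1:-1] += rng.normal(0.0, error_model.jitter_sd, n_chunks - 1)
            bounds = np.clip(np.sort(bounds), 0.0, window)
        pieces = np.array_split(np.array(kept, dtype=object), n_chunks)
        chunks = [
            AsrChunk(
                text=" ".join(piece),
                t_start=float(bounds[j]),
                t_end=float(bounds[j + 1]),
                p_transcription=float(rng.beta(8.0, 2.0)),
                p_nospeech=float(rng.beta(2.0, 8.0)),
            )
            for j, piece in enumerate(pieces)
        ]
        decodings.append(AsrDecoding(chunks))
    return decodings


def decodings_to_jsonl(decodings: list[AsrDecoding]) -> str:
    """Serialize decodings as JSON lines, one decoding per line."""
    import json

    lines = []
    for dec in decodings:
        lines.append(json.dumps([
            {"text": c.text, "start": c.t_start, "end": c.t_end,
             "p_transcription": c.p_transcription, "p_nospeech": c.p_nospeech}
            for c in dec.chunks
        ]))
    return "\n".join(lines)


def decodings_from_jsonl(payload: str) -> list[AsrDecoding]:
    import json

    decodings = []
    for line in payload.splitlines():
        if not line.strip():
            continue
        decodings.append(AsrDecoding([
            AsrChunk(d["text"], d["start"], d["end"],
                     d["p_transcription"], d["p_nospeech"])
            for d in json.loads(line)
        ]))
    return decodings
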