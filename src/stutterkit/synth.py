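"""Synthetic annotated stuttered-speech corpora.

Generates waveforms with ground-truth, syllable-level fluency
annotations so every pipeline stage — segmentation, feature extraction,
classification, evaluation — is testable without any real corpus.  The
default configuration mirrors the study conditions of annotated
clinical recordings: class frequencies of 82.48 / 2.76 / 3.27 / 1.20 /
10.29 % (fluent / prolongation / PWR / WWR / block), class-specific
event-length moments (fluent 222±208 ms, prolongation 521±311, PWR
763±418, WWR 237±155, block 578±467; truncated at 30 ms), hard
speaker-level variation (per-speaker pitch and vocabulary), and
deletion-dominated mock-ASR errors.

The per-class waveform recipes are fully synthetic, not speech-like:
each class gets a distinct temporal *and* spectral signature (a single
amplitude-modulated harmonic burst for fluent syllables; a sustained
vibrato tone for prolongations; trains of narrowband noise bursts for
part-word repetitions; two bright harmonic renditions for whole-word
repetitions; leading silence then an abrupt broadband burst for
blocks), so that classes are acoustically separable and segmentation
effects — not speech realism — are what the pipeline measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustic import normalize_amplitude
from .corpus import AnnotatedRecording, FluencyClass, FluencyEvent
from .linguistic import MockAsrErrorModel

# class-frequency and event-length study conditions (probabilities; ms)
DEFAULT_CLASS_PROBABILITIES = {
    FluencyClass.FLUENT: 0.8248,
    FluencyClass.PROLONGATION: 0.0276,
    FluencyClass.PWR: 0.0327,
    FluencyClass.WWR: 0.0120,
    FluencyClass.BLOCK: 0.1029,
}
DEFAULT_LENGTH_MOMENTS_MS = {
    FluencyClass.FLUENT: (222.0, 208.0),
    FluencyClass.PROLONGATION: (521.0, 311.0),
    FluencyClass.PWR: (763.0, 418.0),
    FluencyClass.WWR: (237.0, 155.0),
    FluencyClass.BLOCK: (578.0, 467.0),
}
MIN_EVENT_S = 0.030

_SYLLABLES = ["ba", "do", "ki", "mu", "ne", "po", "ra", "su", "ta", "vo"]


@dataclass
class SpeakerParams:
    """Per-speaker voice and vocabulary parameters."""

    speaker_id: str
    f0: float
    vocabulary: list[str]
    noise_floor: float = 0.008


@dataclass
class SynthConfig:
    """Study conditions for one synthetic corpus."""

    n_speakers: int = 12
    seconds_per_speaker: float = 50.0
    sample_rate: int = 16000
    class_probabilities: dict[FluencyClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBABILITIES)
    )
    event_length_moments_ms: dict[FluencyClass, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MOMENTS_MS)
    )
    speaker_f0_range: tuple[float, float] = (90.0, 300.0)
    gap_range_s: tuple[float, float] = (0.02, 0.08)
    asr_error_model: MockAsrErrorModel = field(default_factory=MockAsrErrorModel)
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_probabilities.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"class probabilities sum to {total}, expected 1")
        for cls, (mean, _) in self.event_length_moments_ms.items():
            if mean <= 0:
                raise ValueError(f"non-positive mean event length for {cls.name}")


def _harmonic(t: np.ndarray, f0: float, weights: dict[int, float],
              vibrato_depth: float = 0.0, vibrato_hz: float = 5.0) -> np.ndarray:
    phase = 2 * np.pi * f0 * t
    if vibrato_depth:
        phase = phase + vibrato_depth * np.sin(2 * np.pi * vibrato_hz * t)
    out = np.zeros_like(t)
    for k, w in weights.items():
        out += w * np.sin(k * phase)
    return out


def _burst_envelope(n: int, attack: float = 0.2, decay: float = 0.3) -> np.ndarray:
    """Raised-cosine attack/decay envelope for one syllable burst."""
    env = np.ones(n)
    na, nd = max(int(n * attack), 1), max(int(n * decay), 1)
    env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    env[n - nd:] = 0.5 * (1 + np.cos(np.pi * np.arange(nd) / nd))
    return env


def _narrowband_noise(t: np.ndarray, centre_hz: float, width_hz: float,
                      rng: np.random.Generator, n_components: int = 24) -> np.ndarray:
    """Noise confined to a band: random-phase sinusoids across the band."""
    freqs = rng.uniform(centre_hz - width_hz / 2, centre_hz + width_hz / 2,
                        n_components)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    out = np.zeros_like(t)
    for f, ph in zip(freqs, phases):
        out += np.sin(2 * np.pi * f * t + ph)
    return out / np.sqrt(n_components)


def synth_event(
    label: FluencyClass,
    duration: float,
    speaker: SpeakerParams,
    sample_rate: int = 16000,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Render one event's waveform and its reference-transcript tokens.

    Recipes by class: FLUENT — one amplitude-modulated harmonic syllable
    burst; PROLONGATION — sustained vibrato tone at twice the speaker
    pitch, token with an elongated initial character run; PWR — 2-4
    identical narrowband noise bursts with gaps, fragment tokens then
    the word; WWR — two bright harmonic renditions, word token twice;
    BLOCK — leading silence covering at least half the event, then an
    abrupt broadband burst.
    """
    if duration < MIN_EVENT_S:
        raise ValueError(f"event duration {duration * 1000:.0f} ms below the "
                         f"{MIN_EVENT_S * 1000:.0f} ms floor")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = max(int(round(duration * sample_rate)), 2)
    t = np.arange(n) / sample_rate
    word = speaker.vocabulary[rng.integers(len(speaker.vocabulary))]
    wave = np.zeros(n)

    # Class signatures are anchored to class-specific spectral bands with a
    # mild speaker-pitch coupling: classes stay identifiable across unseen
    # speakers (the hard-split setting) while each speaker keeps an audible
    # individual carrier offset, envelope and vocabulary.
    carrier = 350.0 + 0.3 * speaker.f0

    if label is FluencyClass.FLUENT:
        wave = _harmonic(t, carrier, {1: 1.0, 2: 0.5}) * _burst_envelope(n)
        tokens = [word]
    elif label is FluencyClass.PROLONGATION:
        wave = _harmonic(t, 1200.0 + 0.2 * speaker.f0, {1: 1.0, 3: 0.2},
                         vibrato_depth=1.5, vibrato_hz=5.0)
        wave *= 0.9 + 0.1 * np.sin(2 * np.pi * 2.0 * t)
        wave *= _burst_envelope(n, attack=0.05, decay=0.05)
        tokens = [word[0] * 4 + word]
    elif label is FluencyClass.PWR:
        k = int(rng.integers(2, 5))
        slot = n // (2 * k - 1)  # bursts separated by equal gaps
        burst = _narrowband_noise(t[:max(slot, 2)], 2500.0, 900.0, rng)
        burst = burst * _burst_envelope(len(burst), attack=0.1, decay=0.2)
        for b in range(k):
            lo = b * 2 * slot
            wave[lo:lo + len(burst)] = burst[: max(n - lo, 0)][: len(burst)]
        tokens = [word[:2]] * (k - 1) + [word]
    elif label is FluencyClass.WWR:
        half = n // 2
        rend = _harmonic(t[:max(half, 2)], 700.0 + 0.3 * speaker.f0,
                         {1: 1.0, 3: 0.6, 5: 0.3})
        rend = rend * _burst_envelope(len(rend))
        gap = max(int(0.05 * n), 1)
        wave[:len(rend)] = rend
        hi = min(half + gap + len(rend), n)
        wave[half + gap:hi] = rend[: hi - half - gap]
        tokens = [word, word]
    elif label is FluencyClass.BLOCK:
        silence_frac = 0.5 + 0.2 * rng.random()
        onset = int(n * silence_frac)
        burst_t = t[: n - onset]
        burst = rng.standard_normal(len(burst_t)) * np.exp(-burst_t / 0.03)
        burst += 0.4 * _harmonic(burst_t, carrier / 2.0, {1: 1.0})
        wave[onset:] = burst
        tokens = [word]
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown class {label}")

    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / peak * 0.9
    wave += speaker.noise_floor * rng.standard_normal(n)
    return wave, tokens


def _make_speaker(index: int, config: SynthConfig,
                  rng: np.random.Generator) -> SpeakerParams:
    lo, hi = config.speaker_f0_range
    vocab = [
        _SYLLABLES[rng.integers(len(_SYLLABLES))]
        + _SYLLABLES[rng.integers(len(_SYLLABLES))]
        for _ in range(30)
    ]
    return SpeakerParams(
        speaker_id=f"spk{index:02d}",
        f0=float(rng.uniform(lo, hi)),
        vocabulary=vocab,
    )


def _draw_duration(label: FluencyClass, config: SynthConfig,
                   rng: np.random.Generator) -> float:
    mean_ms, sd_ms = config.event_length_moments_ms[label]
    for _ in range(1000):
        d = rng.normal(mean_ms, sd_ms) / 1000.0
        if d >= MIN_EVENT_S:
            return d
    return MIN_EVENT_S


def generate_corpus(config: SynthConfig) -> list[AnnotatedRecording]:
    """Generate one recording per speaker under the configured conditions.

    Events are sampled i.i.d. from the class probabilities with lengths
    from the per-class truncated normals, concatenated with short
    unlabelled silent gaps.  Annotations record exact event boundaries;
    the reference transcript accumulates event tokens, with per-token
    timestamps kept in ``token_times`` for windowed mock-ASR decoding.
    Byte-for-byte deterministic for a fixed seed.
    """
    classes = list(FluencyClass)
    probs = np.array([config.class_probabilities[c] for c in classes])
    recordings = []
    for s in range(config.n_speakers):
        rng = np.random.default_rng([config.seed % (2 ** 31), s])
        speaker = _make_speaker(s, config, rng)
        pieces: list[np.ndarray] = []
        events: list[FluencyEvent] = []
        transcript: list[str] = []
        token_times: list[tuple[str, float, float]] = []
        sr = config.sample_rate
        cursor = 0  # in samples, so event times are exact against the audio
        while cursor < config.seconds_per_speaker * sr:
            gap = float(rng.uniform(*config.gap_range_s))
            gap_samples = int(round(gap * sr))
            pieces.append(np.zeros(gap_samples))
            cursor += gap_samples
            label = classes[rng.choice(len(classes), p=probs)]
            duration = _draw_duration(label, config, rng)
            wave, tokens = synth_event(label, duration, speaker, sr, rng)
            onset = cursor / sr
            offset = (cursor + len(wave)) / sr
            events.append(FluencyEvent(label, onset, offset))
            pieces.append(wave)
            transcript.extend(tokens)
            per_tok = (offset - onset) / len(tokens)
            token_times.extend(
                (tok, onset + i * per_tok, onset + (i + 1) * per_tok)
                for i, tok in enumerate(tokens)
            )
            cursor += len(wave)
        samples = normalize_amplitude(np.concatenate(pieces))
        recordings.append(
            AnnotatedRecording(
                recording_id=f"rec_{speaker.speaker_id}",
                speaker_id=speaker.speaker_id,
                sample_rate=config.sample_rate,
                samples=samples,
                events=events,
                reference_transcript=transcript,
                token_times=token_times,
            ).validate()
        )
    return recordings


def tokens_in_window(rec: AnnotatedRecording, t0: float, t1: float) -> list[str]:
    """Reference tokens whose midpoint falls inside [t0, t1]."""
    if rec.token_times is None:
        raise ValueError(
            f"{rec.recording_id} has no token timing; cannot window the transcript"
        )
    return [tok for tok, a, b in rec.token_times if t0 <= (a + b) / 2.0 <= t1]
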