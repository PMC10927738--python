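"""Optional adapters for pretrained speech models (never required).

These wrap wav2vec 2.0 XLSR-53 (latent acoustic embeddings) and Whisper
(ASR decodings) behind the same interfaces the rest of the package
uses.  Both import their heavy dependencies lazily; without ``torch``
and ``transformers``/``whisper`` installed they raise a clear error.
Nothing in the test suite touches them — the synthetic embedder and
mock ASR cover every tested code path.
"""

from __future__ import annotations

import numpy as np

from .acoustic import LatentEmbedder
from .linguistic import AsrChunk, AsrDecoding


class Wav2VecEmbedder(LatentEmbedder):
    """wav2vec 2.0 XLSR-53 hidden states as per-frame latent features."""

    def __init__(self, model_name: str = "facebook/wav2vec2-large-xlsr-53",
                 layer: int = -1):
        self.name = "wav2vec"
        self.output_dimension = 1024
        self.model_name = model_name
        self.layer = layer
        self._model = None

    def _load(self):
        try:
            import torch  # noqa: F401
            from transformers import Wav2Vec2FeatureExtractor, Wav2Vec2Model
        except ImportError as exc:  # pragma: no cover - optional path
            raise ImportError(
                "the wav2vec adapter needs the optional dependencies "
                "'torch' and 'transformers'"
            ) from exc
        self._extractor = Wav2Vec2FeatureExtractor.from_pretrained(self.model_name)
        self._model = Wav2Vec2Model.from_pretrained(self.model_name).eval()

    def transform(self, samples: np.ndarray, sample_rate: int) -> np.ndarray:
        if self._model is None:
            self._load()
        import torch

        inputs = self._extractor(samples, sampling_rate=sample_rate,
                                 return_tensors="pt")
        with torch.no_grad():
            out = self._model(**inputs, output_hidden_states=True)
        return out.hidden_states[self.layer][0].numpy()


class WhisperAsr:
    """Whisper decodings with the repetition-friendly sampling settings.

    Temperature 0.1 with best-of 5 and three independent decodings per
    sample encourages faithful transcription of repeated words, which a
    greedy decode tends to collapse.
    """

    def __init__(self, model_name: str = "medium", language: str | None = None,
                 temperature: float = 0.1, best_of: int = 5,
                 n_decodings: int = 3):
        self.model_name = model_name
        self.language = language
        self.temperature = temperature
        self.best_of = best_of
        self.n_decodings = n_decodings
        self._model = None

    def _load(self):
        try:
            import whisper
        except ImportError as exc:  # pragma: no cover - optional path
            raise ImportError(
                "the Whisper adapter needs the optional dependency 'openai-whisper'"
            ) from exc
        self._model = whisper.load_model(self.model_name)

    def decode(self, samples: np.ndarray, sample_rate: int) -> list[AsrDecoding]:
        if self._model is None:
            self._load()
        decodings = []
        for _ in range(self.n_decodings):
            result = self._model.transcribe(
                samples.astype(np.float32),
                language=self.language,
                temperature=self.temperature,
                best_of=self.best_of,
            )
            decodings.append(AsrDecoding([
                AsrChunk(
                    text=seg["text"],
                    t_start=float(seg["start"]),
                    t_end=float(seg["end"]),
                    p_transcription=float(np.exp(seg.get("avg_logprob", 0.0))),
                    p_nospeech=float(seg.get("no_speech_prob", 0.0)),
                )
                for seg in result["segments"]
            ]))
        return decodings
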