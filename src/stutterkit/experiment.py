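"""Experiment orchestration: the segmentation x features x model grid.

One experiment fixes a segmentation scheme (event or fixed interval),
a window length (2/3/4 s — the interval size, or the event lookback),
a lookback context for events (window ending at the event, or centred
on it), a feature set (acoustic only, or acoustic + linguistic) and a
model (Gaussian-kernel SVM or MLP).  The pipeline is: segment ->
featurize -> scale (fitted on train+validation) -> train (train fold
only) -> evaluate (test fold).  *Input switching* trains on one
scheme's features and scores the other's, which works because both
schemes emit identical column sets.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .acoustic import (
    FoldAwareScaler,
    LatentEmbedder,
    SyntheticEmbedder,
    segment_acoustic_vector,
)
from .classifiers import GaussianKernelSVC, MlpClassifier
from .corpus import AnnotatedRecording, FeatureTable, Fold, SpeakerSplit
from .evaluation import EvaluationReport, classification_report, macro_auc_roc
from .linguistic import LINGUISTIC_NAMES, linguistic_vector, mock_asr_decode
from .segmentation import (
    Context,
    Scheme,
    SpeechSegment,
    attach_lookback,
    extract_events,
    make_intervals,
)
from .synth import tokens_in_window

ACOUSTIC_FEATURES = "acoustic"
FULL_FEATURES = "acoustic+linguistic"


@dataclass
class ExperimentSpec:
    """One cell of the experimental grid."""

    scheme: Scheme
    length: float = 3.0
    context: Context | None = None
    features: str = ACOUSTIC_FEATURES
    model: str = "gsvm"
    seed: int = 0

    def __post_init__(self):
        self.scheme = Scheme(self.scheme)
        if self.context is not None:
            self.context = Context(self.context)
        if self.scheme is Scheme.INTERVAL and self.context is not None:
            raise ValueError("lookback context applies to the EVENT scheme only")
        if self.scheme is Scheme.EVENT and self.context is None:
            self.context = Context.BEFORE
        if self.features not in (ACOUSTIC_FEATURES, FULL_FEATURES):
            raise ValueError(f"unknown feature set {self.features!r}")
        if self.model not in ("gsvm", "mlp"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.length <= 0:
            raise ValueError("length must be positive")

    def config_hash(self) -> str:
        payload = {k: (v.value if hasattr(v, "value") else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def segment_corpus(corpus: list[AnnotatedRecording],
                   spec: ExperimentSpec) -> dict[str, list[SpeechSegment]]:
    """Per-recording segments under the spec's scheme, lookbacks attached."""
    out: dict[str, list[SpeechSegment]] = {}
    for rec in corpus:
        if spec.scheme is Scheme.EVENT:
            segs = [
                attach_lookback(s, rec.duration, spec.length, spec.context)
                for s in extract_events(rec)
            ]
        else:
            segs = make_intervals(rec, spec.length)
        out[rec.recording_id] = segs
    return out


def _segment_seed(base_seed: int, segment_id: str) -> int:
    return (int(base_seed) ^ zlib.crc32(segment_id.encode())) % (2 ** 31)


def build_feature_table(
    corpus: list[AnnotatedRecording],
    split: SpeakerSplit,
    spec: ExperimentSpec,
    embedder: LatentEmbedder | None = None,
) -> FeatureTable:
    """Featurize every segment of the corpus into one fold-tagged table.

    Acoustic features come from the segment's own audio; linguistic
    features (when requested) from three mock-ASR decodings of the
    segment's lookback window (events) or of the interval itself.
    Column order is deterministic and scheme-independent.
    """
    embedder = embedder if embedder is not None else SyntheticEmbedder()
    by_rec = {rec.recording_id: rec for rec in corpus}
    rows, row_ids, folds, labels = [], [], [], []
    columns: list[str] | None = None
    for rid, segments in segment_corpus(corpus, spec).items():
        rec = by_rec[rid]
        if spec.features == FULL_FEATURES and rec.token_times is None:
            raise ValueError(
                f"{rid}: linguistic features requested but no ASR-decodable "
                "transcript timing is available"
            )
        sr = rec.sample_rate
        for seg in segments:
            lo, hi = int(round(seg.start * sr)), int(round(seg.end * sr))
            vec, names = segment_acoustic_vector(rec.samples[lo:hi], sr, embedder)
            if spec.features == FULL_FEATURES:
                lb0, lb1 = seg.lookback_start, seg.lookback_end
                decodings = mock_asr_decode(
                    tokens_in_window(rec, lb0, lb1),
                    window=lb1 - lb0,
                    seed=_segment_seed(spec.seed, seg.segment_id),
                )
                vec = np.concatenate([vec, linguistic_vector(decodings)])
                names = names + LINGUISTIC_NAMES
            if columns is None:
                columns = names
            rows.append(vec)
            row_ids.append(seg.segment_id)
            folds.append(split.fold_of(rec.speaker_id).value)
            labels.append(int(seg.label))
    if not rows:
        raise ValueError("no segments produced from the corpus")
    index = pd.Index(row_ids, name="segment_id")
    return FeatureTable(
        pd.DataFrame(np.vstack(rows), index=index, columns=columns),
        pd.Series(folds, index=index),
        pd.Series(labels, index=index),
    )


def _make_model(spec: ExperimentSpec):
    if spec.model == "gsvm":
        return GaussianKernelSVC(random_state=spec.seed)
    return MlpClassifier(random_state=spec.seed)


def fit_on_train(model, table: FeatureTable):
    """Fit a model on the TRAIN rows only, guarding against fold leakage."""
    train = table.rows_in(Fold.TRAIN)
    if (table.fold_of_row == Fold.TEST.value).sum() == len(table.fold_of_row):
        raise ValueError("training input consists of TEST rows: fold leakage")
    if len(train.values) == 0:
        raise ValueError("no TRAIN rows available")
    model.fit(train.values.to_numpy(), train.labels.to_numpy())
    return model


def _score_matrix(model, X: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Per-class probability scores, zero-filled for classes unseen in training."""
    proba = model.predict_proba(X)
    scores = np.zeros((len(X), n_classes))
    for col, cls in enumerate(model.classes_):
        scores[:, int(cls)] = proba[:, col]
    return scores


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    report: EvaluationReport
    macro_auc: float
    n_rows: int
    config_hash: str


def run_experiment(
    spec: ExperimentSpec,
    corpus: list[AnnotatedRecording],
    split: SpeakerSplit,
    embedder: LatentEmbedder | None = None,
) -> ExperimentResult:
    """Run one grid cell end-to-end and evaluate on the test fold."""
    for fold in Fold:
        if not split.speakers(fold):
            raise ValueError(f"fold {fold.value} has no speakers")
    table = build_feature_table(corpus, split, spec, embedder)
    scaler = FoldAwareScaler().fit(table)
    scaled = scaler.transform(table)
    model = fit_on_train(_make_model(spec), scaled)
    test = scaled.rows_in(Fold.TEST)
    X_test = test.values.to_numpy()
    y_test = test.labels.to_numpy()
    scores = _score_matrix(model, X_test)
    auc = macro_auc_roc(y_test, scores)
    report = classification_report(y_test, model.predict(X_test), scores)
    return ExperimentResult(spec, report, auc, len(table.values),
                            spec.config_hash())


@dataclass
class SwitchResult:
    """Cross-scheme generalisation: trained on one scheme, tested on the other."""

    train_scheme: Scheme
    test_scheme: Scheme
    macro_auc: float
    report: EvaluationReport


def input_switch(
    train_spec: ExperimentSpec,
    test_spec: ExperimentSpec,
    corpus: list[AnnotatedRecording],
    split: SpeakerSplit,
    embedder: LatentEmbedder | None = None,
) -> SwitchResult:
    """Train on ``train_spec``'s features, score ``test_spec``'s test fold.

    The two specs must use different segmentation schemes.  The scaler
    fitted on the training-side table is applied to both sides (the
    trained model only ever sees its own scheme's scaling).
    """
    if Scheme(train_spec.scheme) is Scheme(test_spec.scheme):
        raise ValueError("input switching requires different schemes")
    embedder = embedder if embedder is not None else SyntheticEmbedder()
    train_table = build_feature_table(corpus, split, train_spec, embedder)
    test_table = build_feature_table(corpus, split, test_spec, embedder)
    if train_table.column_names != test_table.column_names:
        raise ValueError("feature columns differ between schemes")
    scaler = FoldAwareScaler().fit(train_table)
    model = fit_on_train(_make_model(train_spec), scaler.transform(train_table))
    test = scaler.transform(test_table).rows_in(Fold.TEST)
    X_test, y_test = test.values.to_numpy(), test.labels.to_numpy()
    scores = _score_matrix(model, X_test)
    return SwitchResult(
        Scheme(train_spec.scheme),
        Scheme(test_spec.scheme),
        macro_auc_roc(y_test, scores),
        classification_report(y_test, model.predict(X_test), scores),
    )
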