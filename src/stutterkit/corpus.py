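"""Data model and I/O for annotated stuttered-speech corpora.

A corpus is a collection of :class:`AnnotatedRecording` objects: a mono
waveform, a time-ordered list of labelled fluency events (syllable-level
annotations marking fluent speech, prolongations, part-word repetitions,
whole-word repetitions and blocks), a speaker id and a reference
transcript.  Annotations travel as a tab-separated table; Praat TextGrid
interval tiers can be imported.  Speaker-level train/validation/test
splits are *hard*: a speaker contributes to exactly one fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile


class FluencyClass(IntEnum):
    """The five fluency classes, with a fixed ordinal index (0..4).

    The index order is load-bearing: confusion matrices, score matrices
    and class-weight vectors all use it.
    """

    FLUENT = 0
    PROLONGATION = 1
    PWR = 2
    WWR = 3
    BLOCK = 4


N_CLASSES = len(FluencyClass)

_LABEL_ALIASES = {
    "fluent": FluencyClass.FLUENT,
    "prolongation": FluencyClass.PROLONGATION,
    "pwr": FluencyClass.PWR,
    "part-word repetition": FluencyClass.PWR,
    "wwr": FluencyClass.WWR,
    "whole-word repetition": FluencyClass.WWR,
    "block": FluencyClass.BLOCK,
}


def parse_label(text: str) -> FluencyClass:
    """Map an annotation label string to a :class:`FluencyClass`."""
    try:
        return _LABEL_ALIASES[text.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown fluency label {text!r}; accepted labels: "
            f"{sorted(set(_LABEL_ALIASES))}"
        ) from None


class Fold(str, Enum):
    TRAIN = "TRAIN"
    VALIDATION = "VALIDATION"
    TEST = "TEST"


@dataclass(frozen=True)
class FluencyEvent:
    """One labelled speech event with half-open time support [onset, offset)."""

    label: FluencyClass
    onset: float
    offset: float

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ValueError(
                f"event offset must exceed onset, got [{self.onset}, {self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class AnnotatedRecording:
    """A mono recording with aligned fluency events and reference transcript.

    ``samples`` may be ``None`` for annotation-only workflows; the audio
    duration then falls back to the last event offset.  ``token_times``
    optionally aligns each reference-transcript token to the waveform
    (used by the mock ASR to pick tokens inside a lookback window).
    """

    recording_id: str
    speaker_id: str
    sample_rate: int
    samples: np.ndarray | None
    events: list[FluencyEvent] = field(default_factory=list)
    reference_transcript: list[str] = field(default_factory=list)
    token_times: list[tuple[str, float, float]] | None = None

    @property
    def duration(self) -> float:
        if self.samples is not None:
            return len(self.samples) / self.sample_rate
        return max((e.offset for e in self.events), default=0.0)

    def validate(self) -> "AnnotatedRecording":
        """Check ordering, non-overlap and audio-range invariants."""
        if self.sample_rate <= 0:
            raise ValueError(f"{self.recording_id}: sample_rate must be positive")
        ev = sorted(self.events, key=lambda e: e.onset)
        for a, b in zip(ev, ev[1:]):
            if b.onset < a.offset - 1e-9:
                raise ValueError(
                    f"{self.recording_id}: overlapping events "
                    f"[{a.onset}, {a.offset}) and [{b.onset}, {b.offset})"
                )
        if self.samples is not None:
            dur = self.duration
            for e in ev:
                if e.onset < -1e-9 or e.offset > dur + 1e-6:
                    raise ValueError(
                        f"{self.recording_id}: event [{e.onset}, {e.offset}) "
                        f"outside audio duration {dur:.3f}s"
                    )
        self.events = ev
        return self


ANNOTATION_COLUMNS = ["recording_id", "speaker_id", "label", "onset_s", "offset_s"]


def read_annotations(
    path: str | Path,
    dialect: str = "tsv",
    audio_dir: str | Path | None = None,
    tier: str | None = None,
    recording_id: str | None = None,
    speaker_id: str | None = None,
) -> list[AnnotatedRecording]:
    """Read annotations into validated :class:`AnnotatedRecording` objects.

    Parameters
    ----------
    path
        Annotation file.  ``tsv`` dialect: UTF-8, header row, columns
        ``recording_id, speaker_id, label, onset_s, offset_s``.
        ``textgrid`` dialect: a Praat TextGrid; one interval tier (named
        ``tier``, default the first tier) is mapped to events, empty-text
        intervals skipped; ``recording_id``/``speaker_id`` identify the
        single resulting recording.
    audio_dir
        If given, ``<recording_id>.wav`` is loaded for each recording
        (PCM mono; stereo is downmixed by channel averaging).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        recs = _read_tsv(path)
    elif dialect == "textgrid":
        rid = recording_id or path.stem
        recs = [_read_textgrid(path, rid, speaker_id or rid, tier)]
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'textgrid')")
    if audio_dir is not None:
        audio_dir = Path(audio_dir)
        for rec in recs:
            sr, samples = read_wav(audio_dir / f"{rec.recording_id}.wav")
            rec.sample_rate = sr
            rec.samples = samples
    return [r.validate() for r in recs]


def _read_tsv(path: Path) -> list[AnnotatedRecording]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    recs: dict[str, AnnotatedRecording] = {}
    for row in df.itertuples(index=False):
        rid = row.recording_id
        if rid not in recs:
            recs[rid] = AnnotatedRecording(
                recording_id=rid, speaker_id=row.speaker_id,
                sample_rate=16000, samples=None,
            )
        recs[rid].events.append(
            FluencyEvent(parse_label(row.label), float(row.onset_s), float(row.offset_s))
        )
    return list(recs.values())


def write_annotations(recordings: list[AnnotatedRecording], path: str | Path,
                      decimals: int = 6) -> None:
    """Write the TSV annotation dialect; times at fixed decimal precision."""
    rows = [
        {
            "recording_id": rec.recording_id,
            "speaker_id": rec.speaker_id,
            "label": ev.label.name.lower(),
            "onset_s": f"{ev.onset:.{decimals}f}",
            "offset_s": f"{ev.offset:.{decimals}f}",
        }
        for rec in recordings
        for ev in rec.events
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_textgrid(path: Path, recording_id: str, speaker_id: str,
                   tier: str | None) -> AnnotatedRecording:
    # Minimal long/short TextGrid interval-tier reader.  Collects, per
    # IntervalTier, the (xmin, xmax, text) triples; non-empty texts become
    # events on the selected tier.
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    tiers: list[tuple[str, list[tuple[float, float, str]]]] = []
    cur_name, cur_items = None, []
    pending: list[float] = []
    for raw in text.splitlines():
        line = raw.strip()
        if '"IntervalTier"' in line or '"TextTier"' in line:
            if cur_name is not None:
                tiers.append((cur_name, cur_items))
            cur_name, cur_items, pending = "", [], []
            continue
        if cur_name is None:
            continue
        if line.startswith("name") and "=" in line:
            cur_name = line.split("=", 1)[1].strip().strip('"')
        elif line.startswith(("xmin", "xmax")) and "=" in line:
            pending.append(float(line.split("=", 1)[1].strip()))
        elif line.startswith("text") and "=" in line:
            label = line.split("=", 1)[1].strip().strip('"')
            if len(pending) >= 2:
                cur_items.append((pending[-2], pending[-1], label))
            pending = []
    if cur_name is not None:
        tiers.append((cur_name, cur_items))
    if not tiers:
        raise ValueError(f"{path}: no interval tiers found")
    if tier is None:
        name, items = tiers[0]
    else:
        match = [t for t in tiers if t[0] == tier]
        if not match:
            raise ValueError(f"{path}: no tier named {tier!r}; "
                             f"available: {[t[0] for t in tiers]}")
        name, items = match[0]
    events = [FluencyEvent(parse_label(lab), a, b)
              for a, b, lab in items if lab.strip()]
    return AnnotatedRecording(recording_id, speaker_id, 16000, None, events)


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a WAV file to float64 samples in [-1, 1]; stereo is averaged."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(np.int16).max
                                               if data.dtype.itemsize <= 2
                                               else np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return int(sr), data


def write_wav(path: str | Path, sample_rate: int, samples: np.ndarray) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM."""
    clipped = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, sample_rate, (clipped * 32767).astype(np.int16))


@dataclass
class SpeakerSplit:
    """Hard speaker partition into train/validation/test folds."""

    assignment: dict[str, Fold]

    def __post_init__(self):
        for spk, fold in self.assignment.items():
            self.assignment[spk] = Fold(fold)

    def fold_of(self, speaker_id: str) -> Fold:
        return self.assignment[speaker_id]

    def speakers(self, fold: Fold) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)


def assign_speaker_split(
    speakers: list[str], counts: tuple[int, int, int], seed: int
) -> SpeakerSplit:
    """Randomly (but reproducibly) partition speakers into the three folds.

    ``counts`` gives ``(n_train, n_validation, n_test)`` and must sum to
    the number of speakers.  The shuffle is seeded, never row-order based.
    """
    n_train, n_val, n_test = counts
    if n_train + n_val + n_test != len(speakers):
        raise ValueError(
            f"fold counts {counts} sum to {n_train + n_val + n_test}, "
            f"but there are {len(speakers)} speakers"
        )
    order = list(speakers)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    assignment: dict[str, Fold] = {}
    for spk in order[:n_train]:
        assignment[spk] = Fold.TRAIN
    for spk in order[n_train:n_train + n_val]:
        assignment[spk] = Fold.VALIDATION
    for spk in order[n_train + n_val:]:
        assignment[spk] = Fold.TEST
    return SpeakerSplit(assignment)


@dataclass
class FeatureTable:
    """Segments-by-features matrix with per-row fold tags.

    ``values`` is a DataFrame indexed by segment id; ``fold_of_row``
    is aligned to the same index.  Column order is deterministic and
    identical across event- and interval-derived tables so a model
    trained on one scheme can score the other (input switching).
    """

    values: pd.DataFrame
    fold_of_row: pd.Series
    labels: pd.Series | None = None

    def __post_init__(self):
        if not self.values.index.equals(self.fold_of_row.index):
            raise ValueError("fold tags must align with the feature rows")
        if self.labels is not None and not self.values.index.equals(self.labels.index):
            raise ValueError("labels must align with the feature rows")
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    def rows_in(self, *folds: Fold) -> "FeatureTable":
        mask = self.fold_of_row.isin([Fold(f).value for f in folds])
        return FeatureTable(
            self.values.loc[mask],
            self.fold_of_row.loc[mask],
            None if self.labels is None else self.labels.loc[mask],
        )

    def to_csv(self, path: str | Path) -> None:
        """Persist as CSV plus a JSON sidecar with fold tags and labels."""
        path = Path(path)
        self.values.to_csv(path, index_label="segment_id")
        sidecar = {
            "columns": self.column_names,
            "fold_of_row": self.fold_of_row.to_dict(),
            "labels": None if self.labels is None
            else {k: int(v) for k, v in self.labels.items()},
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        values = pd.read_csv(path, index_col="segment_id")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        folds = pd.Series(sidecar["fold_of_row"]).reindex(values.index)
        labels = sidecar.get("labels")
        if labels is not None:
            labels = pd.Series(labels).reindex(values.index).astype(int)
        return cls(values[sidecar["columns"]], folds, labels)
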