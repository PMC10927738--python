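"""Event- and interval-based segmentation of annotated recordings.

Two segmentation schemes produce the observation units for the whole
pipeline.  *Event-based* segmentation emits one segment per annotated
syllable event, preserving its exact onset/offset and label.
*Interval-based* segmentation chops the recording into fixed-length
windows (2, 3 or 4 s) and assigns each window a single label by the
validity rules: fluent iff only fluent events overlap, a disfluent class
iff exactly one distinct disfluent class overlaps (fluent co-occurrence
allowed), dropped otherwise (several disfluent classes, or silence).

The module also computes class-frequency distributions and the Pearson
chi-square test of independence used to compare them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .corpus import AnnotatedRecording, FluencyClass, N_CLASSES


class Scheme(str, Enum):
    EVENT = "EVENT"
    INTERVAL = "INTERVAL"


class Context(str, Enum):
    """Placement of the lookback window relative to an event."""

    BEFORE = "BEFORE"
    MIDDLE = "MIDDLE"


class DropReason(str, Enum):
    MULTIPLE = "multiple"
    SILENT = "silent"
    INTERLOCUTOR = "interlocutor"


@dataclass(frozen=True)
class SpeechSegment:
    """One observation unit (an event or a fixed-length interval)."""

    segment_id: str
    recording_id: str
    scheme: Scheme
    label: FluencyClass
    start: float
    end: float
    lookback_start: float | None = None
    lookback_end: float | None = None
    interval_length: float | None = None

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError(f"segment end must exceed start: [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


def _overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    # Nonzero intersection of half-open intervals [a0,a1) and [b0,b1).
    return a0 < b1 and b0 < a1


def extract_events(rec: AnnotatedRecording) -> list[SpeechSegment]:
    """One EVENT segment per annotated fluency event, in onset order."""
    return [
        SpeechSegment(
            segment_id=f"{rec.recording_id}:ev{i:05d}",
            recording_id=rec.recording_id,
            scheme=Scheme.EVENT,
            label=ev.label,
            start=ev.onset,
            end=ev.offset,
        )
        for i, ev in enumerate(rec.events)
    ]


def label_interval(
    rec: AnnotatedRecording, start: float, end: float
) -> FluencyClass | DropReason:
    """Assign one label to [start, end) or a :class:`DropReason`.

    FLUENT iff at least one fluent event overlaps and no disfluent event
    does; a disfluent class iff exactly one distinct disfluent class
    overlaps (fluent speech may co-occur — the whole interval is marked
    stuttered); ``MULTIPLE`` iff two or more distinct disfluent classes
    overlap; ``SILENT`` iff nothing overlaps.
    """
    if start < -1e-9 or end > rec.duration + 1e-6 or end <= start:
        raise ValueError(
            f"interval [{start}, {end}) outside recording "
            f"{rec.recording_id} of duration {rec.duration:.3f}s"
        )
    overlapping = {
        ev.label for ev in rec.events if _overlaps(ev.onset, ev.offset, start, end)
    }
    if not overlapping:
        return DropReason.SILENT
    disfluent = overlapping - {FluencyClass.FLUENT}
    if not disfluent:
        return FluencyClass.FLUENT
    if len(disfluent) == 1:
        return disfluent.pop()
    return DropReason.MULTIPLE


def make_intervals(
    rec: AnnotatedRecording,
    length: float,
    return_drops: bool = False,
) -> list[SpeechSegment] | tuple[list[SpeechSegment], list[tuple[float, float, DropReason]]]:
    """Fixed-length interval segments [0,L), [L,2L), ... with valid labels.

    The trailing remainder shorter than ``length`` is dropped, as are
    intervals without a single valid label (several disfluent classes,
    or silence).  With ``return_drops`` the dropped candidates and their
    reasons are returned for audit.
    """
    if length <= 0:
        raise ValueError(f"interval length must be positive, got {length}")
    segments: list[SpeechSegment] = []
    drops: list[tuple[float, float, DropReason]] = []
    k = 0
    while (k + 1) * length <= rec.duration + 1e-9:
        start, end = k * length, min((k + 1) * length, rec.duration)
        outcome = label_interval(rec, start, end)
        if isinstance(outcome, DropReason):
            drops.append((start, end, outcome))
        else:
            segments.append(
                SpeechSegment(
                    segment_id=f"{rec.recording_id}:iv{length:g}s{k:05d}",
                    recording_id=rec.recording_id,
                    scheme=Scheme.INTERVAL,
                    label=outcome,
                    start=start,
                    end=end,
                    lookback_start=start,
                    lookback_end=end,
                    interval_length=length,
                )
            )
        k += 1
    return (segments, drops) if return_drops else segments


def attach_lookback(
    seg: SpeechSegment,
    rec_duration: float,
    window: float,
    context: Context = Context.BEFORE,
) -> SpeechSegment:
    """Attach the fixed-duration context window used for linguistic features.

    BEFORE ends the window at the event's end; MIDDLE centres it on the
    event midpoint.  Windows are clipped to [0, rec_duration]; when
    clipping shortens the window the longest available extent is used.
    """
    if window <= 0:
        raise ValueError(f"lookback window must be positive, got {window}")
    context = Context(context)
    if context is Context.BEFORE:
        lb0, lb1 = seg.end - window, seg.end
    else:
        mid = (seg.start + seg.end) / 2.0
        lb0, lb1 = mid - window / 2.0, mid + window / 2.0
    lb0 = max(0.0, lb0)
    lb1 = min(rec_duration, lb1)
    return replace(seg, lookback_start=lb0, lookback_end=lb1)


@dataclass
class ClassDistribution:
    """Counts, relative frequencies (%) and ratio-to-fluent per class."""

    counts: dict[FluencyClass, int]
    total: int
    relative_frequencies: dict[FluencyClass, float]
    ratio_to_fluent: dict[FluencyClass, float]
    empty: bool = False

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in FluencyClass], dtype=float)


def class_distribution(
    segments_or_counts: list[SpeechSegment] | dict[FluencyClass, int] | list[int],
) -> ClassDistribution:
    """Summarise a segment list (or raw counts) as a class distribution.

    Percentages are kept at full precision; rounding is presentation-side
    only.  An all-zero input is flagged ``empty`` with zero frequencies.
    """
    if isinstance(segments_or_counts, dict):
        counts = {c: int(segments_or_counts.get(c, 0)) for c in FluencyClass}
    elif segments_or_counts and isinstance(segments_or_counts[0], SpeechSegment):
        counts = {c: 0 for c in FluencyClass}
        for seg in segments_or_counts:
            counts[seg.label] += 1
    else:
        vals = list(segments_or_counts)
        if len(vals) not in (0, N_CLASSES):
            raise ValueError(f"expected {N_CLASSES} counts, got {len(vals)}")
        counts = {c: int(vals[c]) if vals else 0 for c in FluencyClass}
    total = sum(counts.values())
    if total == 0:
        zero = {c: 0.0 for c in FluencyClass}
        return ClassDistribution(counts, 0, dict(zero), dict(zero), empty=True)
    rel = {c: 100.0 * n / total for c, n in counts.items()}
    n_fluent = counts[FluencyClass.FLUENT]
    ratio = {
        c: (n / n_fluent if n_fluent > 0 else 0.0) for c, n in counts.items()
    }
    return ClassDistribution(counts, total, rel, ratio)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float


def chi_square_independence(
    table: np.ndarray | list[list[float]],
    drop_classes: list[FluencyClass] | None = None,
) -> ChiSquareResult:
    """Pearson chi-square test of independence on a counts matrix.

    Rows are distributions (e.g. the two segmentation schemes), columns
    are classes.  ``drop_classes`` removes columns by class index before
    testing (used to compare stutter-only distributions with fluent
    speech excluded).  No continuity correction is applied.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("counts table must be 2-dimensional")
    if drop_classes:
        keep = [i for i in range(obs.shape[1]) if i not in {int(c) for c in drop_classes}]
        obs = obs[:, keep]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns after drops")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any():
        raise ValueError(f"zero row margin at row {int(np.argmin(row))}")
    if (col == 0).any():
        raise ValueError(f"zero column margin at column {int(np.argmin(col))}")
    expected = np.outer(row, col) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_chi2_dist.sf(statistic, df))
    return ChiSquareResult(statistic, df, p)
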