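"""Evaluation: macro AUC-ROC, classification reports, and word error rate.

The headline model metric is the *unweighted* (macro) one-vs-rest
AUC-ROC: each class present in the test truth contributes equally,
which keeps the dominant fluent class from masking performance on the
rarer stutter types.  Word error rate follows the standard alignment
definition WER = (S + D + I) / N over a minimal-edit alignment of the
reference and hypothesis token sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support as _sk_prfs,
    roc_auc_score as _sk_auc,
)

from .corpus import FluencyClass, N_CLASSES


def macro_auc_roc(true_labels: np.ndarray, score_matrix: np.ndarray) -> float:
    """Unweighted mean of one-vs-rest AUCs over classes present in truth.

    ``score_matrix`` columns are per-class scores indexed by class id.
    Classes absent from the truth cannot have an ROC curve and are
    excluded with a warning; a single-class truth is an error.
    """
    y = np.asarray(true_labels, dtype=int)
    scores = np.asarray(score_matrix, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("score matrix contains non-finite values")
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("macro AUC undefined: fewer than 2 classes in truth")
    if len(present) < scores.shape[1]:
        absent = sorted(set(range(scores.shape[1])) - set(present.tolist()))
        warnings.warn(f"classes {absent} absent from truth; excluded from macro AUC")
    per_class = [_sk_auc((y == c).astype(int), scores[:, c]) for c in present]
    return float(np.mean(per_class))


@dataclass
class EvaluationReport:
    """Per-class precision/recall/F1 (%), confusion matrix and averages."""

    precision: dict[FluencyClass, float]
    recall: dict[FluencyClass, float]
    f1: dict[FluencyClass, float]
    support: dict[FluencyClass, int]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: np.ndarray
    macro_auc: float | None = None
    undefined_precision_classes: list[FluencyClass] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c.name: {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    "support": self.support[c],
                }
                for c in FluencyClass
            },
            "accuracy": self.accuracy,
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall, "f1": self.macro_f1},
            "weighted": {"precision": self.weighted_precision,
                         "recall": self.weighted_recall, "f1": self.weighted_f1},
            "macro_auc": self.macro_auc,
            "confusion": self.confusion.tolist(),
        }

    def to_markdown(self) -> str:
        lines = ["| Class | Precision | Recall | F1 | Support |",
                 "|---|---|---|---|---|"]
        for c in FluencyClass:
            lines.append(
                f"| {c.name.title()} | {self.precision[c]:.2f} | "
                f"{self.recall[c]:.2f} | {self.f1[c]:.2f} | {self.support[c]} |"
            )
        lines.append(f"| Accuracy | | | {self.accuracy:.2f} | "
                     f"{sum(self.support.values())} |")
        if self.macro_auc is not None:
            lines.append(f"| Macro AUC-ROC | | | {self.macro_auc:.3f} | |")
        return "\n".join(lines)


def classification_report(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    score_matrix: np.ndarray | None = None,
) -> EvaluationReport:
    """Five-class report with percentages, confusion matrix and averages.

    Precision for a class nobody was predicted into is undefined; it is
    reported as 0 and the class recorded in
    ``undefined_precision_classes``.  Weighted averages use supports
    over classes present in the truth.
    """
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} true vs {len(p)} predicted")
    labels = list(range(N_CLASSES))
    prec, rec, f1, supp = _sk_prfs(y, p, labels=labels, zero_division=0)
    confusion = _sk_confusion(y, p, labels=labels)
    undefined = [
        FluencyClass(c) for c in labels
        if (p == c).sum() == 0 and (y == c).sum() > 0
    ]
    present = [c for c in labels if supp[c] > 0]
    weights = supp[present] / supp[present].sum()
    report = EvaluationReport(
        precision={FluencyClass(c): 100.0 * prec[c] for c in labels},
        recall={FluencyClass(c): 100.0 * rec[c] for c in labels},
        f1={FluencyClass(c): 100.0 * f1[c] for c in labels},
        support={FluencyClass(c): int(supp[c]) for c in labels},
        accuracy=100.0 * float((y == p).mean()),
        macro_precision=100.0 * float(np.mean(prec[present])),
        macro_recall=100.0 * float(np.mean(rec[present])),
        macro_f1=100.0 * float(np.mean(f1[present])),
        weighted_precision=100.0 * float(prec[present] @ weights),
        weighted_recall=100.0 * float(rec[present] @ weights),
        weighted_f1=100.0 * float(f1[present] @ weights),
        confusion=confusion,
        undefined_precision_classes=undefined,
    )
    if score_matrix is not None:
        report.macro_auc = macro_auc_roc(y, score_matrix)
    return report


@dataclass(frozen=True)
class WerReport:
    """Word-error-rate components: WER (%) = (S + D + I) / N x 100."""

    substitutions: int
    deletions: int
    insertions: int
    correct: int
    n_reference: int

    def __post_init__(self):
        if min(self.substitutions, self.deletions, self.insertions,
               self.correct, self.n_reference) < 0:
            raise ValueError("WER counts must be non-negative")
        if self.substitutions + self.deletions + self.correct != self.n_reference:
            raise ValueError(
                "inconsistent counts: S + D + correct must equal N "
                f"({self.substitutions}+{self.deletions}+{self.correct} "
                f"!= {self.n_reference})"
            )

    @property
    def wer(self) -> float:
        """WER in percent; may exceed 100 when insertions dominate."""
        return 100.0 * (self.substitutions + self.deletions + self.insertions) \
            / self.n_reference

    @classmethod
    def from_counts(cls, substitutions: int, deletions: int, insertions: int,
                    n_reference: int) -> "WerReport":
        """Build a report from printed S/D/I/N counts (correct = N - S - D)."""
        return cls(substitutions, deletions, insertions,
                   n_reference - substitutions - deletions, n_reference)


def wer(reference_tokens: list[str], hypothesis_tokens: list[str]) -> WerReport:
    """Minimal-edit alignment WER with a canonical S/D/I split.

    Unit costs for substitution, deletion and insertion.  At equal-cost
    ties the backtrace prefers match/substitute over delete over insert,
    which makes the S/D/I split deterministic (the total edit count is
    alignment-invariant regardless).
    """
    ref = list(reference_tokens)
    hyp = list(hypothesis_tokens)
    if not ref:
        raise ValueError("reference must be non-empty")
    n, m = len(ref), len(hyp)
    dist = np.zeros((n + 1, m + 1), dtype=np.int64)
    dist[:, 0] = np.arange(n + 1)
    dist[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dist[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1])
            dist[i, j] = min(sub, dist[i - 1, j] + 1, dist[i, j - 1] + 1)
    s = d = ins = correct = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and \
                dist[i, j] == dist[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            if ref[i - 1] == hyp[j - 1]:
                correct += 1
            else:
                s += 1
            i, j = i - 1, j - 1
        elif i > 0 and dist[i, j] == dist[i - 1, j] + 1:
            d += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return WerReport(s, d, ins, correct, n)


def aggregate_wer(per_file: list[WerReport]) -> WerReport:
    """Pool S/D/I/correct counts across files; WER from the summed counts."""
    if not per_file:
        raise ValueError("need at least one report to aggregate")
    return WerReport(
        substitutions=sum(r.substitutions for r in per_file),
        deletions=sum(r.deletions for r in per_file),
        insertions=sum(r.insertions for r in per_file),
        correct=sum(r.correct for r in per_file),
        n_reference=sum(r.n_reference for r in per_file),
    )
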