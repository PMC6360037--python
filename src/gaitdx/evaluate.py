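"""Patient-level evaluation: majority voting, top-k accuracy, confusion.

A patient's predicted form is the one most frequently assigned across that
patient's trials (MLP/SVM) or windows (LSTM); each prediction contributes
its argmax form to the count.  Top-k accuracy asks whether the true form is
among the k most frequent predicted forms.  Frequency ties break toward the
lower form index and are flagged, since neighbouring forms can genuinely
overlap clinically.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .models import Prediction

logger = logging.getLogger(__name__)

N_FORMS = 4


@dataclasses.dataclass
class PatientScore:
    """Prediction counts over one patient's trials or windows."""

    patient_id: str
    form_frequencies: np.ndarray  # length 4, counts
    true_form: int
    tie: bool = False

    def __post_init__(self):
        self.form_frequencies = np.asarray(self.form_frequencies, dtype=int)
        if self.form_frequencies.shape != (N_FORMS,) or np.any(self.form_frequencies < 0):
            raise ValueError("form_frequencies must be 4 non-negative counts")

    def ranked_forms(self) -> list[int]:
        """Forms ordered by descending frequency, lower index first on ties."""
        return sorted(range(1, N_FORMS + 1), key=lambda f: (-self.form_frequencies[f - 1], f))

    @property
    def top_form(self) -> int:
        return self.ranked_forms()[0]


@dataclasses.dataclass
class EvalReport:
    """Per-form and overall top-1/top-2 accuracies plus confusion matrix."""

    per_form_top1: dict[int, float]
    per_form_top2: dict[int, float]
    overall_top1: float
    overall_top2: float
    confusion_matrix: np.ndarray  # rows = ground truth, cols = predicted
    n_patients: dict[int, int]

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("form,T1,T2\n")
            for form in sorted(self.per_form_top1):
                fh.write(
                    f"{form},{self.per_form_top1[form]:.4f},{self.per_form_top2[form]:.4f}\n"
                )
            fh.write(f"overall,{self.overall_top1:.4f},{self.overall_top2:.4f}\n")

    def confusion_to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("true_form," + ",".join(f"pred_{j}" for j in range(1, 5)) + "\n")
            for i in range(N_FORMS):
                row = ",".join(str(int(v)) for v in self.confusion_matrix[i])
                fh.write(f"{i + 1},{row}\n")


def aggregate_patient(
    predictions: list[Prediction], true_forms: dict[str, int]
) -> list[PatientScore]:
    """Count argmax forms per patient over all of their predictions.

    ``true_forms`` maps patient id to the ground-truth form.  Patients
    present in ``true_forms`` but with no predictions are excluded with a
    warning.  Aggregation granularity (trial vs window) is set by what the
    predictions were made on.
    """
    counts: dict[str, np.ndarray] = {}
    for pred in predictions:
        if pred.patient_id is None:
            raise ValueError("every prediction must carry a patient_id")
        c = counts.setdefault(pred.patient_id, np.zeros(N_FORMS, dtype=int))
        c[pred.form - 1] += 1
    missing = set(true_forms) - set(counts)
    for pid in sorted(missing):
        warnings.warn(f"patient {pid} has no predictions; excluded from scoring")
    scores = []
    for pid, freq in sorted(counts.items()):
        if pid not in true_forms:
            raise ValueError(f"no ground-truth form for patient {pid}")
        top = freq.max()
        tie = int(np.sum(freq == top)) > 1
        scores.append(PatientScore(pid, freq, true_forms[pid], tie=tie))
    return scores


def topk_accuracy(scores: list[PatientScore], k: int) -> tuple[dict[int, float], float]:
    """Per-form and overall fraction of patients whose true form is among
    their k most frequent predicted forms.  Overall is patient-weighted."""
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    if not scores:
        raise ValueError("empty score list")
    per_form: dict[int, float] = {}
    for form in sorted({s.true_form for s in scores}):
        members = [s for s in scores if s.true_form == form]
        hits = sum(form in s.ranked_forms()[:k] for s in members)
        per_form[form] = hits / len(members)
    overall = sum(s.true_form in s.ranked_forms()[:k] for s in scores) / len(scores)
    return per_form, overall


def confusion(scores: list[PatientScore]) -> np.ndarray:
    """4 x 4 patient-count matrix: entry (i, j) = patients of true form i+1
    whose majority-vote prediction is form j+1."""
    if not scores:
        raise ValueError("empty score list")
    mat = np.zeros((N_FORMS, N_FORMS), dtype=int)
    for s in scores:
        mat[s.true_form - 1, s.top_form - 1] += 1
    return mat


def evaluate(scores: list[PatientScore]) -> EvalReport:
    """Full patient-level report: top-1/top-2 accuracies and confusion."""
    per1, overall1 = topk_accuracy(scores, 1)
    per2, overall2 = topk_accuracy(scores, 2)
    counts = {
        form: sum(s.true_form == form for s in scores) for form in sorted(per1)
    }
    return EvalReport(per1, per2, overall1, overall2, confusion(scores), counts)
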