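"""Patient-wise dataset assembly: splitting, augmentation, example lists.

Trials of one patient are never divided between training and test — the
classifiers must generalise to unseen patients, not unseen walks of known
patients.  The split is drawn per form (stratified) at a 0.75 : 0.25
ratio by default.  The under-represented form 1 is balanced by duplicating
its training trials; test data are never augmented.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .errors import CannotSplitError
from .features import SpectralFeatures, WindowSet

logger = logging.getLogger(__name__)

N_FORMS = 4


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    """Disjoint per-form train/test patient-id sets."""

    train_patients: dict[int, frozenset[str]]
    test_patients: dict[int, frozenset[str]]
    seed: int

    def __post_init__(self):
        for form in self.train_patients:
            overlap = self.train_patients[form] & self.test_patients.get(form, frozenset())
            if overlap:
                raise ValueError(f"patients in both partitions: {sorted(overlap)}")

    @property
    def all_train(self) -> frozenset[str]:
        return frozenset().union(*self.train_patients.values())

    @property
    def all_test(self) -> frozenset[str]:
        return frozenset().union(*self.test_patients.values())


@dataclasses.dataclass
class LabeledExample:
    """One classifier example: a feature array with a one-hot form label."""

    features: np.ndarray  # (1620,) spectral mode or (75, 81) window mode
    label: np.ndarray     # one-hot over the 4 forms
    patient_id: str
    trial_id: str | None = None

    def __post_init__(self):
        self.label = np.asarray(self.label, dtype=float)
        if self.label.shape != (N_FORMS,) or abs(self.label.sum() - 1.0) > 1e-9:
            raise ValueError("label must be one-hot over the 4 forms")

    @property
    def form(self) -> int:
        return int(np.argmax(self.label)) + 1


def one_hot(form: int) -> np.ndarray:
    if form not in (1, 2, 3, 4):
        raise ValueError(f"form must be in 1..4, got {form}")
    v = np.zeros(N_FORMS)
    v[form - 1] = 1.0
    return v


def split_patients(trials, ratio: float = 0.75, seed: int = 0) -> DatasetSplit:
    """Randomly partition patients per form at the given train fraction.

    Rounds to the nearest patient count while keeping at least one test
    and one train patient per form; deterministic under a fixed seed.

    Raises
    ------
    CannotSplitError
        If some form has fewer than 2 patients.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0, 1)")
    form_of: dict[str, int] = {}
    for t in trials:
        if t.patient_id is None or t.form is None:
            raise ValueError("every trial needs patient_id and form for splitting")
        prev = form_of.setdefault(t.patient_id, t.form)
        if prev != t.form:
            raise ValueError(f"patient {t.patient_id} has inconsistent form labels")
    rng = np.random.default_rng(seed)
    train: dict[int, frozenset[str]] = {}
    test: dict[int, frozenset[str]] = {}
    for form in sorted({f for f in form_of.values()}):
        patients = sorted(p for p, f in form_of.items() if f == form)
        if len(patients) < 2:
            raise CannotSplitError(
                f"form {form} has {len(patients)} patient(s); need >= 2 to split"
            )
        perm = rng.permutation(len(patients))
        n_train = int(round(ratio * len(patients)))
        n_train = min(max(n_train, 1), len(patients) - 1)
        train[form] = frozenset(patients[i] for i in perm[:n_train])
        test[form] = frozenset(patients[i] for i in perm[n_train:])
    return DatasetSplit(train, test, seed)


def augment_form(train_items: list, form: int, factor: int = 2) -> list:
    """Duplicate every training item of one form ``factor - 1`` extra times.

    Works on any items carrying a ``form`` attribute (trials, feature
    objects, examples).  Content is never copied, only referenced again, so
    augmentation changes multiplicity but not the set of distinct items.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out = []
    for item in train_items:
        out.append(item)
        if item.form == form:
            out.extend([item] * (factor - 1))
    return out


def _partition(items, split: DatasetSplit):
    train_ids, test_ids = split.all_train, split.all_test
    train, test = [], []
    for it in items:
        if it.patient_id in train_ids:
            train.append(it)
        elif it.patient_id in test_ids:
            test.append(it)
        else:
            logger.warning("item %s: patient %s not in split; skipped",
                           getattr(it, "trial_id", None), it.patient_id)
    return train, test


def _check_disjoint(train, test):
    crossing = {e.patient_id for e in train} & {e.patient_id for e in test}
    if crossing:
        raise AssertionError(f"patients cross the split boundary: {sorted(crossing)}")


def assemble_mlp_dataset(
    features: list[SpectralFeatures], split: DatasetSplit
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """One flattened 1620-dim example per trial (spectral mode)."""
    train_f, test_f = _partition(features, split)
    train = [
        LabeledExample(f.flatten(), one_hot(f.form), f.patient_id, f.trial_id)
        for f in train_f
    ]
    test = [
        LabeledExample(f.flatten(), one_hot(f.form), f.patient_id, f.trial_id)
        for f in test_f
    ]
    _check_disjoint(train, test)
    return train, test


def assemble_rnn_dataset(
    window_sets: list[WindowSet], split: DatasetSplit
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """One 75 x 81 example per window (sequence mode)."""
    train_w, test_w = _partition(window_sets, split)

    def expand(sets):
        return [
            LabeledExample(w, one_hot(ws.form), ws.patient_id, ws.trial_id)
            for ws in sets
            for w in ws.windows
        ]

    train, test = expand(train_w), expand(test_w)
    _check_disjoint(train, test)
    return train, test


def split_to_csv(split: DatasetSplit, path) -> None:
    """Write the split manifest as CSV ``patient_id,form,partition``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id,form,partition\n")
        for form in sorted(split.train_patients):
            for pid in sorted(split.train_patients[form]):
                fh.write(f"{pid},{form},train\n")
            for pid in sorted(split.test_patients[form]):
                fh.write(f"{pid},{form},test\n")
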