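"""Trial containers and readers/writers for motion-capture walking trials.

A trial is a labelled sequence of 19 reflective-marker positions (millimetres,
lab coordinates) sampled at a constant frame rate.  The marker set is the
standard upper+lower body protocol used in clinical gait analysis:

========  =====================================================
C7        7th cervical vertebra
LA / RA   left / right acromioclavicular joint
LEP / REP left / right lateral elbow epicondyle
LUL / RUL left / right lateral prominence of the ulna
LASIS...  anterior / posterior superior iliac spines
LGT / RGT greater trochanters
LLE / RLE lateral knee epicondyles
LCA / RCA calcaneus (heel)
LFM / RFM first metatarsal head (toe)
========  =====================================================

Lab axis convention (used throughout the package): X = direction of
progression (anterior), Y = mediolateral (subject's left positive),
Z = vertical up.  Units are millimetres.

Two on-disk representations are supported: the binary C3D motion-capture
format (via a minimal built-in codec) and a plain-text CSV fixture dialect
that round-trips losslessly at 6 decimal digits.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _c3d
from .errors import FixtureParseError, MarkerSetError

#: The 19 marker identifiers, in canonical (fixture-column) order.
MARKER_IDS: tuple[str, ...] = (
    "C7", "LA", "RA", "REP", "LEP", "RUL", "LUL",
    "RASIS", "LASIS", "RPSIS", "LPSIS", "RGT", "LGT",
    "RLE", "LLE", "RCA", "LCA", "RFM", "LFM",
)

MARKER_INDEX: dict[str, int] = {m: i for i, m in enumerate(MARKER_IDS)}

N_MARKERS = len(MARKER_IDS)

_FIXTURE_MAGIC = "#gaitdx-fixture v1"


@dataclasses.dataclass(frozen=True)
class MarkerFrame:
    """One time sample: a mapping from marker id to a 3-D point in mm."""

    positions: Mapping[str, np.ndarray]

    def __post_init__(self):
        keys = set(self.positions)
        missing = [m for m in MARKER_IDS if m not in keys]
        if missing:
            raise MarkerSetError(missing)
        extra = keys - set(MARKER_IDS)
        if extra:
            raise ValueError(f"unknown marker ids: {sorted(extra)}")
        for m, p in self.positions.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"marker {m}: expected a finite 3-D point, got {p!r}")

    def as_array(self) -> np.ndarray:
        """Return the frame as a (19, 3) array in canonical marker order."""
        return np.array([self.positions[m] for m in MARKER_IDS], dtype=float)


@dataclasses.dataclass
class Trial:
    """A labelled walking trial.

    Parameters
    ----------
    positions
        Array of shape (n_frames, 19, 3), canonical marker order, mm.
    frame_rate
        Sampling rate in frames per second.
    patient_id
        Opaque patient identifier (may be ``None`` for unlabelled data).
    form
        Clinical gait form, an integer in 1..4, or ``None`` if unknown.
    trial_id
        Optional identifier distinguishing trials of the same patient.
    """

    positions: np.ndarray
    frame_rate: float
    patient_id: str | None = None
    form: int | None = None
    trial_id: str | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (N_MARKERS, 3):
            raise ValueError(
                f"positions must have shape (n_frames, {N_MARKERS}, 3), "
                f"got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise ValueError("a trial requires at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("marker coordinates must be finite")
        if not (self.frame_rate > 0):
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.form is not None and self.form not in (1, 2, 3, 4):
            raise ValueError(f"form must be in 1..4, got {self.form}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Trial duration in seconds (frame count over rate)."""
        return self.n_frames / self.frame_rate

    def frame(self, i: int) -> MarkerFrame:
        return MarkerFrame({m: self.positions[i, j] for j, m in enumerate(MARKER_IDS)})

    def marker(self, marker_id: str) -> np.ndarray:
        """Trajectory of one marker: array of shape (n_frames, 3)."""
        return self.positions[:, MARKER_INDEX[marker_id], :]

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[MarkerFrame],
        frame_rate: float,
        patient_id: str | None = None,
        form: int | None = None,
        trial_id: str | None = None,
    ) -> "Trial":
        pos = np.stack([f.as_array() for f in frames])
        return cls(pos, frame_rate, patient_id, form, trial_id)


# ---------------------------------------------------------------------------
# plain-text fixture dialect
# ---------------------------------------------------------------------------

def write_fixture(trial: Trial, path) -> None:
    """Write a trial in the v1 fixture dialect (UTF-8 CSV, 6 decimals)."""
    path = Path(path)
    cols = [f"{m}_{ax}" for m in MARKER_IDS for ax in "xyz"]
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_FIXTURE_MAGIC + "\n")
        fh.write(f"patient_id,{trial.patient_id if trial.patient_id is not None else ''}\n")
        fh.write(f"form,{trial.form if trial.form is not None else ''}\n")
        fh.write(f"frame_rate,{trial.frame_rate:.6f}\n")
        fh.write("frame," + ",".join(cols) + "\n")
        flat = trial.positions.reshape(trial.n_frames, -1)
        for i, row in enumerate(flat):
            fh.write(str(i) + "," + ",".join(f"{v:.6f}" for v in row) + "\n")


def read_fixture(path) -> Trial:
    """Read a trial from the v1 fixture dialect.

    Raises
    ------
    FixtureParseError
        On malformed header, wrong column count, or unknown marker ids;
        the error message carries the 1-based line number.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _FIXTURE_MAGIC:
        raise FixtureParseError(f"expected magic line {_FIXTURE_MAGIC!r}", line=1)
    if len(lines) < 5:
        raise FixtureParseError("truncated fixture header", line=len(lines))

    def _header(idx, key):
        parts = lines[idx].split(",", 1)
        if len(parts) != 2 or parts[0] != key:
            raise FixtureParseError(f"expected '{key},<value>'", line=idx + 1)
        return parts[1]

    patient_id = _header(1, "patient_id") or None
    form_str = _header(2, "form")
    try:
        form = int(form_str) if form_str else None
    except ValueError:
        raise FixtureParseError(f"form must be an integer 1-4, got {form_str!r}", line=3)
    try:
        frame_rate = float(_header(3, "frame_rate"))
    except ValueError:
        raise FixtureParseError("frame_rate must be a number", line=4)

    expected_cols = ["frame"] + [f"{m}_{ax}" for m in MARKER_IDS for ax in "xyz"]
    header_cols = lines[4].split(",")
    if header_cols != expected_cols:
        bad = next(
            (c for c in header_cols[1:] if c.split("_")[0] not in MARKER_INDEX),
            None,
        )
        if bad is not None:
            raise FixtureParseError(f"unknown marker column {bad!r}", line=5)
        raise FixtureParseError(
            f"expected {len(expected_cols)} columns in canonical marker order, "
            f"got {len(header_cols)}",
            line=5,
        )

    rows = []
    for lineno, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(expected_cols):
            raise FixtureParseError(
                f"expected {len(expected_cols)} values, got {len(parts)}", line=lineno
            )
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError:
            raise FixtureParseError("non-numeric coordinate", line=lineno)
    if len(rows) < 2:
        raise FixtureParseError("a trial requires at least 2 frames", line=len(lines))
    positions = np.asarray(rows, dtype=float).reshape(len(rows), N_MARKERS, 3)
    return Trial(positions, frame_rate, patient_id, form)


# ---------------------------------------------------------------------------
# C3D
# ---------------------------------------------------------------------------

def read_c3d(path, patient_id: str | None = None, form: int | None = None) -> Trial:
    """Read a trial from a C3D file.

    Point labels must cover the full 19-marker set; extra labels (technical
    markers) are permitted and ignored.  ``patient_id`` and ``form`` are
    sidecar metadata — C3D files do not carry the class label.

    Raises
    ------
    MarkerSetError
        If any required marker label is absent, listing the absentees.
    """
    labels, points, frame_rate = _c3d.read(path)
    label_index = {lab: i for i, lab in enumerate(labels)}
    missing = [m for m in MARKER_IDS if m not in label_index]
    if missing:
        raise MarkerSetError(missing)
    order = [label_index[m] for m in MARKER_IDS]
    return Trial(points[:, order, :], frame_rate, patient_id, form)


def write_c3d(trial: Trial, path) -> None:
    """Write a trial as a float-data C3D file (round-trip support)."""
    _c3d.write(path, list(MARKER_IDS), trial.positions, trial.frame_rate)
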