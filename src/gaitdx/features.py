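"""Angular and spectral feature extraction from marker trajectories.

Each frame is reduced to 81 planar triplet angles: markers are projected
orthographically onto the three body planes (sagittal X-Z, frontal Y-Z,
transverse X-Y, lab-fixed) and, in each plane, 27 interior angles are
measured at a vertex marker between rays toward two neighbouring markers.
The triplet list covers hip/knee/ankle chains of both legs, arm and
shoulder geometry, pelvis-trunk alignment and inter-limb relations.

Two per-trial representations are derived from the angle series:

* ``spectral_features`` — the DFT of each angle's full-trial time series,
  sampled at multiples of the single-step fundamental (a trial trimmed to N
  steps has its step-locked harmonics at every N-th DFT bin).  Twenty
  harmonic amplitudes per angle are kept; amplitudes 2..20 are expressed
  relative to the fundamental, the DC term is kept raw.
* ``window_sequences`` — overlapping 75-frame windows (stride 15, at most
  45 per trial) for sequence classifiers.

The feature ordering is frozen: plane-major (sagittal, frontal,
transverse), triplets in the order of :data:`TRIPLETS` within each plane.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .errors import DegenerateGeometryError, TrialTooShortError
from .io import MARKER_INDEX, Trial
from .preprocess import StepSummary

logger = logging.getLogger(__name__)

PLANES = ("sagittal", "frontal", "transverse")

#: Orthographic projections under the lab convention (X forward, Y left, Z up):
#: sagittal keeps (X, Z), frontal keeps (Y, Z), transverse keeps (X, Y).
_PLANE_AXES = {"sagittal": (0, 2), "frontal": (1, 2), "transverse": (0, 1)}

#: The 27 marker triplets (ray endpoint, vertex, ray endpoint).
TRIPLETS: tuple[tuple[str, str, str], ...] = (
    ("LGT", "LPSIS", "LLE"),
    ("LLE", "LGT", "LCA"),
    ("LCA", "LLE", "LFM"),
    ("LEP", "LA", "LUL"),
    ("LEP", "C7", "LUL"),
    ("LLE", "LASIS", "LFM"),
    ("LA", "C7", "LEP"),
    ("RGT", "RPSIS", "RLE"),
    ("RLE", "RGT", "RCA"),
    ("RCA", "RLE", "RFM"),
    ("REP", "RA", "RUL"),
    ("REP", "C7", "RUL"),
    ("RLE", "RASIS", "RFM"),
    ("RA", "C7", "REP"),
    ("LPSIS", "LGT", "RGT"),
    ("LASIS", "LGT", "RGT"),
    ("LPSIS", "LLE", "RLE"),
    ("C7", "LA", "RA"),
    ("C7", "LEP", "REP"),
    ("RPSIS", "LGT", "RGT"),
    ("RASIS", "LGT", "RGT"),
    ("RPSIS", "LLE", "RLE"),
    ("C7", "LUL", "RUL"),
    ("LASIS", "C7", "LPSIS"),
    ("RASIS", "C7", "RPSIS"),
    ("LA", "LASIS", "RASIS"),
    ("RA", "LASIS", "RASIS"),
)

N_ANGLES = len(PLANES) * len(TRIPLETS)  # 81
N_HARMONICS = 20
WINDOW_LENGTH = 75
WINDOW_STRIDE = 15
MAX_WINDOWS = 45

_EPS_MM = 1e-9


@dataclasses.dataclass
class AngleSeries:
    """Per-frame 81-angle vectors (degrees) for one trimmed trial."""

    values: np.ndarray  # (n_frames, 81)
    frame_rate: float
    n_steps: int
    patient_id: str | None = None
    form: int | None = None
    trial_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_ANGLES:
            raise ValueError(f"values must be (n_frames, {N_ANGLES})")
        if np.any(self.values < -1e-9) or np.any(self.values > 180.0 + 1e-9):
            raise ValueError("angles must lie in [0, 180] degrees")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class SpectralFeatures:
    """81 x 20 step-harmonic amplitude matrix for one trial."""

    coeffs: np.ndarray
    patient_id: str | None = None
    form: int | None = None
    trial_id: str | None = None

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (N_ANGLES, N_HARMONICS):
            raise ValueError(f"coeffs must be ({N_ANGLES}, {N_HARMONICS})")
        if not np.all(np.isfinite(self.coeffs)) or np.any(self.coeffs < 0):
            raise ValueError("coeffs must be finite and non-negative")

    def flatten(self) -> np.ndarray:
        """Row-major 1620-vector (angle-major, harmonics contiguous)."""
        return self.coeffs.reshape(-1)


@dataclasses.dataclass
class WindowSet:
    """Overlapping fixed-length windows cut from one trial's angle series."""

    windows: list[np.ndarray]  # each (75, 81)
    patient_id: str | None = None
    form: int | None = None
    trial_id: str | None = None

    def __post_init__(self):
        if len(self.windows) > MAX_WINDOWS:
            raise ValueError(f"at most {MAX_WINDOWS} windows per trial")
        for w in self.windows:
            if w.shape != (WINDOW_LENGTH, N_ANGLES):
                raise ValueError(f"each window must be ({WINDOW_LENGTH}, {N_ANGLES})")


def angle_feature_names() -> list[str]:
    """The frozen 81 feature names, e.g. ``sagittal:LPSIS(LGT-LLE)``."""
    return [
        f"{plane}:{b}({a}-{c})" for plane in PLANES for a, b, c in TRIPLETS
    ]


def project_to_plane(point: np.ndarray, plane: str) -> np.ndarray:
    """Orthographic projection of 3-D point(s) onto a body plane."""
    try:
        i, j = _PLANE_AXES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    point = np.asarray(point, dtype=float)
    return point[..., [i, j]]


def triplet_angle(p1, vertex, p3) -> float:
    """Interior angle (degrees) at ``vertex`` between rays to p1 and p3."""
    p1 = np.asarray(p1, dtype=float)
    vertex = np.asarray(vertex, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    u, v = p1 - vertex, p3 - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS_MM or nv < _EPS_MM:
        raise DegenerateGeometryError("coincident markers in triplet")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_series(trial: Trial, steps: StepSummary) -> AngleSeries:
    """Compute the 81-angle series of a trimmed, subsampled trial.

    Raises
    ------
    DegenerateGeometryError
        Identifying the frame and triplet if two markers of a triplet
        coincide (distance < 1e-9 mm) in some plane projection.
    """
    pos = trial.positions  # (F, 19, 3)
    cols = np.empty((trial.n_frames, N_ANGLES))
    col = 0
    for plane in PLANES:
        i, j = _PLANE_AXES[plane]
        proj = pos[:, :, [i, j]]
        for a, b, c in TRIPLETS:
            u = proj[:, MARKER_INDEX[a]] - proj[:, MARKER_INDEX[b]]
            v = proj[:, MARKER_INDEX[c]] - proj[:, MARKER_INDEX[b]]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            bad = (nu < _EPS_MM) | (nv < _EPS_MM)
            if np.any(bad):
                frame = int(np.argmax(bad))
                raise DegenerateGeometryError(
                    f"frame {frame}, plane {plane}, triplet {a}-{b}-{c}: "
                    "coincident projected markers"
                )
            cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
            cols[:, col] = np.degrees(np.arccos(cosang))
            col += 1
    return AngleSeries(
        cols,
        trial.frame_rate,
        steps.n_steps,
        trial.patient_id,
        trial.form,
        trial.trial_id,
    )


def spectral_features(series: AngleSeries) -> SpectralFeatures:
    """Step-harmonic amplitude features of a whole-trial angle series.

    With the trial trimmed to exactly N steps, the harmonics of the
    single-step fundamental sit at DFT bins 0, N, 2N, ..., 19N.  Their
    complex magnitudes form one row per angle; entries 2..20 are divided by
    the fundamental amplitude (bin N), the DC entry is kept unnormalized.
    Rows whose fundamental amplitude is below 1e-12 have their normalized
    entries zero-filled (a flat angle carries no harmonic information).

    Raises
    ------
    ValueError
        If the series is shorter than 20 N frames, so that bin 19 N does
        not exist.
    """
    n = series.n_steps
    if n < 1:
        raise ValueError("n_steps must be >= 1")
    if series.n_frames < N_HARMONICS * n:
        raise ValueError(
            f"series too short: {series.n_frames} frames < {N_HARMONICS}*{n} "
            "needed to reach the 19th step harmonic"
        )
    spectrum = np.abs(np.fft.fft(series.values, axis=0))  # (F, 81)
    picks = spectrum[np.arange(N_HARMONICS) * n, :]  # (20, 81)
    coeffs = picks.T.copy()  # (81, 20)
    fundamental = coeffs[:, 1].copy()
    ok = fundamental > 1e-12
    coeffs[ok, 1:] /= fundamental[ok, None]
    coeffs[~ok, 1:] = 0.0
    if np.any(~ok):
        logger.warning(
            "%d angle row(s) have a vanishing fundamental; normalized "
            "entries zero-filled (trial %s)",
            int(np.sum(~ok)),
            series.trial_id,
        )
    return SpectralFeatures(coeffs, series.patient_id, series.form, series.trial_id)


def n_windows(n_frames: int) -> int:
    """Window count for a trial of ``n_frames`` frames (0 if too short)."""
    if n_frames < WINDOW_LENGTH:
        return 0
    return min(MAX_WINDOWS, (n_frames - WINDOW_LENGTH) // WINDOW_STRIDE + 1)


def window_sequences(series: AngleSeries) -> WindowSet:
    """Cut 75-frame windows every 15 frames (at most 45 per trial).

    Window contents are views of the angle series — exact slices, no
    transformation.  Trailing frames that do not fill a window are dropped.

    Raises
    ------
    TrialTooShortError
        If the series has fewer than 75 frames.
    """
    count = n_windows(series.n_frames)
    if count == 0:
        raise TrialTooShortError(
            f"trial {series.trial_id}: {series.n_frames} frames < {WINDOW_LENGTH}"
        )
    windows = [
        series.values[s : s + WINDOW_LENGTH]
        for s in range(0, count * WINDOW_STRIDE, WINDOW_STRIDE)
    ]
    return WindowSet(windows, series.patient_id, series.form, series.trial_id)


def spectral_to_csv(features: list[SpectralFeatures], path) -> None:
    """One row per trial; columns named ``<angle>:h<k>`` for k in 0..19."""
    import pandas as pd

    names = [f"{a}:h{k}" for a in angle_feature_names() for k in range(N_HARMONICS)]
    df = pd.DataFrame(
        [f.flatten() for f in features], columns=names
    )
    df.insert(0, "trial_id", [f.trial_id for f in features])
    df.insert(1, "patient_id", [f.patient_id for f in features])
    df.insert(2, "form", [f.form for f in features])
    df.to_csv(path, index=False)
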