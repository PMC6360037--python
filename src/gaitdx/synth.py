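"""Parametric simulator of 19-marker walking trials for the four gait forms.

The simulator is phenomenological, not biomechanical: a pelvis translates
along the walkway with sinusoidal vertical/lateral oscillation, each ankle
follows a scripted stance/swing trajectory, knees are placed by two-link
inverse kinematics, and trunk/shoulder/arm segments swing in anti-phase with
the legs.  Its only job is to produce marker signals whose class structure
mirrors the qualitative traits of the four clinical forms:

* form I   — pronounced forward trunk lean (antepulsion) with toe balancing,
* form II  — crouch gait: pronounced stance knee flexion and short steps,
* form III — large frontal (lateral) trunk sway,
* form IV  — marked equinus (plantarflexed, heel-raised foot) with an
             otherwise close-to-typical pattern.

Each simulated patient draws bounded Gaussian random effects around its
form profile, every trial draws per-step period jitter, and independent
Gaussian noise is added to every marker coordinate.  Scripted foot-strike
and toe-off frames are returned as ground truth, which makes every stage of
the processing pipeline testable without clinical data.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import MARKER_IDS, MARKER_INDEX, N_MARKERS, Trial
from .preprocess import GaitEvents

_TOE_OFF_PHASE = 0.4  # fraction of the same-side gait cycle


@dataclasses.dataclass(frozen=True)
class FormProfile:
    """Kinematic parameters characterising one gait form.

    Angles in degrees, lengths in millimetres, periods in seconds.
    """

    trunk_lean: float        # sagittal trunk antepulsion (+ forward)
    knee_flexion: float      # stance knee-flexion (crouch) offset
    stride_length: float     # distance covered per full gait cycle (2 steps)
    frontal_sway: float      # lateral trunk-sway amplitude
    equinus: float           # ankle plantarflexion offset (heel raised)
    step_period: float       # mean step duration
    step_period_sd: float    # per-step duration jitter

    def __post_init__(self):
        for name in ("trunk_lean", "knee_flexion", "frontal_sway", "equinus"):
            if abs(getattr(self, name)) > 45.0:
                raise ValueError(f"{name} outside physiologic bounds (|x| <= 45 deg)")
        if not (self.step_period > 0):
            raise ValueError("step_period must be positive")


def default_profiles() -> dict[int, FormProfile]:
    """Declared default profiles for the four forms.

    Each form's distinguishing parameter is the largest across forms:
    form I the trunk lean, form II the knee flexion (with the shortest
    stride), form III the frontal sway, form IV the equinus.
    """
    return {
        1: FormProfile(trunk_lean=18.0, knee_flexion=8.0, stride_length=750.0,
                       frontal_sway=3.0, equinus=12.0,
                       step_period=1.1, step_period_sd=0.04),
        2: FormProfile(trunk_lean=6.0, knee_flexion=25.0, stride_length=450.0,
                       frontal_sway=3.0, equinus=8.0,
                       step_period=0.9, step_period_sd=0.04),
        3: FormProfile(trunk_lean=4.0, knee_flexion=8.0, stride_length=700.0,
                       frontal_sway=14.0, equinus=5.0,
                       step_period=1.0, step_period_sd=0.04),
        4: FormProfile(trunk_lean=1.0, knee_flexion=5.0, stride_length=850.0,
                       frontal_sway=2.0, equinus=20.0,
                       step_period=1.0, step_period_sd=0.04),
    }


#: Between-patient random-effect standard deviations, per profile field.
RANDOM_EFFECT_SD = {
    "trunk_lean": 1.5,
    "knee_flexion": 2.0,
    "stride_length": 30.0,
    "frontal_sway": 1.0,
    "equinus": 1.5,
    "step_period": 0.03,
}

#: Child-scale segment lengths (mm) and their between-patient SDs.
_SEGMENTS = {
    "pelvis_width": (220.0, 10.0),   # hip-to-hip
    "thigh": (350.0, 15.0),
    "shank": (340.0, 15.0),
    "trunk": (450.0, 20.0),
    "shoulder_width": (280.0, 12.0),
    "upper_arm": (250.0, 10.0),
    "forearm": (220.0, 10.0),
    "foot": (150.0, 8.0),
    "ankle_height": (80.0, 5.0),
}


@dataclasses.dataclass(frozen=True)
class SynthPatient:
    """A simulated patient: a form profile with individual random effects."""

    patient_id: str
    form: int
    profile: FormProfile
    segments: dict[str, float]
    #: constant per-marker placement offsets (mm) emulating skin-marker
    #: placement variability; also breaks exact bilateral symmetry
    placement: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros((N_MARKERS, 3))
    )


def make_patient(
    patient_id: str,
    form: int,
    rng: np.random.Generator,
    profiles: dict[int, FormProfile] | None = None,
) -> SynthPatient:
    """Draw one patient around the form profile (bounded random effects)."""
    base = (profiles or default_profiles())[form]
    kwargs = {}
    for name, sd in RANDOM_EFFECT_SD.items():
        value = getattr(base, name) + rng.normal(0.0, sd)
        if name == "step_period":
            value = max(0.5, value)
        elif name == "stride_length":
            value = max(200.0, value)
        else:
            value = float(np.clip(value, -44.0, 44.0))
        kwargs[name] = value
    profile = FormProfile(step_period_sd=base.step_period_sd, **kwargs)
    segments = {
        k: max(mean - 3 * sd, mean + rng.normal(0.0, sd))
        for k, (mean, sd) in _SEGMENTS.items()
    }
    placement = rng.normal(0.0, 4.0, size=(N_MARKERS, 3))
    return SynthPatient(patient_id, form, profile, segments, placement)


def _rot_y(deg: float) -> np.ndarray:
    """Rotation about the mediolateral axis; positive pitches forward (+X)."""
    a = np.radians(deg)
    return np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])


def _rot_x(deg: float) -> np.ndarray:
    """Rotation about the walking axis; positive sways to the left (+Y)."""
    a = np.radians(deg)
    return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])


def _step_times(duration, profile, rng):
    """Alternating-foot strike times covering [0, duration] with margin."""
    times = [0.3 * profile.step_period]
    while times[-1] < duration + 2 * profile.step_period:
        d = rng.normal(profile.step_period, profile.step_period_sd)
        d = float(np.clip(d, 0.5 * profile.step_period, 1.5 * profile.step_period))
        times.append(times[-1] + d)
    return np.array(times)


def _phase(t: np.ndarray, strikes: np.ndarray) -> np.ndarray:
    """Piecewise-linear gait-cycle phase: 0 at each strike in ``strikes``.

    Integer part counts completed cycles, fractional part is the in-cycle
    phase; linearly extrapolated before the first and after the last strike.
    """
    k = np.searchsorted(strikes, t, side="right") - 1
    k = np.clip(k, 0, len(strikes) - 2)
    t0, t1 = strikes[k], strikes[k + 1]
    return k + (t - t0) / (t1 - t0)


def generate_trial(
    patient: SynthPatient,
    duration: float = 8.0,
    frame_rate: float = 100.0,
    noise_sd: float = 1.0,
    seed: int | None = None,
    trial_id: str | None = None,
) -> tuple[Trial, GaitEvents]:
    """Simulate one walking trial with ground-truth gait events.

    Parameters
    ----------
    duration
        Trial length in seconds; must fit at least 2 steps.
    frame_rate
        Sampling rate (the native capture rate is 100 frames/sec).
    noise_sd
        SD of the independent Gaussian marker noise, mm per coordinate.
    seed
        Seeds step-period jitter and marker noise; trials are fully
        deterministic under a fixed seed.
    """
    p = patient.profile
    if duration < 2.5 * p.step_period:
        raise ValueError("duration too short for at least 2 complete steps")
    rng = np.random.default_rng(seed)
    seg = patient.segments
    n_frames = int(round(duration * frame_rate))
    t = np.arange(n_frames) / frame_rate

    # alternating global strike times; right foot strikes first
    step_t = _step_times(duration, p, rng)
    strikes = {"right": step_t[0::2], "left": step_t[1::2]}
    step_len = p.stride_length / 2.0

    # pelvis: piecewise-linear forward progression, one step length per step
    x_pelvis = np.interp(t, step_t, step_len * np.arange(len(step_t)))
    phase = {s: _phase(t, strikes[s]) for s in ("left", "right")}
    cyc_r = 2 * np.pi * phase["right"]
    crouch = np.radians(p.knee_flexion)
    leg_len = seg["thigh"] + seg["shank"]
    hip_h = seg["ankle_height"] + leg_len * np.cos(0.6 * crouch)
    z_pelvis = hip_h + 12.0 * np.cos(2 * cyc_r)
    y_pelvis = 18.0 * np.sin(cyc_r)
    pelvis = np.stack([x_pelvis, y_pelvis, z_pelvis], axis=1)

    pos = np.empty((n_frames, N_MARKERS, 3))

    def put(marker, xyz):
        pos[:, MARKER_INDEX[marker], :] = xyz

    # --- pelvis markers (rigid offsets from the pelvis centre) -------------
    half_w = seg["pelvis_width"] / 2.0
    for side, sgn in (("L", 1.0), ("R", -1.0)):
        put(side + "GT", pelvis + [0.0, sgn * half_w, 0.0])
        put(side + "ASIS", pelvis + [80.0, sgn * 0.5 * seg["pelvis_width"], 50.0])
        put(side + "PSIS", pelvis + [-100.0, sgn * 0.25 * seg["pelvis_width"], 70.0])

    # --- trunk, shoulders, arms -------------------------------------------
    sway = p.frontal_sway * np.sin(cyc_r)
    trunk_dir = np.einsum(
        "tij,j->ti",
        np.stack([_rot_x(s) @ _rot_y(p.trunk_lean) for s in sway]),
        np.array([0.0, 0.0, 1.0]),
    )
    c7 = pelvis + seg["trunk"] * trunk_dir
    put("C7", c7)
    lateral = np.einsum(
        "tij,j->ti",
        np.stack([_rot_x(s) for s in sway]),
        np.array([0.0, 1.0, 0.0]),
    )
    half_sh = seg["shoulder_width"] / 2.0
    shoulder = {}
    for side, sgn in (("L", 1.0), ("R", -1.0)):
        shoulder[side] = c7 + sgn * half_sh * lateral + [0.0, 0.0, -30.0]
        put(side + "A", shoulder[side])
    arm_amp = 15.0
    for side, sgn, ph in (("L", 1.0, phase["left"]), ("R", -1.0, phase["right"])):
        # each arm swings in anti-phase with its ipsilateral leg
        alpha = np.radians(arm_amp * np.cos(2 * np.pi * ph + np.pi))
        elbow = shoulder[side] + seg["upper_arm"] * np.stack(
            [np.sin(alpha), np.zeros_like(alpha), -np.cos(alpha)], axis=1
        )
        beta = alpha + np.radians(25.0)  # constant elbow flexion
        wrist = elbow + seg["forearm"] * np.stack(
            [np.sin(beta), np.zeros_like(beta), -np.cos(beta)], axis=1
        )
        put(side + "EP", elbow)
        put(side + "UL", wrist)

    # --- legs: scripted ankles, knees by two-link inverse kinematics -------
    for side, sgn in (("L", 1.0), ("R", -1.0)):
        ph = phase["left" if side == "L" else "right"]
        cyc = 2 * np.pi * ph
        hip = pelvis + np.array([0.0, sgn * half_w, 0.0])
        ankle = np.stack(
            [
                x_pelvis + 0.5 * step_len * np.cos(cyc),
                np.full(n_frames, sgn * half_w),
                seg["ankle_height"] + 90.0 * (0.5 - 0.5 * np.cos(cyc)),
            ],
            axis=1,
        )
        # two-link IK in the sagittal plane; knee bends forward (+X)
        d = np.linalg.norm(ankle - hip, axis=1)
        d = np.clip(d, 1e-6, 0.999 * leg_len)
        along = (ankle - hip) / d[:, None]
        fwd = np.array([1.0, 0.0, 0.0])
        perp = fwd - along * (along @ fwd)[:, None]
        perp /= np.linalg.norm(perp, axis=1)[:, None]
        cos_t = (seg["thigh"] ** 2 + d**2 - seg["shank"] ** 2) / (2 * seg["thigh"] * d)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        sin_t = np.sqrt(1.0 - cos_t**2)
        knee = hip + seg["thigh"] * (cos_t[:, None] * along + sin_t[:, None] * perp)
        put(side + "LE", knee + [0.0, sgn * 45.0, 0.0])

        # foot: pitch = equinus offset plus a swing-phase plantarflexion wave
        pitch = np.radians(p.equinus + 12.0 * (0.5 - 0.5 * np.cos(cyc)))
        cp, sp = np.cos(pitch), np.sin(pitch)
        heel_local = np.array([-60.0, 0.0, -seg["ankle_height"] + 15.0])
        toe_local = np.array([seg["foot"] - 60.0, 0.0, -seg["ankle_height"] + 25.0])
        for marker, local in ((side + "CA", heel_local), (side + "FM", toe_local)):
            dx = cp * local[0] + sp * local[2]
            dz = -sp * local[0] + cp * local[2]
            world = ankle + np.stack(
                [dx, np.full(n_frames, sgn * 0.0), dz], axis=1
            )
            world[:, 1] += sgn * 20.0
            put(marker, world)

    pos += patient.placement[None, :, :]
    if noise_sd > 0:
        pos += rng.normal(0.0, noise_sd, size=pos.shape)

    def to_frames(times):
        idx = np.round(np.asarray(times) * frame_rate).astype(int)
        return np.unique(idx[(idx >= 0) & (idx < n_frames)])

    toe_off_times = {
        s: strikes[s][:-1] + _TOE_OFF_PHASE * np.diff(strikes[s])
        for s in ("left", "right")
    }
    events = GaitEvents(
        {s: to_frames(strikes[s]) for s in ("left", "right")},
        {s: to_frames(toe_off_times[s]) for s in ("left", "right")},
    )
    trial = Trial(pos, frame_rate, patient.patient_id, patient.form, trial_id)
    return trial, events


def generate_dataset(
    n_per_form: dict[int, int] | None = None,
    trials_per_patient: int = 3,
    seed: int | None = None,
    duration: float = 8.0,
    frame_rate: float = 100.0,
    noise_sd: float = 1.0,
    profiles: dict[int, FormProfile] | None = None,
    return_events: bool = False,
):
    """Simulate a labelled multi-patient dataset.

    The default cohort shape (6/16/12/26 patients for forms 1-4) follows the
    uneven clinical prevalence of the forms at roughly one-third scale, with
    3 trials per patient.

    Returns the list of trials, or ``(trials, events)`` with per-trial
    ground-truth events when ``return_events`` is set.
    """
    if n_per_form is None:
        n_per_form = {1: 6, 2: 16, 3: 12, 4: 26}
    rng = np.random.default_rng(seed)
    trials, all_events = [], []
    for form in sorted(n_per_form):
        for i in range(n_per_form[form]):
            pid = f"F{form}P{i:03d}"
            patient = make_patient(pid, form, rng, profiles)
            for j in range(trials_per_patient):
                trial, events = generate_trial(
                    patient,
                    duration=duration,
                    frame_rate=frame_rate,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    trial_id=f"{pid}-T{j}",
                )
                trials.append(trial)
                all_events.append(events)
    return (trials, all_events) if return_events else trials
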