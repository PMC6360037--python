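"""End-to-end pipeline: simulate/load -> preprocess -> features -> split ->
train -> patient-level evaluation.

All randomness flows from one root seed through :class:`numpy.random.SeedSequence`
spawns (data generation, split, model initialization and batching), so a rerun
with the same configuration is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import yaml

from . import dataset as ds
from . import evaluate as ev
from . import features as ft
from . import models as md
from . import preprocess as pp
from . import synth
from .errors import GaitdxError
from .io import Trial, read_fixture

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "runs/default"
    trials_dir: str | None = None      # read fixture trials instead of simulating
    n_per_form: dict = dataclasses.field(
        default_factory=lambda: {1: 6, 2: 16, 3: 12, 4: 26}
    )
    trials_per_patient: int = 3
    duration: float = 8.0
    noise_sd: float = 1.0
    subsample_factor: int = 2
    split_ratio: float = 0.75
    augment: dict = dataclasses.field(default_factory=lambda: {1: 2})
    mlp_hidden_sizes: tuple = (256, 128, 64, 32)
    mlp_dropout: float = 0.5
    lstm_units: int = 128
    lstm_fc_sizes: tuple = (128, 64, 32)
    svm_c: float = 1.0
    seed: int = 0

    def validate(self):
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be >= 1")
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio must be in (0, 1)")
        if self.trials_per_patient < 1 or self.duration <= 0:
            raise ValueError("trials_per_patient and duration must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("n_per_form", "augment"):
            if key in raw:
                raw[key] = {int(k): int(v) for k, v in raw[key].items()}
        for key in ("mlp_hidden_sizes", "lstm_fc_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["mlp_hidden_sizes"] = list(self.mlp_hidden_sizes)
        data["lstm_fc_sizes"] = list(self.lstm_fc_sizes)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclasses.dataclass
class TrialFeatures:
    """Per-trial preprocessing products."""

    spectral: ft.SpectralFeatures
    windows: ft.WindowSet | None  # None if the trimmed trial is too short


def load_trials(config: RunConfig) -> list[Trial]:
    """Simulated cohort, or fixture files if ``trials_dir`` is set."""
    if config.trials_dir is not None:
        paths = sorted(Path(config.trials_dir).glob("*.csv"))
        if not paths:
            raise FileNotFoundError(f"no fixture trials in {config.trials_dir}")
        return [read_fixture(p) for p in paths]
    seed = np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % (2**31)
    return synth.generate_dataset(
        config.n_per_form,
        config.trials_per_patient,
        seed=int(seed),
        duration=config.duration,
        noise_sd=config.noise_sd,
    )


def extract_trial_features(trial: Trial, subsample_factor: int = 2) -> TrialFeatures:
    """Subsample, detect events, trim to whole steps, extract features."""
    sub = pp.subsample(trial, subsample_factor)
    events = pp.detect_gait_events(sub)
    trimmed, steps = pp.trim_to_complete_steps(sub, events)
    series = ft.angle_series(trimmed, steps)
    spectral = ft.spectral_features(series)
    try:
        windows = ft.window_sequences(series)
    except GaitdxError:
        logger.warning("trial %s too short for windows; excluded from RNN data",
                       trial.trial_id)
        windows = None
    return TrialFeatures(spectral, windows)


def run_pipeline(config: RunConfig) -> dict[str, ev.EvalReport]:
    """Execute all stages and write per-model reports under ``out_dir``.

    Produces ``<model>_accuracy.csv`` (per-form T1/T2 rows) and
    ``<model>_confusion.csv`` for the MLP, LSTM and SVM models, plus the
    split manifest and the resolved config echo.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    trials = load_trials(config)
    logger.info("pipeline: %d trials", len(trials))

    feats: list[TrialFeatures] = []
    kept_trials: list[Trial] = []
    for trial in trials:
        try:
            feats.append(extract_trial_features(trial, config.subsample_factor))
            kept_trials.append(trial)
        except GaitdxError as exc:
            logger.warning("stage preprocess/features, trial %s: %s",
                           trial.trial_id, exc)
    if not kept_trials:
        raise GaitdxError("no trial survived preprocessing")

    split_seed = int(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0]
                     % (2**31))
    split = ds.split_patients(kept_trials, config.split_ratio, seed=split_seed)
    ds.split_to_csv(split, out / "split.csv")
    true_forms = {t.patient_id: t.form for t in kept_trials}
    test_ids = split.all_test

    spectral = [f.spectral for f in feats]
    windows = [f.windows for f in feats if f.windows is not None]
    mlp_train, mlp_test = ds.assemble_mlp_dataset(spectral, split)
    rnn_train, rnn_test = ds.assemble_rnn_dataset(windows, split)
    for form, factor in config.augment.items():
        mlp_train = ds.augment_form(mlp_train, form, factor)
        rnn_train = ds.augment_form(rnn_train, form, factor)

    model_seed = int(np.random.SeedSequence([config.seed, 3]).generate_state(1)[0]
                     % (2**31))
    tcfg = md.TrainConfig(seed=model_seed)
    reports: dict[str, ev.EvalReport] = {}

    mlp = md.build_mlp(
        md.MlpConfig(config.mlp_hidden_sizes, config.mlp_dropout), seed=model_seed
    )
    mlp, mlp_trace = md.train_mlp(mlp, mlp_train, tcfg)
    _write_trace(mlp_trace, out / "mlp_loss.csv")
    reports["mlp"] = _score(mlp.predict(mlp_test), true_forms, test_ids)

    lstm = md.build_lstm(
        md.LstmConfig(config.lstm_units, config.lstm_fc_sizes), seed=model_seed
    )
    lstm, lstm_trace = md.train_lstm(lstm, rnn_train, tcfg)
    _write_trace(lstm_trace, out / "lstm_loss.csv")
    reports["lstm"] = _score(lstm.predict(rnn_test), true_forms, test_ids)

    svm = md.train_svm_baseline(mlp_train, C=config.svm_c)
    reports["svm"] = _score(svm.predict(mlp_test), true_forms, test_ids)

    for name, report in reports.items():
        report.to_csv(out / f"{name}_accuracy.csv")
        report.confusion_to_csv(out / f"{name}_confusion.csv")
    return reports


def _score(predictions, true_forms, test_ids) -> ev.EvalReport:
    truth = {pid: form for pid, form in true_forms.items() if pid in test_ids}
    scores = ev.aggregate_patient(predictions, truth)
    return ev.evaluate(scores)


def _write_trace(trace, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("epoch,loss\n")
        for i, loss in enumerate(trace, start=1):
            fh.write(f"{i},{loss:.6f}\n")
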