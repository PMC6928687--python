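"""Cross-validated evaluation of the angle estimator.

Two designs mirror how wearable-gait models are validated:

* intra-participant: per runner, a trial-structured 3-fold CV in which each
  fold holds exactly one repeat of every treadmill speed (so every fold
  spans the full speed range), six output channels;
* inter-participant: leave-one-participant-out CV, three sagittal output
  channels, weighted training loss and 60% bootstrap subsampling.

Metrics per joint: coefficient of determination R^2, RMSE in degrees, and
NRMSE in percent of the test reference's range of motion (max - min), the
normalization most consistent with reported NRMSE values in this field.
Per-speed breakdowns reuse the all-speed-trained model and merely stratify
its test predictions by speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocessing as pp
from .estimator import ModelConfig, TrainConfig, build_model, predict, train
from .synthetic import (
    CHANNEL_NAMES,
    SAGITTAL_CHANNELS,
    ProtocolSpec,
    SensorModel,
    generate_cohort,
)

__all__ = [
    "FoldSpec",
    "ExperimentConfig",
    "ExperimentResult",
    "make_intra_folds",
    "make_lopo_folds",
    "compute_metrics",
    "per_speed_report",
    "run_experiment",
]


@dataclass(frozen=True)
class FoldSpec:
    """Cross-validation assignment: trial->fold (intra) or participant->fold."""

    mode: str  # "intra" | "inter"
    assignments: dict

    @property
    def n_folds(self) -> int:
        return len(set(self.assignments.values()))

    def test_keys(self, fold: int) -> list:
        return [k for k, f in self.assignments.items() if f == fold]

    def train_keys(self, fold: int) -> list:
        return [k for k, f in self.assignments.items() if f != fold]


def make_intra_folds(trials) -> FoldSpec:
    """Three speed-balanced folds: fold i holds repeat i of every speed.

    ``trials`` is a list of objects carrying ``speed`` and ``trial_index``
    labels (e.g. :class:`~gaitstrain.synthetic.JointAngleSeries`). Requires
    exactly three repeats of each speed; anything else is an incomplete
    design for the trial-based 3-fold CV.
    """
    by_speed: dict[float, list[int]] = {}
    for t in trials:
        by_speed.setdefault(float(t.speed), []).append(int(t.trial_index))
    counts = {s: len(v) for s, v in by_speed.items()}
    if any(c != 3 for c in counts.values()):
        raise ValueError(f"need exactly 3 repeats of each speed, got {counts}")
    assignments: dict[int, int] = {}
    for s in sorted(by_speed):
        for fold, trial_index in enumerate(sorted(by_speed[s])):
            assignments[trial_index] = fold
    return FoldSpec(mode="intra", assignments=assignments)


def make_lopo_folds(participant_ids) -> FoldSpec:
    """One fold per participant; the rest train."""
    ids = list(participant_ids)
    if len(ids) < 2:
        raise ValueError("leave-one-participant-out needs at least 2 participants")
    return FoldSpec(mode="inter", assignments={p: i for i, p in enumerate(ids)})


def compute_metrics(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
    """(R^2, RMSE in degrees, NRMSE in % of the reference range)."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size != ref.size or ref.size < 2:
        raise ValueError("need equal-length vectors with at least 2 samples")
    rom = float(ref.max() - ref.min())
    if rom == 0:
        raise ValueError("reference range is zero; NRMSE (and R^2) undefined")
    resid = pred - ref
    ss_res = float((resid**2).sum())
    ss_tot = float(((ref - ref.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt((resid**2).mean()))
    return r2, rmse, 100.0 * rmse / rom


def per_speed_report(
    predictions: np.ndarray,
    references: np.ndarray,
    speed_labels: np.ndarray,
    joint_names: tuple[str, ...],
) -> pd.DataFrame:
    """Metrics per speed stratum plus the pooled row, per joint.

    The same trained model's test predictions are stratified by treadmill
    speed; strata too small to score are omitted with a warning.
    """
    rows = []
    speeds = np.asarray(speed_labels, dtype=float)
    strata = [("pooled", np.ones(speeds.size, dtype=bool))] + [
        (s, speeds == s) for s in sorted(set(speeds.tolist()))
    ]
    for label, mask in strata:
        if mask.sum() < 2:
            warnings.warn(f"speed stratum {label} has too few samples; omitted",
                          stacklevel=2)
            continue
        for j, name in enumerate(joint_names):
            r2, rmse, nrmse = compute_metrics(predictions[mask, j], references[mask, j])
            rows.append(
                {"speed": label, "joint": name, "r2": r2, "rmse_deg": rmse,
                 "nrmse_pct": nrmse, "n": int(mask.sum())}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExperimentConfig:
    """End-to-end experiment: simulate -> preprocess -> train -> score."""

    mode: str = "intra"  # "intra" | "inter"
    n_participants: int = 4
    protocol: ProtocolSpec = field(
        default_factory=lambda: ProtocolSpec(speeds=(8.0, 10.0, 12.0),
                                             trial_duration=20.0)
    )
    sensor_model: SensorModel = field(default_factory=SensorModel)
    model: ModelConfig | None = None
    training: TrainConfig = field(default_factory=TrainConfig)
    stride_train: int = 4
    stride_test: int = 4
    per_speed: bool = False
    master_seed: int = 0


@dataclass
class ExperimentResult:
    """Per-fold metrics plus optional per-speed table and predictions."""

    metrics: pd.DataFrame  # participant, fold, joint, r2, rmse_deg, nrmse_pct
    per_speed: pd.DataFrame | None
    config: ExperimentConfig

    def summarize(self) -> pd.DataFrame:
        """Mean (sd) per joint across folds/participants."""
        g = self.metrics.groupby("joint", sort=False)
        out = g[["r2", "rmse_deg", "nrmse_pct"]].agg(["mean", "std"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()


def _fit_and_score(
    train_sensors,
    train_angles,
    test_sensors,
    test_angles,
    channels: tuple[int, ...],
    cfg: ExperimentConfig,
    fit_seed: int,
    mode: str,
):
    train_wb, _ = pp.preprocess_partition(
        train_sensors, train_angles, target_channels=channels,
        stride=cfg.stride_train, rate=cfg.protocol.sample_rate, source="train",
    )
    # test partition standardized with its own statistics, never the train's
    test_wb, _ = pp.preprocess_partition(
        test_sensors, test_angles, target_channels=channels,
        stride=cfg.stride_test, rate=cfg.protocol.sample_rate, source="test",
    )
    model_cfg = cfg.model or ModelConfig(n_outputs=len(channels))
    model = build_model(model_cfg, seed=fit_seed)
    tc = TrainConfig(
        batch_size=cfg.training.batch_size,
        epochs=cfg.training.epochs,
        subsample_fraction=cfg.training.subsample_fraction,
        loss_weights=cfg.training.loss_weights,
        learning_rate=cfg.training.learning_rate,
        seed=fit_seed,
    )
    _, history = train(model, train_wb, tc, mode=mode)
    preds = predict(model, test_wb)
    return preds, test_wb, history


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full pipeline and report cross-validated metrics.

    Deterministic given ``config.master_seed``: the cohort, every model
    initialization, batch shuffling and bootstrap draw derive from it.
    """
    if config.mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    cohort = generate_cohort(
        config.n_participants,
        protocol=config.protocol,
        seed=config.master_seed,
        sensor_model=config.sensor_model,
    )
    if config.mode == "intra":
        channels = tuple(range(6))
        joint_names = CHANNEL_NAMES
    else:
        channels = SAGITTAL_CHANNELS
        joint_names = tuple(CHANNEL_NAMES[c] for c in channels)

    rows = []
    speed_frames = []
    fit_counter = 0
    if config.mode == "intra":
        for profile in cohort.profiles:
            trials = cohort.participant_trials(profile.participant_id)
            folds = make_intra_folds([t.angles for t in trials])
            by_index = {t.angles.trial_index: t for t in trials}
            for fold in range(folds.n_folds):
                tr = [by_index[i] for i in folds.train_keys(fold)]
                te = [by_index[i] for i in folds.test_keys(fold)]
                preds, test_wb, _ = _fit_and_score(
                    [t.sensors for t in tr], [t.angles for t in tr],
                    [t.sensors for t in te], [t.angles for t in te],
                    channels, config,
                    fit_seed=(config.master_seed * 7919 + fit_counter) % (2**31),
                    mode="intra",
                )
                fit_counter += 1
                for j, name in enumerate(joint_names):
                    r2, rmse, nrmse = compute_metrics(preds[:, j], test_wb.y[:, j])
                    rows.append(
                        {"participant": profile.participant_id, "fold": fold,
                         "joint": name, "r2": r2, "rmse_deg": rmse,
                         "nrmse_pct": nrmse, "n": test_wb.n_windows}
                    )
                if config.per_speed:
                    df = per_speed_report(preds, test_wb.y, test_wb.speed, joint_names)
                    df.insert(0, "participant", profile.participant_id)
                    df.insert(1, "fold", fold)
                    speed_frames.append(df)
    else:
        ids = [p.participant_id for p in cohort.profiles]
        folds = make_lopo_folds(ids)
        for fold in range(folds.n_folds):
            held = folds.test_keys(fold)[0]
            tr = [t for t in cohort.trials if t.angles.participant_id != held]
            te = cohort.participant_trials(held)
            preds, test_wb, _ = _fit_and_score(
                [t.sensors for t in tr], [t.angles for t in tr],
                [t.sensors for t in te], [t.angles for t in te],
                channels, config,
                fit_seed=(config.master_seed * 7919 + fit_counter) % (2**31),
                mode="inter",
            )
            fit_counter += 1
            for j, name in enumerate(joint_names):
                r2, rmse, nrmse = compute_metrics(preds[:, j], test_wb.y[:, j])
                rows.append(
                    {"participant": held, "fold": fold, "joint": name,
                     "r2": r2, "rmse_deg": rmse, "nrmse_pct": nrmse,
                     "n": test_wb.n_windows}
                )
            if config.per_speed:
                df = per_speed_report(preds, test_wb.y, test_wb.speed, joint_names)
                df.insert(0, "participant", held)
                df.insert(1, "fold", fold)
                speed_frames.append(df)

    per_speed = pd.concat(speed_frames, ignore_index=True) if speed_frames else None
    return ExperimentResult(metrics=pd.DataFrame(rows), per_speed=per_speed,
                            config=config)
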