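"""Regression metrics and the leave-one-flight-out evaluation harness.

For each fold one flight session is held out; preprocessing, feature
extraction, SVD selection and column centering/scaling are fitted on the
remaining sessions only, the network is trained on them, and the held-out
session's windows are predicted, RTOR-corrected and scored with per-emotion
RMSE/MAE plus the major-emotion match accuracy (fraction of windows whose
argmax predicted intensity equals the argmax target, ties broken by the
fixed emotion order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import net as nn
from .features import FeatureConfig, FeatureMatrix, build_feature_matrix
from .preprocess import PreprocConfig, preprocess_session, windowize
from .rtor import RTORConfig, rtor_filter
from .select import DEFAULT_COUNTS, SvdReduction
from .session import EMOTIONS, FlightSession


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared residual."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("inputs must be non-empty and of equal shape")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute residual; never exceeds RMSE on the same pair."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("inputs must be non-empty and of equal shape")
    return float(np.mean(np.abs(y - yhat)))


def match_accuracy(
    targets: np.ndarray, preds: np.ndarray
) -> tuple[float, int, int]:
    """Major-emotion match: fraction of rows with agreeing argmax.

    Returns ``(fraction, matched, total)``. np.argmax breaks ties by the
    lowest index, i.e. the fixed emotion order, identically for both sides.
    """
    targets, preds = np.asarray(targets, float), np.asarray(preds, float)
    if targets.shape != preds.shape:
        raise ValueError("shape mismatch")
    if targets.size == 0:
        raise ValueError("empty input")
    matched = int(np.sum(np.argmax(targets, axis=1) == np.argmax(preds, axis=1)))
    total = targets.shape[0]
    return matched / total, matched, total


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, mirroring the test-matrix axes."""

    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    detrend: bool = True
    outliers: bool = True
    feature_extraction: bool = True
    features: FeatureConfig = field(default_factory=FeatureConfig)
    svd: bool = False
    svd_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    svd_mode: str = "select"
    column_center: bool = True
    column_scale: bool = True  # numerical conditioning; see docs/methods.md
    modalities: tuple[str, ...] = ("hr", "gsr", "eeg")
    hidden: tuple[int, ...] = (10, 10)
    activation: str = "sigmoid"
    optimizer: str = "adam"
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 500
    batch_mode: str = "batch"
    # RTOR is off by default for windowed evaluation: with one prediction per
    # 10-s window, a 20-sample batch spans 200 s and would reject genuine
    # task-driven transitions. The test-matrix runner switches it on, where
    # the method's realtime-stream premise is part of the emulated protocol.
    rtor: RTORConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("at least one modality must be enabled")
        if not self.feature_extraction and self.svd:
            raise ValueError("SVD selection requires feature extraction")


class _Standardizer:
    """Column centering (and optional unit-variance scaling) from train stats."""

    def __init__(self, center: bool = True, scale: bool = True):
        self.center = center
        self.scale = scale
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        sd = X.std(axis=0, ddof=0)
        self.sd_ = np.where(sd < 1e-12, 1.0, sd) if self.scale else np.ones(
            X.shape[1]
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


def _raw_matrix(samples, modalities) -> FeatureMatrix:
    """Raw-data mode: each window's normalized samples, concatenated."""
    rows, targets, index = [], [], []
    for s in samples:
        parts = []
        if "hr" in modalities:
            parts.append(np.ravel(s.hr_window))
        if "gsr" in modalities:
            parts.append(np.ravel(s.gsr_window))
        if "eeg" in modalities:
            parts.append(np.ravel(s.eeg_windows))
        rows.append(np.concatenate(parts))
        targets.append(s.target)
        index.append((s.session_id, s.window_idx))
    width = min(len(r) for r in rows)  # guard against boundary-window jitter
    X = pd.DataFrame(
        [r[:width] for r in rows],
        index=pd.MultiIndex.from_tuples(index, names=["session_id", "window_idx"]),
        columns=[f"raw_{i}" for i in range(width)],
    )
    y = pd.DataFrame(
        targets,
        index=X.index,
        columns=list(EMOTIONS),
    )
    return FeatureMatrix(X, y, mode="raw")


def build_cohort_matrix(
    cohort: list[FlightSession], cfg: PipelineConfig
) -> FeatureMatrix:
    """Preprocess, window and featurize every session into one matrix."""
    all_samples = []
    for session in cohort:
        processed = preprocess_session(
            session, cfg.preproc, do_detrend=cfg.detrend, do_outliers=cfg.outliers
        )
        samples = windowize(processed, cfg.preproc)
        if not samples:
            warnings.warn(
                f"session {session.session_id} produced zero windows; skipped",
                stacklevel=2,
            )
            continue
        all_samples.extend(samples)
    if cfg.feature_extraction:
        return build_feature_matrix(all_samples, cfg.features, cfg.modalities)
    return _raw_matrix(all_samples, cfg.modalities)


@dataclass
class FoldResult:
    session_id: str
    rmse: dict[str, float]
    mae: dict[str, float]
    match_fraction: float
    matched: int
    total: int


@dataclass
class EvalReport:
    """Per-fold and aggregated leave-one-flight-out results."""

    folds: list[FoldResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            row = {"session_id": f.session_id}
            for e in EMOTIONS:
                row[f"rmse_{e}"] = f.rmse[e]
                row[f"mae_{e}"] = f.mae[e]
            row["match_accuracy"] = f.match_fraction
            row["matched"] = f.matched
            row["total"] = f.total
            rows.append(row)
        return pd.DataFrame(rows).set_index("session_id")

    def mean_rmse(self) -> dict[str, float]:
        return {e: float(np.mean([f.rmse[e] for f in self.folds])) for e in EMOTIONS}

    def sd_rmse(self) -> dict[str, float]:
        return {
            e: float(np.std([f.rmse[e] for f in self.folds], ddof=1))
            for e in EMOTIONS
        }

    def mean_mae(self) -> dict[str, float]:
        return {e: float(np.mean([f.mae[e] for f in self.folds])) for e in EMOTIONS}

    def mean_match_accuracy(self) -> float:
        return float(np.mean([f.match_fraction for f in self.folds]))

    def summary_dict(self) -> dict:
        return {
            "n_folds": len(self.folds),
            "mean_rmse": self.mean_rmse(),
            "sd_rmse": self.sd_rmse(),
            "mean_mae": self.mean_mae(),
            "mean_match_accuracy": self.mean_match_accuracy(),
        }


def _score_fold(
    session_id: str, targets: np.ndarray, preds: np.ndarray
) -> FoldResult:
    frac, matched, total = match_accuracy(targets, preds)
    return FoldResult(
        session_id=session_id,
        rmse={e: rmse(targets[:, k], preds[:, k]) for k, e in enumerate(EMOTIONS)},
        mae={e: mae(targets[:, k], preds[:, k]) for k, e in enumerate(EMOTIONS)},
        match_fraction=frac,
        matched=matched,
        total=total,
    )


def run_fold(
    fm: FeatureMatrix, held_out: str, cfg: PipelineConfig, fold_seed: int
) -> FoldResult:
    """Train on every session except ``held_out`` and score that session."""
    sids = fm.session_ids()
    train_mask = sids != held_out
    test_mask = ~train_mask
    if not test_mask.any():
        raise ValueError(f"session {held_out!r} not present in matrix")
    fm_train = fm.subset(train_mask)
    fm_test = fm.subset(test_mask)
    assert held_out not in set(fm_train.session_ids())  # no leakage

    if cfg.svd:
        red = SvdReduction(counts=dict(cfg.svd_counts), mode=cfg.svd_mode)
        red.fit(fm_train)
        fm_train = red.transform(fm_train)
        fm_test = red.transform(fm_test)

    scaler = _Standardizer(cfg.column_center, cfg.column_scale)
    X_train = scaler.fit(fm_train.X.to_numpy()).transform(fm_train.X.to_numpy())
    X_test = scaler.transform(fm_test.X.to_numpy())

    spec = nn.NetworkSpec(
        n_input=X_train.shape[1],
        hidden=cfg.hidden,
        activation=cfg.activation,
        optimizer=cfg.optimizer,
        learning_rate=cfg.learning_rate,
        momentum=cfg.momentum,
        epochs=cfg.epochs,
        batch_mode=cfg.batch_mode,
        seed=fold_seed,
    )
    model = nn.init_network(spec)
    nn.train(model, X_train, fm_train.y.to_numpy())

    preds = nn.predict(model, X_test)
    if cfg.rtor is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short folds: RTOR warm-up only
            preds = rtor_filter(preds, cfg.rtor)
    return _score_fold(held_out, fm_test.y.to_numpy(), preds)


def loocv(
    cohort: list[FlightSession], cfg: PipelineConfig | None = None
) -> EvalReport:
    """Leave-one-flight-out evaluation over the whole cohort."""
    if len(cohort) < 2:
        raise ValueError("LOOCV needs at least 2 sessions")
    cfg = cfg or PipelineConfig()
    fm = build_cohort_matrix(cohort, cfg)
    present = list(dict.fromkeys(fm.session_ids()))
    folds = []
    for k, sid in enumerate(present):
        folds.append(run_fold(fm, sid, cfg, fold_seed=cfg.seed + 1000 * (k + 1)))
    return EvalReport(folds=folds)


def decoupled_control(cfg_pipeline: PipelineConfig, synth_cfg,
                      session_ids=None) -> EvalReport:
    """Chance-level control: LOOCV on a cohort with zero coupling gains."""
    from .synth import generate_cohort

    cohort = generate_cohort(synth_cfg.decoupled(), session_ids)
    return loocv(cohort, cfg_pipeline)
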