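"""Prediction scoring (AUC, RMSE, Pearson) and the k-fold CV harness.

AUC uses the binder label IC50 < 500 nM (configurable).  Thresholded
records (bound-only IC50) count as non-binders for AUC but are excluded
from RMSE and Pearson, where a fixed cutoff value would distort the
statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

from .data import BindingDataset
from .graphs import FoldAssignment
from .thermo import ThermoParams
from .training import TrainingConfig, fit_sweep, pack_dataset, predict_packed

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BINDER_THRESHOLD_NM",
    "EvalReport",
    "FoldMetrics",
    "roc_auc",
    "regression_metrics",
    "run_cross_validation",
]

DEFAULT_BINDER_THRESHOLD_NM = 500.0


class UndefinedMetricError(ValueError):
    """Metric has no defined value (single class, zero variance, ...)."""


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney U statistic over (positive, negative) pairs
    normalised by n_pos * n_neg, with ties contributing 1/2.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def regression_metrics(predicted_dG, experimental_dG) -> tuple[float, float]:
    """(RMSE in kcal/mol, Pearson correlation)."""
    pred = np.asarray(predicted_dG, dtype=float)
    obs = np.asarray(experimental_dG, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 values")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise UndefinedMetricError("Pearson undefined: zero variance input")
    return rmse, float(pearsonr(pred, obs).statistic)


@dataclass
class FoldMetrics:
    fold: int
    n: int
    n_binders: int
    auc: float = math.nan
    rmse: float = math.nan
    pearson: float = math.nan
    t_selected: float = math.nan
    auc_defined: bool = True


@dataclass
class EvalReport:
    """Pooled and per-fold cross-validation metrics."""

    auc: float
    rmse: float
    pearson: float
    n: int
    n_binders: int
    per_fold: list[FoldMetrics] = field(default_factory=list)
    predictions: np.ndarray | None = None
    fold_of_record: np.ndarray | None = None

    @property
    def auc_fold_mean(self) -> float:
        vals = [m.auc for m in self.per_fold if m.auc_defined]
        return float(np.mean(vals)) if vals else math.nan

    def summary(self) -> str:
        lines = [
            f"pooled: n={self.n} binders={self.n_binders} AUC={self.auc:.3f} "
            f"RMSE={self.rmse:.3f} r={self.pearson:.3f}",
        ]
        for m in self.per_fold:
            auc = f"{m.auc:.3f}" if m.auc_defined else "NA"
            lines.append(
                f"fold {m.fold}: n={m.n} binders={m.n_binders} AUC={auc} "
                f"RMSE={m.rmse:.3f} r={m.pearson:.3f} t={m.t_selected:.3g}"
            )
        return "\n".join(lines)


def run_cross_validation(
    dataset: BindingDataset,
    folds: FoldAssignment,
    config: TrainingConfig = TrainingConfig(),
    binder_threshold_nM: float = DEFAULT_BINDER_THRESHOLD_NM,
    leak_test_into_train: bool = False,
) -> EvalReport:
    """k-fold cross-validation of the full fit/predict pipeline.

    For each fold the model is fit (full t/start sweep with inner
    validation) on the other folds and scored on the held-out fold; pooled
    held-out predictions give the aggregate metrics and per-fold metrics
    are kept alongside.  ``leak_test_into_train=True`` deliberately trains
    on train+test, the leakage control demonstrating how sequence overlap
    inflates apparent accuracy; never use it for real estimates.
    """
    ids = [r.peptide.id for r in dataset.records]
    missing = [i for i in ids if i not in folds.fold_of]
    if missing:
        raise ValueError(f"records missing from fold assignment: {missing[:5]}")
    fold_ids = np.array([folds.fold_of[i] for i in ids])
    packed = pack_dataset(dataset.sequences, dataset.dG_exp)
    ic50 = dataset.ic50_nM
    thresholded = dataset.thresholded
    labels = (ic50 < binder_threshold_nM).astype(int)
    labels[thresholded] = 0

    predictions = np.full(len(dataset), np.nan)
    per_fold: list[FoldMetrics] = []
    for fold in sorted(set(fold_ids)):
        test_idx = np.flatnonzero(fold_ids == fold)
        train_idx = (
            np.arange(len(dataset))
            if leak_test_into_train
            else np.flatnonzero(fold_ids != fold)
        )
        if not leak_test_into_train:
            assert not set(test_idx) & set(train_idx)
        train = dataset.subset(train_idx)
        fit, _ = fit_sweep(train, config)
        test = dataset.subset(test_idx)
        test_packed = pack_dataset(test.sequences, test.dG_exp)
        pred = predict_packed(test_packed, fit.beta, config.kT, config.model_form)
        predictions[test_idx] = pred

        metrics = FoldMetrics(
            fold=int(fold),
            n=len(test_idx),
            n_binders=int(labels[test_idx].sum()),
            t_selected=fit.t,
        )
        try:
            metrics.auc = roc_auc(pred, labels[test_idx])
        except UndefinedMetricError:
            metrics.auc_defined = False
            logger.warning("fold %d has a single class; AUC omitted", fold)
        keep = ~thresholded[test_idx]
        if keep.sum() >= 2:
            try:
                metrics.rmse, metrics.pearson = regression_metrics(
                    pred[keep], test.dG_exp[keep]
                )
            except UndefinedMetricError:
                pass
        per_fold.append(metrics)

    keep = ~thresholded
    rmse, pearson = regression_metrics(predictions[keep], packed.y[keep])
    try:
        pooled_auc = roc_auc(predictions, labels)
    except UndefinedMetricError:
        pooled_auc = math.nan
        logger.warning("pooled AUC undefined: only one class in the dataset")
    return EvalReport(
        auc=pooled_auc,
        rmse=rmse,
        pearson=pearson,
        n=len(dataset),
        n_binders=int(labels.sum()),
        per_fold=per_fold,
        predictions=predictions,
        fold_of_record=fold_ids,
    )
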