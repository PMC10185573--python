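"""Error metrics and cross-validation for the calibration models.

MAE and RMSE are the two negatively oriented scores used throughout:
``RMSE = sqrt(mean((y - x)^2))`` and ``MAE = mean(|y - x|)`` with y the
estimated and x the expected value.  RMSE >= MAE always (norm inequality);
the pair together separates accuracy from dispersion.

k-fold cross-validation randomly partitions the table into k near-equal
folds; each fold is validated once against a model trained on the remaining
rows, and fold metrics are aggregated by unweighted mean +/- sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .cube_io import CalibrationTable

__all__ = ["MetricPair", "CVReport", "mae", "rmse", "metric_pair", "kfold_cv"]


def _check_pair(estimates, targets) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(estimates, dtype=float).ravel()
    x = np.asarray(targets, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError(f"length mismatch: {y.size} estimates vs {x.size} targets")
    if y.size == 0:
        raise ValueError("empty input")
    return y, x


def mae(estimates, targets) -> float:
    """Mean absolute error, in target units."""
    y, x = _check_pair(estimates, targets)
    return float(np.mean(np.abs(y - x)))


def rmse(estimates, targets) -> float:
    """Root mean square error, in target units."""
    y, x = _check_pair(estimates, targets)
    return float(np.sqrt(np.mean((y - x) ** 2)))


@dataclass(frozen=True)
class MetricPair:
    """MAE/RMSE of one prediction batch; invariant 0 <= mae <= rmse."""

    mae: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.mae <= self.rmse * (1 + 1e-12) + 1e-15):
            raise ValueError(
                f"invalid metric pair: mae={self.mae} must not exceed rmse={self.rmse}"
            )


def metric_pair(estimates, targets) -> MetricPair:
    y, x = _check_pair(estimates, targets)
    return MetricPair(mae=mae(y, x), rmse=rmse(y, x), n=y.size)


@dataclass
class CVReport:
    """Per-fold and aggregate metrics of a k-fold cross-validation.

    ``fold_metrics`` maps a quantity name (e.g. ``"ph"``, ``"po2_layer2"``,
    ``"po2_refined"``) to one MetricPair per fold.
    """

    k: int
    fold_metrics: dict[str, list[MetricPair]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")

    def aggregate(self) -> dict[str, dict[str, float]]:
        """Unweighted mean and sd of each metric over folds."""
        out = {}
        for key, pairs in self.fold_metrics.items():
            maes = np.array([p.mae for p in pairs])
            rmses = np.array([p.rmse for p in pairs])
            out[key] = {
                "mae_mean": float(maes.mean()),
                "mae_sd": float(maes.std(ddof=1)) if len(maes) > 1 else 0.0,
                "rmse_mean": float(rmses.mean()),
                "rmse_sd": float(rmses.std(ddof=1)) if len(rmses) > 1 else 0.0,
            }
        return out

    def to_rows(self) -> list[dict]:
        rows = []
        for key, pairs in self.fold_metrics.items():
            for i, p in enumerate(pairs):
                rows.append(
                    {"quantity": key, "fold": i, "mae": p.mae, "rmse": p.rmse, "n": p.n}
                )
        return rows


def _default_predict(model, spectra):
    return model.predict_samples(spectra)


def kfold_cv(
    table: CalibrationTable,
    k: int = 10,
    trainer=None,
    seed: int = 0,
    predict=_default_predict,
) -> CVReport:
    """k-fold cross-validation of a cascade-style trainer on a labeled table.

    ``trainer(table) -> model`` fits on the training rows of each fold;
    ``predict(model, spectra)`` must return an object with ``ph``,
    ``po2_layer2`` and ``po2_refined`` arrays (the cascade prediction
    contract).  Folds are near-equal random partitions; every row is
    validated exactly once and excluded from that fold's training rows.
    """
    if trainer is None:
        raise ValueError("a trainer callable is required")
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    report = CVReport(
        k=k,
        fold_metrics={"ph": [], "po2_layer2": [], "po2_refined": []},
    )
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, val_idx in splitter.split(np.arange(n)):
        model = trainer(table.subset(train_idx))
        val = table.subset(val_idx)
        pred = predict(model, val.spectra)
        report.fold_metrics["ph"].append(metric_pair(pred.ph, val.ph))
        report.fold_metrics["po2_layer2"].append(metric_pair(pred.po2_layer2, val.po2))
        report.fold_metrics["po2_refined"].append(
            metric_pair(pred.po2_refined, val.po2)
        )
    return report
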