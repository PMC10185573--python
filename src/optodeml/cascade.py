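"""Cascaded gradient-boosted regression for simultaneous pH / O2 prediction.

The final calibration model is a stack of three gradient-boosted tree
ensembles operating on absolute (not ratiometric) fluorescence spectra:

* layer 1 predicts pH from the raw spectrum;
* layer 2 predicts pO2 from the spectrum plus the predicted pH, so the O2
  estimate can compensate pH-dependent cross-talk (inner-filter
  reabsorption couples the two layers' emissions);
* layer 3 refines pO2 from the spectrum, predicted pH and the layer-2 O2
  estimate — one stacked refinement pass.

During training, the pH and layer-2 features fed to later layers are
out-of-fold predictions from an internal k-fold split by default, so later
layers never see optimistically overfitted features; ``conditioning="label"``
switches to conditioning on the training labels instead.

The module also provides the model-selection survey across nine standard
regression families and grid/random hyperparameter search for the boosted
ensembles.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import KFold

from .cube_io import CalibrationTable
from .evalx import mae, rmse

__all__ = [
    "GBTConfig",
    "CascadeModel",
    "CascadePrediction",
    "train_cascade",
    "predict_samples",
    "model_selection",
    "hpo_sweep",
    "SELECTION_ALGORITHMS",
    "PH_VALID_RANGE",
]

#: Dynamic range of the pH sensing layer (pKa +/- 2); predictions outside
#: it are flagged invalid, never clipped.
PH_VALID_RANGE = (5.0, 9.0)


@dataclass(frozen=True)
class GBTConfig:
    """Hyperparameters of one gradient-boosted tree ensemble."""

    n_estimators: int = 250
    min_child_weight: int = 3
    max_depth: int = 9
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in (0, 1]")

    def build(self) -> xgb.XGBRegressor:
        return xgb.XGBRegressor(
            n_estimators=self.n_estimators,
            min_child_weight=self.min_child_weight,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            objective="reg:squarederror",
            tree_method="hist",
            random_state=self.seed,
            n_jobs=1,
            verbosity=0,
        )


#: Tuned defaults for the pH layer and the two O2 layers (the two O2 layers
#: share one configuration).
DEFAULT_PH_CONFIG = GBTConfig(n_estimators=250, min_child_weight=3, max_depth=9,
                              learning_rate=0.05)
DEFAULT_O2_CONFIG = GBTConfig(n_estimators=250, min_child_weight=5, max_depth=7,
                              learning_rate=0.05)


@dataclass
class CascadePrediction:
    """Aligned per-sample outputs of the cascade."""

    ph: np.ndarray
    po2_layer2: np.ndarray
    po2_refined: np.ndarray
    valid: np.ndarray  # True where 5 <= pH <= 9

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ph": self.ph,
                "po2_layer2": self.po2_layer2,
                "po2_refined": self.po2_refined,
                "valid": self.valid,
            }
        )


@dataclass
class CascadeModel:
    """Three trained boosted ensembles sharing one wavelength axis."""

    layer1: xgb.XGBRegressor
    layer2: xgb.XGBRegressor
    layer3: xgb.XGBRegressor
    wavelengths: np.ndarray
    cfg_ph: GBTConfig
    cfg_o2: GBTConfig
    conditioning: str = "oof"
    training_meta: dict = field(default_factory=dict)

    @property
    def n_bands(self) -> int:
        return int(np.asarray(self.wavelengths).size)

    def predict_samples(self, spectra) -> CascadePrediction:
        return predict_samples(self, spectra)

    def save(self, path) -> None:
        """Serialize to a directory: JSON manifest + one model file per layer.

        Layers are stored as plain booster JSON (text), independent of the
        sklearn wrapper, so a saved model reloads across library versions.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "optodeml-cascade-v1",
            "wavelengths": [float(w) for w in np.asarray(self.wavelengths)],
            "cfg_ph": asdict(self.cfg_ph),
            "cfg_o2": asdict(self.cfg_o2),
            "conditioning": self.conditioning,
            "training_meta": self.training_meta,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for name, layer in (
            ("layer1", self.layer1), ("layer2", self.layer2), ("layer3", self.layer3)
        ):
            _booster(layer).save_model(str(path / f"{name}.json"))

    @classmethod
    def load(cls, path) -> "CascadeModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest.get("format") != "optodeml-cascade-v1":
            raise ValueError(f"unrecognized model directory format in {path}")
        layers = []
        for name in ("layer1", "layer2", "layer3"):
            booster = xgb.Booster()
            booster.load_model(str(path / f"{name}.json"))
            layers.append(booster)
        return cls(
            layer1=layers[0],
            layer2=layers[1],
            layer3=layers[2],
            wavelengths=np.array(manifest["wavelengths"]),
            cfg_ph=GBTConfig(**manifest["cfg_ph"]),
            cfg_o2=GBTConfig(**manifest["cfg_o2"]),
            conditioning=manifest["conditioning"],
            training_meta=manifest.get("training_meta", {}),
        )


def _booster(layer) -> xgb.Booster:
    return layer if isinstance(layer, xgb.Booster) else layer.get_booster()


def _layer_predict(layer, X: np.ndarray) -> np.ndarray:
    """Predict with either a fitted sklearn wrapper or a raw Booster."""
    if isinstance(layer, xgb.Booster):
        return layer.inplace_predict(X)
    return layer.predict(X)


def _oof_predictions(
    make_estimator, X: np.ndarray, y: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Out-of-fold predictions from clones fitted on the remaining rows."""
    n = len(y)
    folds = min(n_folds, n)
    if folds < 2:
        return y.astype(float).copy()
    out = np.empty(n, dtype=float)
    for tr, va in KFold(n_splits=folds, shuffle=True, random_state=seed).split(X):
        est = make_estimator()
        est.fit(X[tr], y[tr])
        out[va] = est.predict(X[va])
    return out


def train_cascade(
    train: CalibrationTable,
    cfg_ph: GBTConfig | None = None,
    cfg_o2: GBTConfig | None = None,
    conditioning: str = "oof",
    n_oof_folds: int = 5,
) -> CascadeModel:
    """Fit the three-layer pH -> O2 -> refined-O2 cascade.

    With ``conditioning="oof"`` (default) the pH feature given to layer 2 and
    the pH / O2 features given to layer 3 are out-of-fold predictions from an
    internal ``n_oof_folds``-fold split, avoiding optimistic leakage;
    ``"label"`` conditions on the training labels instead.
    """
    if len(train) == 0:
        raise ValueError("training table is empty")
    if conditioning not in ("oof", "label"):
        raise ValueError(f"unknown conditioning mode '{conditioning}'")
    cfg_ph = cfg_ph or DEFAULT_PH_CONFIG
    cfg_o2 = cfg_o2 or DEFAULT_O2_CONFIG
    X = np.asarray(train.spectra, dtype=float)
    y_ph = np.asarray(train.ph, dtype=float)
    y_po2 = np.asarray(train.po2, dtype=float)
    for name, y in (("ph", y_ph), ("po2", y_po2)):
        if np.unique(y).size == 1:
            warnings.warn(
                f"target '{name}' is single-valued; the corresponding layer "
                "degenerates to a constant predictor"
            )

    layer1 = cfg_ph.build()
    layer1.fit(X, y_ph)
    if conditioning == "oof":
        ph_feat = _oof_predictions(cfg_ph.build, X, y_ph, n_oof_folds, cfg_ph.seed)
    else:
        ph_feat = y_ph.astype(float)

    X2 = np.column_stack([X, ph_feat])
    layer2 = cfg_o2.build()
    layer2.fit(X2, y_po2)
    if conditioning == "oof":
        po2_feat = _oof_predictions(cfg_o2.build, X2, y_po2, n_oof_folds, cfg_o2.seed)
    else:
        po2_feat = y_po2.astype(float)

    X3 = np.column_stack([X, ph_feat, po2_feat])
    layer3 = cfg_o2.build()
    layer3.fit(X3, y_po2)

    return CascadeModel(
        layer1=layer1,
        layer2=layer2,
        layer3=layer3,
        wavelengths=np.asarray(train.wavelengths, dtype=float),
        cfg_ph=cfg_ph,
        cfg_o2=cfg_o2,
        conditioning=conditioning,
        training_meta={"n_rows": len(train), "n_oof_folds": n_oof_folds},
    )


def predict_samples(model: CascadeModel, spectra) -> CascadePrediction:
    """Run the cascade on a batch of spectra.

    Returns aligned pH, first-pass pO2, refined pO2 and the validity flag
    (pH inside the 5-9 dynamic range).  The refined value is the reported O2.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[1] != model.n_bands:
        raise ValueError(
            f"spectra have {spectra.shape[1]} bands but the model expects "
            f"{model.n_bands}"
        )
    ph = _layer_predict(model.layer1, spectra).astype(float)
    po2_l2 = _layer_predict(
        model.layer2, np.column_stack([spectra, ph])
    ).astype(float)
    po2_l3 = _layer_predict(
        model.layer3, np.column_stack([spectra, ph, po2_l2])
    ).astype(float)
    lo, hi = PH_VALID_RANGE
    valid = (ph >= lo) & (ph <= hi)
    return CascadePrediction(ph=ph, po2_layer2=po2_l2, po2_refined=po2_l3, valid=valid)


def _make_selection_algorithms(seed: int):
    from sklearn.linear_model import (
        Lasso,
        LinearRegression,
        LogisticRegression,
        Ridge,
    )
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.svm import SVR
    from sklearn.tree import DecisionTreeRegressor

    return {
        "linear": lambda: LinearRegression(),
        "lasso": lambda: Lasso(),
        "ridge": lambda: Ridge(),
        # Diagnostic only: a classifier on integer-rounded targets, scored
        # as regression; expected to perform poorly on continuous analytes.
        "logistic": lambda: _RoundedTargetClassifier(
            LogisticRegression(max_iter=200)
        ),
        "random_forest": lambda: RandomForestRegressor(
            random_state=seed, n_jobs=1
        ),
        "svm": lambda: SVR(),
        "knn": lambda: KNeighborsRegressor(),
        "decision_tree": lambda: DecisionTreeRegressor(random_state=seed),
        "xgboost": lambda: xgb.XGBRegressor(
            tree_method="hist", random_state=seed, n_jobs=1, verbosity=0
        ),
    }


#: The nine regression families surveyed during model selection.
SELECTION_ALGORITHMS = (
    "linear",
    "lasso",
    "ridge",
    "logistic",
    "random_forest",
    "svm",
    "knn",
    "decision_tree",
    "xgboost",
)


class _RoundedTargetClassifier:
    """Classifier on integer-rounded targets, scored as a regressor."""

    def __init__(self, clf):
        self.clf = clf

    def fit(self, X, y):
        self.clf.fit(X, np.rint(np.asarray(y)).astype(int))
        return self

    def predict(self, X):
        return self.clf.predict(X).astype(float)


def model_selection(
    train: CalibrationTable,
    validation: CalibrationTable,
    algorithms=SELECTION_ALGORITHMS,
    seed: int = 0,
) -> pd.DataFrame:
    """Survey standard regression families, one independent fit per analyte.

    Returns a selection report: one row per (algorithm, analyte) with train
    and validation MAE/RMSE on raw spectra.  An algorithm failure is recorded
    as NaN metrics, never raised.
    """
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("train and validation tables must be nonempty")
    factories = _make_selection_algorithms(seed)
    unknown = set(algorithms) - set(factories)
    if unknown:
        raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
    rows = []
    for name in algorithms:
        for analyte in ("ph", "po2"):
            y_tr = getattr(train, analyte)
            y_va = getattr(validation, analyte)
            row = {"algorithm": name, "analyte": analyte}
            try:
                est = factories[name]()
                est.fit(train.spectra, y_tr)
                pred_tr = est.predict(train.spectra)
                pred_va = est.predict(validation.spectra)
                row.update(
                    train_mae=mae(pred_tr, y_tr),
                    train_rmse=rmse(pred_tr, y_tr),
                    val_mae=mae(pred_va, y_va),
                    val_rmse=rmse(pred_va, y_va),
                )
            except Exception as exc:  # failed cell, not fatal
                warnings.warn(f"{name}/{analyte} failed: {exc}")
                row.update(
                    train_mae=np.nan, train_rmse=np.nan,
                    val_mae=np.nan, val_rmse=np.nan,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def hpo_sweep(
    train: CalibrationTable,
    validation: CalibrationTable,
    space: dict[str, list],
    mode: str = "grid",
    budget: int | None = None,
    seed: int = 0,
    target: str = "ph",
) -> tuple[GBTConfig, pd.DataFrame]:
    """Hyperparameter search for one boosted ensemble on one analyte.

    ``space`` maps GBTConfig field names to candidate lists.  ``mode="grid"``
    enumerates every combination (optionally capped at ``budget``);
    ``mode="random"`` draws ``budget`` distinct combinations with the given
    seed.  Best = lowest validation MAE, ties broken by validation RMSE then
    first-seen order.  Returns the winning config and the full trace.
    """
    if not space:
        raise ValueError("hyperparameter space is empty")
    if target not in ("ph", "po2"):
        raise ValueError("target must be 'ph' or 'po2'")
    if mode not in ("grid", "random"):
        raise ValueError(f"unknown mode '{mode}'")
    if budget is not None and budget < 1:
        raise ValueError("budget must be >= 1")
    keys = list(space.keys())
    valid_fields = set(GBTConfig.__dataclass_fields__)
    unknown = set(keys) - valid_fields
    if unknown:
        raise ValueError(f"unknown hyperparameter(s): {sorted(unknown)}")
    combos = list(itertools.product(*(space[k] for k in keys)))
    if mode == "random":
        if budget is None:
            raise ValueError("random mode requires a budget")
        rng = np.random.default_rng(seed)
        take = min(budget, len(combos))
        idx = rng.choice(len(combos), size=take, replace=False)
        combos = [combos[i] for i in idx]
    elif budget is not None:
        combos = combos[:budget]

    y_tr = getattr(train, target)
    y_va = getattr(validation, target)
    trace_rows = []
    best = None  # (val_mae, val_rmse, order, cfg)
    for order, combo in enumerate(combos):
        cfg = replace(GBTConfig(seed=seed), **dict(zip(keys, combo)))
        est = cfg.build()
        est.fit(train.spectra, y_tr)
        m = {
            "train_mae": mae(est.predict(train.spectra), y_tr),
            "train_rmse": rmse(est.predict(train.spectra), y_tr),
            "val_mae": mae(est.predict(validation.spectra), y_va),
            "val_rmse": rmse(est.predict(validation.spectra), y_va),
        }
        trace_rows.append({**dict(zip(keys, combo)), **m})
        key = (m["val_mae"], m["val_rmse"], order)
        if best is None or key < best[:3]:
            best = (*key, cfg)
    return best[3], pd.DataFrame(trace_rows)
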