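"""Run configuration: one human-editable YAML file driving the whole pipeline.

The schema is validated up front, before any stage runs, and every stochastic
stage must carry a seed.  CLI flags override config values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cascade import DEFAULT_O2_CONFIG, DEFAULT_PH_CONFIG, GBTConfig
from .synthspec import AIR_SATURATION_HPA, Band, SpectralModelParams, WavelengthGrid

__all__ = ["RunConfig", "load_config", "default_config_dict"]


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end pipeline run."""

    seed: int
    grid: WavelengthGrid
    params: SpectralModelParams
    ph_points: list[float]
    po2_points: list[float]
    counts: int | str
    tile: int
    iqr_factor: float
    balance: bool
    split_ratio: float
    cfg_ph: GBTConfig
    cfg_o2: GBTConfig
    conditioning: str
    cv_folds: int
    scene: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ph_points or not self.po2_points:
            raise ConfigError("ph_points and po2_points must be nonempty")
        if not (0.0 < self.split_ratio < 1.0):
            raise ConfigError("split ratio must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv folds must be >= 2")
        if self.conditioning not in ("oof", "label"):
            raise ConfigError(f"unknown conditioning '{self.conditioning}'")
        if self.tile < 1:
            raise ConfigError("tile must be >= 1")


def default_config_dict() -> dict:
    """The default synthetic-study configuration, as a plain dict."""
    return {
        "seed": 1,
        "grid": {"start": 470.0, "stop": 900.0, "step": 3.0},
        "params": {
            "pKa": 7.0,
            "boltzmann_slope": 1.0,
            "acid_band": [490.0, 25.0, 1.0],
            "ref_band": [535.0, 28.0, 0.6],
            "o2_band": [770.0, 20.0, 1.0],
            "K_SV": 0.01,
            "crosstalk_acid": 0.30,
            "crosstalk_ref": 0.15,
            "noise_sd": 0.02,
        },
        "simulate": {
            "ph_points": [float(x) for x in np.arange(4.0, 11.01, 1.0)],
            "po2_points": [float(x) for x in np.linspace(0.0, AIR_SATURATION_HPA, 8)],
            "counts": "imbalanced",
        },
        "prep": {"tile": 5, "iqr_factor": 1.5, "balance": True, "split": 0.8},
        "model": {
            "ph": {
                "n_estimators": DEFAULT_PH_CONFIG.n_estimators,
                "min_child_weight": DEFAULT_PH_CONFIG.min_child_weight,
                "max_depth": DEFAULT_PH_CONFIG.max_depth,
                "learning_rate": DEFAULT_PH_CONFIG.learning_rate,
            },
            "o2": {
                "n_estimators": DEFAULT_O2_CONFIG.n_estimators,
                "min_child_weight": DEFAULT_O2_CONFIG.min_child_weight,
                "max_depth": DEFAULT_O2_CONFIG.max_depth,
                "learning_rate": DEFAULT_O2_CONFIG.learning_rate,
            },
            "conditioning": "oof",
        },
        "cv": {"k": 10},
        "scene": {"height": 40, "width": 60, "ph": [5.0, 9.0], "po2": 50.0},
    }


def _band(value) -> Band:
    try:
        c, w, a = (float(v) for v in value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"band spec must be [center, width, amplitude]: {value!r}") from exc
    return Band(c, w, a)


def load_config(source) -> RunConfig:
    """Build a validated RunConfig from a YAML path or a plain dict."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    if "seed" not in raw:
        raise ConfigError("missing required key 'seed'")

    try:
        g = raw.get("grid", {})
        grid = WavelengthGrid(
            start=float(g.get("start", 470.0)),
            stop=float(g.get("stop", 900.0)),
            step=float(g.get("step", 3.0)),
        )
        pr = raw.get("params", {})
        params = SpectralModelParams(
            pKa=float(pr.get("pKa", 7.0)),
            boltzmann_slope=float(pr.get("boltzmann_slope", 1.0)),
            acid_band=_band(pr.get("acid_band", [490.0, 25.0, 1.0])),
            base_band=(_band(pr["base_band"]) if "base_band" in pr else None),
            ref_band=_band(pr.get("ref_band", [535.0, 28.0, 0.6])),
            o2_band=_band(pr.get("o2_band", [770.0, 20.0, 1.0])),
            K_SV=float(pr.get("K_SV", 0.01)),
            crosstalk_acid=float(pr.get("crosstalk_acid", 0.30)),
            crosstalk_ref=float(pr.get("crosstalk_ref", 0.15)),
            noise_sd=float(pr.get("noise_sd", 0.02)),
        )
        sim = raw.get("simulate", {})
        prep = raw.get("prep", {})
        model = raw.get("model", {})
        seed = int(raw["seed"])
        cfg_ph = GBTConfig(**{**model.get("ph", {}), "seed": seed})
        cfg_o2 = GBTConfig(**{**model.get("o2", {}), "seed": seed})
        defaults = default_config_dict()
        counts = sim.get("counts", "imbalanced")
        if not isinstance(counts, str):
            counts = int(counts)
        return RunConfig(
            seed=seed,
            grid=grid,
            params=params,
            ph_points=[float(x) for x in sim.get("ph_points", defaults["simulate"]["ph_points"])],
            po2_points=[float(x) for x in sim.get("po2_points", defaults["simulate"]["po2_points"])],
            counts=counts,
            tile=int(prep.get("tile", 5)),
            iqr_factor=float(prep.get("iqr_factor", 1.5)),
            balance=bool(prep.get("balance", True)),
            split_ratio=float(prep.get("split", 0.8)),
            cfg_ph=cfg_ph,
            cfg_o2=cfg_o2,
            conditioning=model.get("conditioning", "oof"),
            cv_folds=int(raw.get("cv", {}).get("k", 10)),
            scene=raw.get("scene", defaults["scene"]),
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
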