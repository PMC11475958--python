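"""End-to-end orchestration of the six-run moisture-calibration experiment.

Workflow: generate (or load) spectra -> Savitzky-Golay first derivative ->
SPXY train/test split -> GA-PLS wavelength selection -> train each of the
three regressors on full and on selected wavelengths -> GP prediction
intervals per run -> point and interval metrics in a six-row comparison
grid, plus percent-change comparisons between the full- and
selected-wavelength run of each model.

Moisture enters the models as mass FRACTION (percent / 100), so RMSEP and
interval widths come out on the fraction scale; the report carries both
scales.  Every stochastic stage derives its stream from the single run
seed, so a rerun with the same config reproduces the grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as M
from .partitioning import SplitResult, spxy_split, ks_split, split_diagnostics
from .preprocessing import SGParams, sg_first_derivative
from .regressors import (
    CNNRegressor,
    PredictionSet,
    ResNet1DRegressor,
    XGBConfig,
    make_prediction_set,
    train_xgb,
)
from .selection import GAConfig, SelectionResult, ga_select
from .simulate import GeneratorConfig, SpectraSet, generate_dataset, read_spectra
from .uncertainty import IntervalCalibrator

__all__ = ["RunConfig", "ComparisonReport", "run_experiment"]

logger = logging.getLogger("nirmoist")

MODELS = ("xgb", "cnn", "resnet")
WAVELENGTH_SETS = ("full", "selected")


@dataclass
class NetworkSettings:
    learning_rate: float
    epochs: int
    batch_size: int = 32


@dataclass
class RunConfig:
    """Everything one experiment needs; the single seed fans out to stages."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    spectra_path: str | None = None  # load instead of simulate when set
    sg: SGParams = field(default_factory=SGParams)
    split_method: str = "spxy"
    n_train: int = 300
    ga: GAConfig = field(default_factory=GAConfig)
    xgb: XGBConfig = field(default_factory=XGBConfig)
    cnn: NetworkSettings = field(default_factory=lambda: NetworkSettings(0.001, 800))
    resnet: NetworkSettings = field(default_factory=lambda: NetworkSettings(0.0001, 1200))
    confidence: float = 0.95
    include_test_in_gpr_fit: bool = False
    model_on_fraction_scale: bool = True
    output_dir: str | None = None
    seed: int = 0

    def seeded(self) -> "RunConfig":
        """Propagate the run seed into every stochastic sub-config."""
        rc = dataclasses.replace(self)
        rc.generator = dataclasses.replace(self.generator, seed=self.seed)
        rc.ga = dataclasses.replace(self.ga, seed=self.seed + 1)
        rc.xgb = dataclasses.replace(self.xgb, seed=self.seed + 2)
        return rc


@dataclass
class ComparisonReport:
    """Six-run metric grid plus percent-change comparisons."""

    grid: pd.DataFrame
    percent_changes: dict[str, float]
    diagnostics: dict
    selection: SelectionResult
    split: SplitResult
    prediction_sets: dict[tuple[str, str], PredictionSet]

    def percent_change_lines(self) -> list[str]:
        return [f"{key}: {value:+.1f} %" for key, value in self.percent_changes.items()]


def _make_regressor(model: str, config: RunConfig, seed: int):
    if model == "xgb":
        return None  # handled by train_xgb
    if model == "cnn":
        s = config.cnn
        return CNNRegressor(learning_rate=s.learning_rate, epochs=s.epochs,
                            batch_size=s.batch_size, random_state=seed)
    if model == "resnet":
        s = config.resnet
        return ResNet1DRegressor(learning_rate=s.learning_rate, epochs=s.epochs,
                                 batch_size=s.batch_size, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def _percent_changes(grid: pd.DataFrame) -> dict[str, float]:
    """Full-vs-selected percent changes per model and metric.

    The convention follows the sign of the change: improvements in R²/RPD
    are reported as increases relative to the full-wavelength value,
    RMSEP/PINAW reductions relative to the (smaller) selected value, and
    deteriorations as decreases/increases relative to the full value.
    """
    out: dict[str, float] = {}
    for model in MODELS:
        full = grid[(grid.model == model) & (grid.wavelengths == "full")].iloc[0]
        sel = grid[(grid.model == model) & (grid.wavelengths == "selected")].iloc[0]
        for metric_name in ("r2", "rpd_eq", "rmsep", "pinaw"):
            old, new = float(full[metric_name]), float(sel[metric_name])
            if old == 0 or new == 0:
                continue
            lower_is_better = metric_name in ("rmsep", "pinaw")
            if lower_is_better:
                if new < old:
                    conv, label = "reduction_vs_new", "reduced"
                else:
                    conv, label = "increase_vs_old", "increased"
            else:
                if new > old:
                    conv, label = "increase_vs_old", "increased"
                else:
                    conv, label = "decrease_vs_old", "decreased"
            out[f"{model}_{metric_name}_{label}"] = M.relative_change(old, new, conv)
    return out


def run_experiment(config: RunConfig) -> ComparisonReport:
    """Run the full six-cell experiment grid; see module docstring."""
    config = config.seeded()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    timings: dict[str, float] = {}
    manifest: dict = {"seed": config.seed, "stages": []}

    # --- data -------------------------------------------------------------
    t0 = stage("data")
    if config.spectra_path:
        spectra = read_spectra(config.spectra_path)
        if spectra.moisture is None:
            raise ValueError("input spectra file carries no moisture column")
    else:
        spectra = generate_dataset(config.generator)
    timings["data"] = time.perf_counter() - t0

    # --- preprocessing ----------------------------------------------------
    t0 = stage("preprocess")
    deriv = sg_first_derivative(spectra, config.sg)
    timings["preprocess"] = time.perf_counter() - t0

    x = deriv.absorbance
    y_percent = deriv.moisture
    y = y_percent / 100.0 if config.model_on_fraction_scale else y_percent.copy()

    # --- partitioning -----------------------------------------------------
    t0 = stage("split")
    if config.split_method == "spxy":
        split = spxy_split(x, y, config.n_train)
    elif config.split_method == "ks":
        split = ks_split(x, config.n_train)
    else:
        raise ValueError(f"unknown split method {config.split_method!r}")
    diagnostics = {"split": split_diagnostics(y_percent, split)}
    timings["split"] = time.perf_counter() - t0
    if out_dir:
        split.to_json(out_dir / "split.json")

    tr, te = split.train_indices, split.test_indices
    x_tr, x_te, y_tr, y_te = x[tr], x[te], y[tr], y[te]

    # --- wavelength selection ----------------------------------------------
    t0 = stage("select")
    selection = ga_select(x_tr, y_tr, config.ga, wavelengths=deriv.wavelengths)
    timings["select"] = time.perf_counter() - t0
    if out_dir:
        selection.to_json(out_dir / "selection.json")

    channel_sets = {
        "full": np.arange(x.shape[1]),
        "selected": selection.selected_channels,
    }

    # --- train / intervals / metrics per grid cell --------------------------
    rows = []
    prediction_sets: dict[tuple[str, str], PredictionSet] = {}
    for model in MODELS:
        for wset in WAVELENGTH_SETS:
            t0 = stage(f"train:{model}:{wset}")
            cols = channel_sets[wset]
            if model == "xgb":
                fitted = train_xgb(x_tr[:, cols], y_tr, config.xgb)
            else:
                fitted = _make_regressor(model, config, config.seed + 3)
                fitted.fit(x_tr[:, cols], y_tr)
            ps_train = make_prediction_set(fitted, x_tr[:, cols], y_tr, "train", model, wset)
            ps_test = make_prediction_set(fitted, x_te[:, cols], y_te, "test", model, wset)
            prediction_sets[(model, wset)] = ps_test
            timings[f"train:{model}:{wset}"] = time.perf_counter() - t0

            t0 = stage(f"intervals:{model}:{wset}")
            calib_x, calib_y = ps_train.y_pred, ps_train.y_actual
            if config.include_test_in_gpr_fit:
                calib_x = np.concatenate([calib_x, ps_test.y_pred])
                calib_y = np.concatenate([calib_y, ps_test.y_actual])
            calib = IntervalCalibrator(
                confidence=config.confidence, random_state=config.seed,
            ).fit(calib_x, calib_y)
            interval = calib.predict_interval(ps_test.y_pred)
            timings[f"intervals:{model}:{wset}"] = time.perf_counter() - t0

            pm = M.point_metrics(ps_test)
            im = M.interval_metrics(ps_test.y_actual, interval)
            rows.append({
                "wavelengths": wset, "model": model,
                "r2": pm.r2, "rmsep": pm.rmsep,
                "rpd_eq": pm.rpd_eq, "rpd_sd_ratio": pm.rpd_sd_ratio,
                "picp": im.picp, "pinaw": im.pinaw, "cwc": im.cwc,
                "n_test": pm.n, "n_selected_channels": len(cols),
            })
            if out_dir:
                tag = f"{model}_{wset}"
                pd.DataFrame({
                    "y_actual": ps_test.y_actual, "y_pred": ps_test.y_pred,
                }).to_csv(out_dir / f"predictions_{tag}.csv", index=False)
                pd.DataFrame({
                    "mu": interval.mu, "sigma": interval.sigma,
                    "lower": interval.lower, "upper": interval.upper,
                }).to_csv(out_dir / f"intervals_{tag}.csv", index=False)

    grid = pd.DataFrame(rows)
    report = ComparisonReport(
        grid=grid,
        percent_changes=_percent_changes(grid),
        diagnostics=diagnostics,
        selection=selection,
        split=split,
        prediction_sets=prediction_sets,
    )

    if out_dir:
        grid.to_csv(out_dir / "report.csv", index=False)
        (out_dir / "report.txt").write_text(
            "\n".join(report.percent_change_lines()) + "\n"
        )
        manifest["config_hash"] = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
        manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
        manifest["diagnostics"] = diagnostics
        manifest["n_selected_channels"] = int(len(selection.selected_channels))
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    return report
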