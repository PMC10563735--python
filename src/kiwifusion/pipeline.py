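"""End-to-end study orchestration.

``run_pipeline`` executes the whole analysis for every requested duty
(eight-class storage-day classification, firmness/SSC/TA prediction) and
data mode (e-nose only, hyperspectral only, feature-level fusion):

generate -> e-nose features -> trim + pretreat spectra -> per-duty CARS
selection on the SG1D spectra (calibration rows only) -> PLS-family and
SV-family models with 10-fold cross-validated hyperparameters -> metrics at
the calibration, cross-validation and test stages -> report.

The hyperspectral mode models the CARS-selected SG1D wavelengths (the best
pretreatment for this duty family); the fused mode concatenates the 39
e-nose features with the same selections.  CARS selection is computed
independently per duty.  Everything is reproducible from the config and its
seed; the config hash is recorded in the report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.svm import SVC, SVR

from . import enose as enose_mod
from . import synth
from .cars import CarsSelector
from .config import PipelineConfig
from .evaluation import (
    ConfusionMatrix,
    classification_metrics,
    one_way_anova,
    regression_metrics,
    split_dataset,
)
from .hsi import preprocess_spectra, trim_spectra_table
from .models import (
    CVPLSRegressor,
    FusionDataset,
    GridPolySVC,
    GridPolySVR,
    PLSDAClassifier,
    dummy_rmse,
    fuse_features,
    one_hot,
)

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline", "PipelineError"]

REGRESSION_DUTIES = ("firmness", "ssc", "ta")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunReport:
    """Structured result of one pipeline execution."""

    rows: list[dict]
    anova: pd.DataFrame
    selections: dict                   # duty -> selected wavelengths (nm)
    config_hash: str
    seed: int
    timings_s: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "selections": {k: list(map(float, v)) for k, v in self.selections.items()},
            "rows": self.rows,
            "anova": self.anova.to_dict(orient="records"),
            "timings_s": {k: round(v, 3) for k, v in self.timings_s.items()},
        }
        return json.dumps(payload, indent=2, allow_nan=True)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(self.to_json())
        self.anova.to_csv(directory / "anova.csv", index=False, float_format="%.6g")


def _standardize(table: pd.DataFrame, cal_ids: Sequence[str]) -> pd.DataFrame:
    """Z-score every column using calibration-row statistics only."""
    mu = table.loc[list(cal_ids)].mean(axis=0)
    sd = table.loc[list(cal_ids)].std(axis=0, ddof=0).replace(0, 1.0)
    return (table - mu) / sd


def _classification_stage_metrics(y_true, y_pred_labels, scores, classes, stage):
    cm = ConfusionMatrix.from_labels(y_true, y_pred_labels, labels=classes)
    acc = classification_metrics(cm, stage=stage).accuracy
    Yt = one_hot(np.asarray(y_true), classes)
    Yp = scores if scores is not None else one_hot(np.asarray(y_pred_labels), classes)
    ss_tot = float(((Yt - Yt.mean()) ** 2).sum())
    r2 = 1.0 - float(((Yt - Yp) ** 2).sum()) / ss_tot if ss_tot else float("nan")
    return {"r2": round(r2, 4), "rmse": round(dummy_rmse(y_true, Yp, classes), 4),
            "accuracy": round(acc, 2)}


def _evaluate_classifier(model, X_cal, y_cal, X_test, y_test, folds, seed):
    classes = model.classes_
    out = {}
    out["calibration"] = _classification_stage_metrics(
        y_cal, model.predict(X_cal),
        model.decision_function(X_cal) if isinstance(model, PLSDAClassifier) else None,
        classes, "calibration")
    cv = KFold(min(folds, len(y_cal)), shuffle=True, random_state=seed)
    if isinstance(model, PLSDAClassifier):
        Y = one_hot(y_cal, classes)
        scores = cross_val_predict(
            PLSRegression(n_components=model.n_components_), X_cal, Y, cv=cv)
        pred = classes[np.argmax(scores, axis=1)]
        out["cross-validation"] = _classification_stage_metrics(
            y_cal, pred, scores, classes, "cross-validation")
    else:
        est = SVC(kernel="poly", degree=model.degree, coef0=model.coef0,
                  C=model.best_c_, gamma=model.best_gamma_, max_iter=200_000)
        pred = cross_val_predict(est, X_cal, y_cal, cv=cv)
        out["cross-validation"] = _classification_stage_metrics(
            y_cal, pred, None, classes, "cross-validation")
    out["test"] = _classification_stage_metrics(
        y_test, model.predict(X_test),
        model.decision_function(X_test) if isinstance(model, PLSDAClassifier) else None,
        classes, "test")
    return out


def _evaluate_regressor(model, X_cal, y_cal, X_test, y_test, folds, seed):
    out = {}
    for stage, X, y in (("calibration", X_cal, y_cal), ("test", X_test, y_test)):
        m = regression_metrics(y, model.predict(X), stage=stage)
        out[stage] = {"r2": round(m.r2, 4), "rmse": round(m.rmse, 4)}
    cv = KFold(min(folds, len(y_cal)), shuffle=True, random_state=seed)
    if isinstance(model, CVPLSRegressor):
        pred = cross_val_predict(
            PLSRegression(n_components=model.n_components_), X_cal, y_cal, cv=cv).ravel()
    else:
        z = (y_cal - model._y_mean) / model._y_sd
        est = SVR(kernel="poly", degree=model.degree, coef0=model.coef0,
                  C=model.best_c_, gamma=model.best_gamma_, epsilon=model.epsilon,
                  max_iter=200_000)
        pred = cross_val_predict(est, X_cal, z, cv=cv) * model._y_sd + model._y_mean
    m = regression_metrics(y_cal, pred, stage="cross-validation")
    out["cross-validation"] = {"r2": round(m.r2, 4), "rmse": round(m.rmse, 4)}
    return out


def _model_params_str(model) -> str:
    if isinstance(model, (CVPLSRegressor, PLSDAClassifier)):
        return f"LV = {model.n_components_}"
    return f"c = {model.best_c_:g}, gamma = {model.best_gamma_:g}"


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> RunReport:
    """Execute the configured study and return (and optionally write) the report."""
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else (
        Path(config.outdir) if config.outdir else None)
    timings: dict[str, float] = {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))

    def stage_seed() -> int:
        return int(rng.integers(2**31 - 1))

    def _stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    # -- generate ---------------------------------------------------------
    t0 = _stage("simulate")
    try:
        bundle = synth.generate_experiment(
            config.experiment_design(), config.trajectory_params(),
            config.sensor_panel(), config.spectral_params(),
            seed=config.seed, aroma_noise_sd=config.aroma_noise_sd)
    except Exception as exc:
        raise PipelineError(f"simulate stage failed: {exc}") from exc
    timings["simulate"] = time.perf_counter() - t0
    attributes = bundle.attributes.set_index("fruit_id")
    days = attributes["day"]

    # -- e-nose features --------------------------------------------------
    t0 = _stage("features")
    try:
        enose_table = enose_mod.enose_feature_table(bundle.recordings)
    except Exception as exc:
        raise PipelineError(f"features stage failed: {exc}") from exc
    timings["features"] = time.perf_counter() - t0

    # -- spectra pretreatments --------------------------------------------
    t0 = _stage("preprocess")
    try:
        trimmed = trim_spectra_table(bundle.spectra)
        pretreated = {m: preprocess_spectra(trimmed, m) for m in config.methods}
    except Exception as exc:
        raise PipelineError(f"preprocess stage failed: {exc}") from exc
    timings["preprocess"] = time.perf_counter() - t0

    # -- split ------------------------------------------------------------
    partition = split_dataset(attributes.index.to_numpy(), days.to_numpy(),
                              (config.calibration_fraction, 1 - config.calibration_fraction),
                              seed=stage_seed())
    cal_ids, test_ids = list(partition.calibration_ids), list(partition.test_ids)

    # -- quality-attribute ANOVA ------------------------------------------
    anova = pd.concat([
        one_way_anova(attributes[attr], days).to_frame(attr)
        for attr in REGRESSION_DUTIES
    ], ignore_index=True)

    # -- per-duty CARS selection on SG1D ----------------------------------
    t0 = _stage("select")
    sg1d = pretreated["SG1D"]
    selections: dict[str, np.ndarray] = {}
    selectors: dict[str, CarsSelector] = {}
    for duty in config.duties:
        y = days if duty == "classify" else attributes[duty]
        try:
            sel = CarsSelector(
                n_runs=config.cars.n_runs,
                calibration_fraction=config.cars.calibration_fraction,
                folds=config.cars.folds, max_lv=config.cars.max_lv,
                random_state=stage_seed(),
            ).fit(sg1d.loc[cal_ids].to_numpy(), y.loc[cal_ids].to_numpy(dtype=float))
        except Exception as exc:
            raise PipelineError(f"select stage failed for duty {duty!r}: {exc}") from exc
        selectors[duty] = sel
        selections[duty] = sg1d.columns.to_numpy(dtype=float)[sel.support_]
    timings["select"] = time.perf_counter() - t0

    # -- models -----------------------------------------------------------
    t0 = _stage("fit/evaluate")
    rows: list[dict] = []
    fused_sets: dict[str, FusionDataset] = {}
    for duty in config.duties:
        is_class = duty == "classify"
        y_all = days if is_class else attributes[duty]
        selected_cols = [c for c, keep in
                         zip(sg1d.columns, selectors[duty].support_) if keep]
        tables: dict[str, pd.DataFrame] = {}
        if "enose" in config.modes:
            tables["enose"] = _standardize(enose_table, cal_ids)
        if "hsi" in config.modes:
            tables["hsi"] = _standardize(sg1d[selected_cols], cal_ids)
        if "fusion" in config.modes:
            fused = fuse_features(enose_table, sg1d, selected_cols, cal_ids)
            fused_sets[duty] = fused
            tables["fusion"] = fused.X

        for mode, table in tables.items():
            X_cal = table.loc[cal_ids].to_numpy()
            X_test = table.loc[test_ids].to_numpy()
            y_cal = y_all.loc[cal_ids].to_numpy()
            y_test = y_all.loc[test_ids].to_numpy()
            if is_class:
                families = {
                    "PLSDA": PLSDAClassifier(max_lv=config.models.max_lv,
                                             folds=config.models.folds,
                                             random_state=stage_seed()),
                    "SVM": GridPolySVC(c_grid=config.models.sv_grid,
                                       gamma_grid=config.models.sv_grid,
                                       folds=config.models.folds,
                                       random_state=stage_seed()),
                }
            else:
                families = {
                    "PLSR": CVPLSRegressor(max_lv=config.models.max_lv,
                                           folds=config.models.folds,
                                           random_state=stage_seed()),
                    "SVR": GridPolySVR(c_grid=config.models.sv_grid,
                                       gamma_grid=config.models.sv_grid,
                                       folds=config.models.folds,
                                       random_state=stage_seed()),
                }
            for family, est in families.items():
                try:
                    est.fit(X_cal, y_cal)
                    evaluate = _evaluate_classifier if is_class else _evaluate_regressor
                    stages = evaluate(est, X_cal, y_cal, X_test, y_test,
                                      config.models.folds, stage_seed())
                except Exception as exc:
                    raise PipelineError(
                        f"fit stage failed for {duty}/{mode}/{family}: {exc}") from exc
                row = {"duty": duty, "mode": mode, "model": family,
                       "params": _model_params_str(est)}
                for stage_name, key in (("calibration", "cal"),
                                        ("cross-validation", "val"),
                                        ("test", "test")):
                    for metric, value in stages[stage_name].items():
                        row[f"{metric}_{key}"] = value
                rows.append(row)
                if outdir is not None:
                    _save_model_artifact(outdir, duty, mode, family, est)
    timings["fit/evaluate"] = time.perf_counter() - t0

    report = RunReport(rows, anova, {d: s for d, s in selections.items()},
                       config.config_hash(), config.seed, timings)

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        bundle.save(outdir)
        enose_table.to_csv(outdir / "enose_features.csv", float_format="%.9g")
        for m, table in pretreated.items():
            named = table.copy()
            named.columns = [f"{float(c):.6f}" for c in named.columns]
            named.to_csv(outdir / f"spectra_{m}.csv", float_format="%.9g")
        sel_payload = {
            duty: {
                "selected_wavelengths_nm": [float(w) for w in selections[duty]],
                "n_retained_path": selectors[duty].result_.n_retained_path.tolist(),
                "rmsecv_path": [round(float(v), 6)
                                for v in selectors[duty].result_.rmsecv_path],
                "best_run": int(selectors[duty].result_.best_run) + 1,
            } for duty in config.duties}
        (outdir / "cars_selections.json").write_text(json.dumps(sel_payload, indent=2))
        (outdir / "partition.json").write_text(json.dumps(
            {"calibration": cal_ids, "test": test_ids}, indent=2))
        report.save(outdir)
    return report


def _save_model_artifact(outdir: Path, duty: str, mode: str, family: str, est) -> None:
    mdir = outdir / "models"
    mdir.mkdir(parents=True, exist_ok=True)
    payload: dict = {"duty": duty, "mode": mode, "family": family}
    if isinstance(est, (CVPLSRegressor,)):
        payload |= {"n_components": est.n_components_,
                    "coef": est.coef_.tolist(), "intercept": est.intercept_}
    elif isinstance(est, PLSDAClassifier):
        payload |= {"n_components": est.n_components_,
                    "classes": [int(c) for c in est.classes_],
                    "coef": est.pls_.coef_.tolist()}
    elif isinstance(est, GridPolySVR):
        payload |= {"c": est.best_c_, "gamma": est.best_gamma_,
                    "epsilon": est.epsilon,
                    "support_coef": est.svr_.dual_coef_.ravel().tolist()}
    elif isinstance(est, GridPolySVC):
        payload |= {"c": est.best_c_, "gamma": est.best_gamma_,
                    "n_support": est.svc_.n_support_.tolist()}
    (mdir / f"{duty}_{mode}_{family}.json").write_text(json.dumps(payload))
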