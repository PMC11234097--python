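"""End-to-end orchestration: simulate or load spectra, preprocess, split,
select components by leave-one-out cross-validation, fit, validate, and
report — for the monoculture, polyculture or combined subset.

Every run writes its resolved configuration, processed spectra, model JSON,
metrics JSON and a stage log beside its outputs, so a report is always
traceable to the exact parameters that produced it.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import yaml

from . import peaks
from .pls import (
    NipalsPLS, PLSModelBundle, loo_cv_select, prediction_metrics,
    split_calibration_validation,
)
from .preprocessing import PreprocessConfig, preprocess_pipeline
from .simulate import simulate_dataset
from .spectra import (
    ReferenceTable, SpectraSet, read_metadata_csv, read_reference_table,
    read_spectra_csv, write_reference_table, write_spectra_csv,
)

REPORT_SCHEMA = "driftfa-report/1"

SUBSETS = ("monoculture", "polyculture", "combined")


def _make_logger(log_path: Path | None) -> logging.Logger:
    logger = logging.getLogger(f"driftfa.run.{id(log_path)}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    logger.addHandler(h)
    if log_path is not None:
        fh = logging.FileHandler(log_path, mode="w")
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger


def _load_inputs(cfg: dict) -> tuple[SpectraSet, ReferenceTable]:
    has_inputs = "inputs" in cfg
    has_sim = "simulate" in cfg
    if has_inputs == has_sim:
        raise ValueError("config must contain exactly one of 'inputs' / 'simulate'")
    if has_sim:
        sim = dict(cfg["simulate"])
        spectra, ref, _ = simulate_dataset(
            n_mono=int(sim.get("n_mono", 44)),
            n_poly=int(sim.get("n_poly", 57)),
            seed=int(sim.get("seed", 0)),
        )
        return spectra, ref
    inp = cfg["inputs"]
    meta = inp.get("metadata")
    spectra = read_spectra_csv(
        inp["spectra"], inp.get("orientation", "samples-as-columns"),
        metadata_path=meta,
    )
    ref = read_reference_table(inp["reference"])
    return spectra, ref


def run_analysis(cfg: dict) -> dict:
    """Execute one full modeling run from a configuration mapping.

    Returns the report record; raises with the failing stage name on error.
    """
    out_dir = Path(cfg.get("output_dir", "driftfa_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    logger = _make_logger(out_dir / "run.log")
    subset = cfg.get("subset", "combined")
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}")
    stage = "load"
    try:
        logger.info("stage=load subset=%s", subset)
        spectra, ref = _load_inputs(cfg)
        if subset != "combined":
            spectra = spectra.subset_culture(subset)

        stage = "preprocess"
        pp = {k: v for k, v in cfg.get("preprocess", {}).items()}
        pcfg = PreprocessConfig(**pp)
        logger.info("stage=preprocess lo=%g hi=%g lambda=%g p=%g",
                    pcfg.region_lo, pcfg.region_hi, pcfg.asls_lambda, pcfg.asls_p)
        processed = preprocess_pipeline(spectra, pcfg)
        write_spectra_csv(processed, out_dir / "processed.csv")

        stage = "split"
        split_cfg = cfg.get("split", {})
        frac = float(split_cfg.get("frac", 0.75))
        seed = int(split_cfg.get("seed", 0))
        (cal_s, y_cal), (val_s, y_val) = split_calibration_validation(
            processed, ref, frac=frac, seed=seed
        )
        logger.info("stage=split n_cal=%d n_val=%d seed=%d",
                    cal_s.n_samples, val_s.n_samples, seed)

        stage = "loo_cv"
        k_max = int(cfg.get("k_max", min(10, cal_s.n_samples - 2)))
        k_max = min(k_max, cal_s.n_samples - 2)
        cv = loo_cv_select(cal_s.absorbance, y_cal, k_max)
        logger.info("stage=loo_cv k_max=%d chosen_k=%d", k_max, cv.chosen_k)

        stage = "fit"
        model = NipalsPLS(n_components=cv.chosen_k).fit(cal_s.absorbance, y_cal)
        bundle = PLSModelBundle(model, processed.grid.values, cv.chosen_k, seed)
        bundle.to_json(out_dir / "model.json")

        stage = "validate"
        y_pred = bundle.predict_spectra(val_s)
        metrics = prediction_metrics(y_val, y_pred)
        logger.info("stage=validate rmsep=%.4f re=%.4f r2=%.4f",
                    metrics.rmsep, metrics.re, metrics.r2)

        stage = "peaks"
        h1740 = peaks.peak_height(cal_s, peaks.ESTER_CARBONYL)
        ratio = peaks.peak_ratio(cal_s)
        peak_r2 = {
            "height_1740": peaks.univariate_calibration(h1740, y_cal)["r2"],
            "ratio_1740_1650": peaks.univariate_calibration(ratio, y_cal)["r2"],
        }

        report = {
            "schema": REPORT_SCHEMA,
            "subset": subset,
            "n_cal": int(cal_s.n_samples),
            "n_val": int(val_s.n_samples),
            "chosen_k": int(cv.chosen_k),
            "rmsecv_by_k": [float(v) for v in cv.rmsecv_by_k],
            "rmsep": metrics.rmsep,
            "re": metrics.re,
            "r2": metrics.r2,
            "coef_path": str(out_dir / "model.json"),
            "peak_calibration_r2": peak_r2,
        }
        with open(out_dir / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        with open(out_dir / "resolved_config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        write_reference_table(ref, out_dir / "reference.csv")
        logger.info("stage=done out=%s", out_dir)
        return report
    except Exception as exc:
        logger.error("stage=%s failed: %s", stage, exc)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def evaluate_synthetic(
    seed: int,
    subset: str = "combined",
    n_mono: int = 44,
    n_poly: int = 57,
    frac: float = 0.75,
    k_max: int = 10,
) -> dict:
    """One in-memory modeling run on a freshly simulated dataset.

    Simulates the two-regime dataset with ``seed``, optionally restricts to
    one culture type, preprocesses with defaults, splits with the same seed,
    selects components by leave-one-out cross-validation and validates.
    Returns metrics plus the fitted coefficient vector and its grid.
    """
    spectra, ref, _ = simulate_dataset(n_mono=n_mono, n_poly=n_poly, seed=seed)
    if subset != "combined":
        spectra = spectra.subset_culture(subset)
    processed = preprocess_pipeline(spectra, PreprocessConfig())
    (cal_s, y_cal), (val_s, y_val) = split_calibration_validation(
        processed, ref, frac=frac, seed=seed
    )
    k_max = min(k_max, cal_s.n_samples - 2)
    cv = loo_cv_select(cal_s.absorbance, y_cal, k_max)
    model = NipalsPLS(n_components=cv.chosen_k).fit(cal_s.absorbance, y_cal)
    metrics = prediction_metrics(y_val, model.predict(val_s.absorbance))
    return {
        "subset": subset,
        "seed": int(seed),
        "n_cal": int(cal_s.n_samples),
        "n_val": int(val_s.n_samples),
        "chosen_k": int(cv.chosen_k),
        "rmsep": metrics.rmsep,
        "re": metrics.re,
        "r2": metrics.r2,
        "coef": model.coef_,
        "grid": processed.grid.values,
    }


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return cfg
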