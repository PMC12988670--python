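"""Composable pipeline stages and the end-to-end runner."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import archetypal, io, qc, qol
from .config import PipelineConfig
from .core import integrate_pair

log = logging.getLogger(__name__)


@dataclass
class QCOutcome:
    """Per-patient QC report plus the retained pairs."""

    report: pd.DataFrame
    selected: dict  # patient_id -> VFPair


def run_qc(
    tests,
    asym_threshold: float = qc.DEFAULT_ASYM_THRESHOLD_DB,
    corr_threshold: float = qc.DEFAULT_CORR_THRESHOLD,
    exclude_flagged: bool = False,
    report: io.ValidationReport | None = None,
) -> QCOutcome:
    """Reliability filtering, visit selection and the homonymous screen."""
    pairs_by_patient = io.pair_by_visit(tests, report=report)
    rows = []
    selected = {}
    for pid in sorted(pairs_by_patient):
        visits = pairs_by_patient[pid]
        n_reliable = sum(qc.pair_is_reliable(p) for p in visits)
        chosen = qc.select_analysis_visit(visits)
        row = {
            "patient_id": pid,
            "n_visits": len(visits),
            "n_reliable_visits": n_reliable,
            "selected_date": None if chosen is None else chosen.test_date.isoformat(),
            "vertical_asymmetry_db": np.nan,
            "interocular_r": np.nan,
            "flagged": False,
            "included": False,
        }
        if chosen is not None:
            screen = qc.neuro_screen(chosen, asym_threshold, corr_threshold)
            row["vertical_asymmetry_db"] = screen.vertical_asymmetry_db
            row["interocular_r"] = screen.interocular_r
            row["flagged"] = screen.flagged
            row["included"] = not (exclude_flagged and screen.flagged)
            if row["included"]:
                selected[pid] = chosen
        rows.append(row)
    return QCOutcome(report=pd.DataFrame(rows), selected=selected)


def integrate_selected(outcome: QCOutcome):
    """Integrate each retained pair; returns (ivfs, covariates frame)."""
    ivfs = [integrate_pair(pair) for pair in outcome.selected.values()]
    return ivfs


def covariates_frame(outcome: QCOutcome, meta: pd.DataFrame) -> pd.DataFrame:
    """Age/gender/binocular-foveal covariates for the retained patients."""
    rows = []
    for pid, pair in outcome.selected.items():
        key = (pid, "right", pair.test_date.isoformat())
        m = meta.loc[key]
        if isinstance(m, pd.DataFrame):
            m = m.iloc[0]
        ivf = integrate_pair(pair)
        rows.append(
            {
                "patient_id": pid,
                "test_date": pair.test_date.isoformat(),
                "age": float(m["age_years"]),
                "gender": float(m["gender"]),
                "foveal_binoc_db": ivf.foveal_binoc_db,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def association_predictors(weights: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Join archetype weight percents (dropping AT1, the normal/reference
    archetype) with the regression covariates."""
    at_cols = [c for c in weights.columns if c.startswith("AT") and c != "AT1"]
    X = weights[at_cols].join(covariates[["age", "gender", "foveal_binoc_db"]], how="inner")
    return X


def run_pipeline(
    vf_path,
    meta_path,
    qol_path,
    outdir,
    config: PipelineConfig,
) -> dict:
    """qc -> integrate -> (select-k | fixed K) -> fit -> decompose ->
    associate -> predict; every artifact lands in ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    artifacts: dict[str, str] = {}

    def stage(name):
        log.info("pipeline stage: %s", name)

    stage("qc")
    tests = io.load_tests(vf_path, meta_path, strict=config.strict)
    outcome = run_qc(
        tests,
        asym_threshold=config.asym_threshold_db,
        corr_threshold=config.corr_threshold,
        exclude_flagged=config.exclude_flagged,
    )
    qc_path = os.path.join(outdir, "qc_report.csv")
    outcome.report.to_csv(qc_path, index=False)
    artifacts["qc_report"] = qc_path
    if not outcome.selected:
        raise RuntimeError("qc: no patients retained")

    stage("integrate")
    ivfs = integrate_selected(outcome)
    ivf_path = os.path.join(outdir, "ivf.csv")
    io.write_ivf_csv(ivfs, ivf_path)
    artifacts["ivf"] = ivf_path
    meta = io.read_meta_csv(meta_path)
    cov = covariates_frame(outcome, meta)
    cov_path = os.path.join(outdir, "covariates.csv")
    cov.to_csv(cov_path)
    artifacts["covariates"] = cov_path

    ids, X, _ = io.read_ivf_csv(ivf_path)
    k = config.k
    if k is None:
        stage("select-k")
        if config.folds > X.shape[0]:
            raise ValueError(
                f"folds ({config.folds}) exceed retained patients ({X.shape[0]})"
            )
        cv = archetypal.crossvalidate_k(
            X,
            k_min=config.k_min,
            k_max=config.k_max,
            folds=config.folds,
            restarts=config.restarts,
            seed=config.seed,
            max_iter=config.max_iter,
            tol=config.tol,
            penalty=config.penalty,
        )
        cv_path = os.path.join(outdir, "cv.csv")
        io.write_cv_csv(cv, cv_path)
        artifacts["cv"] = cv_path
        k = archetypal.select_k(cv)
        log.info("selected K=%d", k)

    stage("fit")
    model = archetypal.fit_archetypes(
        X,
        k,
        restarts=config.restarts,
        max_iter=config.max_iter,
        tol=config.tol,
        penalty=config.penalty,
        seed=config.seed,
    )
    model_path = os.path.join(outdir, "model.json")
    model.save(model_path)
    artifacts["model"] = model_path

    stage("decompose")
    W, R = archetypal.decompose_matrix(model, X)
    weights_path = os.path.join(outdir, "weights.csv")
    io.write_weights_csv(ids, W * 100.0, R, weights_path)
    artifacts["weights"] = weights_path

    stage("associate")
    raw_qol = io.read_qol_csv(qol_path)
    item_map = qol.ItemMap.default()
    item_scores = qol.score_items(raw_qol, item_map)
    aspects = qol.aspect_scores(item_scores, item_map)
    weights_df = io.read_weights_csv(weights_path)
    predictors = association_predictors(weights_df, cov)
    if not config.foveal_adjust:
        predictors = predictors.drop(columns=["foveal_binoc_db"])
    assoc = qol.fit_association(
        aspects, predictors, alpha=config.alpha, n_tests=config.n_tests
    )
    assoc_path = os.path.join(outdir, "assoc.csv")
    assoc.table.to_csv(assoc_path, index=False)
    artifacts["assoc"] = assoc_path
    models_path = os.path.join(outdir, "assoc_models.json")
    with open(models_path, "w") as fh:
        fh.write(assoc.models_to_json())
    artifacts["assoc_models"] = models_path

    stage("predict")
    predicted = qol.predict_qol(assoc, predictors.loc[aspects.index.intersection(predictors.index)])
    pred_path = os.path.join(outdir, "predicted.csv")
    predicted.to_csv(pred_path)
    artifacts["predicted"] = pred_path

    manifest_path = os.path.join(outdir, "manifest.json")
    io.write_manifest(
        manifest_path,
        command="run",
        params=config.to_dict(),
        inputs={"vf": str(vf_path), "meta": str(meta_path), "qol": str(qol_path)},
        outputs=artifacts,
        seed=config.seed,
    )
    artifacts["manifest"] = manifest_path
    return artifacts
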