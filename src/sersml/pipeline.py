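"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

The held-out test partition is carved out immediately after preprocessing
and touched only in the final evaluation stage; everything the grid search
sees is the training partition. Every artifact (split plan, grid table,
winner, evaluation report) is written to the output directory together
with the seeds that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import classifiers, evaluate, preprocess, selection, synthetic
from .config import RunConfig, derive_seeds
from .io import SpectralDataset

__all__ = ["run_all", "PipelineError"]

log = logging.getLogger("sersml")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stage(name: str, seed: int, msg: str) -> None:
    log.info("stage=%s seed=%d %s", name, seed, msg)


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic-data pipeline; returns a result summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    (out_dir / "seeds.json").write_text(json.dumps({"master": config.seed, **seeds}, indent=1))

    # --- simulate -----------------------------------------------------------
    try:
        _stage("simulate", seeds["simulate"], "generating synthetic dataset")
        sim = replace(config.sim, seed=seeds["simulate"])
        dataset, truth = synthetic.generate_dataset(config.n_control, config.n_case, sim)
        ref_rng = np.random.default_rng(seeds["simulate"] + 1)
        ref_spectra = [
            synthetic.generate_substrate_spectrum(sim, ref_rng)
            for _ in range(config.n_reference_strips)
        ]
        synthetic.write_dataset(dataset, truth, out_dir / "data")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # --- preprocess ---------------------------------------------------------
    try:
        _stage("preprocess", seeds["simulate"], "substrate subtraction + ALS + L2")
        ref = preprocess.build_reference(ref_spectra)
        processed = preprocess.preprocess_pipeline(dataset, ref, config.preprocess)
        np.savetxt(
            out_dir / "processed_matrix.tsv",
            np.vstack([processed.axis, processed.matrix]),
            delimiter="\t",
        )
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    # --- split + train ------------------------------------------------------
    try:
        _stage("train", seeds["split"], "stratified split and grid search")
        plan = selection.stratified_split(
            processed.labels, processed.patient_ids,
            test_fraction=config.test_fraction, seed=seeds["split"],
        )
        with open(out_dir / "split_plan.json", "w") as fh:
            json.dump(
                {
                    "train_indices": plan.train_indices.tolist(),
                    "test_indices": plan.test_indices.tolist(),
                    "train_counts": plan.train_counts,
                    "test_counts": plan.test_counts,
                },
                fh, indent=1,
            )
        train_ds = processed.subset(plan.train_indices)
        grids = selection.build_grids(
            reductions=config.reductions,
            dims=config.dims,
            families=config.families,
            rf_n_trees=config.rf_n_trees,
        )
        result = selection.grid_search(
            train_ds, grids, config.scoring, seed=seeds["folds"]
        )
        result.table.to_csv(out_dir / "grid_table.csv", index=False, float_format="%.10g")
        winner = result.winner
        with open(out_dir / "winner.json", "w") as fh:
            json.dump(
                {
                    "reduction": winner.reduction,
                    "n_components": winner.n_components,
                    "spec": selection._spec_str(winner.spec),
                },
                fh, indent=1,
            )
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc

    # --- evaluate (only stage that touches the test partition) -------------
    try:
        _stage("evaluate", seeds["classifier"], "held-out evaluation of the winner")
        test_ds = processed.subset(plan.test_indices)
        red = selection._fit_reduction(winner, train_ds.matrix, train_ds.labels)
        if red is None:
            x_tr, x_te = train_ds.matrix, test_ds.matrix
        else:
            x_tr, x_te = red.transform(train_ds.matrix), red.transform(test_ds.matrix)
        model = classifiers.fit(winner.spec, x_tr, train_ds.labels, seed=seeds["classifier"])
        pred = classifiers.predict(model, x_te)
        confusion = evaluate.confusion_matrix(test_ds.labels, pred)
        report = evaluate.metric_panel(confusion)
        scores = classifiers.decision_scores(model, x_te)
        roc_points, auc, degenerate = evaluate.roc_curve(scores, test_ds.labels)
        report.roc_points = roc_points
        report.auc = auc
        payload = {
            "confusion": {"tp": confusion.tp, "fn": confusion.fn,
                          "tn": confusion.tn, "fp": confusion.fp},
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "precision": report.precision,
            "wba": report.wba,
            "auc": auc,
            "roc_degenerate": degenerate,
        }
        with open(out_dir / "evaluation.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        if winner.spec.family == "RF":
            imp = classifiers.feature_importance(model)
            ctrl_mean = train_ds.matrix[train_ds.labels == 0].mean(axis=0)
            case_mean = train_ds.matrix[train_ds.labels == 1].mean(axis=0)
            table, bands = evaluate.importance_report(
                imp, train_ds.axis, ctrl_mean, case_mean
            )
            table.to_csv(out_dir / "importance_report.csv", index=False,
                         float_format="%.10g")
            (out_dir / "top_bands.json").write_text(json.dumps(bands))
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc

    return {
        "split_plan": plan,
        "selection": result,
        "winner": winner,
        "report": report,
        "seeds": seeds,
    }
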