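"""End-to-end study replica: cohort -> SDI -> features -> both arms -> report.

``run_pipeline`` executes, for one endpoint (any fracture SDI>=1, or high
burden SDI>=5 with SDI 1-4 excluded):

1. simulate a cohort (or load a cohort CSV with an ``sdi`` column);
2. encode the 45-variable analysis matrix and drop incomplete records;
3. evolutionary input selection (the ANN arm's variable mask);
4. twin-MLP 5x2 cross-validation on the selected variables;
5. forward-stepwise logistic regression on all 45 variables, evaluated on
   the *same* 5x2 partitions;
6. paired comparison of the two arms' empirical ROC AUCs.

All artefacts (cohort, feature table, selection result, fold tables, ROC
coordinates, comparison, manifest with every seed) land in the run
directory as CSV/TSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, evaluation, features, logistic, mlp, synthetic, twist
from ._util import round_half_away, substream


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    endpoint: str = "sdi1"  # 'sdi1' | 'sdi5'
    cohort_csv: str | None = None  # if None, simulate
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    twist: twist.TwistConfig = field(default_factory=twist.TwistConfig)
    final_mlp: mlp.TrainConfig = field(default_factory=mlp.TrainConfig)
    outdir: str = "runs/run"
    seed: int = 0

    def validate(self) -> None:
        if self.endpoint not in ("sdi1", "sdi5"):
            raise ValueError("endpoint must be 'sdi1' or 'sdi5'")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise FileNotFoundError(self.cohort_csv)


def endpoint_labels(sdi: np.ndarray, endpoint: str) -> tuple[np.ndarray, np.ndarray]:
    """(kept-record mask, binary labels for kept records)."""
    sdi = np.asarray(sdi, dtype=int)
    if endpoint == "sdi1":
        keep = np.ones(sdi.size, dtype=bool)
        y = (sdi >= 1).astype(int)
    else:
        keep = (sdi == 0) | (sdi >= 5)
        y = (sdi[keep] >= 5).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise PipelineError(
            f"endpoint {endpoint}: case or control group is empty "
            f"(cases={int(y.sum())}, total={y.size})"
        )
    return keep, y


def mlp_trainer(train_config: mlp.TrainConfig):
    """Adapter: twin-MLP trainer for the 5x2 protocol (scales inputs on the
    training half, freezes the trained weights for testing)."""

    def trainer(X_train: pd.DataFrame, y_train: np.ndarray, seed: int):
        from dataclasses import replace

        cont = tuple(c for c in X_train.columns if c in features.CONTINUOUS_NAMES)
        scaled_train, scaler = features.scale_inputs(
            X_train, np.ones(len(X_train), dtype=bool), continuous=cont
        )
        model, _ = mlp.train(
            scaled_train.to_numpy(float), y_train, replace(train_config, seed=seed)
        )

        def score(X_test: pd.DataFrame) -> np.ndarray:
            return model.predict(scaler.transform(X_test).to_numpy(float))

        return score

    return trainer


def stepwise_lr_trainer(alpha_enter: float = 0.3, alpha_stay: float = 0.35):
    """Adapter: forward-stepwise logistic trainer for the 5x2 protocol."""

    def trainer(X_train: pd.DataFrame, y_train: np.ndarray, seed: int):
        fit, _ = logistic.forward_stepwise(
            X_train, y_train, alpha_enter=alpha_enter, alpha_stay=alpha_stay
        )
        terms = fit.terms[1:]

        def score(X_test: pd.DataFrame) -> np.ndarray:
            from scipy.special import expit

            A = np.column_stack(
                [np.ones(len(X_test))]
                + [X_test[t].to_numpy(float) for t in terms]
            )
            return expit(A @ fit.coef)

        return score

    return trainer


def compare_arms(
    ann: evaluation.CrossValReport, lr: evaluation.CrossValReport
) -> dict:
    """Paired AUC comparison of the two arms on identical partitions."""
    if ann.seed != lr.seed or not np.array_equal(ann.partitions, lr.partitions):
        raise PipelineError("arms were evaluated on different splits; refusing to compare")
    roc_ann = evaluation.roc_auc(ann.scores.mean(axis=0), ann.labels)
    roc_lr = evaluation.roc_auc(lr.scores.mean(axis=0), lr.labels)
    z, p = evaluation.compare_auc(roc_ann, roc_lr, paired=True)
    return {
        "auc_ann": ann.auc,
        "auc_lr": lr.auc,
        "auc_difference": ann.auc - lr.auc,
        "z": z,
        "p": p,
        "table4": side_by_side(ann, lr).to_dict(orient="records"),
    }


def side_by_side(ann: evaluation.CrossValReport, lr: evaluation.CrossValReport) -> pd.DataFrame:
    rows = []
    for arm, rep in (("ANNs", ann), ("LR", lr)):
        rows.append(
            {
                "arm": arm,
                "n_variables": rep.n_variables,
                "SN (%)": round_half_away(rep.avg_sensitivity, 1),
                "SP (%)": round_half_away(rep.avg_specificity, 1),
                "Accuracy (%)": round_half_away(rep.avg_accuracy, 1),
                "ROC AUC": round_half_away(rep.auc, 3),
                "AUC 95% CI": f"{rep.auc_ci[0]:.3f}-{rep.auc_ci[1]:.3f}",
            }
        )
    return pd.DataFrame(rows)


def _report_json(rep: evaluation.CrossValReport) -> dict:
    chi2, p = evaluation.fold_homogeneity_chi2(rep.folds)
    return {
        "folds": [f.as_dict() for f in rep.folds],
        "avg_sensitivity": rep.avg_sensitivity,
        "avg_specificity": rep.avg_specificity,
        "avg_accuracy": rep.avg_accuracy,
        "auc": rep.auc,
        "auc_ci": list(rep.auc_ci),
        "n_variables": rep.n_variables,
        "fold_homogeneity_chi2": chi2,
        "fold_homogeneity_p": p,
        "seed": rep.seed,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # 1. cohort
    if config.cohort_csv is None:
        from dataclasses import replace

        cohort_cfg = replace(config.cohort, seed=seed)
        cohort = synthetic.generate_cohort(cohort_cfg)
        raw = cohort.records
        sdi = cohort.sdi
        cohort.write(outdir, "cohort")
    else:
        raw = pd.read_csv(config.cohort_csv)
        if "sdi" not in raw.columns:
            raise PipelineError("cohort CSV must carry an 'sdi' column")
        sdi = raw["sdi"].to_numpy(int)
        raw = raw.drop(columns=["sdi"])

    # 2. features + complete cases
    table = features.encode_features(raw)
    table, exclusion_log = features.exclude_incomplete(table)
    sdi = sdi[table.index.to_numpy()]
    table = table.reset_index(drop=True)
    keep, y = endpoint_labels(sdi, config.endpoint)
    table = table.loc[keep].reset_index(drop=True)
    table.assign(label=y).to_csv(outdir / "features.csv", index=False)
    if len(exclusion_log):
        exclusion_log.to_csv(outdir / "excluded.csv", index=False)

    # 3. evolutionary input selection
    from dataclasses import replace

    tw_cfg = replace(config.twist, seed=seed)
    tw = twist.run_twist(table, y, tw_cfg)
    (outdir / "twist.json").write_text(json.dumps(tw.to_dict(), indent=2))

    # 4/5. both arms on shared partitions
    rng = substream(seed, "five_by_two")
    partitions = np.stack(
        [evaluation.stratified_half_split(y, rng) for _ in range(5)]
    )
    ann_report = evaluation.five_by_two_cv(
        table[tw.selected_variables], y,
        mlp_trainer(config.final_mlp), seed=seed, partitions=partitions,
    )
    lr_report = evaluation.five_by_two_cv(
        table, y, stepwise_lr_trainer(), seed=seed, partitions=partitions
    )

    # 6. outputs
    comparison = compare_arms(ann_report, lr_report)
    group = (y == 1)
    table2 = evaluation.group_compare(table, group)
    table2.to_csv(outdir / "table2_group_compare.tsv", sep="\t", index=False)
    ann_report.fold_table().to_csv(outdir / "table5_ann_folds.tsv", sep="\t", index=False)
    lr_report.fold_table().to_csv(outdir / "table5_lr_folds.tsv", sep="\t", index=False)
    side_by_side(ann_report, lr_report).to_csv(outdir / "table4_summary.tsv", sep="\t", index=False)
    evaluation.roc_auc(ann_report.scores.mean(axis=0), y).to_frame().to_csv(
        outdir / "roc_ann.csv", index=False
    )
    evaluation.roc_auc(lr_report.scores.mean(axis=0), y).to_frame().to_csv(
        outdir / "roc_lr.csv", index=False
    )
    (outdir / "ann_report.json").write_text(json.dumps(_report_json(ann_report), indent=2))
    (outdir / "lr_report.json").write_text(json.dumps(_report_json(lr_report), indent=2))
    (outdir / "comparison.json").write_text(json.dumps(comparison, indent=2))
    manifest = {
        "version": __version__,
        "seed": seed,
        "endpoint": config.endpoint,
        "n_records": int(len(table)),
        "n_cases": int(y.sum()),
        "n_controls": int((1 - y).sum()),
        "selected_variables": tw.selected_variables,
        "twist_config": _jsonable(asdict(tw_cfg)),
        "final_mlp_config": _jsonable(asdict(config.final_mlp)),
        "cohort_source": config.cohort_csv or "simulated",
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
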