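"""End-to-end experiment orchestration.

One config drives: synthetic cohort generation -> patient-level train/test
split -> 3-fold cross-validation on the training half -> retraining on the
full training half -> held-out evaluation -> reports.  Every stage's outputs
are written under the run directory together with a manifest carrying the
config hash and all seeds, so a finished run is reproducible and a partial
run refuses to resume under a drifted config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate_eval as ae
from . import charm_baseline as charm
from . import cnn as cnn_mod
from .errors import ConfigDriftError, InvalidArgumentError, InvalidStateError
from .patching import augment_rotations, sample_patches
from .synthetic_data import CohortSpec, SyntheticCohort, generate_cohort, is_failing_label

__all__ = ["ExperimentConfig", "run_experiment", "relabel_and_rescore"]


@dataclass
class ExperimentConfig:
    mode: str = "synthetic"
    cohort: dict = field(default_factory=lambda: {"n_patients": 16, "rng_seed": 0})
    label_schema: str = "v1"
    arms: tuple[str, ...] = ("cnn", "charm_rf")
    patches_per_roi: int = 100
    augment: bool = True
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 0.01
    n_folds: int = 3
    split_seed: int = 0
    fold_seed: int = 0
    train_seed: int = 0
    mrmr_k: int = 20
    n_trees: int = 1000
    image_threshold: float = 0.5
    out_dir: str = "runs/experiment"

    def __post_init__(self):
        if self.mode != "synthetic":
            raise InvalidArgumentError("only synthetic mode is implemented in this build")
        unknown = set(self.arms) - {"cnn", "charm_rf"}
        if unknown:
            raise InvalidArgumentError(f"unknown arms: {sorted(unknown)}")
        if self.label_schema not in ("v1", "v2"):
            raise InvalidArgumentError("label_schema must be 'v1' or 'v2'")

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "arms" in raw:
            raw["arms"] = tuple(raw["arms"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# arm primitives (shared by run_experiment, tests and the acceptance script)


def cohort_patchset(
    cohort: SyntheticCohort,
    patient_ids: list[str],
    patches_per_roi: int,
    augment: bool,
    rng_seed: int,
    schema: str = "v1",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (and optionally rotation-augment) training patches for a set
    of patients; ROIs are rendered one at a time and discarded.  Returns
    stacked uint8 pixels and binary labels (failing = 1)."""
    by_id = {p.patient_id: p for p in cohort.patients}
    ss = np.random.SeedSequence([rng_seed & 0x7FFFFFFF, 17])
    seeds = ss.spawn(len(patient_ids) * cohort.spec.rois_per_patient)
    xs, ys = [], []
    i = 0
    for pid in patient_ids:
        patient = by_id[pid]
        label = 1 if is_failing_label(patient.label(schema)) else 0
        for roi in cohort.iter_rois(patient):
            pset = sample_patches(
                roi, label=str(label), n=patches_per_roi,
                rng_seed=int(seeds[i].generate_state(1)[0] & 0x7FFFFFFF),
            )
            if augment:
                pset = augment_rotations(pset)
            for p in pset:
                xs.append(p.pixels)
                ys.append(label)
            i += 1
    if not xs:
        return np.zeros((0, 64, 64, 3), np.uint8), np.zeros((0,), int)
    return np.stack(xs), np.array(ys, dtype=int)


def cnn_image_probabilities(model, cohort: SyntheticCohort, patient_ids: list[str]) -> pd.DataFrame:
    """Dense probability map per ROI, averaged to the image probability."""
    by_id = {p.patient_id: p for p in cohort.patients}
    rows = []
    for pid in patient_ids:
        for roi in cohort.iter_rois(by_id[pid]):
            pmap = cnn_mod.predict_probability_map(model, roi)
            rows.append(
                {"patient_id": pid, "roi_id": roi.roi_id, "model": "cnn",
                 "probability": cnn_mod.image_probability(pmap)}
            )
    return pd.DataFrame(rows)


def charm_feature_table(cohort: SyntheticCohort, patient_ids: list[str]) -> pd.DataFrame:
    by_id = {p.patient_id: p for p in cohort.patients}
    rois = (roi for pid in patient_ids for roi in cohort.iter_rois(by_id[pid]))
    return charm.extract_feature_table(rois)


def charm_arm(
    train_features: pd.DataFrame,
    train_labels: np.ndarray,
    eval_features: pd.DataFrame,
    mrmr_k: int = 20,
    n_trees: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Standardize -> mRMR -> random forest -> image probabilities."""
    cols = [c for c in train_features.columns if c != "patient_id"]
    scaler = charm.FeatureScaler().fit(train_features[cols].to_numpy())
    Xtr = scaler.transform(train_features[cols].to_numpy())
    Xev = scaler.transform(eval_features[cols].to_numpy())
    sel = charm.mrmr_select(Xtr, train_labels, k=min(mrmr_k, Xtr.shape[1]))
    rf = charm.train_rf(Xtr[:, sel.indices], train_labels, n_trees=n_trees, rng_seed=rng_seed)
    probs = charm.rf_predict(rf, Xev[:, sel.indices])
    return pd.DataFrame(
        {"patient_id": eval_features["patient_id"].to_numpy(),
         "roi_id": eval_features.index, "model": "charm_rf", "probability": probs}
    )


def score_predictions(
    preds: pd.DataFrame, labels: dict[str, str], threshold: float = 0.5,
    fold_id: int | None = None,
) -> dict:
    """Image- and patient-level metric reports for one prediction table."""
    truths_img = np.array([is_failing_label(labels[p]) for p in preds["patient_id"]])
    calls_img = np.array([ae.image_prediction(v, threshold) for v in preds["probability"]])
    image_report = ae.confusion_metrics(calls_img, truths_img, level="image", fold_id=fold_id)
    try:
        *_, auc_img = ae.roc_auc(preds["probability"].to_numpy(), truths_img)
        image_report.auc = auc_img
    except Exception:
        pass
    records = ae.build_patient_records(preds, labels, threshold)
    truths_pat = np.array([is_failing_label(r.label) for r in records])
    calls_pat = np.array([r.diagnosis for r in records])
    patient_report = ae.confusion_metrics(calls_pat, truths_pat, level="patient", fold_id=fold_id)
    try:
        *_, auc_pat = ae.roc_auc(np.array([r.patient_prob for r in records]), truths_pat)
        patient_report.auc = auc_pat
    except Exception:
        pass
    return {"image": image_report.as_dict(), "patient": patient_report.as_dict(),
            "records": records}


def _train_cnn_arm(cohort, train_ids, config: ExperimentConfig, val_ids=None):
    x, y = cohort_patchset(cohort, train_ids, config.patches_per_roi, config.augment,
                           config.train_seed, config.label_schema)
    val = None
    if val_ids:
        val = cohort_patchset(cohort, val_ids, max(1, config.patches_per_roi // 4), False,
                              config.train_seed + 1, config.label_schema)
    model = cnn_mod.build_model(rng_seed=config.train_seed)
    tc = cnn_mod.TrainingConfig(
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate, rng_seed=config.train_seed,
    )
    model, log = cnn_mod.train(model, (x, y), val, tc)
    return model, log


# ---------------------------------------------------------------------------


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the full experiment; returns the run directory.

    Stages: cohort -> split -> per-fold {train on 2 folds, validate on 1}
    -> retrain on the full training half -> held-out test evaluation ->
    predictions/metrics written as CSV/JSON.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "run_manifest.json"
    chash = config.config_hash()
    if manifest_path.exists():
        prior = json.loads(manifest_path.read_text())
        if prior.get("config_hash") != chash:
            raise ConfigDriftError(
                f"run directory {out} holds a run with config hash "
                f"{prior.get('config_hash')}, requested {chash}"
            )
    manifest = {"config_hash": chash, "config": asdict(config), "stages": []}

    spec = CohortSpec(**config.cohort)
    cohort = generate_cohort(spec)
    table = cohort.patient_table()
    table.to_csv(out / "cohort_manifest.csv", index=False)
    labels = {
        p.patient_id: p.label(config.label_schema) for p in cohort.patients
    }
    manifest["stages"].append({"stage": "cohort", "n_patients": len(cohort)})

    train_ids, test_ids = ae.train_test_split_patients(table, rng_seed=config.split_seed,
                                                       schema=config.label_schema)
    json.dump({"train": train_ids, "test": test_ids}, open(out / "split.json", "w"), indent=1)
    manifest["stages"].append({"stage": "split", "n_train": len(train_ids), "n_test": len(test_ids)})

    metrics: dict = {arm: {"folds": [], "test": None} for arm in config.arms}
    all_preds: dict = {arm: [] for arm in config.arms}

    folds = None
    if config.n_folds and config.n_folds >= 2:
        train_table = table[table["patient_id"].isin(train_ids)]
        folds = ae.crossval_split(train_table, n_folds=config.n_folds,
                                  rng_seed=config.fold_seed, schema=config.label_schema)
        # leakage guard: the split and fold assignments must partition patients
        assert not (set(train_ids) & set(test_ids))
        assert sorted(folds.folds) == sorted(train_ids)

    feat_cache: dict[str, pd.DataFrame] = {}

    def features_for(ids: list[str]) -> pd.DataFrame:
        missing = [i for i in ids if i not in feat_cache]
        if missing:
            df = charm_feature_table(cohort, missing)
            for pid, grp in df.groupby("patient_id", sort=False):
                feat_cache[str(pid)] = grp
        return pd.concat([feat_cache[i] for i in ids])

    def run_arm(arm: str, fit_ids: list[str], eval_ids: list[str], fold_id, tag: str) -> pd.DataFrame:
        if arm == "cnn":
            model, _log = _train_cnn_arm(cohort, fit_ids, config)
            preds = cnn_image_probabilities(model, cohort, eval_ids)
        else:
            ftr = features_for(fit_ids)
            fev = features_for(eval_ids)
            ytr = np.array([1 if is_failing_label(labels[p]) else 0 for p in ftr["patient_id"]])
            preds = charm_arm(ftr, ytr, fev, config.mrmr_k, config.n_trees, config.train_seed)
        preds = preds.assign(split=tag)
        scored = score_predictions(preds, labels, config.image_threshold, fold_id)
        entry = {"image": scored["image"], "patient": scored["patient"]}
        if fold_id is None:
            metrics[arm]["test"] = entry
        else:
            metrics[arm]["folds"].append(entry)
        all_preds[arm].append(preds)
        return preds

    for arm in config.arms:
        if folds is not None:
            for f in range(folds.n_folds):
                val_ids = sorted(folds.patients_in(f))
                fit_ids = sorted(set(train_ids) - set(val_ids))
                run_arm(arm, fit_ids, val_ids, fold_id=f, tag=f"fold{f}")
        run_arm(arm, sorted(train_ids), sorted(test_ids), fold_id=None, tag="test")
        pd.concat(all_preds[arm]).to_csv(out / f"predictions_{arm}.csv", index=False)
        manifest["stages"].append({"stage": f"arm:{arm}", "n_predictions": sum(map(len, all_preds[arm]))})

    for arm in config.arms:
        fold_reports = metrics[arm]["folds"]
        if fold_reports:
            metrics[arm]["cv_summary"] = {
                level: _mean_sd([fr[level] for fr in fold_reports])
                for level in ("image", "patient")
            }
    json.dump(metrics, open(out / "metrics.json", "w"), indent=1, default=float)
    manifest["stages"].append({"stage": "metrics"})
    json.dump(manifest, open(manifest_path, "w"), indent=1)
    return out


def _mean_sd(reports: list[dict]) -> dict:
    out = {}
    for key in ("accuracy", "sensitivity", "specificity", "ppv", "auc"):
        vals = np.array([r[key] for r in reports], dtype=float)
        out[key] = {"mean": float(np.nanmean(vals)),
                    "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0}
    return out


def relabel_and_rescore(run_dir, schema: str) -> dict:
    """Recompute all metrics of a finished run under another label schema
    without retraining."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "run_manifest.json"
    cohort_path = run_dir / "cohort_manifest.csv"
    if not manifest_path.exists() or not cohort_path.exists():
        raise InvalidStateError(f"{run_dir} does not hold a completed run")
    table = pd.read_csv(cohort_path)
    col = f"label_{schema}"
    if col not in table.columns:
        raise InvalidArgumentError(f"cohort manifest lacks column {col}")
    labels = dict(zip(table["patient_id"].astype(str), table[col].astype(str)))
    manifest = json.loads(manifest_path.read_text())
    arms = manifest["config"]["arms"]
    threshold = manifest["config"]["image_threshold"]
    out: dict = {}
    for arm in arms:
        pred_path = run_dir / f"predictions_{arm}.csv"
        if not pred_path.exists():
            raise InvalidStateError(f"missing predictions for arm {arm}")
        preds = pd.read_csv(pred_path)
        preds["patient_id"] = preds["patient_id"].astype(str)
        test = preds[preds["split"] == "test"]
        scored = score_predictions(test, labels, threshold)
        out[arm] = {"image": scored["image"], "patient": scored["patient"]}
    json.dump(out, open(run_dir / f"metrics_{schema}.json", "w"), indent=1, default=float)
    return out
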