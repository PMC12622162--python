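"""Gradient-boosted classification in three feature regimes.

Three regimes trade circularity risk against raw power: CTI keeps every
feature including clinical-trained predictor scores, CTE drops the
clinical-trained predictors, and SP drops all predictor scores, leaving only
primary biological signal. Hyperparameters are tuned by a seeded random
search scored on a stratified holdout, and each trained model refuses to score
its own training variants so downstream benchmarks stay circularity-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import lightgbm as lgb
import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .core_io import FeatureMatrix, FeatureMeta
from .dataset import LabeledDataset

REGIMES = ("CTI", "CTE", "SP")

#: Reference feature-catalog dimensions of the full-scale framework: category
#: counts of the compiled catalog and the per-regime dimensions after dropping
#: ACMG-overlapping columns (allele frequency, splicing, domain annotations).
REFERENCE_CATALOG_COUNTS = {
    "vep_score": 45,
    "conservation": 13,
    "structural": 17,
    "residue_constraint": 7,
    "substitution_matrix": 20,
    "plm": 4,
    "gene_level": 465,
}
REFERENCE_REGIME_DIMENSIONS = {"CTI": 558, "CTE": 527, "SP": 513}


@dataclass(frozen=True)
class FeatureConfig:
    """A regime plus the resolved feature-name list."""

    regime: str
    feature_names: tuple

    def __len__(self):
        return len(self.feature_names)


def resolve_feature_config(catalog, regime: str) -> FeatureConfig:
    """Resolve the feature list for a regime.

    CTI keeps everything; CTE removes clinical-trained predictor scores; SP
    removes all predictor scores. By construction SP <= CTE <= CTI as sets.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    names = []
    for f in catalog:
        if regime == "SP" and f.category == "vep_score":
            continue
        if regime == "CTE" and f.category == "vep_score" and f.clinical_trained:
            continue
        names.append(f.name)
    if not names:
        raise ValueError(f"regime {regime} leaves an empty feature set")
    return FeatureConfig(regime=regime, feature_names=tuple(names))


@dataclass
class TrainedModel:
    """A fitted booster with everything needed to reproduce and audit it."""

    booster: lgb.LGBMClassifier
    features: list[FeatureMeta]
    decision_threshold: float
    holdout_auc: float
    holdout_accuracy: float
    manifest: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def excluded_keys(self) -> frozenset:
        return frozenset(self.manifest.get("excluded_training_keys", []))


_BASE_PARAMS = dict(
    objective="binary",
    n_estimators=200,
    deterministic=True,
    force_row_wise=True,
    n_jobs=1,
    verbose=-1,
)

# Random-search space: tree complexity, shrinkage, and regularization knobs.
_SEARCH_SPACE = dict(
    num_leaves=(7, 63),
    max_depth=(3, 8),
    learning_rate=(0.01, 0.3),  # log-uniform
    min_child_samples=(5, 50),
    reg_alpha=(1e-8, 1.0),  # log-uniform
    reg_lambda=(1e-8, 1.0),  # log-uniform
    colsample_bytree=(0.6, 1.0),
    subsample=(0.6, 1.0),
)


def _sample_params(rng: np.random.Generator) -> dict:
    s = _SEARCH_SPACE
    return dict(
        num_leaves=int(rng.integers(s["num_leaves"][0], s["num_leaves"][1] + 1)),
        max_depth=int(rng.integers(s["max_depth"][0], s["max_depth"][1] + 1)),
        learning_rate=float(np.exp(rng.uniform(*np.log(s["learning_rate"])))),
        min_child_samples=int(
            rng.integers(s["min_child_samples"][0], s["min_child_samples"][1] + 1)
        ),
        reg_alpha=float(np.exp(rng.uniform(*np.log(s["reg_alpha"])))),
        reg_lambda=float(np.exp(rng.uniform(*np.log(s["reg_lambda"])))),
        colsample_bytree=float(rng.uniform(*s["colsample_bytree"])),
        subsample=float(rng.uniform(*s["subsample"])),
        subsample_freq=1,
    )


def _design(matrix: FeatureMatrix, feature_names):
    cols = {n: j for j, n in enumerate(matrix.feature_names)}
    missing = [n for n in feature_names if n not in cols]
    if missing:
        raise KeyError(f"matrix lacks feature columns: {missing}")
    idx = [cols[n] for n in feature_names]
    import pandas as pd

    return pd.DataFrame(matrix.values[:, idx], columns=list(feature_names))


def train_classifier(
    dataset: LabeledDataset,
    matrix: FeatureMatrix,
    config: FeatureConfig,
    split: float = 0.9,
    trials: int = 50,
    seed: int = 0,
) -> TrainedModel:
    """Train a binary classifier with seeded random hyperparameter search.

    The labeled records are matched to matrix rows by variant key, split
    stratified-by-label into ``split`` train / (1-split) holdout, and the
    configuration with the best holdout AUC over ``trials`` random draws wins
    (first winner on ties). The final model is refit on the training split
    with the best configuration; sample weights apply throughout. The manifest
    records the training-split variant keys, which `predict` refuses to score.
    """
    if len(dataset) < 20:
        raise ValueError(f"need >= 20 records to train, got {len(dataset)}")
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")

    row_of = {k: i for i, k in enumerate(matrix.variant_keys)}
    missing = [k for k in dataset.keys if k not in row_of]
    if missing:
        raise KeyError(f"dataset variants absent from the matrix: {missing[:5]}")
    rows = np.array([row_of[k] for k in dataset.keys])
    x = _design(matrix, config.feature_names).iloc[rows].reset_index(drop=True)
    y = labels
    w = dataset.weights
    keys = np.array(dataset.keys)

    idx_train, idx_hold = train_test_split(
        np.arange(len(y)),
        train_size=split,
        stratify=y,
        random_state=seed,
        shuffle=True,
    )

    rng = np.random.default_rng(seed)
    best_auc, best_params = -np.inf, None
    for _ in range(trials):
        params = _sample_params(rng)
        clf = lgb.LGBMClassifier(random_state=seed, **_BASE_PARAMS, **params)
        clf.fit(x.iloc[idx_train], y[idx_train], sample_weight=w[idx_train])
        probs = clf.predict_proba(x.iloc[idx_hold])[:, 1]
        auc = roc_auc_score(y[idx_hold], probs)
        if auc > best_auc:
            best_auc, best_params = auc, params

    clf = lgb.LGBMClassifier(random_state=seed, **_BASE_PARAMS, **best_params)
    clf.fit(x.iloc[idx_train], y[idx_train], sample_weight=w[idx_train])
    hold_scores = clf.predict_proba(x.iloc[idx_hold])[:, 1]
    holdout_auc = float(roc_auc_score(y[idx_hold], hold_scores))
    threshold = optimize_threshold(hold_scores, y[idx_hold])
    accuracy = float(np.mean((hold_scores >= threshold).astype(int) == y[idx_hold]))

    meta_of = {f.name: f for f in matrix.features}
    features = [meta_of[n] for n in config.feature_names]
    manifest = {
        "regime": config.regime,
        "seed": int(seed),
        "trials": int(trials),
        "split": float(split),
        "best_params": best_params,
        "feature_names": list(config.feature_names),
        "decision_threshold": float(threshold),
        "holdout_auc": holdout_auc,
        "holdout_accuracy": accuracy,
        "excluded_training_keys": sorted(keys[idx_train].tolist()),
    }
    return TrainedModel(
        booster=clf,
        features=features,
        decision_threshold=float(threshold),
        holdout_auc=holdout_auc,
        holdout_accuracy=accuracy,
        manifest=manifest,
    )


def optimize_threshold(scores, labels) -> float:
    """Balanced-accuracy-optimal cut by exhaustive sweep over score midpoints.

    Candidates are midpoints of adjacent sorted unique scores; on ties the
    smallest qualifying cut is returned. Depends on ranks only, so any
    monotone rescaling of scores yields the same partition of variants.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to optimize a threshold")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best_ba, best_cut = -1.0, cuts[0]
    for c in cuts:
        pred = scores >= c
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        ba = 0.5 * (tp / n_pos + tn / n_neg)
        if ba > best_ba + 1e-12:
            best_ba, best_cut = ba, c
    return float(best_cut)


EXCLUDED_TRAINING = "EXCLUDED_TRAINING"


@dataclass
class PredictionResult:
    """Scores with per-variant exclusion flags.

    ``scores`` is NaN and ``flags`` is ``EXCLUDED_TRAINING`` for variants that
    appear in the model's training manifest — the model never emits a number
    for its own training data.
    """

    keys: list[str]
    scores: np.ndarray
    flags: list[str | None]


def predict(model: TrainedModel, matrix: FeatureMatrix) -> PredictionResult:
    """Score matrix variants, flagging the model's own training variants."""
    x = _design(matrix, model.feature_names)
    raw = model.booster.predict_proba(x)[:, 1]
    excluded = model.excluded_keys
    keys = matrix.variant_keys
    scores = np.asarray(raw, dtype=float)
    flags: list[str | None] = [None] * len(keys)
    for i, k in enumerate(keys):
        if k in excluded:
            scores[i] = np.nan
            flags[i] = EXCLUDED_TRAINING
    return PredictionResult(keys=keys, scores=scores, flags=flags)


def feature_attribution(model: TrainedModel, matrix: FeatureMatrix):
    """Mean absolute per-feature contribution (TreeSHAP), ranked.

    Returns ``(ranked, category_totals)``: a list of (feature_name, mean |phi|)
    sorted descending (ties broken by name for determinism), and per-category
    totals that partition the individual attributions.
    """
    x = _design(matrix, model.feature_names)
    contrib = model.booster.predict_proba(x, pred_contrib=True)
    # last column is the expected-value offset
    phi = np.abs(contrib[:, : len(model.feature_names)]).mean(axis=0)
    ranked = sorted(
        zip(model.feature_names, phi.tolist()), key=lambda t: (-t[1], t[0])
    )
    totals: dict[str, float] = {}
    for f, v in zip(model.features, phi.tolist()):
        totals[f.category] = totals.get(f.category, 0.0) + v
    return ranked, totals


def save_model(model: TrainedModel, directory) -> None:
    """Persist as a directory: LightGBM text booster + manifest.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    model.booster.booster_.save_model(str(d / "booster.txt"))
    manifest = dict(model.manifest)
    manifest["features"] = [
        {
            "name": f.name,
            "category": f.category,
            "clinical_trained": f.clinical_trained,
            "tool_id": f.tool_id,
        }
        for f in model.features
    ]
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_model(directory) -> TrainedModel:
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    booster = lgb.Booster(model_file=str(d / "booster.txt"))
    clf = _BoosterAdapter(booster)
    features = [
        FeatureMeta(
            name=f["name"],
            category=f["category"],
            clinical_trained=f["clinical_trained"],
            tool_id=f["tool_id"],
        )
        for f in manifest.pop("features")
    ]
    return TrainedModel(
        booster=clf,
        features=features,
        decision_threshold=manifest["decision_threshold"],
        holdout_auc=manifest["holdout_auc"],
        holdout_accuracy=manifest["holdout_accuracy"],
        manifest=manifest,
    )


class _BoosterAdapter:
    """Expose a raw Booster through the predict_proba surface predict() uses."""

    def __init__(self, booster: lgb.Booster):
        self.booster_ = booster

    def predict_proba(self, x, pred_contrib: bool = False):
        if pred_contrib:
            return self.booster_.predict(x, pred_contrib=True)
        p = self.booster_.predict(x)
        return np.column_stack([1 - p, p])
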