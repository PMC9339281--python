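"""Easy-ensemble of balanced random forests for RLBP prediction.

The positive class (a few hundred consensus RLBPs) is dwarfed by the rest
of the proteome.  Rather than weighting, class imbalance is handled by the
easy-ensemble strategy: train many random forests, each on *all* positives
plus a fresh, equally sized-ish random sample of negatives (1:1-ish class
ratio), then average the per-protein positive-class probabilities across
the whole ensemble.  Each member forest is tuned by cross-validated
ROC-AUC over a small grid of ``mtry`` (features considered per split) and
evaluated on its own stratified held-out split.

Thresholds on the averaged probability: mean >= 0.5 calls a candidate
RLBP; mean > 0.8 (strict) calls a high-confidence RLBP.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .features import FEATURE_COLUMNS

log = logging.getLogger(__name__)

CANDIDATE_THRESHOLD = 0.5       # mean probability >= 0.5
HIGH_CONFIDENCE_THRESHOLD = 0.8  # mean probability > 0.8, strictly
# Means within float summation error of a threshold count as equal to it,
# so a protein averaging exactly 0.8 is a candidate but not high-confidence.
THRESHOLD_EPS = 1e-9


@dataclass
class EnsembleConfig:
    """Ensemble hyperparameters.

    ``n_negatives_per_model`` controls the balanced resample size: the
    IP-MS preset draws 300 negatives per model (positive class ~292) and
    the Prox-MS preset 100 (positive class ~101).
    """

    n_models: int = 100
    n_negatives_per_model: int = 300
    train_fraction: float = 0.8
    cv_folds: int = 10
    mtry_grid: tuple[int, ...] = (2, 5, 10, 15)
    n_trees: int = 500
    base_seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if any(not 1 <= m <= 30 for m in self.mtry_grid):
            raise ValueError("mtry_grid values must lie in [1, 30]")
        if self.n_models < 1 or self.n_trees < 1:
            raise ValueError("n_models and n_trees must be positive")

    @classmethod
    def preset(cls, name: str, **overrides) -> "EnsembleConfig":
        presets = {"ipms": 300, "proxms": 100}
        if name not in presets:
            raise ValueError(f"unknown preset {name!r} (expected ipms/proxms)")
        return cls(n_negatives_per_model=presets[name], **overrides)


@dataclass
class ModelRecord:
    """One fitted ensemble member plus its tuning and evaluation record."""

    index: int
    seed: int
    forest: RandomForestClassifier
    negative_ids: list[str]
    mtry: int
    cv_roc_auc: float
    metrics: dict[str, float]  # accuracy, f1, mcc, roc_auc on held-out 20%


@dataclass
class EnsembleModel:
    config: EnsembleConfig
    models: list[ModelRecord]
    feature_columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))

    def metrics_frame(self) -> pd.DataFrame:
        rows = [{"model": m.index, "seed": m.seed, "mtry": m.mtry,
                 "cv_roc_auc": m.cv_roc_auc, **m.metrics} for m in self.models]
        return pd.DataFrame(rows).set_index("model")

    def summary(self) -> pd.DataFrame:
        """Held-out metric mean and SD across the ensemble members."""
        frame = self.metrics_frame()[["accuracy", "f1", "mcc", "roc_auc"]]
        return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, outdir / "ensemble.joblib")
        self.metrics_frame().to_csv(outdir / "model_metrics.tsv", sep="\t")
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, default=list)

    @classmethod
    def load(cls, outdir: str | Path) -> "EnsembleModel":
        return joblib.load(Path(outdir) / "ensemble.joblib")


@dataclass
class PredictionResult:
    """Per-protein ensemble probabilities, their mean, and threshold calls."""

    probabilities: pd.DataFrame  # proteins x models
    mean_probability: pd.Series
    candidate: pd.Series
    high_confidence: pd.Series

    @property
    def candidate_ids(self) -> set[str]:
        return set(self.candidate.index[self.candidate])

    @property
    def high_confidence_ids(self) -> set[str]:
        return set(self.high_confidence.index[self.high_confidence])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_prob": self.mean_probability,
            "candidate": self.candidate.astype(int),
            "high_confidence": self.high_confidence.astype(int),
        })

    def to_tsv(self, path: str | Path) -> None:
        self.frame().to_csv(path, sep="\t", index_label="id",
                            float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PredictionResult":
        frame = pd.read_csv(path, sep="\t", index_col="id")
        required = {"mean_prob", "candidate", "high_confidence"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(pd.DataFrame(index=frame.index), frame["mean_prob"],
                   frame["candidate"].astype(bool),
                   frame["high_confidence"].astype(bool))


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, F1 and Matthews correlation from confusion counts.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)), defined as
    0 when any margin is zero.  F1 is 0 when the positive margin vanishes.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative confusion counts: {counts}")
    total = sum(counts)
    if total == 0:
        raise ValueError("all confusion counts are zero")
    accuracy = (tp + tn) / total
    denom_f1 = 2 * tp + fp + fn
    f1 = 2 * tp / denom_f1 if denom_f1 > 0 else 0.0
    margins = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(margins) if margins > 0 else 0.0
    return {"accuracy": accuracy, "f1": f1, "mcc": mcc}


def sample_balanced(positives: pd.DataFrame, negative_pool: pd.DataFrame,
                    n_neg: int, seed: int) -> pd.DataFrame:
    """All positives plus ``n_neg`` negatives sampled without replacement."""
    if len(negative_pool) < n_neg:
        raise ValueError(
            f"negative pool ({len(negative_pool)}) smaller than n_neg ({n_neg})")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(negative_pool), size=n_neg, replace=False)
    sample = negative_pool.iloc[np.sort(chosen)]
    return pd.concat([positives, sample])


def train_one(table: pd.DataFrame, config: EnsembleConfig, seed: int,
              feature_columns: Sequence[str] | None = None) -> tuple[
                  RandomForestClassifier, int, float, dict[str, float]]:
    """Fit and tune one forest on a balanced table.

    Stratified 80/20 split; ``mtry`` chosen by mean 10-fold CV ROC-AUC on
    the training portion; the winning forest is refit on the full training
    portion and scored (accuracy, F1, MCC, ROC-AUC) on the held-out 20%.
    """
    cols = list(feature_columns or FEATURE_COLUMNS)
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training table must contain both classes")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, train_size=config.train_fraction, stratify=y, random_state=seed)
    min_class = int(np.bincount(y_train).min())
    if min_class < config.cv_folds:
        raise ValueError(
            f"smallest training class has {min_class} members, fewer than "
            f"cv_folds={config.cv_folds}; provide a larger input table")
    grid = sorted({min(m, len(cols)) for m in config.mtry_grid})
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        RandomForestClassifier(n_estimators=config.n_trees, random_state=seed),
        {"max_features": grid}, scoring="roc_auc", cv=cv, refit=True)
    search.fit(X_train, y_train)
    forest = search.best_estimator_
    mtry = int(search.best_params_["max_features"])
    cv_auc = float(search.best_score_)
    prob = forest.predict_proba(X_test)[:, list(forest.classes_).index(1)]
    pred = (prob >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    metrics = classification_metrics(tp, fp, tn, fn)
    metrics["roc_auc"] = float(roc_auc_score(y_test, prob))
    return forest, mtry, cv_auc, metrics


def train_ensemble(features: pd.DataFrame, positives: Iterable[str],
                   config: EnsembleConfig) -> EnsembleModel:
    """Train the full easy-ensemble.

    ``features`` is the labeled complete-case table (30 feature columns +
    ``label``); ``positives`` the consensus set ids.  Model *i* uses seed
    ``base_seed + i`` for both the negative sample and the forest.
    """
    pos_ids = {str(p).strip().upper() for p in positives}
    missing = pos_ids - set(features.index)
    pos_rows = features.loc[features.index.isin(pos_ids)]
    neg_rows = features.loc[~features.index.isin(pos_ids)]
    if pos_rows.empty:
        raise ValueError("no positive-class rows in the feature table")
    if missing:
        log.info("train_ensemble: %d positives absent from feature table "
                 "(dropped by complete-case filtering)", len(missing))
    pos_rows = pos_rows.assign(label=1)
    neg_rows = neg_rows.assign(label=0)
    models = []
    for i in range(config.n_models):
        seed = config.base_seed + i
        table = sample_balanced(pos_rows, neg_rows,
                                config.n_negatives_per_model, seed)
        forest, mtry, cv_auc, metrics = train_one(table, config, seed)
        models.append(ModelRecord(
            index=i, seed=seed, forest=forest,
            negative_ids=list(table.index[table["label"] == 0]),
            mtry=mtry, cv_roc_auc=cv_auc, metrics=metrics))
        log.info("model %d (seed %d): mtry=%d cv_auc=%.3f heldout=%s",
                 i, seed, mtry, cv_auc,
                 {k: round(v, 3) for k, v in metrics.items()})
    return EnsembleModel(config=config, models=models)


def predict_proteome(ensemble: EnsembleModel,
                     features: pd.DataFrame) -> PredictionResult:
    """Average positive-class probabilities across the ensemble and call
    candidate (mean >= 0.5) and high-confidence (mean > 0.8) RLBPs."""
    missing = [c for c in ensemble.feature_columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    X = features[ensemble.feature_columns].to_numpy(dtype=float)
    probs = np.column_stack([
        m.forest.predict_proba(X)[:, list(m.forest.classes_).index(1)]
        for m in ensemble.models])
    prob_frame = pd.DataFrame(
        probs, index=features.index,
        columns=[f"model_{m.index}" for m in ensemble.models])
    mean = prob_frame.mean(axis=1)
    return PredictionResult(
        probabilities=prob_frame,
        mean_probability=mean,
        candidate=mean >= CANDIDATE_THRESHOLD - THRESHOLD_EPS,
        high_confidence=mean > HIGH_CONFIDENCE_THRESHOLD + THRESHOLD_EPS,
    )


def compare_to_screens(predictions: PredictionResult,
                       screens: Mapping[str, Iterable[str]],
                       background_size: int) -> pd.DataFrame:
    """Recovered-hit counts and Fisher enrichment of the high-confidence
    call set against each screen's hit list."""
    from .consensus import overlap_stats

    called = predictions.high_confidence_ids
    rows = []
    for name, members in screens.items():
        screen = {str(m).strip().upper() for m in members}
        if not screen:
            raise ValueError(f"screen {name!r} is empty")
        res = overlap_stats(called, screen, background_size)
        rows.append({"screen": name, "screen_size": len(screen),
                     "recovered": len(called & screen),
                     "odds_ratio": res.odds_ratio, "p_value": res.p_value})
    return pd.DataFrame(rows).set_index("screen")
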