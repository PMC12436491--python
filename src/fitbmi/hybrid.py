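"""Hybrid model: attention-pooled encoder features into boosted trees.

The trained encoder is frozen and used as a feature extractor: each record's
attention-pooled feature vector (optionally concatenated with its four raw
normalized scores) becomes the input row of a LightGBM multiclass
classifier.  Class imbalance enters tree training through per-sample
inverse-frequency weights, mirroring the weighted cross-entropy of the
encoder stage, so both stages optimize a consistently balanced objective.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

from .encoder import (EncoderConfig, EncoderParams, encode, train_encoder)
from .losses import LossWeights, training_class_weights
from .preprocess import (CATEGORIES, FEATURE_COLUMNS, NormalizationStats,
                         SequenceBatch, apply_normalizer, category_codes,
                         fit_normalizer, make_sequences)

__all__ = [
    "TreeConfig",
    "TrainedHybrid",
    "extract_features",
    "train_gbdt",
    "fit_hybrid",
    "predict",
    "save_bundle",
    "load_bundle",
]


@dataclass
class TreeConfig:
    """Boosted-tree stage hyperparameters (LightGBM)."""

    n_estimators: int = 200
    max_depth: int = 6
    learning_rate: float = 0.1
    reg_lambda: float = 1.0
    num_leaves: int = 63
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _make_booster(tree_config: TreeConfig) -> LGBMClassifier:
    return LGBMClassifier(
        n_estimators=tree_config.n_estimators,
        max_depth=tree_config.max_depth,
        num_leaves=tree_config.num_leaves,
        learning_rate=tree_config.learning_rate,
        reg_lambda=tree_config.reg_lambda,
        random_state=tree_config.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )


def extract_features(encoder_params: EncoderParams,
                     batch: SequenceBatch,
                     include_raw: bool = True) -> np.ndarray:
    """Per-record transferred features for the tree stage.

    The pooled (attention-weighted) feature vector of each sequence,
    optionally concatenated with the record's raw normalized scores.
    Deterministic: identical inputs give identical rows.
    """
    encoder_params.check_finite()
    out = encode(encoder_params, batch)
    feats = out.pooled
    if include_raw:
        feats = np.concatenate([feats, batch.full[batch.record_index]],
                               axis=1)
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite values in extracted features")
    return feats


def train_gbdt(features: np.ndarray, labels: np.ndarray,
               class_weights: np.ndarray,
               tree_config: TreeConfig | None = None) -> LGBMClassifier:
    """Fit the boosted multiclass ensemble with per-class sample weights."""
    tree_config = tree_config or TreeConfig()
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("tree training needs at least 2 classes present")
    booster = _make_booster(tree_config)
    w = np.asarray(class_weights, dtype=float)[labels]
    booster.fit(np.asarray(features, dtype=float), labels, sample_weight=w)
    return booster


@dataclass
class TrainedHybrid:
    """Frozen encoder + boosted-tree ensemble + normalizer."""

    encoder_params: EncoderParams
    booster: LGBMClassifier
    stats: NormalizationStats
    tree_config: TreeConfig
    include_raw: bool = True
    class_weights: np.ndarray | None = None
    seed: int = 0


def fit_hybrid(train_df: pd.DataFrame,
               encoder_config: EncoderConfig | None = None,
               tree_config: TreeConfig | None = None,
               loss_weights: LossWeights | None = None,
               include_raw: bool = True) -> TrainedHybrid:
    """Full training pipeline on a cohort table.

    Normalizer and count bins are fitted on the training cohort only; the
    encoder is trained under the composite loss, frozen, and its pooled
    features (plus raw scores unless ``include_raw=False``) feed the trees.
    """
    encoder_config = encoder_config or EncoderConfig()
    tree_config = tree_config or TreeConfig(seed=encoder_config.seed)
    stats = fit_normalizer(train_df)
    x = apply_normalizer(stats, train_df)
    y = category_codes(train_df["bmi_category"])
    batch = make_sequences(x, labels=y)
    if loss_weights is None:
        counts = np.bincount(y, minlength=4)
        loss_weights = LossWeights(
            class_weights=training_class_weights(np.maximum(counts, 1)))
    params, _ = train_encoder(batch, encoder_config, loss_weights)
    feats = extract_features(params, batch, include_raw=include_raw)
    booster = train_gbdt(feats, y, loss_weights.class_weights, tree_config)
    return TrainedHybrid(encoder_params=params, booster=booster, stats=stats,
                         tree_config=tree_config, include_raw=include_raw,
                         class_weights=loss_weights.class_weights,
                         seed=encoder_config.seed)


def _predict_proba(booster, feats: np.ndarray) -> np.ndarray:
    feats = np.asarray(feats, dtype=float)
    if hasattr(booster, "predict_proba"):
        names = getattr(booster, "feature_names_in_", None)
        if names is not None:
            feats = pd.DataFrame(feats, columns=list(names))
        return booster.predict_proba(feats)
    return np.asarray(booster.predict(feats))  # raw lgb.Booster


def predict(model: TrainedHybrid, records: pd.DataFrame):
    """Predict BMI categories for raw records.

    Applies normalize -> sequence -> encode -> feature transfer -> trees.
    Returns ``(categories, probabilities)`` with probability rows summing
    to 1.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required fields: {missing}")
    x = apply_normalizer(model.stats, records)
    batch = make_sequences(x)
    feats = extract_features(model.encoder_params, batch,
                             include_raw=model.include_raw)
    probs = _predict_proba(model.booster, feats)
    cats = np.asarray(CATEGORIES)[np.argmax(probs, axis=1)]
    return cats, probs


# ---------------------------------------------------------------------------
# model bundle persistence (directory of text artifacts + manifest)

def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def save_bundle(model: TrainedHybrid, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "encoder.json").write_text(model.encoder_params.to_json())
    (path / "booster.txt").write_text(model.booster.booster_.model_to_string())
    (path / "normalizer.json").write_text(model.stats.to_json())
    manifest = {
        "tree_config": model.tree_config.to_dict(),
        "include_raw": model.include_raw,
        "class_weights": (None if model.class_weights is None
                          else list(map(float, model.class_weights))),
        "seed": model.seed,
        "encoder_config": model.encoder_params.config.to_dict(),
    }
    manifest["config_hash"] = _config_hash(manifest)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundle(path) -> TrainedHybrid:
    import lightgbm as lgb

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    params = EncoderParams.from_json((path / "encoder.json").read_text())
    stats = NormalizationStats.from_json(
        (path / "normalizer.json").read_text())
    booster_raw = lgb.Booster(
        model_str=(path / "booster.txt").read_text())
    cw = manifest.get("class_weights")
    return TrainedHybrid(
        encoder_params=params, booster=booster_raw, stats=stats,
        tree_config=TreeConfig(**manifest["tree_config"]),
        include_raw=manifest["include_raw"],
        class_weights=None if cw is None else np.asarray(cw),
        seed=manifest["seed"])
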