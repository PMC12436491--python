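"""BMI derivation, WHO categorization, normalization, sequences and splits."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CATEGORIES",
    "FEATURE_COLUMNS",
    "BMI_CUTPOINTS",
    "compute_bmi",
    "categorize_bmi",
    "NormalizationStats",
    "fit_normalizer",
    "apply_normalizer",
    "SequenceBatch",
    "make_sequences",
    "stratified_split",
    "stratified_kfold",
]

#: BMI categories: A underweight, B normal, C overweight, D obese
CATEGORIES = ("A", "B", "C", "D")

#: fixed feature order of the length-4 input sequence
FEATURE_COLUMNS = ("run_3000m_s", "pullups", "situps", "shuttle_60m_s")

#: WHO cut-points; intervals are half-open [lo, hi)
BMI_CUTPOINTS = (18.5, 25.0, 30.0)


def compute_bmi(weight_kg, height_cm):
    """BMI in kg/m^2 from weight in kg and height in cm."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_cm <= 0):
        raise ValueError("weight and height must be strictly positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    return float(bmi) if bmi.ndim == 0 else bmi


def categorize_bmi(bmi):
    """WHO category for a BMI value: A < 18.5 <= B < 25 <= C < 30 <= D.

    Boundaries belong to the upper class (half-open intervals).
    Accepts scalars or arrays; returns 'A'..'D' correspondingly.
    """
    arr = np.asarray(bmi, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("BMI must be finite and positive")
    idx = np.digitize(arr, BMI_CUTPOINTS, right=False)
    cats = np.asarray(CATEGORIES)[idx]
    return str(cats) if arr.ndim == 0 else cats


def category_codes(categories) -> np.ndarray:
    """Map 'A'..'D' labels to integer codes 0..3."""
    lut = {c: i for i, c in enumerate(CATEGORIES)}
    try:
        return np.asarray([lut[c] for c in np.asarray(categories, dtype=object)])
    except KeyError as exc:  # pragma: no cover - message detail
        raise ValueError(f"unknown category label: {exc.args[0]!r}") from exc


@dataclass
class NormalizationStats:
    """Per-feature mean/sd estimated on training data only (z-scoring)."""

    mean: np.ndarray
    std: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_COLUMNS

    def to_json(self) -> str:
        return json.dumps({
            "mean": list(map(float, self.mean)),
            "std": list(map(float, self.std)),
            "feature_names": list(self.feature_names),
        })

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        d = json.loads(text)
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]),
                   tuple(d["feature_names"]))


def _feature_matrix(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        return data.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def fit_normalizer(train) -> NormalizationStats:
    """Fit z-score statistics on the training cohort (never on test data)."""
    x = _feature_matrix(train)
    if x.shape[0] == 0:
        raise ValueError("cannot fit a normalizer on an empty cohort")
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    for j, s in enumerate(std):
        if s <= 0:
            raise ValueError(
                f"feature {FEATURE_COLUMNS[j]!r} has zero variance")
    return NormalizationStats(mean=mean, std=std)


def apply_normalizer(stats: NormalizationStats, data) -> np.ndarray:
    """Apply training z-score statistics; returns an (n, 4) float array."""
    x = _feature_matrix(data)
    return (x - stats.mean) / stats.std


@dataclass
class SequenceBatch:
    """Windowed feature sequences with aligned labels.

    ``x`` has shape (n_sequences, window); ``labels`` are integer category
    codes, one per sequence; ``record_index`` maps each sequence back to its
    source record.  ``full`` keeps the complete normalized (n_records, 4)
    matrix for the auxiliary reconstruction targets.
    """

    x: np.ndarray
    labels: np.ndarray
    record_index: np.ndarray
    full: np.ndarray

    def __len__(self) -> int:
        return self.x.shape[0]


def make_sequences(features, labels=None, window: int = 4,
                   stride: int = 1) -> SequenceBatch:
    """Cut each record's ordered 4-score vector into sliding sub-windows.

    With the defaults (window=4, stride=1) every record yields exactly one
    sequence covering all four tests in the fixed order
    (3000 m, pull-ups, sit-ups, shuttle).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D (records x scores)")
    n, length = x.shape
    if window > length:
        raise ValueError(f"window {window} exceeds sequence length {length}")
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    starts = np.arange(0, length - window + 1, stride)
    seqs = np.stack([x[:, s:s + window] for s in starts], axis=1)
    seqs = seqs.reshape(n * len(starts), window)
    rec_idx = np.repeat(np.arange(n), len(starts))
    if labels is None:
        lab = np.full(len(rec_idx), -1, dtype=int)
    else:
        lab = np.asarray(labels)[rec_idx]
    return SequenceBatch(x=seqs, labels=lab, record_index=rec_idx, full=x)


def _largest_remainder(counts: np.ndarray, frac: float) -> np.ndarray:
    """Per-class train sizes by the largest-remainder rounding rule."""
    exact = counts * frac
    base = np.floor(exact).astype(int)
    short = int(round(exact.sum())) - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return base


def stratified_split(df: pd.DataFrame, train_frac: float = 0.7,
                     seed: int = 0):
    """Label-stratified train/test split of a cohort table.

    Per class, the train size follows the largest-remainder rule on
    ``count * train_frac``; membership is a seeded shuffle.  Returns
    ``(train_df, test_df)`` with disjoint, exhaustive index sets.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    labels = df["bmi_category"].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise ValueError(f"class with < 2 members cannot be split: {small}")
    rng = np.random.default_rng(seed)
    n_train = _largest_remainder(counts.astype(float), train_frac)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls, k in zip(classes, n_train):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        train_idx.append(members[:k])
        test_idx.append(members[k:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return df.iloc[tr].reset_index(drop=True), df.iloc[te].reset_index(drop=True)


def stratified_kfold(df: pd.DataFrame, k: int = 10, seed: int = 0):
    """Stratified k-fold partition; returns a list of test-index arrays.

    Classes with fewer than k members are kept but trigger a warning (their
    members cannot appear in every fold).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = df["bmi_category"].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    rare = classes[counts < k]
    if rare.size:
        warnings.warn(
            f"classes with fewer than {k} members are pooled across folds: "
            f"{list(rare)}", UserWarning, stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in skf.split(np.zeros(len(labels)), labels)]
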