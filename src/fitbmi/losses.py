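"""Loss components of the composite training objective.

The classifier is trained under a sum of three terms: an inverse-frequency
class-weighted cross-entropy (imbalance correction), a multi-task weighted
loss over the four fitness-test auxiliary heads, and an attention loss that
couples the attention weights to the per-sample cross-entropy. Every term is
exposed here as a pure function so each can be unit-tested in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossWeights",
    "class_weights",
    "training_class_weights",
    "weighted_cross_entropy",
    "multi_task_loss",
    "attention_loss",
    "total_loss",
]

#: order of the auxiliary fitness tasks everywhere in the package
TASK_NAMES = ("run_3000m", "pullups", "situps", "shuttle")

#: default task weights (3000 m run, pull-ups, sit-ups, shuttle run)
DEFAULT_TASK_WEIGHTS = (0.4, 0.2, 0.2, 0.2)

PROB_FLOOR = 1e-12


@dataclass
class LossWeights:
    """Weights of the composite objective.

    ``class_weights`` holds one positive weight per BMI category (A..D),
    typically the inverse class frequency.  ``task_weights`` are the
    coefficients of the four auxiliary task losses, ordered as
    :data:`TASK_NAMES`; the endurance run carries the largest weight because
    it is the strongest single BMI correlate.  ``attention_coefficient`` is
    the lambda multiplying the attention loss.
    """

    class_weights: np.ndarray
    task_weights: tuple[float, float, float, float] = DEFAULT_TASK_WEIGHTS
    attention_coefficient: float = 0.1

    def __post_init__(self) -> None:
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if np.any(self.class_weights <= 0):
            raise ValueError("class weights must be strictly positive")
        if any(w <= 0 for w in self.task_weights):
            raise ValueError("task weights must be strictly positive")
        if self.attention_coefficient < 0:
            raise ValueError("attention coefficient must be non-negative")


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency class weights ``w_i = 1 / count_i``.

    Parameters
    ----------
    counts : array-like of int
        Number of samples per class; all entries must be >= 1.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("every class count must be >= 1")
    return 1.0 / counts


def training_class_weights(counts) -> np.ndarray:
    """Inverse-frequency weights rescaled to mean 1 over the data.

    With raw ``1/count`` weights a batch-mean cross-entropy shrinks by a
    factor ~n_classes/N relative to the auxiliary task losses, so the label
    signal would be drowned out.  Rescaling by ``N / n_classes`` keeps the
    batch mean on the same scale as an unweighted loss (it equals the
    class-balanced mean cross-entropy) while preserving the inverse-frequency
    ratios, and is invariant to batch size.
    """
    counts = np.asarray(counts, dtype=float)
    w = class_weights(counts)
    return w * counts.sum() / counts.size


def weighted_cross_entropy(probs, labels, weights) -> float:
    """Mean class-weighted cross-entropy over a batch.

    ``probs`` is an (n, k) array of predicted class probabilities (rows sum
    to 1), ``labels`` integer class indices, ``weights`` a length-k class
    weight vector.  Probabilities are floored at 1e-12 before the log.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probs must be 2-D (n_samples, n_classes)")
    if np.any(labels < 0) or np.any(labels >= probs.shape[1]):
        raise ValueError("label index outside the class range")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    p_true = np.clip(probs[np.arange(len(labels)), labels], PROB_FLOOR, None)
    return float(np.mean(weights[labels] * -np.log(p_true)))


def multi_task_loss(task_losses, task_weights=DEFAULT_TASK_WEIGHTS) -> float:
    """Weighted sum of the four auxiliary task losses."""
    task_losses = np.asarray(task_losses, dtype=float)
    if task_losses.shape != (4,):
        raise ValueError("expected exactly four task losses")
    if np.any(~np.isfinite(task_losses)) or np.any(task_losses < 0):
        raise ValueError("task losses must be finite and non-negative")
    return float(np.dot(task_losses, np.asarray(task_weights, dtype=float)))


def attention_loss(attention_weights, per_sample_ce, coefficient,
                   *, _validate: bool = True) -> float:
    """Attention loss: lambda times the mean of (sum of attention) x CE.

    With softmax-normalized attention rows the inner sum is identically 1,
    so the term reduces to ``coefficient * mean(per_sample_ce)``; the literal
    product form is kept so the definition is testable on its own.
    """
    attention_weights = np.asarray(attention_weights, dtype=float)
    per_sample_ce = np.asarray(per_sample_ce, dtype=float)
    row_sums = attention_weights.sum(axis=-1)
    if _validate and not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("attention rows must sum to 1 (within 1e-6)")
    return float(coefficient * np.mean(row_sums * per_sample_ce))


def total_loss(multi_task: float, attention: float, class_weighted_ce: float) -> float:
    """Total objective: exact sum of the three components."""
    parts = {"multi_task": multi_task, "attention": attention,
             "class_weighted_ce": class_weighted_ce}
    for name, value in parts.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite loss component: {name}")
    return float(multi_task + attention + class_weighted_ce)
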