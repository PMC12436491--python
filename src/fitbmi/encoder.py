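"""Multi-kernel 1D-convolution encoder with attention pooling.

The four fitness scores of a record form an ordered length-4 sequence
(3000 m, pull-ups, sit-ups, shuttle).  Parallel 1D convolutions of several
kernel widths ("same" zero-padding, centered, so every width stays aligned
to the input positions), ReLU, and per-position concatenation yield
per-position feature vectors H_t.  A single-query additive attention (v . tanh(W h_t + b)) scores each
position; the softmax weights alpha form a convex combination
u = sum_t alpha_t H_t — the pooled feature handed to the classification
head, the auxiliary task heads, and (downstream) the boosted-tree stage.

Training minimizes the composite objective from :mod:`fitbmi.losses`:
class-weighted cross-entropy + weighted auxiliary task losses + attention
loss.  The auxiliary tasks reconstruct each normalized test score from the
pooled feature — squared error for the two timed tests, cross-entropy over
quintile bins for the two count tests.  Forward and backward passes are
explicit NumPy; gradients are verified against finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .losses import DEFAULT_TASK_WEIGHTS, PROB_FLOOR, LossWeights
from .preprocess import SequenceBatch

__all__ = [
    "EncoderConfig",
    "EncoderParams",
    "EncoderOutput",
    "init_encoder",
    "encode",
    "train_encoder",
    "loss_and_grads",
    "attention_importance",
]

#: sequence indices of the timed (regression) and count (classification)
#: auxiliary tasks, in task order (3000 m, pull-ups, sit-ups, shuttle)
_REG_TASKS = {0: "run_3000m", 3: "shuttle"}
_CLS_TASKS = {1: "pullups", 2: "situps"}


@dataclass
class EncoderConfig:
    kernel_widths: tuple[int, ...] = (2, 3)
    channels_per_kernel: int = 8
    attention_dim: int = 16
    n_classes: int = 4
    seq_len: int = 4
    count_bins: int = 5
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 1 or w > self.seq_len for w in self.kernel_widths):
            raise ValueError(
                f"kernel widths must lie in [1, {self.seq_len}]")
        if self.channels_per_kernel < 1 or self.attention_dim < 1:
            raise ValueError("channels and attention_dim must be positive")

    @property
    def feature_dim(self) -> int:
        return self.channels_per_kernel * len(self.kernel_widths)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["kernel_widths"] = list(self.kernel_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        d["kernel_widths"] = tuple(d["kernel_widths"])
        return cls(**d)


@dataclass
class EncoderParams:
    """All trainable tensors plus the frozen config and count-bin edges."""

    config: EncoderConfig
    tensors: dict[str, np.ndarray]
    count_bin_edges: dict[int, np.ndarray] = field(default_factory=dict)

    def check_finite(self) -> None:
        for name, t in self.tensors.items():
            if not np.all(np.isfinite(t)):
                raise ValueError(f"non-finite parameter tensor: {name}")

    def copy(self) -> "EncoderParams":
        return EncoderParams(
            config=self.config,
            tensors={k: v.copy() for k, v in self.tensors.items()},
            count_bin_edges={k: v.copy()
                             for k, v in self.count_bin_edges.items()})

    # single portable JSON checkpoint with the config embedded
    def to_json(self) -> str:
        return json.dumps({
            "config": self.config.to_dict(),
            "tensors": {k: v.tolist() for k, v in self.tensors.items()},
            "count_bin_edges": {str(k): v.tolist()
                                for k, v in self.count_bin_edges.items()},
        })

    @classmethod
    def from_json(cls, text: str) -> "EncoderParams":
        d = json.loads(text)
        return cls(
            config=EncoderConfig.from_dict(d["config"]),
            tensors={k: np.asarray(v, dtype=float)
                     for k, v in d["tensors"].items()},
            count_bin_edges={int(k): np.asarray(v, dtype=float)
                             for k, v in d["count_bin_edges"].items()})


@dataclass
class EncoderOutput:
    features: np.ndarray        # (B, L, F) per-position features H
    attention: np.ndarray       # (B, L) softmax weights alpha
    pooled: np.ndarray          # (B, F) attention-pooled feature
    logits: np.ndarray          # (B, n_classes)
    probs: np.ndarray           # (B, n_classes)
    task_reg: dict[str, np.ndarray]      # scalar predictions per timed task
    task_logits: dict[str, np.ndarray]   # bin logits per count task


def init_encoder(config: EncoderConfig) -> EncoderParams:
    """Seeded Glorot-style initialization; same seed, same tensors."""
    rng = np.random.default_rng(config.seed)
    F, A, K = config.feature_dim, config.attention_dim, config.n_classes

    def glorot(*shape):
        fan = sum(shape) / len(shape)
        return rng.normal(0.0, np.sqrt(1.0 / fan), size=shape)

    tensors: dict[str, np.ndarray] = {}
    for w in config.kernel_widths:
        tensors[f"conv_w{w}"] = glorot(config.channels_per_kernel, w)
        tensors[f"conv_b{w}"] = np.zeros(config.channels_per_kernel)
    tensors["att_W"] = glorot(A, F)
    tensors["att_b"] = np.zeros(A)
    tensors["att_v"] = glorot(A)
    tensors["cls_W"] = glorot(K, F)
    tensors["cls_b"] = np.zeros(K)
    for t, name in _REG_TASKS.items():
        tensors[f"reg_{name}_w"] = glorot(F)
        tensors[f"reg_{name}_b"] = np.zeros(1)
    for t, name in _CLS_TASKS.items():
        tensors[f"bin_{name}_W"] = glorot(config.count_bins, F)
        tensors[f"bin_{name}_b"] = np.zeros(config.count_bins)
    return EncoderParams(config=config, tensors=tensors)


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _conv_forward(x: np.ndarray, kernel: np.ndarray,
                  bias: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered "same"-padded 1D convolution of a (B, L) single-channel
    sequence; returns pre-activation (B, L, C) and the padded input.

    Width w covers input positions [t - (w-1)//2, t + w//2], so the output
    at position t stays centred on feature t for every kernel width."""
    B, L = x.shape
    C, w = kernel.shape
    pl = (w - 1) // 2
    xp = np.pad(x, ((0, 0), (pl, w - 1 - pl)))
    # position t covers padded slice [t, t+w)
    z = np.zeros((B, L, C))
    for j in range(w):
        z += xp[:, j:j + L, None] * kernel[None, None, :, j]
    z += bias[None, None, :]
    return z, xp


def encode(params: EncoderParams, batch: SequenceBatch | np.ndarray,
           _cache: dict | None = None) -> EncoderOutput:
    """Forward pass: convolutions, ReLU, attention pooling, heads."""
    params.check_finite()
    cfg = params.config
    x = batch.x if isinstance(batch, SequenceBatch) else np.asarray(batch,
                                                                    dtype=float)
    if x.ndim != 2:
        raise ValueError("batch must be 2-D (samples x positions)")
    if x.shape[1] != cfg.seq_len:
        raise ValueError(
            f"sequence length {x.shape[1]} != configured {cfg.seq_len}")
    T = params.tensors

    feats, pre_acts, pads = [], [], []
    for w in cfg.kernel_widths:
        z, xp = _conv_forward(x, T[f"conv_w{w}"], T[f"conv_b{w}"])
        pre_acts.append(z)
        pads.append(xp)
        feats.append(np.maximum(z, 0.0))
    H = np.concatenate(feats, axis=2)                      # (B, L, F)

    P = H @ T["att_W"].T + T["att_b"]                      # (B, L, A)
    Tt = np.tanh(P)
    s = Tt @ T["att_v"]                                    # (B, L)
    alpha = _softmax(s, axis=1)
    pooled = np.einsum("bl,blf->bf", alpha, H)             # (B, F)

    logits = pooled @ T["cls_W"].T + T["cls_b"]
    probs = _softmax(logits, axis=1)
    task_reg = {name: pooled @ T[f"reg_{name}_w"] + T[f"reg_{name}_b"][0]
                for name in _REG_TASKS.values()}
    task_logits = {name: pooled @ T[f"bin_{name}_W"].T + T[f"bin_{name}_b"]
                   for name in _CLS_TASKS.values()}

    if _cache is not None:
        _cache.update(x=x, pre_acts=pre_acts, pads=pads, H=H, P=P, Tt=Tt,
                      s=s, alpha=alpha, pooled=pooled, logits=logits,
                      probs=probs, task_reg=task_reg, task_logits=task_logits)
    return EncoderOutput(features=H, attention=alpha, pooled=pooled,
                         logits=logits, probs=probs, task_reg=task_reg,
                         task_logits=task_logits)


def _count_bins(params: EncoderParams, full: np.ndarray) -> dict[int, np.ndarray]:
    """Quintile-bin targets for the count tasks from stored training edges."""
    out = {}
    for t in _CLS_TASKS:
        edges = params.count_bin_edges[t]
        out[t] = np.clip(np.digitize(full[:, t], edges),
                         0, params.config.count_bins - 1)
    return out


def loss_and_grads(params: EncoderParams, batch: SequenceBatch,
                   loss_weights: LossWeights,
                   compute_grads: bool = True):
    """Composite loss (and, optionally, gradients for every tensor).

    Returns ``(components, grads)`` where components maps
    {'total', 'class_weighted_ce', 'multi_task', 'attention',
    'task_<name>'} to floats.
    """
    cfg = params.config
    cache: dict = {}
    encode(params, batch, _cache=cache)
    B = batch.x.shape[0]
    T = params.tensors
    y = batch.labels
    w_cls = np.asarray(loss_weights.class_weights, dtype=float)
    lam = loss_weights.attention_coefficient
    tw = dict(zip((0, 1, 2, 3), loss_weights.task_weights))

    probs, alpha, pooled, H = (cache["probs"], cache["alpha"],
                               cache["pooled"], cache["H"])
    sum_alpha = alpha.sum(axis=1)                      # identically 1

    # class-weighted cross-entropy (batch mean) and its attention coupling
    p_true = np.clip(probs[np.arange(B), y], PROB_FLOOR, None)
    ce_i = w_cls[y] * -np.log(p_true)
    L_ce = float(ce_i.mean())
    L_att = float(lam * np.mean(sum_alpha * ce_i))

    # auxiliary task losses on the full normalized score vector
    targets_full = batch.full[batch.record_index]
    bins = _count_bins(params, targets_full)
    task_losses: dict[int, float] = {}
    reg_err: dict[int, np.ndarray] = {}
    cls_probs: dict[int, np.ndarray] = {}
    for t, name in _REG_TASKS.items():
        err = cache["task_reg"][name] - targets_full[:, t]
        reg_err[t] = err
        task_losses[t] = float(np.mean(err ** 2))
    for t, name in _CLS_TASKS.items():
        p = _softmax(cache["task_logits"][name], axis=1)
        cls_probs[t] = p
        pt = np.clip(p[np.arange(B), bins[t]], PROB_FLOOR, None)
        task_losses[t] = float(np.mean(-np.log(pt)))
    L_task = float(sum(tw[t] * task_losses[t] for t in range(4)))

    components = {
        "class_weighted_ce": L_ce,
        "attention": L_att,
        "multi_task": L_task,
        "total": L_ce + L_att + L_task,
    }
    for t, name in {**_REG_TASKS, **_CLS_TASKS}.items():
        components[f"task_{name}"] = task_losses[t]
    if not compute_grads:
        return components, None

    grads = {k: np.zeros_like(v) for k, v in T.items()}

    # --- classification head; CE path carries factor (1 + lam*sum_alpha),
    # sum_alpha == 1 with identically-zero gradient under softmax
    ce_scale = (1.0 + lam * sum_alpha) * w_cls[y] / B
    dlogits = (probs - np.eye(cfg.n_classes)[y]) * ce_scale[:, None]
    grads["cls_W"] += dlogits.T @ pooled
    grads["cls_b"] += dlogits.sum(axis=0)
    dpooled = dlogits @ T["cls_W"]

    # --- task heads
    for t, name in _REG_TASKS.items():
        dpred = 2.0 * tw[t] * reg_err[t] / B
        grads[f"reg_{name}_w"] += dpred @ pooled
        grads[f"reg_{name}_b"] += np.array([dpred.sum()])
        dpooled += dpred[:, None] * T[f"reg_{name}_w"][None, :]
    for t, name in _CLS_TASKS.items():
        dtl = (cls_probs[t] - np.eye(cfg.count_bins)[bins[t]]) * tw[t] / B
        grads[f"bin_{name}_W"] += dtl.T @ pooled
        grads[f"bin_{name}_b"] += dtl.sum(axis=0)
        dpooled += dtl @ T[f"bin_{name}_W"]

    # --- attention pooling: u = sum_t alpha_t H_t
    dalpha = np.einsum("bf,blf->bl", dpooled, H)
    dH = alpha[:, :, None] * dpooled[:, None, :]
    ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    grads["att_v"] += np.einsum("bl,bla->a", ds, cache["Tt"])
    dP = ds[:, :, None] * T["att_v"][None, None, :] * (1.0 - cache["Tt"] ** 2)
    grads["att_W"] += np.einsum("bla,blf->af", dP, H)
    grads["att_b"] += dP.sum(axis=(0, 1))
    dH += dP @ T["att_W"]

    # --- back through ReLU and the causal convolutions
    C = cfg.channels_per_kernel
    for i, w in enumerate(cfg.kernel_widths):
        dZ = dH[:, :, i * C:(i + 1) * C] * (cache["pre_acts"][i] > 0)
        xp = cache["pads"][i]
        L = cache["x"].shape[1]
        for j in range(w):
            grads[f"conv_w{w}"][:, j] += np.einsum(
                "blc,bl->c", dZ, xp[:, j:j + L])
        grads[f"conv_b{w}"] += dZ.sum(axis=(0, 1))

    return components, grads


def _fit_count_bins(config: EncoderConfig,
                    full: np.ndarray) -> dict[int, np.ndarray]:
    qs = np.linspace(0, 1, config.count_bins + 1)[1:-1]
    return {t: np.quantile(full[:, t], qs) for t in _CLS_TASKS}


def train_encoder(batch: SequenceBatch, config: EncoderConfig,
                  loss_weights: LossWeights):
    """Mini-batch Adam on the composite objective.

    Returns ``(params, history)``; history is a list of per-epoch dicts of
    the loss components evaluated on the full training set.  Deterministic
    for a fixed config seed and data.
    """
    if len(batch) == 0:
        raise ValueError("empty training batch")
    params = init_encoder(config)
    params.count_bin_edges = _fit_count_bins(config, batch.full)
    rng = np.random.default_rng(config.seed + 1)

    m = {k: np.zeros_like(v) for k, v in params.tensors.items()}
    v = {k: np.zeros_like(v) for k, v in params.tensors.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(batch)
    bs = min(config.batch_size, n)

    history: list[dict] = []
    comps, _ = loss_and_grads(params, batch, loss_weights,
                              compute_grads=False)
    history.append({"epoch": 0, **comps})

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for lo in range(0, n, bs):
            idx = order[lo:lo + bs]
            sub = SequenceBatch(x=batch.x[idx], labels=batch.labels[idx],
                                record_index=batch.record_index[idx],
                                full=batch.full)
            comps, grads = loss_and_grads(params, sub, loss_weights)
            if not np.isfinite(comps["total"]):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            step += 1
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** step)
                vhat = v[k] / (1 - b2 ** step)
                params.tensors[k] -= (config.learning_rate * mhat
                                      / (np.sqrt(vhat) + eps))
        comps, _ = loss_and_grads(params, batch, loss_weights,
                                  compute_grads=False)
        history.append({"epoch": epoch, **comps})
    return params, history


def attention_importance(params: EncoderParams, batch) -> np.ndarray:
    """Mean attention weight per input position (sums to 1).

    The profile is the model's feature-importance signal: positions the
    encoder attends to on average contribute most to the pooled feature.
    """
    out = encode(params, batch)
    if out.attention.shape[0] == 0:
        raise ValueError("cannot average attention over an empty cohort")
    return out.attention.mean(axis=0)
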