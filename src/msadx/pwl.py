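"""The pointwise linear model.

A hypernetwork (a plain MLP trunk) maps each encoded case x(n) to its own
per-class linear weight vector w_c(n) and bias b_c(n); the class score is the
tailored linear form

    z_c(n) = w_c(n) . x(n) + b_c(n),        p(n) = softmax(z(n)),

so every prediction comes with per-sample, per-class regression coefficients
that can be read directly. Training minimises label-smoothed cross-entropy
plus an elastic-net penalty on the *emitted* weight vectors (not on the trunk
parameters), optimised with Adam. The whole model is implemented in numpy
(float32 forward/backward written out by hand), which keeps it dependency-light
and exactly reproducible on a single CPU.

Two reduced modes exist for analysis and testing:

* ``constant_weights=True`` bypasses the trunk and trains one shared weight
  matrix — exactly a multinomial logistic regression with elastic net;
* ``ovr_models=True`` trains one two-class model per subtype (one-vs-rest)
  and renormalises the positive-class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .encoding import DesignMatrix, FeatureCodebook
from .registry import SUBTYPES

__all__ = ["PWLConfig", "PWLParams", "PWLPrediction", "forward", "loss",
           "train", "predict_proba"]


@dataclass(frozen=True)
class PWLConfig:
    """Hyperparameters; defaults are the tuned configuration."""

    n_epochs: int = 100
    n_inner_layers: int = 16
    layer_size: int = 180
    label_smoothing: float = 0.055
    learning_rate: float = 1.83e-4
    momentum: float = 0.968          # Adam's beta1
    optimizer: str = "adam"
    dropout_inner: float = 0.027
    dropout_input: float = 0.171
    reg_coef: float = 9.29e-5        # elastic-net lambda on emitted weights
    l1_ratio: float = 0.048
    batch_size: int = 128
    seed: int = 0
    n_classes: int = 3
    beta2: float = 0.999
    adam_eps: float = 1e-8
    constant_weights: bool = False
    ovr_models: bool = False

    def __post_init__(self):
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0,1)")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must be in [0,1]")
        if self.reg_coef < 0:
            raise ValueError("reg_coef must be >= 0")
        for p in (self.dropout_inner, self.dropout_input):
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout rates must be in [0,1)")
        if self.optimizer != "adam":
            raise ValueError("only adam is implemented")


@dataclass
class PWLParams:
    """Trained parameters plus the context needed to reuse them."""

    trunk: list  # [(W, b), ...] input layer then inner layers; [] in constant mode
    W_head: np.ndarray | None
    b_head: np.ndarray | None
    config: PWLConfig
    input_dim: int
    feature_names: list[str]
    history: list[float] = field(default_factory=list)  # per-epoch mean loss
    submodels: list | None = None  # one-vs-rest binary models

    @property
    def n_classes(self) -> int:
        return self.config.n_classes


@dataclass
class PWLPrediction:
    weights: np.ndarray  # n x C x d tailored weight vectors
    bias: np.ndarray     # n x C
    logits: np.ndarray   # n x C
    probs: np.ndarray    # n x C, rows sum to 1


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _trunk_forward(params: PWLParams, X32: np.ndarray,
                   training: bool, rng: np.random.Generator | None):
    """Run the MLP trunk; returns (head input, backprop caches)."""
    cfg = params.config
    caches = []
    h = X32
    if training and cfg.dropout_input > 0:
        mask = (rng.random(h.shape, dtype=np.float32) >= cfg.dropout_input)
        h = h * mask / np.float32(1.0 - cfg.dropout_input)
    x_used = h
    for W, b in params.trunk:
        pre = h @ W + b
        act = np.maximum(pre, 0.0)
        grad_mult = (pre > 0).astype(np.float32)
        if training and cfg.dropout_inner > 0:
            mask = (rng.random(act.shape, dtype=np.float32) >= cfg.dropout_inner)
            scale = np.float32(1.0 / (1.0 - cfg.dropout_inner))
            act = act * mask * scale
            grad_mult *= mask * scale
        caches.append((h, grad_mult))
        h = act
    return h, x_used, caches


def _emit(params: PWLParams, X: np.ndarray, training: bool = False,
          rng: np.random.Generator | None = None):
    """Emit per-sample weights/bias; returns (w, bias, trunk caches, h)."""
    cfg = params.config
    n, d = X.shape
    C = cfg.n_classes
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    if cfg.constant_weights:
        out = np.broadcast_to(params.W_head, (n, C * (d + 1)))
        caches, h = None, None
    else:
        h, _, caches = _trunk_forward(params, X32, training, rng)
        out = h @ params.W_head + params.b_head
    out = out.reshape(n, C, d + 1)
    return out[:, :, :d], out[:, :, d], caches, h, X32


def forward(params: PWLParams, X: np.ndarray) -> PWLPrediction:
    """Evaluation-mode forward pass (dropout off).

    The returned weights and bias exactly reproduce the logits:
    logit[n, c] == weights[n, c] . X[n] + bias[n, c].
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params.input_dim:
        raise ValueError(
            f"expected n x {params.input_dim} input, got {X.shape}")
    if params.submodels is not None:
        return _forward_ovr(params, X)
    w, b, _, _, X32 = _emit(params, X, training=False)
    w64 = w.astype(np.float64)
    b64 = b.astype(np.float64)
    logits = np.einsum("ncd,nd->nc", w64, X) + b64
    return PWLPrediction(w64, b64, logits, _softmax(logits))


def _forward_ovr(params: PWLParams, X: np.ndarray) -> PWLPrediction:
    """One-vs-rest composition: class c's weights are the positive-minus-rest
    contrast of its binary model; probabilities renormalised across classes."""
    n, d = X.shape
    C = params.config.n_classes
    w = np.empty((n, C, d))
    b = np.empty((n, C))
    pos = np.empty((n, C))
    for c, sub in enumerate(params.submodels):
        pred = forward(sub, X)
        w[:, c] = pred.weights[:, 1] - pred.weights[:, 0]
        b[:, c] = pred.bias[:, 1] - pred.bias[:, 0]
        pos[:, c] = pred.probs[:, 1]
    probs = pos / pos.sum(axis=1, keepdims=True)
    logits = np.einsum("ncd,nd->nc", w, X) + b
    return PWLPrediction(w, b, logits, probs)


def _smoothed_targets(y: np.ndarray, C: int, eps: float) -> np.ndarray:
    t = np.full((len(y), C), eps / C)
    t[np.arange(len(y)), y] += 1.0 - eps
    return t


def _penalty(w: np.ndarray, cfg: PWLConfig) -> float:
    """Elastic net on emitted weight vectors, averaged over the batch."""
    if cfg.reg_coef == 0:
        return 0.0
    l1 = np.abs(w).sum(axis=(1, 2)).mean()
    l2 = (w ** 2).sum(axis=(1, 2)).mean()
    return float(cfg.reg_coef * (cfg.l1_ratio * l1 + (1 - cfg.l1_ratio) * 0.5 * l2))


def loss(prediction: PWLPrediction, labels: np.ndarray, config: PWLConfig
         ) -> float:
    """Label-smoothed cross-entropy plus the elastic-net weight penalty.

    The true-class target is (1-eps) + eps/C and every off-class target is
    eps/C; the penalty applies to the emitted per-sample weights, never to
    the per-sample bias.
    """
    y = np.asarray(labels)
    t = _smoothed_targets(y, config.n_classes, config.label_smoothing)
    logp = np.log(np.clip(prediction.probs, 1e-12, None))
    ce = float(-(t * logp).sum(axis=1).mean())
    return ce + _penalty(prediction.weights, config)


class _Adam:
    def __init__(self, shapes, cfg: PWLConfig):
        self.m = [np.zeros(s, dtype=np.float32) for s in shapes]
        self.v = [np.zeros(s, dtype=np.float32) for s in shapes]
        self.t = 0
        self.b1, self.b2 = np.float32(cfg.momentum), np.float32(cfg.beta2)
        self.lr, self.eps = np.float32(cfg.learning_rate), np.float32(cfg.adam_eps)

    def step(self, params: list, grads: list) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _init_params(d: int, codebook_names: list[str], cfg: PWLConfig,
                 rng: np.random.Generator) -> PWLParams:
    C, H = cfg.n_classes, cfg.layer_size
    if cfg.constant_weights:
        return PWLParams([], np.zeros(C * (d + 1), dtype=np.float32), None,
                         cfg, d, codebook_names)
    trunk = []
    fan = d
    for _ in range(cfg.n_inner_layers + 1):  # input layer + inner stack
        W = rng.standard_normal((fan, H)).astype(np.float32) \
            * np.sqrt(np.float32(2.0 / fan))
        trunk.append((W, np.zeros(H, dtype=np.float32)))
        fan = H
    # zero head: the model starts at uniform probabilities
    W_head = np.zeros((H, C * (d + 1)), dtype=np.float32)
    b_head = np.zeros(C * (d + 1), dtype=np.float32)
    return PWLParams(trunk, W_head, b_head, cfg, d, codebook_names)


def _batch_grad(params: PWLParams, Xb: np.ndarray, yb: np.ndarray,
                rng: np.random.Generator):
    """Forward + backward on one minibatch; returns (loss, grads).

    Gradients follow the parameter order: trunk W/b pairs, then head W/b
    (constant mode: just the shared weight vector).
    """
    cfg = params.config
    B, d = Xb.shape
    C = cfg.n_classes
    w, bias, caches, h, X32 = _emit(params, Xb, training=True, rng=rng)

    logits = np.einsum("ncd,nd->nc", w, X32).astype(np.float64) \
        + bias.astype(np.float64)
    probs = _softmax(logits)
    t = _smoothed_targets(yb, C, cfg.label_smoothing)
    ce = float(-(t * np.log(np.clip(probs, 1e-12, None))).sum(axis=1).mean())
    total = ce + _penalty(w.astype(np.float64), cfg)

    dz = ((probs - t) / B).astype(np.float32)              # B x C
    dw = dz[:, :, None] * X32[:, None, :]                  # B x C x d
    if cfg.reg_coef > 0:
        lam = np.float32(cfg.reg_coef / B)
        dw += lam * (np.float32(cfg.l1_ratio) * np.sign(w)
                     + np.float32(1 - cfg.l1_ratio) * w)
    dout = np.concatenate([dw, dz[:, :, None]], axis=2).reshape(B, C * (d + 1))

    if cfg.constant_weights:
        return total, [dout.sum(axis=0)]

    grads_head_W = h.T @ dout
    grads_head_b = dout.sum(axis=0)
    dh = dout @ params.W_head.T
    trunk_grads = []
    for (W, b), (h_in, gmult) in zip(reversed(params.trunk), reversed(caches)):
        dpre = dh * gmult
        trunk_grads.append((h_in.T @ dpre, dpre.sum(axis=0)))
        dh = dpre @ W.T
    trunk_grads.reverse()
    flat = []
    for gW, gb in trunk_grads:
        flat += [gW, gb]
    flat += [grads_head_W, grads_head_b]
    return total, flat


def _flat_params(params: PWLParams) -> list:
    if params.config.constant_weights:
        return [params.W_head]
    flat = []
    for W, b in params.trunk:
        flat += [W, b]
    flat += [params.W_head, params.b_head]
    return flat


def _train_single(X: np.ndarray, y: np.ndarray, names: list[str],
                  cfg: PWLConfig) -> PWLParams:
    rng = np.random.default_rng(cfg.seed)
    n, d = X.shape
    params = _init_params(d, names, cfg, rng)
    flat = _flat_params(params)
    opt = _Adam([p.shape for p in flat], cfg)
    bs = min(cfg.batch_size, n)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for _ in range(cfg.n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            lval, grads = _batch_grad(params, X32[idx], y[idx], rng)
            opt.step(flat, grads)
            losses.append(lval)
        params.history.append(float(np.mean(losses)))
    return params


def train(matrix: DesignMatrix, config: PWLConfig | None = None) -> PWLParams:
    """Fit the model on a complete design matrix.

    Deterministic given (seed, data, config): initialisation, epoch shuffles
    and dropout masks all come from one seeded generator. Raises if the
    training set contains a single class (downstream AUC is undefined).
    """
    cfg = PWLConfig() if config is None else config
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    names = matrix.codebook.names
    if cfg.ovr_models:
        subcfg = replace(cfg, n_classes=2, ovr_models=False)
        subs = []
        for c in range(cfg.n_classes):
            yb = (y == c).astype(np.int64)
            subs.append(_train_single(matrix.values, yb, names,
                                      replace(subcfg, seed=cfg.seed + c)))
        params = PWLParams([], None, None, cfg, matrix.d, names,
                           submodels=subs)
        params.history = [h for s in subs for h in s.history]
        return params
    return _train_single(matrix.values, y, names, cfg)


def predict_proba(params: PWLParams, matrix: DesignMatrix):
    """Per-case subtype probability table (columns SND/SDS/OPCA).

    The ``predicted`` column flags the argmax subtype for each case.
    """
    import pandas as pd

    pred = forward(params, matrix.values)
    df = pd.DataFrame(pred.probs, columns=list(SUBTYPES))
    if matrix.case_ids is not None:
        df.insert(0, "case_id", matrix.case_ids)
    df["predicted"] = [SUBTYPES[i] for i in pred.probs.argmax(axis=1)]
    return df
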