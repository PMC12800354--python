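"""Gated attention multiple-instance learning, trained from scratch.

A slide is a *bag* of tile-feature instances; the label attaches to the bag,
never to single tiles.  The aggregator is the gated attention pooling of
deep attention MIL: per-instance scores

    s_k = w^T ( tanh(V h_k) * sigmoid(U h_k) )

are softmax-normalized into attention weights a_k, the bag representation is
the attention-weighted sum z = sum_k a_k h_k, and a logistic head on z gives
the bag probability.  The construction is exactly permutation- and
duplication-invariant.

Training minimizes binary cross-entropy by Adam on analytically derived
gradients (verified against finite differences in the test suite); no
autodiff framework is involved, keeping the model dependency-free and
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class BagError(ValueError):
    """Empty or malformed bag."""


@dataclass
class Bag:
    """One slide's instances with its binary label."""

    instances: np.ndarray  # n x D
    label: int
    slide_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.instances = np.asarray(self.instances, dtype=float)
        if self.instances.ndim != 2 or self.instances.shape[0] < 1:
            raise BagError("bag needs a non-empty (n, D) instance matrix")
        if not np.all(np.isfinite(self.instances)):
            raise BagError("non-finite instance features")


@dataclass
class AttentionMILModel:
    V: np.ndarray  # hidden x D, tanh branch
    U: np.ndarray  # hidden x D, sigmoid gate branch
    w: np.ndarray  # hidden
    head_weights: np.ndarray  # D
    head_bias: float

    @property
    def hidden(self) -> int:
        return self.V.shape[0]

    @property
    def dim(self) -> int:
        return self.V.shape[1]

    @classmethod
    def init(
        cls, dim: int, hidden: int = 64, rng: np.random.Generator | int = 0
    ) -> "AttentionMILModel":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        scale_v = 1.0 / np.sqrt(dim)
        return cls(
            V=rng.normal(0, scale_v, (hidden, dim)),
            U=rng.normal(0, scale_v, (hidden, dim)),
            w=rng.normal(0, 1.0 / np.sqrt(hidden), hidden),
            head_weights=rng.normal(0, scale_v, dim),
            head_bias=0.0,
        )

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "V": self.V,
            "U": self.U,
            "w": self.w,
            "head_weights": self.head_weights,
            "head_bias": np.array([self.head_bias]),
        }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _forward(model: AttentionMILModel, h: np.ndarray) -> dict[str, np.ndarray]:
    t = np.tanh(h @ model.V.T)  # n x H
    g = _sigmoid(h @ model.U.T)  # n x H
    e = t * g
    s = e @ model.w  # n
    s_shift = s - s.max()
    exp_s = np.exp(s_shift)
    a = exp_s / exp_s.sum()
    z = a @ h  # D
    logit = float(z @ model.head_weights + model.head_bias)
    p = float(_sigmoid(np.array([logit]))[0])
    return {"t": t, "g": g, "e": e, "s": s, "a": a, "z": z, "logit": logit, "p": p}


def attention_weights(model: AttentionMILModel, bag: Bag) -> np.ndarray:
    """Non-negative per-instance weights summing to 1."""
    return _forward(model, bag.instances)["a"]


def mil_forward(model: AttentionMILModel, bag: Bag) -> float:
    """Bag probability: logistic head on the attention-pooled representation."""
    return _forward(model, bag.instances)["p"]


def _gradients(
    model: AttentionMILModel, bag: Bag
) -> tuple[float, dict[str, np.ndarray]]:
    """Binary cross-entropy loss and its analytic parameter gradients."""
    h = bag.instances
    f = _forward(model, h)
    y = float(bag.label)
    p = f["p"]
    eps = 1e-12
    loss = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))

    dlogit = p - y
    d_head_w = dlogit * f["z"]
    d_head_b = dlogit
    dz = dlogit * model.head_weights  # D
    da = h @ dz  # n
    a = f["a"]
    ds = a * (da - float(a @ da))  # softmax backward
    de = np.outer(ds, model.w)  # n x H
    dw = f["e"].T @ ds  # H
    dVh = de * f["g"] * (1.0 - f["t"] ** 2)
    dUh = de * f["t"] * f["g"] * (1.0 - f["g"])
    dV = dVh.T @ h
    dU = dUh.T @ h
    return loss, {
        "V": dV,
        "U": dU,
        "w": dw,
        "head_weights": d_head_w,
        "head_bias": np.array([d_head_b]),
    }


@dataclass
class MILTrainConfig:
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 8
    hidden: int = 64
    seed: int = 0


def train_mil(bags: list[Bag], config: MILTrainConfig | None = None) -> AttentionMILModel:
    """Adam training of the gated attention model; deterministic given seed."""
    if config is None:
        config = MILTrainConfig()
    labels = {bag.label for bag in bags}
    if labels != {0, 1}:
        raise BagError(f"training needs both labels, got {sorted(labels)}")
    rng = np.random.default_rng(config.seed)
    dim = bags[0].instances.shape[1]
    model = AttentionMILModel.init(dim, hidden=config.hidden, rng=rng)

    params = model.parameters()
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(p) for k, p in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(bags))
        for start in range(0, len(bags), config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = {k: np.zeros_like(p) for k, p in params.items()}
            for i in batch:
                _, g = _gradients(model, bags[i])
                for k in grads:
                    grads[k] += g[k] / len(batch)
            step += 1
            for k, p in params.items():
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                m_hat = m[k] / (1 - beta1**step)
                v_hat = v[k] / (1 - beta2**step)
                p -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            # scalar bias lives outside the in-place array updates
            model.head_bias = float(params["head_bias"][0])
    return model


def predict_bags(model: AttentionMILModel, bags: list[Bag]) -> np.ndarray:
    return np.array([mil_forward(model, bag) for bag in bags])
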