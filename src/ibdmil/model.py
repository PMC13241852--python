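"""Gated-attention MIL network: forward, loss, and analytic gradients.

The architecture is the standard attention-based MIL design for
whole-slide classification:

* **Instance encoder** — two fully connected layers with ReLU and
  dropout, followed by layer normalization, projecting each patch
  embedding to a 256-D hidden vector ``h_k``.
* **Gated attention pooling** — a per-instance score
  ``s_k = w^T (tanh(V h_k) * sigmoid(U h_k))``, softmax-normalized
  over the *real* (unpadded) instances of a bag; the bag vector is the
  attention-weighted sum of hidden vectors.  Padded slots receive
  weight exactly 0.
* **Classifier** — a single linear layer to K class logits.

Training uses focal loss with per-class weights; at ``gamma = 0`` and
unit weights it reduces exactly to cross-entropy.

Everything is plain NumPy with hand-derived backpropagation (the
network is small enough that an autodiff framework buys nothing), and
the gradients are validated against finite differences in the test
suite.  All randomness (init, dropout) flows through explicit
``numpy.random.Generator`` objects, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

_LN_EPS = 1e-5


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters."""

    embed_dim: int
    n_classes: int
    hidden_dim: int = 256
    attn_dim: int = 128
    dropout: float = 0.3


def init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-initialized parameter set for the full network."""
    d, h, a, k = config.embed_dim, config.hidden_dim, config.attn_dim, config.n_classes

    def he(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float64)

    return {
        "W1": he(d, (d, h)),
        "b1": np.zeros(h),
        "W2": he(h, (h, h)),
        "b2": np.zeros(h),
        "ln_g": np.ones(h),
        "ln_b": np.zeros(h),
        "V": he(h, (a, h)),
        "U": he(h, (a, h)),
        "w": he(a, (a,)),
        "Wc": he(h, (h, k)),
        "bc": np.zeros(k),
    }


@dataclass
class BagBatch:
    """A zero-padded mini-batch of bags.

    ``embeddings`` has shape (batch, max_len, dim); ``mask`` is 1.0 at
    real instances and 0.0 at padded slots; every bag must have at
    least one real instance.
    """

    embeddings: np.ndarray
    mask: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.sum(axis=1).min() < 1:
            raise ValueError("every bag needs at least one real (unmasked) instance")


def make_batch(bags_vectors: list[np.ndarray], labels: list[int]) -> BagBatch:
    """Zero-pad a list of (n_i, dim) arrays to the batch maximum length."""
    if not bags_vectors:
        raise ValueError("empty batch")
    max_len = max(len(v) for v in bags_vectors)
    dim = bags_vectors[0].shape[1]
    x = np.zeros((len(bags_vectors), max_len, dim))
    m = np.zeros((len(bags_vectors), max_len))
    for i, v in enumerate(bags_vectors):
        x[i, : len(v)] = v
        m[i, : len(v)] = 1.0
    return BagBatch(x, m, np.asarray(labels, dtype=int))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def encode_instances(
    x: np.ndarray,
    params: dict[str, np.ndarray],
    *,
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    cache: Optional[dict] = None,
) -> np.ndarray:
    """Instance encoder: linear -> ReLU -> dropout -> linear -> ReLU ->
    dropout -> layer norm.  Dropout is inverted and active only when a
    generator is supplied (training); evaluation is deterministic.
    Padded (all-zero) rows produce finite outputs that downstream
    masking ignores.
    """
    z1 = x @ params["W1"] + params["b1"]
    r1 = np.maximum(z1, 0.0)
    if dropout > 0.0 and rng is not None:
        m1 = (rng.random(r1.shape) >= dropout) / (1.0 - dropout)
    else:
        m1 = None
    d1 = r1 * m1 if m1 is not None else r1
    z2 = d1 @ params["W2"] + params["b2"]
    r2 = np.maximum(z2, 0.0)
    if dropout > 0.0 and rng is not None:
        m2 = (rng.random(r2.shape) >= dropout) / (1.0 - dropout)
    else:
        m2 = None
    d2 = r2 * m2 if m2 is not None else r2

    mu = d2.mean(axis=-1, keepdims=True)
    var = d2.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (d2 - mu) * inv_std
    h = params["ln_g"] * xhat + params["ln_b"]

    if cache is not None:
        cache.update(x=x, z1=z1, m1=m1, d1=d1, z2=z2, m2=m2, d2=d2,
                     xhat=xhat, inv_std=inv_std)
    return h


def gated_attention_pool(
    h: np.ndarray,
    mask: np.ndarray,
    params: dict[str, np.ndarray],
    *,
    cache: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Masked gated-attention pooling.

    Scores ``s_k = w^T (tanh(V h_k) * sigmoid(U h_k))`` are softmaxed
    over real instances only; padded slots get weight exactly 0.
    Returns ``(bag_vector (B, H), attention (B, L))``.
    """
    if mask.sum(axis=1).min() < 1:
        raise ValueError("a bag with no real instances cannot be pooled")
    t = np.tanh(h @ params["V"].T)
    g = _sigmoid(h @ params["U"].T)
    e = t * g
    s = e @ params["w"]
    s_shift = np.where(mask > 0, s, -np.inf)
    s_shift = s_shift - s_shift.max(axis=1, keepdims=True)
    ex = np.where(mask > 0, np.exp(s_shift), 0.0)
    a = ex / ex.sum(axis=1, keepdims=True)
    z = np.einsum("bl,blh->bh", a, h)
    if cache is not None:
        cache.update(h=h, t=t, g=g, e=e, a=a, mask=mask)
    return z, a


def classify(z: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """Linear classification head: bag vector -> K logits."""
    return z @ params["Wc"] + params["bc"]


def forward(
    batch: BagBatch,
    params: dict[str, np.ndarray],
    *,
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    cache: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full forward pass; returns (logits (B, K), attention (B, L))."""
    enc_cache: Optional[dict] = {} if cache is not None else None
    att_cache: Optional[dict] = {} if cache is not None else None
    h = encode_instances(batch.embeddings, params, dropout=dropout, rng=rng, cache=enc_cache)
    z, a = gated_attention_pool(h, batch.mask, params, cache=att_cache)
    logits = classify(z, params)
    if cache is not None:
        cache.update(enc=enc_cache, att=att_cache, z=z)
    return logits, a


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def focal_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: Optional[np.ndarray] = None,
    gamma: float = 2.0,
) -> float:
    """Mean focal loss: ``-w_y (1 - p_y)^gamma log p_y``.

    At ``gamma = 0`` this is exactly weighted cross-entropy; as the
    true-class probability approaches 1 the loss vanishes faster than
    cross-entropy, down-weighting easy examples.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    logp = _log_softmax(logits)
    idx = np.arange(len(labels))
    logp_y = logp[idx, labels]
    p_y = np.exp(logp_y)
    w = np.ones(len(labels)) if class_weights is None else np.asarray(class_weights)[labels]
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    return float(np.mean(-w * (1.0 - p_y) ** gamma * logp_y))


def focal_loss_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: Optional[np.ndarray] = None,
    gamma: float = 2.0,
) -> np.ndarray:
    """Analytic gradient of :func:`focal_loss` w.r.t. the logits."""
    logp = _log_softmax(logits)
    p = np.exp(logp)
    idx = np.arange(len(labels))
    q = p[idx, labels]
    logq = logp[idx, labels]
    w = np.ones(len(labels)) if class_weights is None else np.asarray(class_weights)[labels]
    # dL/dq for one sample; the gamma term vanishes identically at gamma=0
    one_m_q = np.maximum(1.0 - q, 0.0)
    if gamma == 0.0:
        dL_dq = -w / q
    else:
        dL_dq = w * gamma * one_m_q ** (gamma - 1.0) * logq - w * one_m_q**gamma / q
    onehot = np.zeros_like(p)
    onehot[idx, labels] = 1.0
    dlogits = dL_dq[:, None] * q[:, None] * (onehot - p)
    return dlogits / len(labels)


def dynamic_class_weights(
    class_counts: np.ndarray | list[int], eps: float = 1.0
) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    ``w_c ∝ N / (K * (n_c + eps))`` computed from the current epoch's
    training label counts; the smoothing ``eps`` keeps weights finite
    for empty classes.  Balanced counts give all-ones.
    """
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    w = 1.0 / (counts + eps)
    return w / w.mean()


# ---------------------------------------------------------------------------
# Backward pass
# ---------------------------------------------------------------------------


def backward(
    batch: BagBatch,
    params: dict[str, np.ndarray],
    cache: dict,
    dlogits: np.ndarray,
) -> dict[str, np.ndarray]:
    """Backpropagate ``dlogits`` through classifier, attention pooling,
    layer norm and the encoder MLP.  ``cache`` is the dict filled by
    :func:`forward`.  Returns gradients keyed like ``params``.
    """
    enc, att = cache["enc"], cache["att"]
    h, t, g, e, a, mask = att["h"], att["t"], att["g"], att["e"], att["a"], att["mask"]
    z = cache["z"]

    grads: dict[str, np.ndarray] = {}
    # classifier
    grads["Wc"] = z.T @ dlogits
    grads["bc"] = dlogits.sum(axis=0)
    dz = dlogits @ params["Wc"].T  # (B, H)

    # pooling: z = sum_k a_k h_k
    da = np.einsum("bh,blh->bl", dz, h)
    dh = a[..., None] * dz[:, None, :]
    # masked softmax backward (a is 0 at pads, so ds is 0 there too)
    ds = a * (da - (a * da).sum(axis=1, keepdims=True))
    # attention score s = (t*g) @ w
    de = ds[..., None] * params["w"]
    dt = de * g
    dg = de * t
    dpre_t = dt * (1.0 - t**2)
    dpre_g = dg * g * (1.0 - g)
    grads["V"] = np.einsum("bla,blh->ah", dpre_t, h)
    grads["U"] = np.einsum("bla,blh->ah", dpre_g, h)
    grads["w"] = np.einsum("bla,bl->a", e, ds)
    dh = dh + dpre_t @ params["V"] + dpre_g @ params["U"]
    dh = dh * mask[..., None]  # pads contribute nothing upstream

    # layer norm backward
    xhat, inv_std = enc["xhat"], enc["inv_std"]
    grads["ln_g"] = (dh * xhat).sum(axis=(0, 1))
    grads["ln_b"] = dh.sum(axis=(0, 1))
    dxhat = dh * params["ln_g"]
    dd2 = inv_std * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )

    # encoder MLP backward
    m2, z2, d1 = enc["m2"], enc["z2"], enc["d1"]
    dr2 = dd2 * m2 if m2 is not None else dd2
    dz2 = dr2 * (z2 > 0)
    grads["W2"] = np.einsum("bld,blh->dh", d1, dz2)
    grads["b2"] = dz2.sum(axis=(0, 1))
    dd1 = dz2 @ params["W2"].T
    m1, z1, x = enc["m1"], enc["z1"], enc["x"]
    dr1 = dd1 * m1 if m1 is not None else dd1
    dz1 = dr1 * (z1 > 0)
    grads["W1"] = np.einsum("bld,blh->dh", x, dz1)
    grads["b1"] = dz1.sum(axis=(0, 1))
    return grads


def loss_and_grads(
    batch: BagBatch,
    params: dict[str, np.ndarray],
    *,
    class_weights: Optional[np.ndarray] = None,
    gamma: float = 2.0,
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """One forward/backward pass; returns (loss, grads, attention)."""
    cache: dict = {}
    logits, a = forward(batch, params, dropout=dropout, rng=rng, cache=cache)
    loss = focal_loss(logits, batch.labels, class_weights, gamma)
    dlogits = focal_loss_grad(logits, batch.labels, class_weights, gamma)
    grads = backward(batch, params, cache, dlogits)
    return loss, grads, a


@dataclass
class AdamState:
    """Adam optimizer with bias correction."""

    lr: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, gr in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(gr)
                self.v[key] = np.zeros_like(gr)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * gr
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * gr**2
            mhat = self.m[key] / (1 - self.beta1**self.t)
            vhat = self.v[key] / (1 - self.beta2**self.t)
            params[key] = params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
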