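"""Neural-network building blocks on top of the autodiff engine.

All layers are mask-aware: token 0 is padding, padded positions are zeroed
after every convolution, pooled masks propagate through max pooling, the
LSTM freezes its state across masked steps, and attention assigns padded
keys a large negative score before the softmax.  Together these make the
forward pass exactly invariant to the amount of trailing padding.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate, embedding, softmax, stack


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def embed_masked(weight: Tensor, ids: np.ndarray, mask: np.ndarray) -> Tensor:
    """Embedding lookup with padded positions forced to zero vectors."""
    return embedding(weight, ids) * mask[..., None]


def dropout(x: Tensor, p: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    if not training or p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * keep


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor, kernel_size: int,
                mask: np.ndarray) -> Tensor:
    """1-D convolution over axis 1, stride 1, zero 'same' padding.

    ``weight`` has shape (kernel_size * C_in, C_out).  The output is
    re-masked so positions past the true length stay exactly zero.
    """
    B, L, c_in = x.shape
    pad_left = (kernel_size - 1) // 2
    pad_right = kernel_size - 1 - pad_left
    xp = x.pad_axis(1, pad_left, pad_right)
    terms = []
    for j in range(kernel_size):
        w_j = weight[j * c_in:(j + 1) * c_in]
        terms.append(xp[:, j:j + L, :] @ w_j)
    y = terms[0]
    for t in terms[1:]:
        y = y + t
    y = (y + bias).relu()
    return y * mask[..., None]


def maxpool1d(x: Tensor, pool: int, mask: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Ceil max pooling with fixed window boundaries (stride = window).

    The sequence is zero-padded up to a multiple of ``pool`` so real
    positions are never dropped and window boundaries do not depend on the
    amount of padding.  Returns the pooled tensor and the pooled mask
    (1 where any window position was real).
    """
    B, L, C = x.shape
    L_out = -(-L // pool)
    extra = L_out * pool - L
    if extra:
        x = x.pad_axis(1, 0, extra)
        mask = np.pad(mask, ((0, 0), (0, extra)))
    pooled = x.reshape(B, L_out, pool, C).max(axis=2)
    pooled_mask = mask.reshape(B, L_out, pool).max(axis=2)
    return pooled * pooled_mask[..., None], pooled_mask


def lstm_direction(x: Tensor, mask: np.ndarray, wx: Tensor, wh: Tensor,
                   b: Tensor, hidden: int, reverse: bool) -> tuple[Tensor, Tensor]:
    """One LSTM direction with masked state updates.

    Returns (outputs (B, T, H), final hidden state (B, H)).  At masked
    steps the hidden and cell states carry over unchanged (and the output
    is zero), so trailing padding cannot perturb the recurrence.
    """
    B, T, _ = x.shape
    if reverse:
        x = x.flip(1)
        mask = mask[:, ::-1]
    h = Tensor(np.zeros((B, hidden)))
    c = Tensor(np.zeros((B, hidden)))
    outputs = []
    for t in range(T):
        m = mask[:, t:t + 1]  # (B, 1) constant
        gates = x[:, t, :] @ wx + h @ wh + b
        i = gates[:, :hidden].sigmoid()
        f = gates[:, hidden:2 * hidden].sigmoid()
        g = gates[:, 2 * hidden:3 * hidden].tanh()
        o = gates[:, 3 * hidden:].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        c = c_new * m + c * (1.0 - m)
        h = h_new * m + h * (1.0 - m)
        outputs.append(h * m)
    out = stack(outputs, axis=1)
    if reverse:
        out = out.flip(1)
    return out, h


def bilstm(x: Tensor, mask: np.ndarray, params: dict, prefix: str,
           hidden: int) -> tuple[Tensor, Tensor]:
    """Bidirectional LSTM with per-position combination.

    The forward and backward output sequences Cf, Cb are combined per
    position as Hm = tanh(Cf W4 + Cb W6); the summary vector H concatenates
    the final forward and backward hidden states (2 * hidden dims).
    """
    cf, h_fwd = lstm_direction(x, mask, params[f"{prefix}.wx_f"],
                               params[f"{prefix}.wh_f"], params[f"{prefix}.b_f"],
                               hidden, reverse=False)
    cb, h_bwd = lstm_direction(x, mask, params[f"{prefix}.wx_b"],
                               params[f"{prefix}.wh_b"], params[f"{prefix}.b_b"],
                               hidden, reverse=True)
    hm = (cf @ params[f"{prefix}.w4"] + cb @ params[f"{prefix}.w6"]).tanh()
    hm = hm * mask[..., None]
    h_summary = concatenate([h_fwd, h_bwd], axis=-1)
    return hm, h_summary


def self_attention_pool(hm: Tensor, mask: np.ndarray, wq: Tensor, wk: Tensor,
                        wv: Tensor, scaled: bool = False) -> tuple[Tensor, np.ndarray]:
    """Single-head self-attention over Hm, mean-pooled to one vector.

    Q = Hm Wq, K = Hm Wk, V = Hm Wv; raw scores are the query-key dot
    products, padded keys receive a large negative score before the softmax
    (normalization over the key axis, so each query's weights sum to 1);
    the attended sequence is mean-pooled over unmasked query positions.

    Returns the pooled output (B, d_attn) and the attention-weight matrix
    (B, T, T) as a plain array for inspection.
    """
    if mask.sum() == 0:
        raise ValueError("attention requires at least one unmasked position")
    q = hm @ wq
    k = hm @ wk
    v = hm @ wv
    scores = q @ k.swapaxes(-1, -2)  # (B, T_query, T_key)
    if scaled:
        scores = scores * (1.0 / np.sqrt(wq.shape[-1]))
    key_bias = (mask[:, None, :] - 1.0) * 1e9
    scores = scores + key_bias
    attn = softmax(scores, axis=-1)
    context = attn @ v  # (B, T, d_attn)
    lengths = mask.sum(axis=1, keepdims=True)
    pooled = (context * mask[..., None]).sum(axis=1) / lengths
    return pooled, attn.data


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return x @ w + b


class Adam:
    """Adaptive-moment gradient descent over a parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad ** 2
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
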