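"""Two-layer (sequence + subregion) ALiBi transformer classifier.

The encoder is a BERT-style post-norm transformer whose positional
information enters only through ALiBi: head ``i`` adds a bias
``-slope_i * |q - k|`` with geometric slopes ``slope_i = 2^(-8 i / h)`` to its
attention logits.  The bias is symmetric (non-causal) since the encoder is
bidirectional.  The CLS hidden state feeds a linear+sigmoid sequence head;
the remaining token states are merged into subregions (non-overlapping
mean- and max-pooling over ``m`` adjacent tokens, concatenated and projected
back to ``d_h``) and feed a linear+sigmoid subregion head.

The training objective mixes a plain binary cross-entropy over sequence
labels with a validity-masked, positive-reweighted cross-entropy over
subregion labels: ``L = lambda * l_sequence + (1 - lambda) * l_token``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .autograd import (Tensor, concatenate, embedding, layer_norm, softmax,
                       stack)
from .tokenizer import N_SPECIAL, DEFAULT_N_T

PROB_EPS = 1e-7  # probability clamp so logit/log stay finite
_MASK_NEG = -1e9


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and loss hyperparameters.

    Defaults follow the full-scale configuration (768 hidden units, 12
    layers, 12 heads, n_t = 60, pooling window m = 20, lambda = 0.2);
    :meth:`tiny` gives a desk-scale preset trainable from scratch on a CPU.
    """

    d_h: int = 768
    n_layers: int = 12
    h: int = 12
    n_t: int = DEFAULT_N_T
    m: int = 20
    lam: float = 0.2
    dropout: float = 0.1
    vocab_size: int = 4096  # content tokens; embedding adds 4 special rows
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_h % self.h != 0:
            raise ValueError("d_h must be divisible by h")
        if not 1 <= self.m <= self.n_t - 1:
            raise ValueError(f"m must be in [1, n_t-1], got {self.m}")
        if not 0.0 < self.lam < 1.0:
            raise ValueError("lambda must be in (0, 1)")

    @property
    def d_k(self) -> int:
        return self.d_h // self.h

    @property
    def n_subregions(self) -> int:
        """ceil((n_t - 1) / m): CLS is excluded before pooling."""
        return -(-(self.n_t - 1) // self.m)

    @classmethod
    def tiny(cls, **kw) -> "ModelConfig":
        kw.setdefault("d_h", 64)
        kw.setdefault("n_layers", 2)
        kw.setdefault("h", 4)
        return cls(**kw)


@dataclass
class Predictions:
    """Sequence probability p_i and subregion probabilities p_{i,t}."""

    p_seq: np.ndarray  # (B,)
    p_sub: np.ndarray  # (B, n_subregions)


def alibi_bias(n_t: int, h: int) -> np.ndarray:
    """Per-head symmetric ALiBi bias matrices, shape (h, n_t, n_t).

    ``B_i[q, k] = -slope_i * |q - k|`` with ``slope_i = 2^(-8 i / h)`` for
    heads i = 1..h; content-independent and zero on the diagonal.
    """
    if n_t < 1 or h < 1:
        raise ValueError("n_t and h must be >= 1")
    slopes = 2.0 ** (-8.0 * np.arange(1, h + 1) / h)
    dist = np.abs(np.arange(n_t)[:, None] - np.arange(n_t)[None, :])
    return -slopes[:, None, None] * dist[None, :, :]


def _glorot(rng: np.random.Generator, shape, dtype=np.float32) -> np.ndarray:
    scale = np.sqrt(2.0 / sum(shape[-2:])) if len(shape) >= 2 else 0.02
    return (rng.standard_normal(shape) * scale).astype(dtype)


class Model:
    """Parameter container plus forward pass."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        d, f = cfg.d_h, 4 * cfg.d_h
        p: dict[str, Tensor] = {}
        p["embed"] = Tensor(
            (rng.standard_normal((cfg.vocab_size + N_SPECIAL, d)) * 0.02)
            .astype(dtype), requires_grad=True)
        for i in range(cfg.n_layers):
            p[f"l{i}.Wq"] = Tensor(_glorot(rng, (d, d), dtype), requires_grad=True)
            p[f"l{i}.Wk"] = Tensor(_glorot(rng, (d, d), dtype), requires_grad=True)
            p[f"l{i}.Wv"] = Tensor(_glorot(rng, (d, d), dtype), requires_grad=True)
            p[f"l{i}.Wo"] = Tensor(_glorot(rng, (d, d), dtype), requires_grad=True)
            p[f"l{i}.ln1.g"] = Tensor(np.ones(d, dtype), requires_grad=True)
            p[f"l{i}.ln1.b"] = Tensor(np.zeros(d, dtype), requires_grad=True)
            p[f"l{i}.W1"] = Tensor(_glorot(rng, (d, f), dtype), requires_grad=True)
            p[f"l{i}.b1"] = Tensor(np.zeros(f, dtype), requires_grad=True)
            p[f"l{i}.W2"] = Tensor(_glorot(rng, (f, d), dtype), requires_grad=True)
            p[f"l{i}.b2"] = Tensor(np.zeros(d, dtype), requires_grad=True)
            p[f"l{i}.ln2.g"] = Tensor(np.ones(d, dtype), requires_grad=True)
            p[f"l{i}.ln2.b"] = Tensor(np.zeros(d, dtype), requires_grad=True)
        p["seq.w"] = Tensor(_glorot(rng, (d, 1), dtype), requires_grad=True)
        p["seq.b"] = Tensor(np.zeros(1, dtype), requires_grad=True)
        p["Wc"] = Tensor(_glorot(rng, (2 * d, d), dtype), requires_grad=True)
        p["sub.w"] = Tensor(_glorot(rng, (d, 1), dtype), requires_grad=True)
        p["sub.b"] = Tensor(np.zeros(1, dtype), requires_grad=True)
        self.params = p
        self._alibi = alibi_bias(cfg.n_t, cfg.h).astype(dtype)

    # -- forward ----------------------------------------------------------
    def hidden_states(self, ids: np.ndarray, mask: np.ndarray,
                      training: bool = False,
                      rng: Optional[np.random.Generator] = None) -> Tensor:
        """Run the encoder stack; returns final states, shape (B, n_t, d_h)."""
        cfg, p = self.cfg, self.params
        ids = np.atleast_2d(ids)
        mask = np.atleast_2d(mask)
        if ids.shape[1] != cfg.n_t:
            raise ValueError(f"ids must have n_t={cfg.n_t} columns")
        B = ids.shape[0]
        x = embedding(p["embed"], ids)
        key_bias = np.where(mask[:, None, None, :] > 0, 0.0, _MASK_NEG) \
            .astype(self.dtype)
        scale = 1.0 / math.sqrt(cfg.d_k)  # python float: keeps float32

        def dropout(t: Tensor) -> Tensor:
            if not training or cfg.dropout <= 0 or rng is None:
                return t
            keep = (rng.random(t.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            return t * keep.astype(self.dtype)

        for i in range(cfg.n_layers):
            q = (x @ p[f"l{i}.Wq"]).reshape(B, cfg.n_t, cfg.h, cfg.d_k) \
                .transpose(0, 2, 1, 3)
            k = (x @ p[f"l{i}.Wk"]).reshape(B, cfg.n_t, cfg.h, cfg.d_k) \
                .transpose(0, 2, 1, 3)
            v = (x @ p[f"l{i}.Wv"]).reshape(B, cfg.n_t, cfg.h, cfg.d_k) \
                .transpose(0, 2, 1, 3)
            scores = (q @ k.transpose(0, 1, 3, 2)) * scale \
                + self._alibi[None] + key_bias
            att = softmax(scores, axis=-1)
            ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, cfg.n_t, cfg.d_h)
            x = layer_norm(x + dropout(ctx @ p[f"l{i}.Wo"]),
                           p[f"l{i}.ln1.g"], p[f"l{i}.ln1.b"])
            ff = ((x @ p[f"l{i}.W1"] + p[f"l{i}.b1"]).gelu()
                  @ p[f"l{i}.W2"] + p[f"l{i}.b2"])
            x = layer_norm(x + dropout(ff),
                           p[f"l{i}.ln2.g"], p[f"l{i}.ln2.b"])
        return x

    def forward_tensors(self, ids: np.ndarray, mask: np.ndarray,
                        training: bool = False,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[Tensor, Tensor]:
        """Both heads as autograd tensors: (p_seq (B,), p_sub (B, n_hat))."""
        cfg, p = self.cfg, self.params
        hid = self.hidden_states(ids, mask, training, rng)
        cls = hid[:, 0, :]
        p_seq = (cls @ p["seq.w"] + p["seq.b"]).reshape(-1).sigmoid()
        # non-CLS tokens feed the pooling; PAD states are zeroed so padding
        # content can never leak into subregion scores
        mask = np.atleast_2d(mask)
        mt = hid[:, 1:, :] * mask[:, 1:, None].astype(self.dtype)
        mm = merge_tokens(mt, cfg.m, p["Wc"])
        p_sub = (mm @ p["sub.w"] + p["sub.b"]) \
            .reshape(-1, cfg.n_subregions).sigmoid()
        return p_seq, p_sub

    def predict(self, ids: np.ndarray, mask: np.ndarray,
                batch_size: int = 256) -> Predictions:
        ids = np.atleast_2d(ids)
        mask = np.atleast_2d(mask)
        ps, pt = [], []
        for a in range(0, ids.shape[0], batch_size):
            s, t = self.forward_tensors(ids[a:a + batch_size],
                                        mask[a:a + batch_size])
            ps.append(s.data)
            pt.append(t.data)
            s.release()
            t.release()
        return Predictions(p_seq=np.concatenate(ps), p_sub=np.concatenate(pt))

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.asarray(state[k], dtype=self.dtype)

    def save(self, path: Path | str) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.cfg)),
                 **self.state_dict())

    @classmethod
    def load(cls, path: Path | str) -> "Model":
        with np.load(path, allow_pickle=False) as z:
            cfg = ModelConfig(**json.loads(str(z["__config__"])))
            model = cls(cfg)
            model.load_state_dict({k: z[k] for k in z.files
                                   if k != "__config__"})
        return model


def encoder_forward(ids: np.ndarray, mask: np.ndarray,
                    model: Model) -> np.ndarray:
    """Final encoder hidden states as a plain array, shape (B, n_t, d_h)."""
    return model.hidden_states(ids, mask).data


def merge_tokens(mt: Tensor, m: int, wc: Tensor) -> Tensor:
    """Merge adjacent token states into subregion states.

    Window ``t`` covers rows [t*m, (t+1)*m) of ``mt`` (the final window may be
    partial); its mean- and max-pooled vectors are concatenated (2*d_h) and
    projected by ``wc`` back to d_h.
    """
    if not isinstance(mt, Tensor):
        mt = Tensor(mt)
    if not isinstance(wc, Tensor):
        wc = Tensor(wc)
    T = mt.shape[-2]
    if not 1 <= m <= T:
        raise ValueError(f"pooling window m={m} out of range [1, {T}]")
    rows = []
    for a in range(0, T, m):
        win = mt[:, a:a + m, :] if mt.ndim == 3 else mt[a:a + m, :]
        ax = 1 if mt.ndim == 3 else 0
        rows.append(concatenate([win.mean(axis=ax), win.max(axis=ax)],
                                axis=-1))
    pooled = stack(rows, axis=-2)
    return pooled @ wc


# -- losses ---------------------------------------------------------------
def _lift_prob(p) -> tuple[Tensor, np.dtype]:
    """Clamped probability tensor plus the dtype the loss should use.

    Tensor inputs keep their dtype (float32 during training); raw arrays are
    promoted to float64 so reference computations are exact.
    """
    t = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    return t.clip(PROB_EPS, 1.0 - PROB_EPS), t.data.dtype


def sequence_loss(y, p) -> Tensor:
    """Mean binary cross-entropy over sequence labels."""
    p, dt = _lift_prob(p)
    y = np.asarray(y, dtype=dt)
    if y.size == 0:
        raise ValueError("empty batch")
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -ll.mean()


def token_loss(y, p, V) -> Tensor:
    """Validity-masked, positive-reweighted BCE over subregions.

    The positive-class weight ``w`` is the ratio of valid negatives to valid
    positives in the batch, falling back to the valid-negative count when the
    batch holds no valid positive subregion.
    """
    p, dt = _lift_prob(p)
    y = np.asarray(y, dtype=dt)
    V = np.asarray(V, dtype=dt)
    if y.shape != V.shape:
        raise ValueError("y and V must have the same shape")
    n_valid = float(V.sum())
    if n_valid == 0:
        raise ValueError("no valid subregions in batch")
    n_pos = float((V * y).sum())
    n_neg = float((V * (1.0 - y)).sum())
    w = (n_neg / n_pos) if n_pos > 0 else n_neg
    ll = Tensor(V) * (w * Tensor(y) * p.log()
                      + Tensor(1.0 - y) * (1.0 - p).log())
    return -ll.sum() * (1.0 / n_valid)


def combined_loss(l_seq, l_tok, lam: float = 0.2) -> Tensor:
    """Convex combination lambda * l_sequence + (1 - lambda) * l_token."""
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must be in (0, 1)")
    l_seq = l_seq if isinstance(l_seq, Tensor) else Tensor(np.float64(l_seq))
    l_tok = l_tok if isinstance(l_tok, Tensor) else Tensor(np.float64(l_tok))
    return lam * l_seq + (1.0 - lam) * l_tok


def logit(p: np.ndarray | float) -> np.ndarray | float:
    """log-odds with the module-wide probability clamp."""
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return np.log(p / (1.0 - p))
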