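"""Bidirectional transformer encoder with a contiguous-k-mer masked-LM objective.

The encoder is the standard post-norm BERT block: multi-head scaled
dot-product self-attention, residual + layer norm, position-wise GELU
feed-forward, residual + layer norm, repeated L times over token + learned
position embeddings. Training masks runs of k contiguous k-mer tokens
(about 15% of each chunk's content), replaces them with [MASK], and
minimizes mean cross-entropy of the original tokens at the masked
positions, optimized with AdamW (decoupled weight decay) and dropout on
the final hidden states feeding the MLM head.

Everything, including backpropagation, is implemented directly on numpy
arrays; the backward pass is validated against finite differences in the
test suite. The per-sequence feature is the final-layer [CLS] state of each
chunk — 64-dimensional with the default width — aggregated over chunks by a
content-length-weighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import erf

from .tokenizer import (
    CLS_ID,
    MASK_ID,
    MAX_POSITIONS,
    PAD_ID,
    SEP_ID,
    TokenizedDoc,
    Vocabulary,
)

_INIT_STD = 0.02
_LN_EPS = 1e-8


@dataclass
class EncoderConfig:
    """Architecture and masking hyper-parameters.

    d_model must be divisible by n_heads; d_out is the width of the exported
    sequence feature (when equal to d_model the final [CLS] hidden state is
    used directly, otherwise a linear projection head maps onto d_out).
    """

    vocab_size: int
    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 64
    d_ff: int = 128
    d_out: int = 64
    dropout: float = 0.1
    mask_rate: float = 0.15
    k: int = 3

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 < self.mask_rate < 1:
            raise ValueError("mask_rate must be in (0, 1)")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class OptimizerSettings:
    """AdamW settings; weight decay is applied to matrices only (not to
    biases or layer-norm parameters)."""

    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 16


@dataclass
class EncoderModel:
    config: EncoderConfig
    params: dict[str, np.ndarray]
    trained: bool = False
    loss_trace: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        import json

        path = Path(path)
        np.savez(path, **self.params)
        cfg = {k: getattr(self.config, k) for k in (
            "vocab_size", "n_layers", "n_heads", "d_model", "d_ff",
            "d_out", "dropout", "mask_rate", "k")}
        cfg["trained"] = self.trained
        cfg["loss_trace"] = self.loss_trace
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(cfg, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        import json

        path = Path(path)
        npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
        with open(Path(npz).with_suffix(".json")) as fh:
            cfg = json.load(fh)
        trained = cfg.pop("trained")
        trace = cfg.pop("loss_trace")
        params = dict(np.load(npz))
        return cls(config=EncoderConfig(**cfg), params=params,
                   trained=trained, loss_trace=trace)


@dataclass
class MaskedBatch:
    """MLM training view of one or more chunks.

    ``input_ids`` has masked positions replaced by [MASK]; ``labels`` holds
    the original token id at masked positions and -1 elsewhere.
    """

    input_ids: np.ndarray
    attention_masks: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if (self.labels >= 0).sum() == 0:
            raise ValueError("masked batch contains no masked positions")


def init_model(cfg: EncoderConfig, seed: int) -> EncoderModel:
    """Gaussian(0, 0.02) weights, zero biases, unit layer-norm gains."""
    rng = np.random.default_rng(seed)
    D, F, V = cfg.d_model, cfg.d_ff, cfg.vocab_size
    p: dict[str, np.ndarray] = {
        "tok_emb": rng.normal(0.0, _INIT_STD, (V, D)),
        "pos_emb": rng.normal(0.0, _INIT_STD, (MAX_POSITIONS, D)),
    }
    for i in range(cfg.n_layers):
        for w in ("Wq", "Wk", "Wv", "Wo"):
            p[f"l{i}.{w}"] = rng.normal(0.0, _INIT_STD, (D, D))
        for b in ("bq", "bk", "bv", "bo"):
            p[f"l{i}.{b}"] = np.zeros(D)
        p[f"l{i}.ln1_g"] = np.ones(D)
        p[f"l{i}.ln1_b"] = np.zeros(D)
        p[f"l{i}.W1"] = rng.normal(0.0, _INIT_STD, (D, F))
        p[f"l{i}.b1"] = np.zeros(F)
        p[f"l{i}.W2"] = rng.normal(0.0, _INIT_STD, (F, D))
        p[f"l{i}.b2"] = np.zeros(D)
        p[f"l{i}.ln2_g"] = np.ones(D)
        p[f"l{i}.ln2_b"] = np.zeros(D)
    p["mlm_W"] = rng.normal(0.0, _INIT_STD, (D, V))
    p["mlm_b"] = np.zeros(V)
    if cfg.d_out != cfg.d_model:
        p["proj_W"] = rng.normal(0.0, _INIT_STD, (D, cfg.d_out))
        p["proj_b"] = np.zeros(cfg.d_out)
    return EncoderModel(config=cfg, params=p)


# ---------------------------------------------------------------------------
# primitive blocks


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0))) + x * phi


def masked_softmax(scores: np.ndarray, key_mask: np.ndarray) -> np.ndarray:
    """Row-wise softmax over positions where ``key_mask`` is 1.

    Padding key positions are excluded from the normalization (equivalent to
    a -inf score); a row with no valid key yields an all-zero row.
    """
    valid = key_mask.astype(bool)
    neg = np.where(valid, scores, -np.inf)
    m = np.max(np.where(valid, scores, -np.inf), axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.where(valid, np.exp(neg - m), 0.0)
    denom = e.sum(axis=-1, keepdims=True)
    return e / np.maximum(denom, 1e-300)


def attention_head(
    M: np.ndarray,
    Wq: np.ndarray,
    Wk: np.ndarray,
    Wv: np.ndarray,
    attn_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Single scaled dot-product attention head on a (T, d) state matrix.

    softmax(M Wq (M Wk)^T / sqrt(d_k)) . M Wv with padding keys excluded;
    each output row is a convex combination of rows of M Wv.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or Wq.shape[0] != M.shape[1]:
        raise ValueError("shape mismatch between M and projections")
    if Wq.shape != Wk.shape or Wv.shape[0] != M.shape[1]:
        raise ValueError("inconsistent projection shapes")
    T = M.shape[0]
    mask = np.ones(T) if attn_mask is None else np.asarray(attn_mask)
    if mask.shape != (T,):
        raise ValueError("attn_mask must have one entry per position")
    q, k, v = M @ Wq, M @ Wk, M @ Wv
    scores = q @ k.T / math.sqrt(Wq.shape[1])
    w = masked_softmax(scores, mask[None, :].repeat(T, axis=0))
    return w @ v


def multi_head(
    M: np.ndarray, layer_weights: dict[str, np.ndarray], attn_mask: np.ndarray | None = None
) -> np.ndarray:
    """Concat(head_1..head_h) W^O on a (T, d_model) state matrix.

    ``layer_weights`` holds "Wq","Wk","Wv" as (h, d_model, d_k) stacks and
    "Wo" as (d_model, d_model).
    """
    heads = [
        attention_head(M, layer_weights["Wq"][i], layer_weights["Wk"][i],
                       layer_weights["Wv"][i], attn_mask)
        for i in range(layer_weights["Wq"].shape[0])
    ]
    return np.concatenate(heads, axis=1) @ layer_weights["Wo"]


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


# ---------------------------------------------------------------------------
# full forward / backward


def _split_heads(x: np.ndarray, h: int) -> np.ndarray:
    B, T, D = x.shape
    return x.reshape(B, T, h, D // h).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    B, h, T, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)


def encoder_forward(
    model: EncoderModel, input_ids: np.ndarray, attn_mask: np.ndarray
) -> tuple[np.ndarray, list]:
    """Run the encoder stack; returns final hidden states (B, T, D) + caches."""
    cfg, p = model.config, model.params
    B, T = input_ids.shape
    x = p["tok_emb"][input_ids] + p["pos_emb"][:T]
    caches = []
    key_mask = attn_mask[:, None, None, :]  # broadcast over heads and queries
    scale = 1.0 / math.sqrt(cfg.d_k)
    for i in range(cfg.n_layers):
        pre = f"l{i}."
        q = _split_heads(x @ p[pre + "Wq"] + p[pre + "bq"], cfg.n_heads)
        k = _split_heads(x @ p[pre + "Wk"] + p[pre + "bk"], cfg.n_heads)
        v = _split_heads(x @ p[pre + "Wv"] + p[pre + "bv"], cfg.n_heads)
        scores = np.einsum("bhqd,bhkd->bhqk", q, k) * scale
        w = masked_softmax(scores, np.broadcast_to(key_mask, scores.shape))
        att = np.einsum("bhqk,bhkd->bhqd", w, v)
        concat = _merge_heads(att)
        o = concat @ p[pre + "Wo"] + p[pre + "bo"]
        r1 = x + o
        y1, ln1_cache = _layer_norm(r1, p[pre + "ln1_g"], p[pre + "ln1_b"])
        z1 = y1 @ p[pre + "W1"] + p[pre + "b1"]
        a1 = _gelu(z1)
        f = a1 @ p[pre + "W2"] + p[pre + "b2"]
        r2 = y1 + f
        y2, ln2_cache = _layer_norm(r2, p[pre + "ln2_g"], p[pre + "ln2_b"])
        caches.append((x, q, k, v, w, concat, ln1_cache, y1, z1, a1, ln2_cache))
        x = y2
    return x, caches


def mlm_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of true token ids under softmax(logits).

    ``logits`` is (n_masked, vocab) for the masked positions only; ``labels``
    the matching token ids.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if logits.ndim != 2 or logits.shape[0] != labels.shape[0]:
        raise ValueError("logits/labels shape mismatch")
    if logits.shape[0] == 0:
        raise ValueError("loss undefined with zero masked positions")
    m = logits.max(axis=1, keepdims=True)
    logz = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
    return float(np.mean(logz - logits[np.arange(len(labels)), labels]))


def loss_and_grads(
    model: EncoderModel,
    batch: MaskedBatch,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Forward + full backward pass over one masked batch.

    Dropout (inverted, on the hidden states feeding the MLM output head) is
    active only when ``dropout_rng`` is given.
    """
    cfg, p = model.config, model.params
    ids, attn_mask, labels = batch.input_ids, batch.attention_masks, batch.labels
    B, T = ids.shape
    h, caches = encoder_forward(model, ids, attn_mask)

    mask_pos = labels >= 0
    hm = h[mask_pos]  # (N, D)
    y = labels[mask_pos]
    drop_mask = None
    if dropout_rng is not None and cfg.dropout > 0.0:
        keep = 1.0 - cfg.dropout
        drop_mask = (dropout_rng.random(hm.shape) < keep) / keep
        hm = hm * drop_mask
    logits = hm @ p["mlm_W"] + p["mlm_b"]
    loss = mlm_loss(logits, y)
    if not np.isfinite(loss):
        raise FloatingPointError(f"MLM loss diverged (loss={loss})")

    grads = {name: np.zeros_like(arr) for name, arr in p.items()}
    N = len(y)
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    probs = e / e.sum(axis=1, keepdims=True)
    dlogits = probs
    dlogits[np.arange(N), y] -= 1.0
    dlogits /= N
    grads["mlm_W"] += hm.T @ dlogits
    grads["mlm_b"] += dlogits.sum(axis=0)
    dhm = dlogits @ p["mlm_W"].T
    if drop_mask is not None:
        dhm = dhm * drop_mask
    dh = np.zeros_like(h)
    dh[mask_pos] = dhm

    scale = 1.0 / math.sqrt(cfg.d_k)
    dx = dh
    for i in reversed(range(cfg.n_layers)):
        pre = f"l{i}."
        x, q, k, v, w, concat, ln1_cache, y1, z1, a1, ln2_cache = caches[i]
        dr2, dg2, db2 = _layer_norm_backward(dx, ln2_cache, p[pre + "ln2_g"])
        grads[pre + "ln2_g"] += dg2
        grads[pre + "ln2_b"] += db2
        df = dr2
        dy1 = dr2.copy()
        # feed-forward
        grads[pre + "W2"] += a1.reshape(-1, cfg.d_ff).T @ df.reshape(-1, cfg.d_model)
        grads[pre + "b2"] += df.sum(axis=(0, 1))
        da1 = df @ p[pre + "W2"].T
        dz1 = da1 * _gelu_grad(z1)
        grads[pre + "W1"] += y1.reshape(-1, cfg.d_model).T @ dz1.reshape(-1, cfg.d_ff)
        grads[pre + "b1"] += dz1.sum(axis=(0, 1))
        dy1 += dz1 @ p[pre + "W1"].T
        dr1, dg1, db1 = _layer_norm_backward(dy1, ln1_cache, p[pre + "ln1_g"])
        grads[pre + "ln1_g"] += dg1
        grads[pre + "ln1_b"] += db1
        dx = dr1.copy()
        do = dr1
        # attention output projection
        grads[pre + "Wo"] += concat.reshape(-1, cfg.d_model).T @ do.reshape(-1, cfg.d_model)
        grads[pre + "bo"] += do.sum(axis=(0, 1))
        datt = _split_heads(do @ p[pre + "Wo"].T, cfg.n_heads)
        dw = np.einsum("bhqd,bhkd->bhqk", datt, v)
        dv = np.einsum("bhqk,bhqd->bhkd", w, datt)
        dscores = w * (dw - (dw * w).sum(axis=-1, keepdims=True))
        dq = np.einsum("bhqk,bhkd->bhqd", dscores, k) * scale
        dk = np.einsum("bhqk,bhqd->bhkd", dscores, q) * scale
        for name, grad in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
            g2 = _merge_heads(grad)
            grads[pre + "W" + name[1]] += x.reshape(-1, cfg.d_model).T @ g2.reshape(-1, cfg.d_model)
            grads[pre + "b" + name[1]] += g2.sum(axis=(0, 1))
            dx += g2 @ p[pre + name].T
    # embeddings
    np.add.at(grads["tok_emb"], ids, dx)
    grads["pos_emb"][:T] += dx.sum(axis=0)
    return loss, grads


# ---------------------------------------------------------------------------
# masking


def _mask_chunk(
    ids_row: np.ndarray, n_content: int, k: int, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mask disjoint runs of k content tokens covering ~rate of the chunk.

    Content occupies positions 1..n_content (position 0 is [CLS]); specials
    are never masked. Returns (masked ids, labels with -1 off-mask).
    """
    masked = ids_row.copy()
    labels = np.full_like(ids_row, -1)
    n_runs = int(np.floor(rate * n_content / k))
    if n_runs == 0:
        return masked, labels
    starts = rng.permutation(np.arange(1, n_content - k + 2))
    taken: list[int] = []
    for s in starts:
        if all(abs(s - t) >= k for t in taken):
            taken.append(int(s))
            if len(taken) == n_runs:
                break
    for s in taken:
        labels[s : s + k] = ids_row[s : s + k]
        masked[s : s + k] = MASK_ID
    return masked, labels


def make_masked_batch(doc: TokenizedDoc, cfg: EncoderConfig, seed: int) -> MaskedBatch:
    """Draw a fresh MLM mask over every chunk of one document."""
    rng = np.random.default_rng(seed)
    lengths = doc.chunk_content_lengths()
    inputs, labels = [], []
    for c in range(doc.n_chunks):
        masked, lab = _mask_chunk(doc.chunks[c], int(lengths[c]), cfg.k, cfg.mask_rate, rng)
        inputs.append(masked)
        labels.append(lab)
    return MaskedBatch(
        input_ids=np.stack(inputs),
        attention_masks=doc.attention_masks.copy(),
        labels=np.stack(labels),
    )


# ---------------------------------------------------------------------------
# training


def _adamw_step(params, grads, state, opt: OptimizerSettings) -> None:
    state["t"] += 1
    t = state["t"]
    for name, p in params.items():
        g = grads[name]
        m = state["m"][name]
        v = state["v"][name]
        m *= opt.beta1
        m += (1 - opt.beta1) * g
        v *= opt.beta2
        v += (1 - opt.beta2) * g * g
        mhat = m / (1 - opt.beta1**t)
        vhat = v / (1 - opt.beta2**t)
        update = mhat / (np.sqrt(vhat) + opt.eps)
        if p.ndim >= 2:  # decoupled decay on weight matrices only
            update = update + opt.weight_decay * p
        p -= opt.learning_rate * update


def train_mlm(
    corpus: Sequence[TokenizedDoc],
    cfg: EncoderConfig,
    opt: OptimizerSettings | None = None,
    epochs: int = 3,
    seed: int = 0,
) -> EncoderModel:
    """Train the encoder by masked-token prediction over the whole corpus.

    Masks are redrawn each epoch; ``model.loss_trace`` records the mean
    batch loss per epoch. ``epochs=0`` returns the freshly initialized model.
    """
    if not corpus:
        raise ValueError("empty corpus")
    opt = opt or OptimizerSettings()
    model = init_model(cfg, seed)
    if epochs == 0:
        return model
    # flatten to (chunk row, attention row, content length)
    chunks = [
        (doc.chunks[c], doc.attention_masks[c], int(doc.chunk_content_lengths()[c]))
        for doc in corpus
        for c in range(doc.n_chunks)
    ]
    state = {
        "t": 0,
        "m": {n: np.zeros_like(a) for n, a in model.params.items()},
        "v": {n: np.zeros_like(a) for n, a in model.params.items()},
    }
    master = np.random.SeedSequence(seed)
    for epoch in range(epochs):
        ep_rng = np.random.default_rng(master.spawn(1)[0])
        order = ep_rng.permutation(len(chunks))
        losses = []
        for start in range(0, len(chunks), opt.batch_size):
            idx = order[start : start + opt.batch_size]
            rows = [chunks[i] for i in idx]
            tmax = max(r[1].sum() for r in rows)
            ids = np.stack([r[0][:tmax] for r in rows])
            att = np.stack([r[1][:tmax] for r in rows])
            inp = np.empty_like(ids)
            lab = np.empty_like(ids)
            n_masked = 0
            for j, (row_ids, _, n_content) in enumerate(rows):
                mi, ml = _mask_chunk(row_ids[:tmax], n_content, cfg.k, cfg.mask_rate, ep_rng)
                inp[j], lab[j] = mi, ml
                n_masked += (ml >= 0).sum()
            if n_masked == 0:
                raise ValueError("mask rate too low: a batch produced no masked positions")
            batch = MaskedBatch(input_ids=inp, attention_masks=att, labels=lab)
            loss, grads = loss_and_grads(model, batch, dropout_rng=ep_rng)
            _adamw_step(model.params, grads, state, opt)
            losses.append(loss)
        model.loss_trace.append(float(np.mean(losses)))
    model.trained = True
    return model


def mlm_accuracy(model: EncoderModel, corpus: Sequence[TokenizedDoc], seed: int = 0) -> float:
    """Fraction of masked tokens recovered exactly (dropout off)."""
    correct = total = 0
    for i, doc in enumerate(corpus):
        batch = make_masked_batch(doc, model.config, seed + i)
        h, _ = encoder_forward(model, batch.input_ids, batch.attention_masks)
        mask_pos = batch.labels >= 0
        logits = h[mask_pos] @ model.params["mlm_W"] + model.params["mlm_b"]
        pred = logits.argmax(axis=1)
        correct += int((pred == batch.labels[mask_pos]).sum())
        total += int(mask_pos.sum())
    return correct / total


# ---------------------------------------------------------------------------
# feature extraction


def extract_feature(model: EncoderModel, doc: TokenizedDoc) -> np.ndarray:
    """The d_out-dim sequence feature: per-chunk final [CLS] states,
    combined by a content-length-weighted mean over chunks.

    Chunks are processed cropped to their own content window; attention
    masking makes the result invariant to the amount of right-padding.
    """
    if not model.trained:
        raise ValueError("extract_feature requires a trained model")
    for name, arr in model.params.items():
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"model parameter {name} contains non-finite values")
    cfg = model.config
    lengths = doc.chunk_content_lengths().astype(np.float64)
    feats = []
    for c in range(doc.n_chunks):
        t = int(lengths[c]) + 2
        ids = doc.chunks[c : c + 1, :t]
        att = doc.attention_masks[c : c + 1, :t]
        h, _ = encoder_forward(model, ids, att)
        cls_state = h[0, 0]
        if cfg.d_out != cfg.d_model:
            cls_state = cls_state @ model.params["proj_W"] + model.params["proj_b"]
        feats.append(cls_state)
    feats = np.stack(feats)
    weights = lengths / lengths.sum()
    out = weights @ feats
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature vector")
    return out


def extract_features(
    model: EncoderModel, docs: Sequence[TokenizedDoc]
) -> tuple[list[str], np.ndarray]:
    """Feature matrix for a corpus, rows ordered as ``docs``."""
    ids = [d.seq_id for d in docs]
    mat = np.stack([extract_feature(model, d) for d in docs])
    return ids, mat
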