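"""The two-level hierarchical attention network and its training loop.

Architecture, per fragment (a length-w window of raw residue features):

1. the 1024-d embedding block is projected to P=50 dimensions by a
   trainable rectified affine layer and spliced with the other five
   blocks into the fused per-residue vector (101-d at defaults);
2. within each K-mer, a bidirectional GRU encodes the residues and an
   attention layer pools them into one K-mer vector (residue-level
   attention — the "words");
3. across K-mers, a second Bi-GRU plus attention pools the K-mer vectors
   into a fragment vector (K-mer-level attention — the "sentences");
4. a 2-unit softmax head classifies the central residue as
   non-site / site.

Training minimises class-weighted cross-entropy (positive residues
weighted ~7x, countering the ~1:5.5 imbalance) with Adam, batch size 3,
and keeps the parameters of the epoch with the best validation F1.
Padded window positions never influence the result: the GRU carries its
state through them and both attention levels give them exactly zero
weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import TrainConfig
from .fragmenter import DatasetSplit, Fragment, kmer_slices, truncate_record
from .io_features import ProteinRecord, raw_block_slices

__all__ = [
    "HanParams",
    "AttentionTrace",
    "init_params",
    "project_embedding",
    "fuse",
    "bigru_encode",
    "attention_pool",
    "forward",
    "forward_batch",
    "weighted_bce_loss",
    "adam_step",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

PROB_CLIP = 1e-7  # keeps log-loss finite


@dataclass
class AttentionTrace:
    """Both attention levels for one prediction.

    ``kmer_weights`` sums to 1 over the window's K-mers;
    ``residue_weights[j]`` sums to 1 over K-mer j's real residues (or is
    all zero if K-mer j is entirely padding).
    """

    kmer_weights: np.ndarray
    residue_weights: list[np.ndarray]


@dataclass
class HanParams:
    """All trainable tensors, keyed by name."""

    tensors: dict[str, Tensor]

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data for k, t in self.tensors.items()}

    def copy_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.tensors.items()}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, t in self.tensors.items():
            t.data = np.asarray(arrays[k], dtype=np.float64)

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


def _gru_param_shapes(d: int, u: int) -> dict[str, tuple]:
    return {
        "Wzr": (d, 2 * u), "Uzr": (u, 2 * u), "bzr": (2 * u,),
        "Wc": (d, u), "Uc": (u, u), "bc": (u,),
    }


def init_params(config: TrainConfig, seed: Optional[int] = None) -> HanParams:
    """Seeded Glorot-uniform initialisation of every tensor (biases zero)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    u, a = config.hidden, config.attention
    d_in = config.fused_width
    tensors: dict[str, Tensor] = {}

    def add(name: str, shape: tuple, fan_in: int, fan_out: int):
        tensors[name] = Tensor(_glorot(rng, fan_in, fan_out, shape), requires_grad=True)

    def add_bias(name: str, shape: tuple):
        tensors[name] = Tensor(np.zeros(shape), requires_grad=True)

    if "embedding" in config.active_blocks:
        add("proj_W", (config.embed_dim, config.projection),
            config.embed_dim, config.projection)
        add_bias("proj_b", (config.projection,))
    for level, d in (("res", d_in), ("kmer", 2 * u)):
        for direction in ("fw", "bw"):
            prefix = f"{level}_{direction}"
            for pname, shape in _gru_param_shapes(d, u).items():
                full = f"{prefix}_{pname}"
                if pname.startswith("b"):
                    add_bias(full, shape)
                else:
                    add(full, shape, shape[0], u)
        add(f"{level}_att_W", (2 * u, a), 2 * u, a)
        add_bias(f"{level}_att_b", (a,))
        add(f"{level}_att_u", (a, 1), a, 1)
    add("out_W", (2 * u, 2), 2 * u, 2)
    add_bias("out_b", (2,))
    return HanParams(tensors)


# -- building blocks ---------------------------------------------------------


def project_embedding(e, W: Tensor, b: Tensor) -> Tensor:
    """Rectified affine projection of embedding rows: relu(e @ W + b)."""
    e = Tensor._lift(e)
    if e.shape[-1] != W.shape[0]:
        raise ValueError(f"embedding width {e.shape[-1]} != W rows {W.shape[0]}")
    return ad.relu(e @ W + b)


def fuse(bundle, params: HanParams, config: TrainConfig) -> np.ndarray:
    """Fused vector for a single residue bundle (fixed block order).

    Block order: one_hot, pssm, ss9, hydropathy, rel_pos, projected
    embedding; blocks named in ``config.dropped_blocks`` are omitted.
    Convenience single-residue form of the batched fusion used in
    :func:`forward_batch`.
    """
    raw = bundle.raw_vector()[None, :]
    with ad.no_grad():
        fused = _fuse_raw(raw, params, config)
    return fused.data[0]


def _fuse_raw(raw: np.ndarray, params: HanParams, config: TrainConfig) -> Tensor:
    """Fuse raw feature rows [..., 51+E] -> [..., fused_width]."""
    slices = raw_block_slices(config.embed_dim)
    parts: list[Tensor] = []
    for block in config.active_blocks:
        chunk = raw[..., slices[block]]
        if block == "embedding":
            flat = chunk.reshape(-1, config.embed_dim)
            proj = project_embedding(flat, params["proj_W"], params["proj_b"])
            parts.append(proj.reshape(*chunk.shape[:-1], config.projection))
        else:
            parts.append(Tensor(np.asarray(chunk, dtype=np.float64)))
    return ad.concat(parts, axis=-1)


def _gru_direction(
    X: Tensor, mask: np.ndarray, params: HanParams, prefix: str, reverse: bool
) -> Tensor:
    """One GRU direction over [B, T, d]; masked steps carry the state through."""
    B, T, _ = X.shape
    u = params[f"{prefix}_Uc"].shape[0]
    h = Tensor(np.zeros((B, u)))
    outs: list[Optional[Tensor]] = [None] * T
    order = range(T - 1, -1, -1) if reverse else range(T)
    m = np.asarray(mask, dtype=np.float64)
    for t in order:
        x_t = X[:, t, :]
        zr = ad.sigmoid(
            x_t @ params[f"{prefix}_Wzr"] + h @ params[f"{prefix}_Uzr"]
            + params[f"{prefix}_bzr"]
        )
        z, r = zr[:, :u], zr[:, u:]
        cand = ad.tanh(
            x_t @ params[f"{prefix}_Wc"] + (r * h) @ params[f"{prefix}_Uc"]
            + params[f"{prefix}_bc"]
        )
        h_new = (1.0 - z) * h + z * cand
        m_t = m[:, t : t + 1]
        h = h_new * m_t + h * (1.0 - m_t)
        outs[t] = h
    return ad.stack(outs, axis=1)


def bigru_encode(
    X, params: HanParams, mask: Optional[np.ndarray] = None, level: str = "res"
) -> Tensor:
    """Bidirectional GRU over [B, T, d] (or [T, d]) -> [B, T, 2u].

    Standard gated recurrence per direction — update gate z, reset gate r,
    candidate state tanh(W_h x + U_h (r*h) + b_h), convexly combined as
    h_t = (1-z)*h_{t-1} + z*h~_t — with forward and backward outputs
    concatenated.  Positions with mask 0 copy the previous hidden state.
    """
    X = Tensor._lift(X)
    squeeze = X.ndim == 2
    if squeeze:
        X = X.reshape(1, *X.shape)
    if mask is None:
        mask = np.ones(X.shape[:2])
    mask = np.atleast_2d(np.asarray(mask))
    fw = _gru_direction(X, mask, params, f"{level}_fw", reverse=False)
    bw = _gru_direction(X, mask, params, f"{level}_bw", reverse=True)
    H = ad.concat([fw, bw], axis=2)
    return H.reshape(*H.shape[1:]) if squeeze else H


def attention_pool(
    H, W_a: Tensor, b_a: Tensor, u_ctx: Tensor, mask: Optional[np.ndarray] = None
) -> tuple[Tensor, Tensor]:
    """Context-vector attention: s_t = tanh(W_a h_t + b_a)^T u_ctx, a = softmax(s).

    Returns the pooled vector v = sum_t a_t h_t and the weights a.  Masked
    positions receive weight exactly 0; if every position is masked the
    weights are all zero and v is the zero vector.
    """
    H = Tensor._lift(H)
    squeeze = H.ndim == 2
    if squeeze:
        H = H.reshape(1, *H.shape)
    B, T, _ = H.shape
    if mask is None:
        mask = np.ones((B, T))
    mask = np.atleast_2d(np.asarray(mask))
    s = (ad.tanh(H @ W_a + b_a) @ u_ctx).reshape(B, T)
    alpha = ad.masked_softmax(s, mask, axis=1)
    v = (alpha.reshape(B, T, 1) * H).sum(axis=1)
    if squeeze:
        return v.reshape(v.shape[1]), alpha.reshape(T)
    return v, alpha


# -- forward pass ------------------------------------------------------------


def forward_batch(
    windows: np.ndarray,
    masks: np.ndarray,
    params: HanParams,
    config: TrainConfig,
    need_trace: bool = False,
):
    """Forward pass over a batch of fragments.

    ``windows``: [B, w, 51+E] raw features; ``masks``: [B, w] 0/1.
    Returns (probs [B, 2] Tensor, traces or None).
    """
    B, w, _ = windows.shape
    if w != config.window:
        raise ValueError(f"fragments built with w={w}, config.window={config.window}")
    fused = _fuse_raw(np.asarray(windows, dtype=np.float64), params, config)
    slots = kmer_slices(config.window, config.kmer)
    kmer_vecs, res_alphas, kmer_mask = [], [], np.zeros((B, len(slots)))
    for j, sl in enumerate(slots):
        Xs = fused[:, sl, :]
        ms = masks[:, sl]
        H = bigru_encode(Xs, params, ms, level="res")
        v, alpha = attention_pool(
            H, params["res_att_W"], params["res_att_b"], params["res_att_u"], ms
        )
        kmer_vecs.append(v)
        res_alphas.append(alpha)
        kmer_mask[:, j] = (np.asarray(ms) > 0).any(axis=1)
    K = ad.stack(kmer_vecs, axis=1)  # [B, nk, 2u]
    H2 = bigru_encode(K, params, kmer_mask, level="kmer")
    frag_vec, kmer_alpha = attention_pool(
        H2, params["kmer_att_W"], params["kmer_att_b"], params["kmer_att_u"], kmer_mask
    )
    logits = frag_vec @ params["out_W"] + params["out_b"]
    probs = ad.softmax(logits, axis=1)
    traces = None
    if need_trace:
        traces = [
            AttentionTrace(
                kmer_weights=kmer_alpha.data[i].copy(),
                residue_weights=[a.data[i].copy() for a in res_alphas],
            )
            for i in range(B)
        ]
    return probs, traces


def forward(
    fragment: Fragment, params: HanParams, config: TrainConfig
) -> tuple[np.ndarray, AttentionTrace]:
    """Class probabilities [p(non-site), p(site)] and attention trace."""
    with ad.no_grad():
        probs, traces = forward_batch(
            fragment.window_features[None],
            fragment.pad_mask[None],
            params,
            config,
            need_trace=True,
        )
    return probs.data[0], traces[0]


# -- loss and optimiser ------------------------------------------------------


def weighted_bce_loss(y, p_site, w_pos: float = 7.0):
    """Class-weighted binary cross-entropy.

    -(1/n) sum_i c_i [y_i log p_i + (1-y_i) log(1-p_i)] with c_i = w_pos
    for positive samples and 1 otherwise; w_pos=1 recovers the unweighted
    form.  Probabilities are clipped to [1e-7, 1-1e-7].  Accepts numpy
    arrays (returns a float) or a Tensor ``p_site`` (returns a Tensor for
    backprop).
    """
    y = np.asarray(y, dtype=np.float64)
    is_tensor = isinstance(p_site, Tensor)
    p = p_site if is_tensor else Tensor(np.asarray(p_site, dtype=np.float64))
    if y.shape != p.shape:
        raise ValueError(f"label shape {y.shape} != probability shape {p.shape}")
    p = ad.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    weights = np.where(y == 1, float(w_pos), 1.0)
    per_sample = -(y * ad.log(p) + (1.0 - y) * ad.log(1.0 - p)) * weights
    loss = per_sample.mean()
    return loss if is_tensor else loss.item()


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: dict,
    t: int,
    alpha: float = 1e-3,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> tuple[dict[str, np.ndarray], dict]:
    """One Adam update: theta <- theta - alpha * m^ / (sqrt(v^) + eps).

    ``state`` holds first/second moments per parameter (initialised to
    zero when absent); ``t`` is the 1-based step count used for bias
    correction.  Pure: returns new parameter and state dicts.
    """
    if alpha <= 0:
        raise ValueError("learning rate must be positive")
    new_params, new_state = {}, {}
    for name, theta in params.items():
        g = grads.get(name)
        if g is None:
            g = np.zeros_like(theta)
        m_prev, v_prev = state.get(name, (np.zeros_like(theta), np.zeros_like(theta)))
        m = beta1 * m_prev + (1.0 - beta1) * g
        v = beta2 * v_prev + (1.0 - beta2) * g**2
        m_hat = m / (1.0 - beta1**t)
        v_hat = v / (1.0 - beta2**t)
        new_params[name] = theta - alpha * m_hat / (np.sqrt(v_hat) + eps)
        new_state[name] = (m, v)
    return new_params, new_state


# -- training ----------------------------------------------------------------


def _stack_fragments(frags: Sequence[Fragment]):
    windows = np.stack([f.window_features for f in frags]).astype(np.float64)
    masks = np.stack([f.pad_mask for f in frags]).astype(np.float64)
    labels = np.array([f.label for f in frags], dtype=np.int8)
    return windows, masks, labels


def predict_fragments(
    params: HanParams,
    frags: Sequence[Fragment],
    config: TrainConfig,
    chunk: int = 512,
) -> np.ndarray:
    """p(site) for a list of fragments, batched, no gradient tape."""
    out = np.empty(len(frags))
    with ad.no_grad():
        for start in range(0, len(frags), chunk):
            batch = frags[start : start + chunk]
            windows, masks, _ = _stack_fragments(batch)
            probs, _ = forward_batch(windows, masks, params, config)
            out[start : start + len(batch)] = probs.data[:, 1]
    return out


def _f1_at_threshold(y: np.ndarray, p: np.ndarray, threshold: float) -> float:
    calls = p >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def train(
    split: DatasetSplit, config: TrainConfig, verbose: bool = False
) -> tuple[HanParams, list[dict]]:
    """Mini-batch Adam training; returns best-validation-F1 parameters.

    A protein-level validation subset (``config.val_fraction`` of the
    train partition) is held out for epoch selection; the test partition
    is never touched.  With ``epochs=0`` the seeded initialisation is
    returned with an empty history.  Fully deterministic given (data,
    config).
    """
    if not split.train:
        raise ValueError("empty training partition")
    rng = np.random.default_rng(config.seed)
    params = init_params(config, seed=int(rng.integers(2**31)))

    # protein-level validation carve-out from the train partition
    proteins = sorted({f.protein_id for f in split.train})
    rng.shuffle(proteins)
    n_val = int(round(config.val_fraction * len(proteins)))
    val_ids = set(proteins[:n_val]) if n_val > 0 else set()
    fit_frags = [f for f in split.train if f.protein_id not in val_ids]
    val_frags = [f for f in split.train if f.protein_id in val_ids]
    if not fit_frags:  # degenerate carve-out: train on everything
        fit_frags, val_frags = list(split.train), []
    val_labels = np.array([f.label for f in val_frags], dtype=np.int8)

    state: dict = {}
    t = 0
    history: list[dict] = []
    best = (-np.inf, params.copy_arrays())
    n = len(fit_frags)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_loss, total_weight = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = [fit_frags[i] for i in order[start : start + config.batch_size]]
            windows, masks, labels = _stack_fragments(batch)
            params.zero_grad()
            probs, _ = forward_batch(windows, masks, params, config)
            loss = weighted_bce_loss(labels, probs[:, 1], config.pos_weight)
            loss.backward()
            t += 1
            grads = {k: tt.grad for k, tt in params.tensors.items() if tt.grad is not None}
            new_arrays, state = adam_step(
                params.arrays(), grads, state, t,
                alpha=config.learning_rate, beta1=config.beta1,
                beta2=config.beta2, eps=config.eps,
            )
            params.load_arrays(new_arrays)
            total_loss += loss.item() * len(batch)
            total_weight += len(batch)
        train_loss = total_loss / total_weight
        if val_frags:
            val_p = predict_fragments(params, val_frags, config)
            val_f1 = _f1_at_threshold(val_labels, val_p, config.threshold)
        else:
            val_f1 = None  # no validation carve-out; select on train loss
        history.append({"epoch": epoch + 1, "train_loss": train_loss, "val_f1": val_f1})
        if verbose:
            print(f"epoch {epoch + 1}: train_loss={train_loss:.4f} val_f1={val_f1}")
        score = val_f1 if val_frags else -train_loss
        if score > best[0]:
            best = (score, params.copy_arrays())
    if history:
        params.load_arrays(best[1])
    return params, history


def predict(
    params: HanParams,
    record: ProteinRecord,
    feature_source,
    config: TrainConfig,
) -> np.ndarray:
    """p(site) for every residue of the (truncated) protein."""
    from .fragmenter import extract_window

    if not record.sequence:
        raise ValueError("empty sequence")
    rec = truncate_record(record, config.max_len)
    features = np.asarray(feature_source.features(rec), dtype=np.float64)
    frags = [
        extract_window(features, rec.sequence, rec.labels, c, config.window, rec.id)
        for c in range(len(rec.sequence))
    ]
    return predict_fragments(params, frags, config)


# -- checkpointing -----------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(path, params: HanParams, config: TrainConfig) -> None:
    """Versioned .npz archive holding the config and all parameter tensors."""
    import json

    meta = json.dumps({"version": _CHECKPOINT_VERSION, "config": config.to_dict()})
    np.savez(path, __meta__=np.array(meta), **params.arrays())


def load_checkpoint(path) -> tuple[HanParams, TrainConfig]:
    import json

    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        config = TrainConfig.from_dict(meta["config"])
        tensors = {
            k: Tensor(npz[k], requires_grad=True) for k in npz.files if k != "__meta__"
        }
    return HanParams(tensors), config
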