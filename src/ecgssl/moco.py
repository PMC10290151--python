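"""Momentum-contrast pretraining with a distribution-divergence penalty.

A Siamese pair of encoders embeds augmented views of each recording onto the
unit sphere in d dimensions.  The query encoder is trained by gradient; the
key (momentum) encoder is an exponential moving average of it and fills a
FIFO queue of K negative keys.  For an anchor view with embedding q, a
positive key k+ (the momentum embedding of another augmented view of the
same recording) and the queue of negatives, the (K+1)-way softmax at
temperature tau

    P(q, k)_0 = exp(q.k+ / tau) / (exp(q.k+ / tau) + sum_j exp(q.k-_j / tau))

defines the contrastive loss L_C = -log P(q,k)_0.  With N extra augmented
views q_1..q_N of the same recording, the distribution-divergence loss

    L_D = sum_i KL( P(q, k) || P(q_i, k) )

pulls the views' softmax distributions together (small intraclass
divergence), and the total objective is L = L_C + beta * L_D.  Defaults
follow the reference training recipe: tau = 0.07, momentum m = 0.9,
beta = 0.15, N = 3, d = 128, Adam at 1e-3; the queue is sized for desk-scale
runs (512) and configurable up to corpus scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .augment import AugmentationPolicy, apply_policy
from .io import EcgRecord
from .msdnn import Msdnn, MsdnnConfig, ProjectionHead, build_msdnn

_EPS = 1e-12


@dataclass
class MoCoConfig:
    tau: float = 0.07
    momentum: float = 0.9
    beta: float = 0.15
    n_views: int = 3
    dim: int = 128
    queue_size: int = 512
    batch_size: int = 32
    lr: float = 1e-3

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must be in [0,1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.n_views < 1:
            raise ValueError("need at least one extra view")


@dataclass
class MoCoState:
    """Query/key encoder pair, key queue and contrastive hyperparameters."""

    encoder_q: Msdnn
    proj_q: ProjectionHead
    encoder_k: Msdnn
    proj_k: ProjectionHead
    queue: np.ndarray
    cfg: MoCoConfig
    ptr: int = 0

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.queue, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("queue rows must be unit-norm")

    def query_params(self) -> list[nn.Parameter]:
        return self.encoder_q.parameters() + self.proj_q.parameters()

    def key_params(self) -> list[nn.Parameter]:
        return self.encoder_k.parameters() + self.proj_k.parameters()


def init_moco(enc_cfg: MsdnnConfig, cfg: MoCoConfig, seed: int) -> MoCoState:
    """Build the Siamese pair (key weights start equal to query weights) and
    a random unit-norm queue."""
    rng = np.random.default_rng(seed)
    enc_cfg_proj = enc_cfg
    encoder_q = build_msdnn(enc_cfg_proj, seed=seed)
    proj_q = ProjectionHead(encoder_q.feature_channels, cfg.dim,
                            rng=np.random.default_rng(seed + 1))
    encoder_k = build_msdnn(enc_cfg_proj, seed=seed)
    proj_k = ProjectionHead(encoder_k.feature_channels, cfg.dim,
                            rng=np.random.default_rng(seed + 1))
    for pk, pq in zip(encoder_k.parameters() + proj_k.parameters(),
                      encoder_q.parameters() + proj_q.parameters()):
        pk.data[...] = pq.data
    queue = rng.standard_normal((cfg.queue_size, cfg.dim))
    queue /= np.linalg.norm(queue, axis=1, keepdims=True)
    return MoCoState(encoder_q, proj_q, encoder_k, proj_k, queue, cfg)


# ---------------------------------------------------------------------------
# the loss pieces (operate on plain arrays; unit tests target these directly)

def l2_normalize(y: np.ndarray, axis: int = -1) -> np.ndarray:
    return y / np.maximum(np.linalg.norm(y, axis=axis, keepdims=True), _EPS)


def softmax_distribution(q: np.ndarray, k_pos: np.ndarray,
                         queue: np.ndarray, tau: float = 0.07) -> np.ndarray:
    """(K+1)-way softmax over [positive, negatives] similarities; entry 0 is
    the positive key."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    logits = np.concatenate([[q @ k_pos], queue @ q]) / tau
    return nn.softmax(logits)

def contrastive_loss(distribution: np.ndarray) -> float:
    """L_C = -log of the positive-key probability (entry 0)."""
    return float(-np.log(max(distribution[0], _EPS)))


def divergence_loss(anchor_dist: np.ndarray,
                    view_dists: list[np.ndarray]) -> float:
    """Sum over views of KL(anchor || view) on the shared (K+1)-way support."""
    total = 0.0
    for vd in view_dists:
        if vd.shape != anchor_dist.shape:
            raise ValueError("distributions must share the key support")
        p = np.maximum(anchor_dist, _EPS)
        q = np.maximum(vd, _EPS)
        total += float(np.sum(anchor_dist * np.log(p / q)))
    return total


def total_pretrain_loss(l_c: float, l_d: float, beta: float) -> float:
    return l_c + beta * l_d


def momentum_update(theta_k: list[np.ndarray], theta_q: list[np.ndarray],
                    m: float) -> list[np.ndarray]:
    """theta_k' = m*theta_k + (1-m)*theta_q, elementwise per tensor."""
    if len(theta_k) != len(theta_q):
        raise ValueError("parameter lists differ in length")
    out = []
    for k, q in zip(theta_k, theta_q):
        if k.shape != q.shape:
            raise ValueError("parameter shape mismatch")
        out.append(m * k + (1.0 - m) * q)
    return out


def enqueue(state: MoCoState, new_keys: np.ndarray) -> MoCoState:
    """FIFO replacement at the pointer, wrapping modulo K, in place."""
    keys = np.atleast_2d(new_keys)
    if keys.shape[0] > state.queue.shape[0]:
        raise ValueError("batch larger than the queue")
    if not np.allclose(np.linalg.norm(keys, axis=1), 1.0, atol=1e-6):
        raise ValueError("keys must be unit-norm")
    k = state.queue.shape[0]
    for row in keys:
        state.queue[state.ptr] = row
        state.ptr = (state.ptr + 1) % k
    return state


def _batch_loss_and_grads(z: np.ndarray, k_pos: np.ndarray,
                          queue: np.ndarray, tau: float, beta: float,
                          ) -> tuple[float, float, np.ndarray]:
    """Loss components and d(loss)/d(z) for stacked view embeddings.

    ``z`` is (V, B, d) with view 0 the anchor; ``k_pos`` is (B, d) detached
    momentum keys; the queue is detached.  Returns (mean L_C, mean L_D,
    gradient of the total mean loss w.r.t. z).
    """
    v, b, d = z.shape
    l_pos = np.einsum("vbd,bd->vb", z, k_pos)            # (V, B)
    l_neg = np.einsum("vbd,kd->vbk", z, queue)           # (V, B, K)
    logits = np.concatenate([l_pos[:, :, None], l_neg], axis=2) / tau
    log_p = nn.log_softmax(logits, axis=2)
    p = np.exp(log_p)

    l_c = float(-log_p[0, :, 0].mean())
    kl = np.einsum("bk,vbk->vb", p[0],
                   log_p[0][None] - log_p)               # KL(anchor||view_v)
    l_d = float(kl[1:].sum(axis=0).mean())

    dlogits = np.zeros_like(logits)
    # contrastive: softmax cross-entropy toward slot 0, anchor only
    dlogits[0] = p[0]
    dlogits[0, :, 0] -= 1.0
    if beta > 0 and v > 1:
        # views: d KL/d logits_i = P_i - P_0
        dlogits[1:] += beta * (p[1:] - p[0][None])
        # anchor: P_0 * (sum_i [log(P0/Pi)] - KL_i), elementwise per view
        for i in range(1, v):
            g = log_p[0] - log_p[i]
            dlogits[0] += beta * p[0] * (g - kl[i][:, None])
    dlogits /= b
    dz = (dlogits[:, :, :1] * k_pos[None] +
          np.einsum("vbk,kd->vbd", dlogits[:, :, 1:], queue)) / tau
    return l_c, l_d, dz


def _normalize_backward(y: np.ndarray, z: np.ndarray,
                        dz: np.ndarray) -> np.ndarray:
    """Backward of z = y/||y|| given upstream dz."""
    norm = np.maximum(np.linalg.norm(y, axis=-1, keepdims=True), _EPS)
    return (dz - z * (z * dz).sum(axis=-1, keepdims=True)) / norm


def embed(encoder: Msdnn, proj: ProjectionHead,
          x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Encoder + projection + L2 normalisation; returns (raw, unit) outputs."""
    y = proj(encoder.forward_features(x))
    return y, l2_normalize(y)


def pretrain(records: list[EcgRecord] | np.ndarray,
             policy: AugmentationPolicy, enc_cfg: MsdnnConfig,
             cfg: MoCoConfig | None = None, epochs: int = 10,
             seed: int = 0, fs: float = 500.0) -> tuple[MoCoState, list[dict]]:
    """Run the full pretraining loop; deterministic under a fixed seed.

    Per step: draw a batch, build N+1 query views and one key view of every
    record with the augmentation policy, embed queries with the query
    encoder and keys with the momentum encoder, evaluate
    L = L_C + beta*L_D, update the query encoder by Adam, the key encoder by
    momentum moving average, and the queue FIFO.  Returns the final state
    and a per-epoch trace of mean loss components.
    """
    cfg = cfg or MoCoConfig()
    if isinstance(records, list):
        signals = np.stack([r.signal for r in records])
        fs = records[0].fs
    else:
        signals = np.asarray(records)
    n = signals.shape[0]
    if n == 0:
        raise ValueError("empty pretraining dataset")
    if cfg.queue_size < cfg.batch_size:
        raise ValueError("queue smaller than the batch")
    batch_size = min(cfg.batch_size, n)
    lead_names = tuple(f"CH{j}" for j in range(signals.shape[1]))
    state = init_moco(enc_cfg, cfg, seed)
    opt = nn.Adam(state.query_params(), lr=cfg.lr)
    rng = np.random.default_rng(seed + 17)
    state.encoder_q.set_train(True)
    state.encoder_k.set_train(True)
    trace: list[dict] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        lcs, lds = [], []
        for start in range(0, n - batch_size + 1, batch_size):
            batch = signals[order[start:start + batch_size]]
            b = batch.shape[0]
            view_seeds = rng.integers(0, 2 ** 31 - 1,
                                      size=(b, cfg.n_views + 2))
            stacks = []
            for v in range(cfg.n_views + 1):
                views = [apply_policy(
                    EcgRecord(batch[i], fs, lead_names),
                    policy, int(view_seeds[i, v])).signal
                    for i in range(b)]
                stacks.append(np.stack(views))
            big = np.concatenate(stacks)                 # ((N+1)*B, C, L)
            y_raw = state.proj_q(state.encoder_q.forward_features(big))
            z_flat = l2_normalize(y_raw)
            z = z_flat.reshape(cfg.n_views + 1, b, cfg.dim)

            key_views = np.stack([apply_policy(
                EcgRecord(batch[i], fs, lead_names),
                policy, int(view_seeds[i, -1])).signal for i in range(b)])
            _, k_pos = embed(state.encoder_k, state.proj_k, key_views)

            l_c, l_d, dz = _batch_loss_and_grads(
                z, k_pos, state.queue, cfg.tau, cfg.beta)
            lcs.append(l_c)
            lds.append(l_d)

            state.encoder_q.zero_grad()
            for p in state.proj_q.parameters():
                p.grad[...] = 0.0
            dy = _normalize_backward(y_raw, z_flat,
                                     dz.reshape(-1, cfg.dim))
            state.encoder_q.backward_from_features(
                state.proj_q.backward(dy))
            opt.step()

            new_k = momentum_update(
                [p.data for p in state.key_params()],
                [p.data for p in state.query_params()], cfg.momentum)
            for p, v_ in zip(state.key_params(), new_k):
                p.data[...] = v_
            enqueue(state, k_pos)
        trace.append({"epoch": epoch,
                      "loss_contrastive": float(np.mean(lcs)),
                      "loss_divergence": float(np.mean(lds)),
                      "loss_total": float(np.mean(lcs) +
                                          cfg.beta * np.mean(lds))})
    return state, trace
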