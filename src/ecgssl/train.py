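"""Supervised multilabel training of the ECG classifier.

The loss is a weighted binary cross-entropy plus a pairwise ranking term.
BCE weights are the inverse of each class's positive-recording count
(rescaled to mean 1), which counteracts the long-tail prevalence of
diagnostic terms; the ranking term is the log-sum-exp pairwise (LSEP) form

    L_rank = log(1 + sum_{p in pos, n in neg} exp(logit_n - logit_p)),

which pushes every positive label's logit above every negative one's and is
zero-pair-safe (all-positive or all-negative label vectors contribute 0).
Optimisation is SGD with momentum 0.9 and weight decay 5e-4 under a
one-cycle learning-rate schedule: linear warm-up 1e-3 -> 1e-2 over the
first 45% of epochs, decay to 1e-3 at 90%, then to 1e-6.  A network
initialised from pretrained weights skips the warm-up and runs only the
decaying half of the cycle.  The checkpoint with the lowest validation loss
is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .augment import AugmentationPolicy, apply_policy
from .io import EcgRecord, LabelCatalog
from .msdnn import Msdnn, MsdnnConfig, build_msdnn

_EPS = 1e-7

DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, 1e-3), (45.0, 1e-2), (90.0, 1e-3), (100.0, 1e-6))


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    sgd_momentum: float = 0.9
    weight_decay: float = 5e-4
    schedule_anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    init: str = "random"            # {"random", "pretrained"}
    lambda_rank: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        epochs = [a[0] for a in self.schedule_anchors]
        if any(b <= a for a, b in zip(epochs, epochs[1:])):
            raise ValueError("schedule anchors must increase in epoch")
        if any(a[1] <= 0 for a in self.schedule_anchors):
            raise ValueError("learning rates must be positive")


@dataclass
class ClassWeights:
    w: np.ndarray
    zero_count_classes: tuple[str, ...] = ()


def compute_class_weights(catalog: LabelCatalog) -> ClassWeights:
    """Inverse-positive-count weights, rescaled to mean 1.

    Classes with zero positives cannot define an inverse count; they receive
    the largest finite weight and are flagged.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    counts = catalog.counts_vector()
    zero = counts == 0
    safe = np.where(zero, np.inf, counts)
    raw = 1.0 / safe
    if zero.all():
        raw = np.ones_like(counts)
    elif zero.any():
        raw[zero] = raw[~zero].max()
    w = raw / raw.mean()
    flagged = tuple(c for c, z in zip(catalog.codes, zero) if z)
    return ClassWeights(w, flagged)


def weighted_bce(scores: np.ndarray, y: np.ndarray,
                 w: np.ndarray | ClassWeights | None = None) -> float:
    """-sum_c w_c [y_c log s_c + (1-y_c) log(1-s_c)] / C, averaged over any
    leading batch axis.  Scores are clamped to (eps, 1-eps)."""
    scores = np.clip(np.asarray(scores, float), _EPS, 1.0 - _EPS)
    y = np.asarray(y, float)
    if isinstance(w, ClassWeights):
        w = w.w
    wv = np.ones(scores.shape[-1]) if w is None else np.asarray(w, float)
    ll = wv * (y * np.log(scores) + (1 - y) * np.log1p(-scores))
    per_sample = -ll.sum(axis=-1) / scores.shape[-1]
    return float(per_sample.mean())


def pairwise_ranking_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """LSEP ranking loss, averaged over any leading batch axis."""
    logits = np.atleast_2d(np.asarray(logits, float))
    y = np.atleast_2d(np.asarray(y))
    losses = []
    for row_l, row_y in zip(logits, y):
        pos = row_l[row_y == 1]
        neg = row_l[row_y == 0]
        if pos.size == 0 or neg.size == 0:
            losses.append(0.0)
            continue
        a = _logsumexp(neg)
        b = _logsumexp(-pos)
        losses.append(float(np.logaddexp(0.0, a + b)))
    return float(np.mean(losses))


def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


def _loss_and_grad(logits: np.ndarray, y: np.ndarray, w: np.ndarray,
                   lambda_rank: float) -> tuple[float, float, np.ndarray]:
    """(bce, rank, d(total)/d(logits)) for a batch, total = bce + lam*rank."""
    b, c = logits.shape
    scores = nn.sigmoid(logits)
    bce = weighted_bce(scores, y, w)
    dl = w[None, :] * (scores - y) / (c * b)
    rank = 0.0
    if lambda_rank > 0:
        ranks = []
        for i in range(b):
            pos_mask = y[i] == 1
            neg_mask = ~pos_mask
            if not pos_mask.any() or not neg_mask.any():
                ranks.append(0.0)
                continue
            ln, lp = logits[i][neg_mask], logits[i][pos_mask]
            a = _logsumexp(ln)
            bb = _logsumexp(-lp)
            ranks.append(float(np.logaddexp(0.0, a + bb)))
            gate = nn.sigmoid(np.array([a + bb]))[0]
            gn = gate * np.exp(ln - a)
            gp = -gate * np.exp(-lp - bb)
            dl[i, neg_mask] += lambda_rank * gn / b
            dl[i, pos_mask] += lambda_rank * gp / b
        rank = float(np.mean(ranks))
    return bce, rank, dl


def lr_at_epoch(cfg: TrainConfig, epoch: float,
                init_mode: str | None = None) -> float:
    """Piecewise-linear one-cycle schedule, anchor epochs rescaled to
    ``cfg.epochs``.  Pretrained initialisation uses only the post-warm-up
    half of the cycle, shifted to epoch 0."""
    mode = init_mode or cfg.init
    anchors = list(cfg.schedule_anchors)
    if mode == "pretrained":
        peak = max(range(len(anchors)), key=lambda i: anchors[i][1])
        shift = anchors[peak][0]
        anchors = [(e - shift, lr) for e, lr in anchors[peak:]]
    nominal = anchors[-1][0]
    scale = cfg.epochs / nominal
    xs = np.array([e * scale for e, _ in anchors])
    ys = np.array([lr for _, lr in anchors])
    if not 0.0 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    return float(np.interp(epoch, xs, ys))


@dataclass
class TrainResult:
    model: Msdnn
    best_state: list[np.ndarray]
    trace: list[dict] = field(default_factory=list)
    best_val_loss: float = np.inf


def train_classifier(x_train: np.ndarray, y_train: np.ndarray,
                     x_val: np.ndarray, y_val: np.ndarray,
                     catalog: LabelCatalog, net_cfg: MsdnnConfig,
                     cfg: TrainConfig,
                     policy: AugmentationPolicy | None = None,
                     init_encoder_state: list[np.ndarray] | None = None,
                     fs: float = 500.0) -> TrainResult:
    """Train the multilabel classifier; deterministic under ``cfg.seed``.

    ``x_*`` are (records, leads, samples) arrays of preprocessed signals and
    ``y_*`` binary label matrices aligned with ``catalog``.  Augmentation is
    applied on the fly per sample when a policy is given.  When
    ``init_encoder_state`` holds pretrained encoder weights they are loaded
    before training (the head stays fresh) and the schedule runs its
    warm-up-free half.  The model state with the lowest validation loss is
    returned alongside the per-epoch trace.
    """
    if y_train.shape[1] != len(catalog):
        raise ValueError("label width does not match catalog")
    model = build_msdnn(net_cfg, seed=cfg.seed)
    init_mode = cfg.init
    if init_encoder_state is not None:
        _load_encoder_state(model, init_encoder_state)
        init_mode = "pretrained"
    weights = compute_class_weights(catalog).w
    opt = nn.SGD(model.parameters(), lr=1e-3, momentum=cfg.sgd_momentum,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 23)
    # separate stream so augmentation never perturbs the shuffle sequence
    aug_rng = np.random.default_rng(cfg.seed + 41)
    n = x_train.shape[0]
    batch = min(cfg.batch_size, n)
    lead_names = tuple(f"CH{j}" for j in range(x_train.shape[1]))
    trace: list[dict] = []
    best_state = model.get_state()
    best_val = np.inf
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch, init_mode)
        model.set_train(True)
        order = rng.permutation(n)
        ep_losses = []
        for start in range(0, n - batch + 1, batch):
            idx = order[start:start + batch]
            xb = x_train[idx]
            if policy is not None:
                seeds = aug_rng.integers(0, 2 ** 31 - 1, size=len(idx))
                xb = np.stack([
                    apply_policy(EcgRecord(xb[i], fs, lead_names), policy,
                                 int(seeds[i])).signal
                    for i in range(len(idx))])
            yb = y_train[idx].astype(float)
            logits = model.forward_logits(xb)
            bce, rank, dl = _loss_and_grad(logits, yb, weights,
                                           cfg.lambda_rank)
            ep_losses.append(bce + cfg.lambda_rank * rank)
            model.zero_grad()
            model.backward(dl)
            opt.step()
        val_loss = evaluate_loss(model, x_val, y_val, weights,
                                 cfg.lambda_rank)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
        trace.append({"epoch": epoch, "lr": opt.lr,
                      "train_loss": float(np.mean(ep_losses)),
                      "val_loss": val_loss})
    model.set_state(best_state)
    return TrainResult(model=model, best_state=best_state, trace=trace,
                       best_val_loss=best_val)


def evaluate_loss(model: Msdnn, x: np.ndarray, y: np.ndarray,
                  weights: np.ndarray, lambda_rank: float,
                  batch: int = 64) -> float:
    model.set_train(False)
    losses, counts = [], []
    for start in range(0, x.shape[0], batch):
        xb, yb = x[start:start + batch], y[start:start + batch].astype(float)
        logits = model.forward_logits(xb)
        bce = weighted_bce(nn.sigmoid(logits), yb, weights)
        rank = pairwise_ranking_loss(logits, yb)
        losses.append(bce + lambda_rank * rank)
        counts.append(len(xb))
    return float(np.average(losses, weights=counts))


def predict_scores(model: Msdnn, x: np.ndarray, batch: int = 64) -> np.ndarray:
    model.set_train(False)
    return np.concatenate([
        nn.sigmoid(model.forward_logits(x[s:s + batch]))
        for s in range(0, x.shape[0], batch)])


def _load_encoder_state(model: Msdnn, encoder_state: list[np.ndarray]) -> None:
    """Copy pretrained encoder weights into a fresh classifier (head kept)."""
    donor_arrays = encoder_state
    targets = _encoder_state_arrays(model)
    if len(donor_arrays) != len(targets):
        raise ValueError("pretrained state does not match the encoder")
    for dst, src in zip(targets, donor_arrays):
        if dst.shape != src.shape:
            raise ValueError("pretrained state shape mismatch")
        dst[...] = src


def _encoder_state_arrays(model: Msdnn) -> list[np.ndarray]:
    head_params = {id(p) for p in model.head.parameters()}
    arrays = [p.data for p in model.parameters() if id(p) not in head_params]
    for mod in model._all_modules():
        if isinstance(mod, nn.BatchNorm1d):
            arrays.extend([mod.running_mean, mod.running_var])
    return arrays


def encoder_state(model: Msdnn) -> list[np.ndarray]:
    """Extract copyable encoder weights (everything but the head)."""
    return [a.copy() for a in _encoder_state_arrays(model)]
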