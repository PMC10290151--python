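"""Desk-scale experiment orchestration.

Reproduces the study designs — ablation arms, label-fraction sweep,
robustness split, lead-subset comparison and the wearing-situation
classifier — on the synthetic benchmark at CPU scale.  The benchmark
conventions live in :func:`prepare_benchmark` / :func:`desk_net_config`:
600 records of 7 surrogate classes at 100 Hz / 6 s with a two-unit
multiscale network, sizes chosen so a full experiment grid runs in CPU
minutes while exercising every pipeline stage end to end.  Directional
comparisons (pretrained vs random, augmented vs plain, more vs fewer
leads) are evaluated as medians over seeds, never single runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .augment import AugmentationPolicy
from .evaluate import label_metrics_report, paired_ttest_auprc, slice_leads
from .io import LabelCatalog
from .moco import MoCoConfig, MoCoState, pretrain
from .msdnn import MsdnnConfig, build_msdnn
from .preprocess import FilterConfig, highpass_filter
from .synthetic import (DEFAULT_ARTIFACT_LEVELS, WEARING_SITUATIONS,
                        SyntheticSpec, apply_wearing_situation, desk_spec,
                        generate_dataset, generate_record, inject_artifacts)
from .train import (TrainConfig, TrainResult, encoder_state, predict_scores,
                    train_classifier)


@dataclass
class Bench:
    """A ready-to-train benchmark: preprocessed arrays + metadata."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    catalog: LabelCatalog
    fs: float
    spec: SyntheticSpec
    x_test_corrupt: np.ndarray | None = None


def prepare_benchmark(n_records: int = 600, seed: int = 0,
                      artifact_levels: dict | None = None,
                      corrupt_test: bool = False,
                      test_fraction: float = 0.3) -> Bench:
    """Generate, filter and split the synthetic benchmark.

    When ``corrupt_test`` is set, an artifact-injected copy of the test
    records (same generation parameters, artifacts only difference) is
    attached for robustness comparisons.
    """
    spec = desk_spec(n_records=n_records, seed=seed,
                     artifact_levels=artifact_levels or {})
    manifest, records, _ = generate_dataset(spec, out_dir=None,
                                            test_fraction=test_fraction)
    cfg = FilterConfig()
    split_of = {e.record_id: e.split for e in manifest.entries}
    xs = {"train": [], "test": []}
    ys = {"train": [], "test": []}
    corrupt = []
    for rec, entry in zip(records, manifest.entries):
        split = split_of[entry.record_id]
        if corrupt_test and split == "test":
            bad, _ = inject_artifacts(rec, DEFAULT_ARTIFACT_LEVELS,
                                      seed=spec.seed + 7919 + len(corrupt))
            corrupt.append(highpass_filter(bad, cfg).signal)
        filtered = highpass_filter(rec, cfg)
        xs[split].append(filtered.signal)
        ys[split].append(entry.annotation.y)
    return Bench(
        x_train=np.stack(xs["train"]), y_train=np.stack(ys["train"]),
        x_test=np.stack(xs["test"]), y_test=np.stack(ys["test"]),
        catalog=manifest.catalog, fs=spec.fs, spec=spec,
        x_test_corrupt=np.stack(corrupt) if corrupt else None)


def desk_net_config(n_classes: int = 7, n_leads: int = 12,
                    input_samples: int = 600) -> MsdnnConfig:
    return MsdnnConfig.desk(n_classes=n_classes, input_samples=input_samples,
                            input_leads=n_leads, base_channels=8, growth=8,
                            residual_units=2, proj_dim=16)


def desk_train_config(seed: int, epochs: int = 12,
                      batch_size: int = 16, **overrides) -> TrainConfig:
    kw = dict(epochs=epochs, batch_size=batch_size, seed=seed)
    kw.update(overrides)
    return TrainConfig(**kw)


def desk_policy() -> AugmentationPolicy:
    return AugmentationPolicy()


def _fit(bench: Bench, seed: int, epochs: int,
         policy: AugmentationPolicy | None,
         enc_state: list[np.ndarray] | None = None,
         x_train: np.ndarray | None = None,
         y_train: np.ndarray | None = None,
         x_val: np.ndarray | None = None,
         net_cfg: MsdnnConfig | None = None) -> TrainResult:
    x = bench.x_train if x_train is None else x_train
    y = bench.y_train if y_train is None else y_train
    xv = bench.x_test if x_val is None else x_val
    cfg = desk_train_config(seed, epochs=epochs)
    net = net_cfg or desk_net_config(
        n_classes=y.shape[1], n_leads=x.shape[1], input_samples=x.shape[2])
    return train_classifier(x, y, xv, bench.y_test, bench.catalog,
                            net, cfg, policy=policy,
                            init_encoder_state=enc_state, fs=bench.fs)


def _macro_auprc(result: TrainResult, x: np.ndarray,
                 y: np.ndarray) -> tuple[float, np.ndarray]:
    scores = predict_scores(result.model, x)
    report = label_metrics_report(scores, y)
    return report.macro["auprc"], report.auprc


def pretrain_encoder(bench: Bench, seed: int = 0, epochs: int = 8,
                     ) -> tuple[list[np.ndarray], list[dict], MoCoState]:
    """Contrastive pretraining on the (unlabeled view of the) training
    split; returns transferable encoder weights and the loss trace."""
    net_cfg = desk_net_config(n_leads=bench.x_train.shape[1],
                              input_samples=bench.x_train.shape[2])
    cfg = MoCoConfig(queue_size=128, batch_size=16, dim=net_cfg.proj_dim,
                     n_views=3)
    state, trace = pretrain(bench.x_train, desk_policy(), net_cfg, cfg,
                            epochs=epochs, seed=seed, fs=bench.fs)
    return encoder_state(state.encoder_q), trace, state


# ---------------------------------------------------------------------------
# study designs

@dataclass
class ExperimentPlan:
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    epochs: int = 12
    label_fractions: tuple[float, ...] = (0.1, 1.0)
    n_records: int = 600
    arms: tuple[str, ...] = ("plain", "aug", "pw", "aug_pw")

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("need at least one arm")
        if any(not 0 < f <= 1 for f in self.label_fractions):
            raise ValueError("label fractions must sit in (0,1]")


def run_ablation(bench: Bench, plan: ExperimentPlan,
                 enc_state: list[np.ndarray] | None = None) -> dict:
    """Macro-AUPRC per arm per seed; arms share seeds and splits.

    Arms: ``plain`` (random init, no augmentation), ``aug``, ``pw``
    (pretrained weights), ``aug_pw``.  Pretrained arms require
    ``enc_state``.  Paired t-tests compare per-class AUPRC between arms at
    the first seed.
    """
    needs_pw = {"pw", "aug_pw"} & set(plan.arms)
    if needs_pw and enc_state is None:
        raise ValueError("pretrained arms need encoder weights")
    policy = desk_policy()
    arm_setup = {
        "plain": (None, None), "aug": (policy, None),
        "pw": (None, enc_state), "aug_pw": (policy, enc_state)}
    results: dict[str, list[float]] = {a: [] for a in plan.arms}
    per_class: dict[str, np.ndarray] = {}
    for arm in plan.arms:
        pol, enc = arm_setup[arm]
        for seed in plan.seeds:
            fit = _fit(bench, seed, plan.epochs, pol, enc)
            macro, classes = _macro_auprc(fit, bench.x_test, bench.y_test)
            results[arm].append(macro)
            if seed == plan.seeds[0]:
                per_class[arm] = classes
    ttests = {}
    arms = list(plan.arms)
    for a, b in zip(arms, arms[1:]):
        va, vb = per_class[a], per_class[b]
        ok = ~(np.isnan(va) | np.isnan(vb))
        if ok.sum() >= 2:
            t, p, degen = paired_ttest_auprc(vb[ok], va[ok])
            ttests[f"{b}_vs_{a}"] = {"t": t, "p": p, "degenerate": degen}
    return {"macro_auprc": results,
            "median": {a: float(np.median(v)) for a, v in results.items()},
            "ttests": ttests}


def run_label_fraction_sweep(bench: Bench, enc_state: list[np.ndarray],
                             plan: ExperimentPlan) -> dict:
    """Pretrained vs random macro-AUPRC at each label fraction.

    Both arms train on the identical per-fraction subsample (shared seed);
    classes that lose all positives at a small fraction are left in place
    but their AUPRC is NaN-flagged and excluded from the macro.
    """
    out: dict[float, dict] = {}
    for frac in plan.label_fractions:
        rows = {"random": [], "pretrained": []}
        for seed in plan.seeds:
            rng = np.random.default_rng(1000 + seed)
            n = bench.x_train.shape[0]
            keep = rng.choice(n, size=max(2, int(round(frac * n))),
                              replace=False)
            xt, yt = bench.x_train[keep], bench.y_train[keep]
            for arm, enc in (("random", None), ("pretrained", enc_state)):
                fit = _fit(bench, seed, plan.epochs, None, enc,
                           x_train=xt, y_train=yt)
                macro, _ = _macro_auprc(fit, bench.x_test, bench.y_test)
                rows[arm].append(macro)
        out[frac] = {
            "random": rows["random"], "pretrained": rows["pretrained"],
            "median_gap": float(np.median(np.asarray(rows["pretrained"]) -
                                          np.asarray(rows["random"])))}
    return out


def run_robustness_split(bench: Bench, plan: ExperimentPlan) -> dict:
    """Clean vs artifact-corrupted test AUPRC for augmented vs plain
    training; the quantity of interest is the clean-corrupt gap per arm."""
    if bench.x_test_corrupt is None:
        raise ValueError("benchmark lacks a corrupted test copy")
    policy = desk_policy()
    gaps = {"plain": [], "aug": []}
    scores = {"plain": [], "aug": []}
    for arm, pol in (("plain", None), ("aug", policy)):
        for seed in plan.seeds:
            fit = _fit(bench, seed, plan.epochs, pol)
            clean, _ = _macro_auprc(fit, bench.x_test, bench.y_test)
            corrupt, _ = _macro_auprc(fit, bench.x_test_corrupt,
                                      bench.y_test)
            gaps[arm].append(clean - corrupt)
            scores[arm].append({"clean": clean, "corrupt": corrupt})
    return {"per_seed": scores, "gaps": gaps,
            "median_gap": {a: float(np.median(v)) for a, v in gaps.items()}}


def run_lead_subset_comparison(bench: Bench, plan: ExperimentPlan,
                               subsets: dict[str, tuple[str, ...]] | None
                               = None) -> dict:
    """Macro-AUPRC per lead subset per seed (12-lead vs 3-lead vs 1-lead)."""
    from .evaluate import LEAD_SUBSETS
    subsets = subsets or {k: LEAD_SUBSETS[k] for k in
                          ("single_lead", "holter_3lead", "twelve_lead")}
    results: dict[str, list[float]] = {}
    for name, leads in subsets.items():
        xt = slice_leads(bench.x_train, leads)
        xe = slice_leads(bench.x_test, leads)
        vals = []
        for seed in plan.seeds:
            net = desk_net_config(n_classes=bench.y_train.shape[1],
                                  n_leads=len(leads),
                                  input_samples=xt.shape[2])
            fit = _fit(bench, seed, plan.epochs, None, net_cfg=net,
                       x_train=xt, y_train=bench.y_train, x_val=xe)
            macro, _ = _macro_auprc(fit, xe, bench.y_test)
            vals.append(macro)
        results[name] = vals
    return {"macro_auprc": results,
            "median": {k: float(np.median(v)) for k, v in results.items()}}


# ---------------------------------------------------------------------------
# wearing-situation classifier

def make_wearing_dataset(n_per_situation: int = 40, seed: int = 0,
                         fs: float = 100.0, duration_s: float = 6.0,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                    np.ndarray]:
    """Clean synthetic records under all six wearing situations.

    Returns (x_train, y_train, x_test, y_test) with integer situation
    labels; the split is subject-disjoint (one record per subject).
    """
    spec = SyntheticSpec(fs=fs, duration_s=duration_s,
                         n_records=6 * n_per_situation, seed=seed)
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for i in range(6 * n_per_situation):
        situation = WEARING_SITUATIONS[i % 6]
        rec, truth = generate_record(
            spec, {"NORM"}, int(rng.integers(0, 2 ** 31 - 1)),
            record_id=f"wear{i:04d}")
        rec = apply_wearing_situation(rec, situation, truth.potentials)
        xs.append(highpass_filter(rec).signal)
        ys.append(WEARING_SITUATIONS.index(situation))
    x = np.stack(xs)
    y = np.asarray(ys)
    order = rng.permutation(len(y))
    n_test = len(y) // 4
    test, trainset = order[:n_test], order[n_test:]
    return x[trainset], y[trainset], x[test], y[test]


def train_wearing_classifier(x_train: np.ndarray, y_train: np.ndarray,
                             x_test: np.ndarray, y_test: np.ndarray,
                             seed: int = 0, epochs: int = 15,
                             batch_size: int = 16) -> dict:
    """Six-way softmax classifier on the MSDNN backbone with cross-entropy.

    Returns held-out accuracy, the 6x6 confusion matrix, and the model.
    """
    present = set(np.unique(y_train))
    if present != set(range(6)):
        raise ValueError("all six wearing situations must be represented")
    net = desk_net_config(n_classes=6, n_leads=x_train.shape[1],
                          input_samples=x_train.shape[2])
    model = build_msdnn(net, seed=seed)
    opt = nn.Adam(model.parameters(), lr=1e-3)
    rng = np.random.default_rng(seed + 5)
    n = x_train.shape[0]
    batch = min(batch_size, n)
    for _ in range(epochs):
        model.set_train(True)
        order = rng.permutation(n)
        for start in range(0, n - batch + 1, batch):
            idx = order[start:start + batch]
            logits = model.forward_logits(x_train[idx])
            p = nn.softmax(logits, axis=1)
            grad = p.copy()
            grad[np.arange(len(idx)), y_train[idx]] -= 1.0
            model.zero_grad()
            model.backward(grad / len(idx))
            opt.step()
    model.set_train(False)
    pred = np.concatenate([
        np.argmax(model.forward_logits(x_test[s:s + 64]), axis=1)
        for s in range(0, x_test.shape[0], 64)])
    acc = float((pred == y_test).mean())
    confusion = np.zeros((6, 6), dtype=int)
    for t, p_ in zip(y_test, pred):
        confusion[t, p_] += 1
    return {"accuracy": acc, "confusion": confusion, "model": model}


def predict_wearing_proba(model, x: np.ndarray) -> np.ndarray:
    model.set_train(False)
    return nn.softmax(model.forward_logits(x), axis=1)
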