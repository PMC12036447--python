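"""Multi-session pretraining, session fine-tuning, and evaluation.

Pretraining mixes trials from all sessions in every batch; each trial is
assigned an independently sampled masking scheme.  Session-specific modules
(input matrices, session embedding, output heads) are created when a session
is registered and updated jointly with the shared backbone.  Fine-tuning on
a new session freezes the backbone by default and trains only that session's
modules.

Evaluation applies a *fixed* masking scheme at inference: behavior masking
for decoding (predict behavior from spikes), neural masking with a chosen
conditioning subset for encoding (predict spikes from all behavior variables
or from a single one, which ranks each variable's contribution).
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.special import gammaln

from .autodiff import AdamW, Tensor
from .errors import ConfigError, DataError
from .masking import ALL, BEHAVIOR_VARS, MaskingScheme, SCHEME_KINDS, apply_mask, build_mask, sample_scheme
from .metrics import LossBreakdown, EvalReport, bits_per_spike, classification_accuracy, single_trial_r2
from .simulate import SessionBundle, SplitIndices, SplitSpec, softplus_inv, split_trials
from .tokenization import CONTINUOUS_VARS, DISCRETE_VARS, MODALITIES, assemble_batch
from .transformer import ModelConfig, ModelState, decode_continuous, decode_discrete, decode_rates, predicted_class

__all__ = ["TrainConfig", "pretrain", "finetune", "evaluate_decoding",
           "evaluate_encoding", "compute_losses"]

CONDITIONING_NAMES = ("all", "wheel", "whisker", "choice", "block")


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    epochs: int = Field(default=50, ge=1)
    batch_size: int = Field(default=16, ge=1)
    lr: float = Field(default=3e-3, gt=0)
    weight_decay: float = Field(default=1e-4, ge=0)
    patience: int = Field(default=10, ge=1)
    seed: int = 0
    mask_ratio: float = Field(default=0.3, gt=0, le=1)
    p_all: float = Field(default=0.5, ge=0, le=1)
    scheme_kinds: tuple[str, ...] = SCHEME_KINDS
    modalities: str = Field(default="all", pattern="^(all|neural)$")
    loss_weights: dict[str, float] = Field(
        default_factory=lambda: {m: 1.0 for m in MODALITIES}
    )
    lr_schedule: str = Field(default="cosine", pattern="^(cosine|constant)$")
    min_lr_factor: float = Field(default=0.1, gt=0, le=1)


def _trial_data(bundle: SessionBundle, idx: np.ndarray, modalities: str) -> dict:
    data = {"neural": bundle.spikes[idx]}
    if modalities == "all":
        data["wheel"] = bundle.wheel[idx]
        data["whisker"] = bundle.whisker[idx]
        data["choice"] = bundle.choice[idx]
        data["block"] = bundle.block[idx]
    return data


def _stack_plans(schemes, layout, rng):
    masks, losses = [], []
    for scheme in schemes:
        plan = build_mask(scheme, layout, rng)
        masks.append(plan.mask)
        losses.append(plan.loss_mask)
    return np.stack(masks), np.stack(losses)


def _tensor_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Stable mean cross-entropy as an autodiff expression."""
    z = logits
    zmax = z.data.max(axis=-1, keepdims=True)
    lse = (z - Tensor(zmax)).exp().sum(axis=-1).log() + Tensor(zmax[..., 0])
    onehot = np.zeros(z.shape, dtype=np.float32)
    onehot[np.arange(labels.shape[0]), labels] = 1.0
    return (lse - (z * Tensor(onehot)).sum(axis=-1)).mean()


def compute_losses(
    state: ModelState,
    bundle: SessionBundle,
    trial_idx: np.ndarray,
    schemes: list[MaskingScheme],
    rng: np.random.Generator,
    training: bool,
    loss_weights: dict[str, float],
    modalities: str = "all",
) -> tuple[Tensor, LossBreakdown]:
    """Masked-reconstruction loss for one batch of same-session trials.

    Each loss component is averaged over its own loss-mask positions; the
    total is their weighted sum.  Gradients flow only from loss positions.
    """
    sid = bundle.session_id
    mod = state.require_session(sid)
    adapters, heads = mod["adapters"], mod["heads"]
    backbone = state.backbone

    data = _trial_data(bundle, trial_idx, modalities)
    seq = assemble_batch(data, adapters, sid, backbone.modality_embeddings,
                         backbone.temporal_pe)
    mask, loss_mask = _stack_plans(schemes, seq.layout, rng)
    masked = apply_mask(seq, mask, backbone.mask_token)
    e = backbone.encode(masked, rng, training)
    parts = masked.split(e)
    layout = seq.layout

    breakdown = LossBreakdown()
    total: Tensor | None = None

    def accumulate(component: Tensor, weight: float):
        nonlocal total
        weighted = component * weight
        total = weighted if total is None else total + weighted

    # neural: Poisson NLL over masked bins, all neurons
    lm = loss_mask[:, layout.slice_for("neural")]  # (B, T)
    if lm.any():
        counts = np.swapaxes(data["neural"], -1, -2).astype(np.float32)  # (B, T, N)
        rates = decode_rates(parts["neural"], heads, state.cfg.rate_link)
        nll_elem = rates - Tensor(counts) * rates.log()
        w = Tensor(lm[..., None].astype(np.float32))
        n_entries = float(lm.sum()) * counts.shape[-1]
        component = (nll_elem * w).sum() * (1.0 / n_entries)
        accumulate(component, loss_weights.get("neural", 1.0))
        const = float((gammaln(counts + 1.0) * lm[..., None]).sum() / n_entries)
        breakdown.poisson_nll = float(component.data) + const
        breakdown.token_counts["neural"] = int(lm.sum())

    for var in CONTINUOUS_VARS:
        if var not in layout.present:
            continue
        lm = loss_mask[:, layout.slice_for(var)]
        if not lm.any():
            continue
        pred = decode_continuous(parts[var], heads, var)  # (B, T)
        truth = Tensor(data[var].astype(np.float32))
        w = Tensor(lm.astype(np.float32))
        component = ((pred - truth) ** 2.0 * w).sum() * (1.0 / float(lm.sum()))
        accumulate(component, loss_weights.get(var, 1.0))
        breakdown.mse[var] = float(component.data)
        breakdown.token_counts[var] = int(lm.sum())

    for var in DISCRETE_VARS:
        if var not in layout.present:
            continue
        lm = loss_mask[:, layout.slice_for(var)]  # (B, T)
        rows = lm.any(axis=1)
        if not rows.any():
            continue
        pool = lm[rows].astype(np.float32)
        pool /= pool.sum(axis=1, keepdims=True)
        logits = decode_discrete(parts[var][rows], heads, var, pool_weights=pool)
        labels = np.asarray(data[var])[rows].astype(int)
        component = _tensor_cross_entropy(logits, labels)
        accumulate(component, loss_weights.get(var, 1.0))
        breakdown.cross_entropy[var] = float(component.data)
        breakdown.token_counts[var] = int(lm.sum())

    if total is None:
        raise ConfigError("no loss components produced; check masking configuration")
    breakdown.total = float(total.data)
    return total, breakdown


def _full_scheme_validation_loss(state, bundle, idx, cfg: TrainConfig) -> float:
    """Deterministic early-stopping signal on the validation trials.

    Uses the full masking schemes present in the configured mixture (neural
    conditioned on ALL, and behavior); a model trained only on random
    schemes falls back to a fixed-seed within-modality mask so the signal
    is identical across epochs."""
    if idx.size == 0:
        return 0.0
    kinds = cfg.scheme_kinds if cfg.modalities == "all" else ("within_modality",)
    probes: list[list[MaskingScheme]] = []
    if "neural" in kinds:
        probes.append([MaskingScheme(kind="neural", conditioning=ALL)] * idx.size)
    if "behavior" in kinds:
        probes.append([MaskingScheme(kind="behavior")] * idx.size)
    if not probes:
        target = "neural" if cfg.modalities == "neural" else "neural"
        probes.append([
            MaskingScheme(kind="within_modality", target_modality=target,
                          ratio=cfg.mask_ratio)
        ] * idx.size)
    total = 0.0
    for schemes in probes:
        rng = np.random.default_rng(0)  # fixed: same probe masks every epoch
        t, _ = compute_losses(state, bundle, idx, schemes, rng, False,
                              cfg.loss_weights, cfg.modalities)
        total += float(t.data)
    return total


def _epoch_lr(cfg: TrainConfig, epoch: int) -> float:
    if cfg.lr_schedule == "constant" or cfg.epochs == 1:
        return cfg.lr
    floor = cfg.lr * cfg.min_lr_factor
    cos = 0.5 * (1.0 + np.cos(np.pi * epoch / (cfg.epochs - 1)))
    return floor + (cfg.lr - floor) * cos


def _rate_bias_init(bundle: SessionBundle, train_idx: np.ndarray) -> np.ndarray:
    """Initialize the rate head bias at each neuron's mean training count per
    bin (through the inverse link), so the model starts at the null rate."""
    mean_counts = bundle.spikes[train_idx].mean(axis=(0, 2)).astype(np.float64)
    return softplus_inv(np.maximum(mean_counts, 1e-3)).astype(np.float32)


def _train_loop(
    state: ModelState,
    bundles: dict[str, SessionBundle],
    splits: dict[str, SplitIndices],
    cfg: TrainConfig,
    params: list,
) -> None:
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    present = MODALITIES if cfg.modalities == "all" else ("neural",)
    kinds = cfg.scheme_kinds if cfg.modalities == "all" else ("within_modality",)

    pairs = [(sid, t) for sid, sp in splits.items() for t in sp.train]
    if not pairs:
        raise DataError("no training trials across sessions")

    best_loss, best_snap, best_epoch, bad_epochs = np.inf, None, -1, 0
    for epoch in range(cfg.epochs):
        opt.lr = _epoch_lr(cfg, epoch)
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [pairs[i] for i in order[start: start + cfg.batch_size]]
            by_session: dict[str, list[int]] = {}
            for sid, t in batch:
                by_session.setdefault(sid, []).append(t)
            opt.zero_grad()
            batch_loss = 0.0
            for sid, trials in by_session.items():
                schemes = [
                    sample_scheme(rng, present_modalities=present,
                                  ratio=cfg.mask_ratio, p_all=cfg.p_all, kinds=kinds)
                    for _ in trials
                ]
                state.history["scheme_log"].extend(s.kind for s in schemes)
                total, _ = compute_losses(
                    state, bundles[sid], np.asarray(trials), schemes, rng, True,
                    cfg.loss_weights, cfg.modalities,
                )
                scale = len(trials) / len(batch)
                total.backward(np.asarray(scale, dtype=total.data.dtype))
                batch_loss += float(total.data) * scale
            opt.step()
            epoch_losses.append(batch_loss)
        state.history["train_loss"].append(float(np.mean(epoch_losses)))

        valid_loss = sum(
            _full_scheme_validation_loss(state, bundles[sid], splits[sid].valid, cfg)
            for sid in sorted(bundles)
        )
        state.history["valid_loss"].append(valid_loss)
        if valid_loss < best_loss - 1e-9:
            best_loss, best_snap, best_epoch, bad_epochs = valid_loss, state.snapshot(), epoch, 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    if best_snap is not None:
        state.restore(best_snap)
    state.history["best_epoch"] = best_epoch


def pretrain(
    sessions: list[SessionBundle],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    splits: dict[str, SplitIndices] | None = None,
) -> ModelState:
    """Train a model jointly on several sessions with mixed masking schemes."""
    if not sessions:
        raise DataError("pretraining needs at least one session")
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    bundles = {b.session_id: b for b in sessions}
    if len(bundles) != len(sessions):
        raise DataError("duplicate session ids")
    if splits is None:
        splits = {
            sid: split_trials(b, SplitSpec(seed=train_cfg.seed))
            for sid, b in bundles.items()
        }
    for sid, sp in splits.items():
        if sp.train.size == 0:
            raise DataError(f"session '{sid}' has zero training trials")

    state = ModelState(model_cfg, np.random.default_rng(model_cfg.seed))
    for sid, b in bundles.items():
        state.register_session(sid, b.n_neurons)
        state.sessions[sid]["heads"].b_rate.data = _rate_bias_init(b, splits[sid].train)
    state.audit_partition()
    params = [p for _, p in state.all_parameters()]
    _train_loop(state, bundles, splits, train_cfg, params)
    return state


def finetune(
    state: ModelState,
    new_session: SessionBundle,
    ft_cfg: TrainConfig | None = None,
    splits: SplitIndices | None = None,
    unfreeze_backbone: bool = False,
) -> ModelState:
    """Register a new session and adapt its session-specific components.

    The shared backbone stays frozen unless ``unfreeze_backbone``; a fresh
    input matrix and heads are always created for the new session's neuron
    count, never reused from another session.
    """
    ft_cfg = ft_cfg or TrainConfig()
    sid = new_session.session_id
    if splits is None:
        splits = split_trials(new_session, SplitSpec(seed=ft_cfg.seed))
    state.register_session(sid, new_session.n_neurons)
    state.sessions[sid]["heads"].b_rate.data = _rate_bias_init(new_session, splits.train)
    params = [p for _, p in state.session_parameters(sid)]
    if unfreeze_backbone:
        params += [p for _, p in state.backbone_parameters()]
    else:
        # snapshot so early-stopping restore cannot drift the frozen backbone
        frozen = {name: p.data for name, p in state.backbone_parameters()}
    _train_loop(state, {sid: new_session}, {sid: splits}, ft_cfg, params)
    if not unfreeze_backbone:
        for name, p in state.backbone_parameters():
            p.data = frozen[name]
    return state


# ---------------------------------------------------------------------------
# evaluation


def _iter_chunks(idx: np.ndarray, size: int):
    for start in range(0, idx.size, size):
        yield idx[start: start + size]


def evaluate_decoding(
    state: ModelState,
    bundle: SessionBundle,
    split: SplitIndices,
    batch_size: int = 32,
) -> EvalReport:
    """Behavior-masking inference on the test trials: predict all four task
    variables from spikes, score R2 (continuous) and accuracy (discrete)."""
    sid = bundle.session_id
    mod = state.require_session(sid)
    rng = np.random.default_rng(0)  # full scheme: rng unused
    preds = {var: [] for var in BEHAVIOR_VARS}
    for chunk in _iter_chunks(split.test, batch_size):
        data = _trial_data(bundle, chunk, "all")
        seq = assemble_batch(data, mod["adapters"], sid,
                             state.backbone.modality_embeddings, state.backbone.temporal_pe)
        plan = build_mask(MaskingScheme(kind="behavior"), seq.layout, rng)
        masked = apply_mask(seq, np.broadcast_to(plan.mask, (chunk.size, plan.mask.size)),
                            state.backbone.mask_token)
        e = state.backbone.encode(masked)
        parts = masked.split(e)
        for var in CONTINUOUS_VARS:
            preds[var].append(decode_continuous(parts[var], mod["heads"], var).data)
        for var in DISCRETE_VARS:
            logits = decode_discrete(parts[var], mod["heads"], var).data
            preds[var].append(predicted_class(logits))
    return EvalReport(
        session_id=sid,
        task="decode",
        r2_wheel=single_trial_r2(np.concatenate(preds["wheel"]), bundle.wheel[split.test]),
        r2_whisker=single_trial_r2(np.concatenate(preds["whisker"]), bundle.whisker[split.test]),
        acc_choice=classification_accuracy(np.concatenate(preds["choice"]),
                                           bundle.choice[split.test]),
        acc_block=classification_accuracy(np.concatenate(preds["block"]),
                                          bundle.block[split.test]),
        n_test_trials=int(split.test.size),
    )


def evaluate_encoding(
    state: ModelState,
    bundle: SessionBundle,
    split: SplitIndices,
    conditioning: str | list[str] = "all",
    batch_size: int = 32,
) -> EvalReport:
    """Neural-masking inference: predict spike rates from the stated
    conditioning subset of behavior variables and score bits per spike
    against the training-split constant-rate null."""
    names = [conditioning] if isinstance(conditioning, str) else list(conditioning)
    for name in names:
        if name not in CONDITIONING_NAMES:
            raise ConfigError(
                f"unknown conditioning '{name}'; expected one of {CONDITIONING_NAMES}"
            )
    sid = bundle.session_id
    mod = state.require_session(sid)
    rng = np.random.default_rng(0)
    null_rates = bundle.spikes[split.train].mean(axis=(0, 2))  # per-neuron counts/bin
    null_rates = np.maximum(null_rates, 1e-6)
    counts = bundle.spikes[split.test]  # (n_test, N, T)

    co_bps = {}
    for name in names:
        cond = ALL if name == "all" else name
        rates_chunks = []
        for chunk in _iter_chunks(split.test, batch_size):
            data = _trial_data(bundle, chunk, "all")
            seq = assemble_batch(data, mod["adapters"], sid,
                                 state.backbone.modality_embeddings,
                                 state.backbone.temporal_pe)
            plan = build_mask(MaskingScheme(kind="neural", conditioning=cond),
                              seq.layout, rng)
            masked = apply_mask(seq, np.broadcast_to(plan.mask, (chunk.size, plan.mask.size)),
                                state.backbone.mask_token)
            e = state.backbone.encode(masked)
            parts = masked.split(e)
            rates = decode_rates(parts["neural"], mod["heads"], state.cfg.rate_link)
            rates_chunks.append(np.swapaxes(rates.data, -1, -2))  # (B, N, T)
        pred_rates = np.concatenate(rates_chunks)
        co_bps[name] = bits_per_spike(pred_rates, counts, null_rates[None, :, None])
    return EvalReport(session_id=sid, task="encode", co_bps=co_bps,
                      n_test_trials=int(split.test.size))
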