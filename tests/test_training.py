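"""Training-loop contracts: loss improvement, determinism, freezing,
loss-mask isolation, and evaluation schemas."""

import numpy as np
import pytest

import spikecast as sc
from spikecast.errors import ConfigError, DataError
from spikecast.masking import ALL, MaskingScheme
from spikecast.simulate import SplitIndices, SplitSpec, split_trials
from spikecast.training import compute_losses, evaluate_decoding, evaluate_encoding
from spikecast.transformer import ModelState

from conftest import MODALITY_WEIGHTS, micro_model_config, micro_sim_config, micro_train_config


def micro_sessions(n=2, seed=0, **overrides):
    cfg = micro_sim_config(n_sessions=n, seed=seed, **overrides)
    return sc.generate_dataset(cfg)


def test_validation_loss_improves_from_first_epoch():
    sessions = micro_sessions(2, n_trials=40)
    state = sc.pretrain(sessions, micro_model_config(), micro_train_config(epochs=5))
    valid = state.history["valid_loss"]
    assert len(valid) >= 2
    assert min(valid) < valid[0]


def test_scheme_log_covers_configured_mixture():
    sessions = micro_sessions(1, n_trials=40)
    state = sc.pretrain(sessions, micro_model_config(), micro_train_config(epochs=4))
    log = state.history["scheme_log"]
    assert set(log) == {"neural", "behavior", "within_modality", "cross_modal"}
    freqs = {k: log.count(k) / len(log) for k in set(log)}
    for f in freqs.values():  # loose multinomial band at this sample size
        assert abs(f - 0.25) < 5 * np.sqrt(0.25 * 0.75 / len(log))


def test_identical_seeds_give_identical_weights():
    sessions = micro_sessions(1, n_trials=30)
    kwargs = dict(model_cfg=micro_model_config(), train_cfg=micro_train_config(epochs=2))
    a = sc.pretrain(sessions, **kwargs)
    b = sc.pretrain(sessions, **kwargs)
    for (name_a, pa), (name_b, pb) in zip(a.all_parameters(), b.all_parameters()):
        assert name_a == name_b
        np.testing.assert_array_equal(pa.data, pb.data)


def test_zero_training_trials_rejected():
    sessions = micro_sessions(1)
    empty = {
        sessions[0].session_id: SplitIndices(
            np.array([], dtype=int), np.arange(3), np.arange(3, 6)
        )
    }
    with pytest.raises(DataError):
        sc.pretrain(sessions, micro_model_config(), micro_train_config(), empty)


def test_parameter_partition_audit():
    sessions = micro_sessions(2)
    state = ModelState(micro_model_config())
    for b in sessions:
        state.register_session(b.session_id, b.n_neurons)
    state.audit_partition()
    n_backbone = len(list(state.backbone_parameters()))
    n_session = len(list(state.session_parameters()))
    assert len(list(state.all_parameters())) == n_backbone + n_session


def test_finetune_frozen_backbone_bit_identical():
    pre = micro_sessions(1, n_trials=30)
    state = sc.pretrain(pre, micro_model_config(), micro_train_config(epochs=2))
    before = {name: p.data.copy() for name, p in state.backbone_parameters()}
    new = micro_sessions(1, seed=9, n_neurons_per_session=15)[0]
    sc.finetune(state, new, micro_train_config(epochs=2))
    for name, p in state.backbone_parameters():
        np.testing.assert_array_equal(p.data, before[name])
    # a fresh input matrix was created for the new neuron count
    assert state.sessions[new.session_id]["adapters"].n_neurons == 15


def test_finetune_unfrozen_backbone_moves():
    pre = micro_sessions(1, n_trials=30)
    state = sc.pretrain(pre, micro_model_config(), micro_train_config(epochs=2))
    before = {name: p.data.copy() for name, p in state.backbone_parameters()}
    new = micro_sessions(1, seed=9)[0]
    sc.finetune(state, new, micro_train_config(epochs=2), unfreeze_backbone=True)
    moved = any(
        not np.array_equal(p.data, before[name]) for name, p in state.backbone_parameters()
    )
    assert moved


def test_loss_masking_excludes_nonconditioning_behavior(micro_bundle, micro_state, rng):
    """Under single-variable conditioning, the masked non-conditioning
    behaviors are excluded from both input and loss: perturbing them cannot
    change the loss, while perturbing the visible conditioning variable
    does."""
    idx = np.arange(4)
    schemes = [MaskingScheme(kind="neural", conditioning="wheel")] * idx.size

    def loss_for(bundle):
        total, _ = compute_losses(
            micro_state, bundle, idx, schemes, np.random.default_rng(0), False,
            MODALITY_WEIGHTS,
        )
        return float(total.data)

    base = loss_for(micro_bundle)
    original_whisker = micro_bundle.whisker.copy()
    micro_bundle.whisker = original_whisker + 5.0  # masked, not conditioned on
    assert loss_for(micro_bundle) == base
    micro_bundle.whisker = original_whisker
    micro_bundle.wheel = micro_bundle.wheel + 5.0  # visible conditioning input
    assert loss_for(micro_bundle) != base


def test_loss_gradients_only_from_loss_positions(micro_bundle, micro_state):
    """With full neural masking, spike counts enter the loss only as
    targets; perturbing counts changes the Poisson term, while the graph
    assigns no gradient to unmasked-content paths (all neural content is
    replaced by the mask token)."""
    idx = np.arange(2)
    schemes = [MaskingScheme(kind="neural", conditioning=ALL)] * idx.size
    total, _ = compute_losses(
        micro_state, micro_bundle, idx, schemes, np.random.default_rng(0), False,
        MODALITY_WEIGHTS,
    )
    total.backward()
    # neural input map received no gradient: its tokens were fully masked
    g = micro_state.sessions[micro_bundle.session_id]["adapters"].W_X_input.grad
    assert g is None or np.allclose(g, 0.0)


def test_decoding_report_has_exactly_four_tasks():
    sessions = micro_sessions(1, n_trials=30)
    state = sc.pretrain(sessions, micro_model_config(), micro_train_config(epochs=1))
    split = split_trials(sessions[0], SplitSpec(seed=0))
    report = evaluate_decoding(state, sessions[0], split)
    metrics = report.decoding_metrics()
    assert set(metrics) == {"choice", "block", "wheel", "whisker"}
    assert all(v is not None for v in metrics.values())


def test_unknown_conditioning_rejected():
    sessions = micro_sessions(1, n_trials=30)
    state = sc.pretrain(sessions, micro_model_config(), micro_train_config(epochs=1))
    split = split_trials(sessions[0], SplitSpec(seed=0))
    with pytest.raises(ConfigError):
        evaluate_encoding(state, sessions[0], split, "pupil")


def test_unregistered_session_rejected(micro_bundle):
    state = ModelState(micro_model_config())
    with pytest.raises(ConfigError):
        evaluate_decoding(state, micro_bundle,
                          split_trials(micro_bundle, SplitSpec(seed=0)))
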