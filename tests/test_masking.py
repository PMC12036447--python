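"""Masking schemes: closed-form mask/loss sets and sampling statistics."""

import numpy as np
import pytest

from spikecast.autodiff import Tensor
from spikecast.errors import ConfigError
from spikecast.masking import (
    ALL,
    BEHAVIOR_VARS,
    MaskPlan,
    MaskingScheme,
    apply_mask,
    build_mask,
    sample_scheme,
)
from spikecast.tokenization import MODALITIES, Segment, TokenLayout, TokenSequence

T = 100


def full_layout(t=T):
    return TokenLayout(
        segments=[Segment(m, i * t, t) for i, m in enumerate(MODALITIES)],
        n_bins=t,
        session_id="s0",
    )


def neural_only_layout(t=T):
    return TokenLayout(segments=[Segment("neural", 0, t)], n_bins=t, session_id="s0",
                       missing=tuple(m for m in MODALITIES if m != "neural"))


# -- scheme construction --------------------------------------------------


def test_invalid_schemes_rejected():
    with pytest.raises(ConfigError):
        MaskingScheme(kind="spatial")
    with pytest.raises(ConfigError):
        MaskingScheme(kind="neural", conditioning="saccade")
    with pytest.raises(ConfigError):
        MaskingScheme(kind="behavior", conditioning="wheel")
    with pytest.raises(ConfigError):
        MaskingScheme(kind="within_modality", target_modality="neural", ratio=1.5)
    with pytest.raises(ConfigError):
        MaskingScheme(kind="within_modality", ratio=0.3)


def test_loss_mask_must_be_subset_and_nonempty():
    mask = np.zeros(10, dtype=bool)
    mask[:5] = True
    loss = np.zeros(10, dtype=bool)
    loss[4:6] = True
    with pytest.raises(ConfigError):
        MaskPlan(mask=mask, loss_mask=loss)
    with pytest.raises(ConfigError):
        MaskPlan(mask=mask, loss_mask=np.zeros(10, dtype=bool))


# -- build_mask closed forms ----------------------------------------------


def test_neural_all_masks_neural_only():
    plan = build_mask(MaskingScheme(kind="neural", conditioning=ALL), full_layout())
    assert plan.mask.sum() == T  # 100 masked
    assert plan.mask[:T].all() and not plan.mask[T:].any()  # behavior visible
    np.testing.assert_array_equal(plan.loss_mask, plan.mask)


@pytest.mark.parametrize("cond", BEHAVIOR_VARS)
def test_neural_single_conditioning_masks_other_behaviors(cond):
    layout = full_layout()
    plan = build_mask(MaskingScheme(kind="neural", conditioning=cond), layout)
    assert plan.mask.sum() == 4 * T  # neural + 3 non-conditioning behaviors
    assert not plan.mask[layout.slice_for(cond)].any()
    assert plan.mask[layout.slice_for("neural")].all()
    assert plan.loss_mask.sum() == T  # loss on neural only
    assert plan.loss_mask[layout.slice_for("neural")].all()


def test_behavior_masking_masks_all_behavior_tokens():
    layout = full_layout()
    plan = build_mask(MaskingScheme(kind="behavior"), layout)
    assert plan.mask.sum() == 4 * T
    assert not plan.mask[layout.slice_for("neural")].any()
    np.testing.assert_array_equal(plan.loss_mask, plan.mask)


def test_discrete_variables_masked_all_or_none_by_full_schemes():
    layout = full_layout()
    plan = build_mask(MaskingScheme(kind="neural", conditioning="wheel"), layout)
    for var in ("choice", "block"):
        seg = plan.mask[layout.slice_for(var)]
        assert seg.all() or not seg.any()
        assert seg.all()  # non-conditioning => fully masked


def test_within_modality_masks_stated_fraction(rng):
    layout = full_layout()
    plan = build_mask(
        MaskingScheme(kind="within_modality", target_modality="wheel", ratio=0.3),
        layout, rng,
    )
    assert plan.mask.sum() == 30
    assert plan.mask[layout.slice_for("wheel")].sum() == 30
    np.testing.assert_array_equal(plan.loss_mask, plan.mask)


def test_cross_modal_masks_fraction_of_all_tokens(rng):
    plan = build_mask(MaskingScheme(kind="cross_modal", ratio=0.3), full_layout(), rng)
    assert plan.mask.sum() == round(0.3 * 5 * T)


def test_zero_ratio_rejected(rng):
    with pytest.raises(ConfigError):
        build_mask(MaskingScheme(kind="cross_modal", ratio=0.001), full_layout(t=10), rng)


def test_random_mask_count_concentrates_at_binomial_mean(rng):
    """Masked counts across draws behave like draws of fixed size
    round(ratio*n): the mean matches the binomial mean within 4 sigma."""
    counts = [
        build_mask(MaskingScheme(kind="cross_modal", ratio=0.3), full_layout(), rng).mask.sum()
        for _ in range(200)
    ]
    assert np.mean(counts) == 150  # exact: sampling without replacement


def test_missing_modality_errors():
    with pytest.raises(ConfigError):
        build_mask(MaskingScheme(kind="behavior"), neural_only_layout())
    with pytest.raises(ConfigError):
        build_mask(MaskingScheme(kind="neural", conditioning="wheel"), neural_only_layout())


# -- scheme sampling ------------------------------------------------------


def test_scheme_kinds_uniform(rng):
    draws = [sample_scheme(rng).kind for _ in range(8000)]
    freqs = {k: draws.count(k) / len(draws) for k in set(draws)}
    assert set(freqs) == {"neural", "behavior", "within_modality", "cross_modal"}
    for f in freqs.values():
        assert abs(f - 0.25) < 4 * np.sqrt(0.25 * 0.75 / 8000)


def test_neural_conditioning_split_matches_p_all(rng):
    conds = []
    while len(conds) < 4000:
        s = sample_scheme(rng, p_all=0.5)
        if s.kind == "neural":
            conds.append(s.conditioning)
    frac_all = conds.count(ALL) / len(conds)
    assert abs(frac_all - 0.5) < 4 * np.sqrt(0.25 / len(conds))
    for var in BEHAVIOR_VARS:
        f = conds.count(var) / len(conds)
        assert abs(f - 0.125) < 4 * np.sqrt(0.125 * 0.875 / len(conds))


# -- apply_mask -----------------------------------------------------------


def _sequence(rng, t=10):
    layout = full_layout(t)
    content = Tensor(rng.standard_normal((layout.length, 6)).astype(np.float32))
    embed = Tensor(rng.standard_normal((layout.length, 6)).astype(np.float32))
    return TokenSequence(content=content, embed=embed, layout=layout)


def test_apply_mask_replaces_only_masked_content(rng):
    seq = _sequence(rng)
    token = Tensor(np.full(6, 9.0, dtype=np.float32))
    plan = build_mask(MaskingScheme(kind="behavior"), seq.layout)
    masked = apply_mask(seq, plan, token)
    np.testing.assert_array_equal(masked.content.data[~plan.mask], seq.content.data[~plan.mask])
    np.testing.assert_array_equal(masked.content.data[plan.mask],
                                  np.full((plan.mask.sum(), 6), 9.0))
    # embeddings untouched: masked tokens still differ by their embeddings
    np.testing.assert_array_equal(masked.embed.data, seq.embed.data)


def test_apply_mask_idempotent(rng):
    seq = _sequence(rng)
    token = Tensor(np.zeros(6, dtype=np.float32))
    plan = build_mask(MaskingScheme(kind="neural", conditioning=ALL), seq.layout)
    once = apply_mask(seq, plan, token)
    twice = apply_mask(once, plan, token)
    np.testing.assert_array_equal(once.content.data, twice.content.data)


def test_apply_mask_length_mismatch_rejected(rng):
    seq = _sequence(rng)
    with pytest.raises(ConfigError):
        apply_mask(seq, np.ones(seq.length + 1, dtype=bool), Tensor(np.zeros(6)))
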