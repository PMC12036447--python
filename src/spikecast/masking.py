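"""The four multi-task masking schemes and their application to sequences.

Training alternates uniformly between four schemes:

* **neural** — all neural tokens are masked and predicted from behavior
  (encoding, E[X|Y]); alternates between conditioning on all behavior
  variables and on a single one, in which case the other behavior variables
  are masked too but excluded from the loss.
* **behavior** — all behavior tokens are masked and predicted from neural
  activity (decoding, E[Y|X]).
* **within_modality** — a random fraction of one modality's tokens is
  masked and reconstructed from the rest of that modality.
* **cross_modal** — a random fraction of all tokens is masked and
  reconstructed from both modalities jointly.

A :class:`MaskPlan` carries two boolean vectors: ``mask`` (token replaced by
the learned mask token) and ``loss_mask`` (token contributes to the loss);
``loss_mask`` is always a subset of ``mask``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import where
from .errors import ConfigError
from .tokenization import DISCRETE_VARS, MODALITIES, TokenLayout, TokenSequence

__all__ = [
    "SCHEME_KINDS",
    "BEHAVIOR_VARS",
    "ALL",
    "MaskingScheme",
    "MaskPlan",
    "sample_scheme",
    "build_mask",
    "apply_mask",
]

SCHEME_KINDS = ("neural", "behavior", "within_modality", "cross_modal")
BEHAVIOR_VARS = ("wheel", "whisker", "choice", "block")
ALL = "ALL"  # sentinel conditioning subset: every behavior variable visible


@dataclass(frozen=True)
class MaskingScheme:
    kind: str
    conditioning: str | None = None  # for kind="neural": ALL or one behavior variable
    target_modality: str | None = None  # for kind="within_modality"
    ratio: float | None = None  # for the two random schemes

    def __post_init__(self):
        if self.kind not in SCHEME_KINDS:
            raise ConfigError(f"unknown masking scheme kind '{self.kind}'")
        if self.kind == "neural":
            if self.conditioning != ALL and self.conditioning not in BEHAVIOR_VARS:
                raise ConfigError(
                    f"neural masking needs conditioning ALL or one of {BEHAVIOR_VARS}, "
                    f"got {self.conditioning!r}"
                )
        elif self.conditioning is not None:
            raise ConfigError("conditioning_subset applies only to neural masking")
        if self.kind in ("within_modality", "cross_modal"):
            if self.ratio is None or not 0.0 <= self.ratio <= 1.0:
                raise ConfigError("random masking schemes need ratio in [0, 1]")
        if self.kind == "within_modality" and self.target_modality not in MODALITIES:
            raise ConfigError("within-modality masking needs a target modality")


@dataclass(frozen=True)
class MaskPlan:
    mask: np.ndarray  # bool (L,): token replaced by the mask token
    loss_mask: np.ndarray  # bool (L,): token contributes to the loss

    def __post_init__(self):
        if np.any(self.loss_mask & ~self.mask):
            raise ConfigError("loss positions must be a subset of masked positions")
        if not self.loss_mask.any():
            raise ConfigError("mask plan has no loss positions")


def sample_scheme(
    rng: np.random.Generator,
    present_modalities: tuple[str, ...] = MODALITIES,
    ratio: float = 0.3,
    p_all: float = 0.5,
    kinds: tuple[str, ...] = SCHEME_KINDS,
) -> MaskingScheme:
    """Draw a scheme uniformly over ``kinds``; for neural masking, condition
    on ALL variables with probability ``p_all``, else on one variable
    uniformly at random."""
    kind = kinds[rng.integers(len(kinds))]
    if kind == "neural":
        if rng.random() < p_all:
            conditioning = ALL
        else:
            conditioning = BEHAVIOR_VARS[rng.integers(len(BEHAVIOR_VARS))]
        return MaskingScheme(kind="neural", conditioning=conditioning)
    if kind == "behavior":
        return MaskingScheme(kind="behavior")
    if kind == "within_modality":
        target = present_modalities[rng.integers(len(present_modalities))]
        return MaskingScheme(kind="within_modality", target_modality=target, ratio=ratio)
    return MaskingScheme(kind="cross_modal", ratio=ratio)


def _random_subset(mask_pool: np.ndarray, ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Mask round(ratio * n) of the pooled positions, uniformly without
    replacement."""
    idx = np.flatnonzero(mask_pool)
    n_mask = int(round(ratio * idx.size))
    if n_mask == 0:
        raise ConfigError(
            f"mask ratio {ratio} selects zero of {idx.size} tokens; no loss positions"
        )
    chosen = rng.choice(idx, size=n_mask, replace=False)
    out = np.zeros_like(mask_pool)
    out[chosen] = True
    return out


def build_mask(scheme: MaskingScheme, layout: TokenLayout,
               rng: np.random.Generator | None = None) -> MaskPlan:
    """Materialize a scheme on a concrete layout."""
    present = layout.present
    behavior_present = [v for v in BEHAVIOR_VARS if v in present]

    if scheme.kind == "neural":
        if "neural" not in present:
            raise ConfigError("neural masking on a layout without neural tokens")
        mask = layout.token_mask("neural")
        if scheme.conditioning != ALL:
            if scheme.conditioning not in present:
                raise ConfigError(
                    f"conditioning variable '{scheme.conditioning}' absent from layout"
                )
            for var in behavior_present:
                if var != scheme.conditioning:
                    mask |= layout.token_mask(var)
        return MaskPlan(mask=mask, loss_mask=layout.token_mask("neural"))

    if scheme.kind == "behavior":
        if not behavior_present:
            raise ConfigError("behavior masking on a layout without behavior tokens")
        mask = np.zeros(layout.length, dtype=bool)
        for var in behavior_present:
            mask |= layout.token_mask(var)
        return MaskPlan(mask=mask, loss_mask=mask.copy())

    if rng is None:
        raise ConfigError("random masking schemes need an rng")

    if scheme.kind == "within_modality":
        if scheme.target_modality not in present:
            raise ConfigError(f"target modality '{scheme.target_modality}' absent from layout")
        pool = layout.token_mask(scheme.target_modality)
        mask = _random_subset(pool, scheme.ratio, rng)
        return MaskPlan(mask=mask, loss_mask=mask.copy())

    # cross_modal: random fraction of all tokens
    pool = np.ones(layout.length, dtype=bool)
    mask = _random_subset(pool, scheme.ratio, rng)
    return MaskPlan(mask=mask, loss_mask=mask.copy())


def discrete_loss_units(layout: TokenLayout, plan: MaskPlan) -> dict[str, np.ndarray]:
    """Per discrete variable, the boolean over its T replicas that are loss
    positions (full schemes mask them all-or-none; random schemes per-token)."""
    out = {}
    for var in DISCRETE_VARS:
        if var in layout.present:
            out[var] = plan.loss_mask[layout.slice_for(var)]
    return out


def apply_mask(seq: TokenSequence, plan_mask, mask_token) -> TokenSequence:
    """Replace masked token *content* with the learned mask token.

    Modality/session embeddings (``seq.embed``) are untouched, so masked
    positions still announce what is to be reconstructed and where.
    ``plan_mask`` is a :class:`MaskPlan`, a boolean (L,) vector, or a
    boolean (B, L) batch of per-trial masks.
    """
    mask = plan_mask.mask if isinstance(plan_mask, MaskPlan) else np.asarray(plan_mask)
    if mask.shape[-1] != seq.length:
        raise ConfigError(
            f"mask length {mask.shape[-1]} does not match sequence length {seq.length}"
        )
    masked_content = where(mask[..., None], mask_token, seq.content)
    return TokenSequence(
        content=masked_content, embed=seq.embed, layout=seq.layout, time_index=seq.time_index
    )
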