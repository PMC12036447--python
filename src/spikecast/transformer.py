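"""Shared pre-norm transformer encoder with rotary attention, plus the
session- and modality-specific output heads.

The encoder runs full bidirectional self-attention over the unified
multimodal token sequence.  Temporal position enters through rotary
embeddings (RoPE) applied to queries and keys inside attention, so the
model sees *relative* time offsets; an additive temporal embedding can be
enabled in the config as an alternative.  Output heads are linear maps per
session: a rate head (through a positive link, softplus by default) for
Poisson spike-count emission, one scalar head per continuous behavior, and
one logit head per discrete behavior.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .autodiff import (
    AdamW,
    Tensor,
    concat,
    dropout,
    embedding,
    gelu,
    layer_norm,
    parameter,
    softmax,
    softplus,
)
from .errors import ConfigError, DataError
from .tokenization import (
    CONTINUOUS_VARS,
    DISCRETE_CARDINALITY,
    DISCRETE_VARS,
    MODALITIES,
    SessionAdapters,
    TokenSequence,
)

__all__ = ["ModelConfig", "Backbone", "OutputHeads", "ModelState",
           "decode_rates", "decode_continuous", "decode_discrete"]


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    width: int = Field(default=128, ge=2)
    n_layers: int = Field(default=4, ge=1)
    n_heads: int = Field(default=4, ge=1)
    d_ff: int = Field(default=512, ge=1)
    dropout: float = Field(default=0.1, ge=0, lt=1)
    rate_link: str = Field(default="softplus", pattern="^(softplus|exp)$")
    rope_base: float = 10000.0
    additive_temporal_pe: bool = False
    max_bins: int = Field(default=256, ge=1)  # only used by the additive PE table
    seed: int = 0

    @model_validator(mode="after")
    def _rotary_divisibility(self):
        if self.width % (2 * self.n_heads) != 0:
            raise ValueError(
                f"width ({self.width}) must be divisible by 2*n_heads "
                f"({2 * self.n_heads}) for rotary pairing"
            )
        return self


def _linear_init(rng, fan_in, fan_out):
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), (fan_in, fan_out))


class Backbone:
    """Shared transformer weights plus the shared modality embeddings and
    mask token."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        d, f = cfg.width, cfg.d_ff
        self.blocks = []
        for _ in range(cfg.n_layers):
            blk = {
                "ln1_g": parameter(np.ones(d)), "ln1_b": parameter(np.zeros(d)),
                "wq": parameter(_linear_init(rng, d, d)), "bq": parameter(np.zeros(d)),
                "wk": parameter(_linear_init(rng, d, d)), "bk": parameter(np.zeros(d)),
                "wv": parameter(_linear_init(rng, d, d)), "bv": parameter(np.zeros(d)),
                "wo": parameter(_linear_init(rng, d, d)), "bo": parameter(np.zeros(d)),
                "ln2_g": parameter(np.ones(d)), "ln2_b": parameter(np.zeros(d)),
                "w1": parameter(_linear_init(rng, d, f)), "b1": parameter(np.zeros(f)),
                "w2": parameter(_linear_init(rng, f, d)), "b2": parameter(np.zeros(d)),
            }
            self.blocks.append(blk)
        self.ln_f_g = parameter(np.ones(d))
        self.ln_f_b = parameter(np.zeros(d))
        self.modality_embeddings = parameter(rng.normal(0.0, 0.02, (len(MODALITIES), d)))
        self.mask_token = parameter(rng.normal(0.0, 0.02, (d,)))
        self.temporal_pe = (
            parameter(rng.normal(0.0, 0.02, (cfg.max_bins, d)))
            if cfg.additive_temporal_pe else None
        )

    def parameters(self):
        for i, blk in enumerate(self.blocks):
            for name, p in blk.items():
                yield f"blocks.{i}.{name}", p
        yield "ln_f_g", self.ln_f_g
        yield "ln_f_b", self.ln_f_b
        yield "modality_embeddings", self.modality_embeddings
        yield "mask_token", self.mask_token
        if self.temporal_pe is not None:
            yield "temporal_pe", self.temporal_pe

    # -- rotary helpers ----------------------------------------------------
    def _rope_tables(self, time_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hd = self.cfg.width // self.cfg.n_heads
        half = hd // 2
        freqs = self.cfg.rope_base ** (-np.arange(half, dtype=np.float64) * 2.0 / hd)
        angles = np.asarray(time_index, dtype=np.float64)[:, None] * freqs  # (L, half)
        # (L, half) broadcasts over the (..., H, L, half) query/key heads
        return np.cos(angles).astype(np.float32), np.sin(angles).astype(np.float32)

    @staticmethod
    def _rotate(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
        half = x.shape[-1] // 2
        x1 = x[..., :half]
        x2 = x[..., half:]
        c, s = Tensor(cos), Tensor(sin)
        return concat([x1 * c - x2 * s, x1 * s + x2 * c], axis=-1)

    def _attention(self, blk, x: Tensor, cos, sin, rng, training) -> Tensor:
        cfg = self.cfg
        b_dims = x.shape[:-2]
        L, d = x.shape[-2], cfg.width
        h, hd = cfg.n_heads, d // cfg.n_heads

        def heads(t: Tensor) -> Tensor:
            t = t.reshape(b_dims + (L, h, hd))
            axes = tuple(range(len(b_dims))) + (len(b_dims) + 1, len(b_dims), len(b_dims) + 2)
            return t.transpose(axes)  # (..., H, L, hd)

        q = heads(x @ blk["wq"] + blk["bq"])
        k = heads(x @ blk["wk"] + blk["bk"])
        v = heads(x @ blk["wv"] + blk["bv"])
        q = self._rotate(q, cos, sin)
        k = self._rotate(k, cos, sin)
        scores = (q @ k.transpose(tuple(range(q.ndim - 2)) + (q.ndim - 1, q.ndim - 2))) * (
            1.0 / np.sqrt(hd)
        )
        att = softmax(scores, axis=-1)
        out = att @ v  # (..., H, L, hd)
        axes = tuple(range(len(b_dims))) + (len(b_dims) + 1, len(b_dims), len(b_dims) + 2)
        out = out.transpose(axes).reshape(b_dims + (L, d))
        out = out @ blk["wo"] + blk["bo"]
        return dropout(out, cfg.dropout, rng, training)

    def encode(self, seq: TokenSequence, rng: np.random.Generator | None = None,
               training: bool = False) -> Tensor:
        """Run the encoder over ``seq.tokens``; returns per-token width-D
        representations with the same leading shape."""
        x = seq.tokens
        if x.shape[-1] != self.cfg.width:
            raise ConfigError(
                f"sequence width {x.shape[-1]} does not match model width {self.cfg.width}"
            )
        if training and rng is None:
            raise ConfigError("training-mode encode needs an rng for dropout")
        cos, sin = self._rope_tables(seq.time_index)
        for blk in self.blocks:
            h = layer_norm(x, blk["ln1_g"], blk["ln1_b"])
            x = x + self._attention(blk, h, cos, sin, rng, training)
            h = layer_norm(x, blk["ln2_g"], blk["ln2_b"])
            h = gelu(h @ blk["w1"] + blk["b1"]) @ blk["w2"] + blk["b2"]
            x = x + dropout(h, self.cfg.dropout, rng, training)
        return layer_norm(x, self.ln_f_g, self.ln_f_b)


class OutputHeads:
    """Per-session linear decoders: rates, continuous traces, class logits."""

    def __init__(self, n_neurons: int, width: int, rng: np.random.Generator,
                 rate_bias_init: float = 0.0):
        self.n_neurons = n_neurons
        self.W_rate = parameter(_linear_init(rng, width, n_neurons))
        self.b_rate = parameter(np.full(n_neurons, rate_bias_init))
        self.W_continuous = {
            name: parameter(_linear_init(rng, width, 1)) for name in CONTINUOUS_VARS
        }
        self.b_continuous = {name: parameter(np.zeros(1)) for name in CONTINUOUS_VARS}
        self.W_discrete = {
            name: parameter(_linear_init(rng, width, DISCRETE_CARDINALITY[name]))
            for name in DISCRETE_VARS
        }
        self.b_discrete = {
            name: parameter(np.zeros(DISCRETE_CARDINALITY[name])) for name in DISCRETE_VARS
        }

    def parameters(self):
        yield "W_rate", self.W_rate
        yield "b_rate", self.b_rate
        for name in CONTINUOUS_VARS:
            yield f"W_continuous.{name}", self.W_continuous[name]
            yield f"b_continuous.{name}", self.b_continuous[name]
        for name in DISCRETE_VARS:
            yield f"W_discrete.{name}", self.W_discrete[name]
            yield f"b_discrete.{name}", self.b_discrete[name]


def decode_rates(e_neural: Tensor, heads: OutputHeads, link: str = "softplus") -> Tensor:
    """Map neural-segment representations (..., T, D) to strictly positive
    firing rates (..., T, neurons), in expected counts per bin."""
    z = e_neural @ heads.W_rate + heads.b_rate
    if link == "softplus":
        # tiny floor keeps rates strictly positive where float32 softplus
        # underflows for very negative pre-activations
        return softplus(z) + 1e-8
    if link == "exp":
        return z.exp() + 1e-8
    raise ConfigError(f"unknown rate link '{link}'")


def decode_continuous(e_var: Tensor, heads: OutputHeads, variable: str) -> Tensor:
    """Map a behavior segment (..., T, D) to a length-T trace (..., T)."""
    if variable not in CONTINUOUS_VARS:
        raise ConfigError(f"unknown continuous variable '{variable}'")
    out = e_var @ heads.W_continuous[variable] + heads.b_continuous[variable]
    return out.reshape(out.shape[:-1])


def decode_discrete(e_var: Tensor, heads: OutputHeads, variable: str,
                    pool_weights: np.ndarray | None = None) -> Tensor:
    """Map a discrete-variable segment (..., T, D) to one logit vector per
    trial by mean-pooling per-token logits over the T replicas.

    ``pool_weights`` (..., T), if given, restricts pooling to a weighted
    subset (e.g. the masked replicas); it must sum to 1 over T per trial.
    """
    if variable not in DISCRETE_VARS:
        raise ConfigError(f"unknown discrete variable '{variable}'")
    logits = e_var @ heads.W_discrete[variable] + heads.b_discrete[variable]  # (..., T, C)
    T = logits.shape[-2]
    if pool_weights is None:
        return logits.mean(axis=-2)
    w = Tensor(np.asarray(pool_weights, dtype=np.float32)[..., None])
    return (logits * w).sum(axis=-2)


def predicted_class(logits: np.ndarray) -> np.ndarray:
    """Argmax with ties broken toward the lowest class index."""
    return np.argmax(logits, axis=-1)


class ModelState:
    """Backbone plus the per-session adapters and heads, with a registry.

    The parameter partition — shared backbone vs. per-session modules — is
    what pretraining updates jointly and fine-tuning splits (backbone frozen
    by default).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg, self.rng)
        self.sessions: dict[str, dict] = {}
        self.history: dict = {"train_loss": [], "valid_loss": [], "scheme_log": []}

    def register_session(self, session_id: str, n_neurons: int,
                         rate_bias_init: float = 0.0) -> None:
        if session_id in self.sessions:
            raise ConfigError(f"session '{session_id}' already registered")
        self.sessions[session_id] = {
            "adapters": SessionAdapters(n_neurons, self.cfg.width, self.rng),
            "heads": OutputHeads(n_neurons, self.cfg.width, self.rng,
                                 rate_bias_init=rate_bias_init),
            "n_neurons": n_neurons,
        }

    def require_session(self, session_id: str) -> dict:
        if session_id not in self.sessions:
            raise ConfigError(f"session '{session_id}' is not registered")
        return self.sessions[session_id]

    # -- parameter partition ----------------------------------------------
    def backbone_parameters(self):
        yield from self.backbone.parameters()

    def session_parameters(self, session_id: str | None = None):
        ids = [session_id] if session_id is not None else sorted(self.sessions)
        for sid in ids:
            mod = self.require_session(sid)
            for name, p in mod["adapters"].parameters():
                yield f"sessions.{sid}.adapters.{name}", p
            for name, p in mod["heads"].parameters():
                yield f"sessions.{sid}.heads.{name}", p

    def all_parameters(self):
        yield from self.backbone_parameters()
        yield from self.session_parameters()

    def audit_partition(self) -> None:
        """Assert backbone and session parameters partition all trainables."""
        backbone_ids = {id(p) for _, p in self.backbone_parameters()}
        session_ids = {id(p) for _, p in self.session_parameters()}
        if backbone_ids & session_ids:
            raise AssertionError("backbone and session parameter sets overlap")
        all_ids = {id(p) for _, p in self.all_parameters()}
        if all_ids != backbone_ids | session_ids:
            raise AssertionError("parameter registry does not cover all trainables")

    def snapshot(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.all_parameters()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for name, p in self.all_parameters():
            p.data = snap[name].copy()
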