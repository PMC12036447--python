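"""Tokenization of multimodal trial data into a unified token sequence.

Each modality is tokenized independently — spike-count bins and continuous
behavior bins through session-specific linear maps, discrete trial-level
variables by replicating a learned category embedding T times — and the
per-modality segments are concatenated in a fixed order (neural, wheel,
whisker, choice, block).  Modality and session embeddings are additive;
temporal position is carried as per-token time indices consumed by rotary
attention in the encoder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, embedding, parameter
from .errors import ConfigError, DataError

__all__ = [
    "MODALITIES",
    "CONTINUOUS_VARS",
    "DISCRETE_VARS",
    "DISCRETE_CARDINALITY",
    "Segment",
    "TokenLayout",
    "SessionAdapters",
    "TokenSequence",
    "tokenize_neural",
    "tokenize_continuous",
    "tokenize_discrete",
    "assemble_sequence",
    "assemble_batch",
]

#: fixed concatenation order of modality segments
MODALITIES = ("neural", "wheel", "whisker", "choice", "block")
CONTINUOUS_VARS = ("wheel", "whisker")
DISCRETE_VARS = ("choice", "block")
DISCRETE_CARDINALITY = {"choice": 2, "block": 3}


@dataclass(frozen=True)
class Segment:
    modality: str
    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass
class TokenLayout:
    """Where each modality's tokens sit in the concatenated sequence."""

    segments: list[Segment]
    n_bins: int
    session_id: str
    missing: tuple[str, ...] = ()

    def __post_init__(self):
        seen = set()
        for seg in self.segments:
            if seg.modality in seen:
                raise ConfigError(f"duplicate modality '{seg.modality}' in layout")
            seen.add(seg.modality)

    @property
    def length(self) -> int:
        return sum(seg.length for seg in self.segments)

    @property
    def present(self) -> tuple[str, ...]:
        return tuple(seg.modality for seg in self.segments)

    def segment(self, modality: str) -> Segment:
        for seg in self.segments:
            if seg.modality == modality:
                return seg
        raise ConfigError(f"modality '{modality}' absent from layout")

    def slice_for(self, modality: str) -> slice:
        seg = self.segment(modality)
        return slice(seg.start, seg.stop)

    def token_mask(self, modality: str) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        mask[self.slice_for(modality)] = True
        return mask

    def time_index(self) -> np.ndarray:
        """Per-token time index: 0..T-1 within every segment (discrete
        replicas are co-located with their trial's bins)."""
        return np.concatenate([np.arange(seg.length) for seg in self.segments])

    def modality_index(self) -> np.ndarray:
        return np.concatenate(
            [np.full(seg.length, MODALITIES.index(seg.modality)) for seg in self.segments]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "session_id": self.session_id,
                "n_bins": self.n_bins,
                "segments": [
                    {"modality": s.modality, "start": s.start, "length": s.length}
                    for s in self.segments
                ],
                "missing": list(self.missing),
            }
        )


class SessionAdapters:
    """Session-specific input maps plus the session embedding.

    ``W_X_input`` maps that session's neuron dimension to model width D;
    each continuous behavior has a 1->D map; each discrete behavior has a
    per-category embedding table.  The learned mask token and the modality
    embeddings live on the shared backbone, not here.
    """

    def __init__(self, n_neurons: int, width: int, rng: np.random.Generator):
        self.n_neurons = n_neurons
        self.width = width
        self.W_X_input = parameter(rng.normal(0.0, 1.0 / np.sqrt(n_neurons), (n_neurons, width)))
        self.b_X = parameter(np.zeros(width))
        self.W_Y_input = {
            name: parameter(rng.normal(0.0, 1.0, (1, width))) for name in CONTINUOUS_VARS
        }
        self.b_Y = {name: parameter(np.zeros(width)) for name in CONTINUOUS_VARS}
        self.discrete_embedding = {
            name: parameter(rng.normal(0.0, 0.5, (DISCRETE_CARDINALITY[name], width)))
            for name in DISCRETE_VARS
        }
        self.session_embedding = parameter(rng.normal(0.0, 0.02, (width,)))

    def parameters(self):
        yield "W_X_input", self.W_X_input
        yield "b_X", self.b_X
        for name in CONTINUOUS_VARS:
            yield f"W_Y_input.{name}", self.W_Y_input[name]
            yield f"b_Y.{name}", self.b_Y[name]
        for name in DISCRETE_VARS:
            yield f"discrete_embedding.{name}", self.discrete_embedding[name]
        yield "session_embedding", self.session_embedding


@dataclass
class TokenSequence:
    """A unified token stream for one trial (or a batch of trials).

    ``content`` holds the tokenized data (this is what masking replaces);
    ``embed`` holds the additive modality + session (+ optional temporal)
    embeddings.  The transformer consumes ``tokens = content + embed``.
    """

    content: Tensor  # (L, D) or (B, L, D)
    embed: Tensor  # broadcastable to content
    layout: TokenLayout
    time_index: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.time_index is None:
            self.time_index = self.layout.time_index()

    @property
    def tokens(self) -> Tensor:
        return self.content + self.embed

    @property
    def length(self) -> int:
        return self.content.shape[-2]

    def split(self, representations: Tensor) -> dict[str, Tensor]:
        """Re-split per-token transformer output into per-modality blocks."""
        return {
            seg.modality: representations[..., seg.start: seg.stop, :]
            for seg in self.layout.segments
        }


def _as_float(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32)


def tokenize_neural(spikes_trial: np.ndarray, adapters: SessionAdapters,
                    session_id: str = "") -> Tensor:
    """Map a (neurons, T) count matrix — or a (B, neurons, T) batch — to
    T tokens of width D.  Token t depends only on bin t's count vector."""
    spikes_trial = np.asarray(spikes_trial)
    n_neurons = spikes_trial.shape[-2]
    if n_neurons != adapters.n_neurons:
        raise DataError(
            f"session '{session_id}': spike matrix has {n_neurons} neurons "
            f"but the session input matrix expects {adapters.n_neurons}"
        )
    x = Tensor(_as_float(np.swapaxes(spikes_trial, -1, -2)))  # (..., T, N)
    return x @ adapters.W_X_input + adapters.b_X


def tokenize_continuous(trace: np.ndarray, adapters: SessionAdapters, variable: str) -> Tensor:
    """Map a length-T trace — or (B, T) batch — to T tokens of width D."""
    if variable not in CONTINUOUS_VARS:
        raise ConfigError(f"'{variable}' is not a continuous behavior variable")
    x = Tensor(_as_float(np.asarray(trace)[..., None]))  # (..., T, 1)
    return x @ adapters.W_Y_input[variable] + adapters.b_Y[variable]


def tokenize_discrete(value, T: int, adapters: SessionAdapters, variable: str) -> Tensor:
    """Replicate the category embedding of ``value`` T times.

    ``value`` may be a scalar or a batch of per-trial labels."""
    if variable not in DISCRETE_VARS:
        raise ConfigError(f"'{variable}' is not a discrete behavior variable")
    values = np.asarray(value)
    n_cat = DISCRETE_CARDINALITY[variable]
    if values.min() < 0 or values.max() >= n_cat:
        raise DataError(
            f"'{variable}' label out of range [0, {n_cat}): {values.min()}..{values.max()}"
        )
    idx = np.repeat(values[..., None], T, axis=-1)  # (..., T)
    return embedding(adapters.discrete_embedding[variable], idx)


def _build_layout(present: list[str], T: int, session_id: str) -> TokenLayout:
    segments, start = [], 0
    for modality in MODALITIES:
        if modality in present:
            segments.append(Segment(modality, start, T))
            start += T
    missing = tuple(m for m in MODALITIES if m not in present)
    return TokenLayout(segments=segments, n_bins=T, session_id=session_id, missing=missing)


def assemble_batch(
    trial_data: dict[str, np.ndarray],
    adapters: SessionAdapters,
    session_id: str,
    modality_embeddings: Tensor,
    temporal_embeddings: Tensor | None = None,
) -> TokenSequence:
    """Tokenize a batch of trials into one (B, L, D) sequence.

    ``trial_data`` maps modality names to batched arrays: ``neural`` is
    (B, neurons, T); ``wheel``/``whisker`` are (B, T); ``choice``/``block``
    are (B,).  Missing modalities are simply omitted from the dict (and the
    sequence); present modalities must agree on T.
    """
    present = [m for m in MODALITIES if m in trial_data]
    if not present:
        raise DataError("no modalities present")
    if "neural" in trial_data:
        T = np.asarray(trial_data["neural"]).shape[-1]
    elif any(v in trial_data for v in CONTINUOUS_VARS):
        T = np.asarray(trial_data[[v for v in CONTINUOUS_VARS if v in trial_data][0]]).shape[-1]
    else:
        raise DataError("discrete-only input needs an explicit T; include a timed modality")

    pieces = []
    for modality in present:
        if modality == "neural":
            tok = tokenize_neural(trial_data["neural"], adapters, session_id)
        elif modality in CONTINUOUS_VARS:
            tok = tokenize_continuous(trial_data[modality], adapters, modality)
        else:
            tok = tokenize_discrete(trial_data[modality], T, adapters, modality)
        if tok.shape[-2] != T:
            raise DataError(f"modality '{modality}' has {tok.shape[-2]} bins, expected {T}")
        pieces.append(tok)
    content = concat(pieces, axis=-2)

    layout = _build_layout(present, T, session_id)
    embed = embedding(modality_embeddings, layout.modality_index()) + adapters.session_embedding
    time_index = layout.time_index()
    if temporal_embeddings is not None:
        embed = embed + embedding(temporal_embeddings, time_index)
    return TokenSequence(content=content, embed=embed, layout=layout, time_index=time_index)


def assemble_sequence(
    trial_data: dict[str, np.ndarray],
    adapters: SessionAdapters,
    session_id: str,
    modality_embeddings: Tensor,
    temporal_embeddings: Tensor | None = None,
) -> TokenSequence:
    """Single-trial version of :func:`assemble_batch` (tokens shaped (L, D))."""
    return assemble_batch(trial_data, adapters, session_id, modality_embeddings,
                          temporal_embeddings)
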