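"""Model/Results surface tying the pipeline together.

:class:`EncoderDecoderModel` is constructed from one or more session
bundles; :meth:`~EncoderDecoderModel.fit` runs multi-task-masked training
and returns an :class:`EncoderDecoderResults` carrying the trained state,
loss history, and evaluation/embedding methods, with a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np

from .embeddings import (
    NeuronEmbedding,
    RegionClassificationReport,
    classify_regions,
    extract_embeddings,
)
from .errors import ConfigError, DataError
from .metrics import EvalReport, reports_to_frame
from .simulate import SessionBundle, SplitIndices, SplitSpec, split_trials
from .training import TrainConfig, evaluate_decoding, evaluate_encoding, finetune, pretrain
from .transformer import ModelConfig, ModelState

__all__ = ["EncoderDecoderModel", "EncoderDecoderResults"]


class EncoderDecoderModel:
    """Multimodal masked-transformer model of spiking activity and behavior.

    Parameters
    ----------
    sessions
        One or more :class:`SessionBundle` objects (one per animal/recording).
    model_config, train_config
        Architecture and optimization settings; defaults are a desk-scale
        width-128, 4-layer, 4-head encoder.
    splits
        Optional per-session train/valid/test trial indices; by default a
        seeded 70/10/20 split is drawn per session.
    """

    def __init__(
        self,
        sessions: list[SessionBundle] | SessionBundle,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        splits: dict[str, SplitIndices] | None = None,
    ):
        if isinstance(sessions, SessionBundle):
            sessions = [sessions]
        if not sessions:
            raise DataError("at least one session is required")
        self.sessions = list(sessions)
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        if splits is None:
            splits = {
                b.session_id: split_trials(b, SplitSpec(seed=self.train_config.seed))
                for b in self.sessions
            }
        self.splits = splits

    @classmethod
    def from_files(cls, paths, **kwargs) -> "EncoderDecoderModel":
        from .sessionio import read_session

        return cls([read_session(p) for p in paths], **kwargs)

    def fit(self) -> "EncoderDecoderResults":
        state = pretrain(self.sessions, self.model_config, self.train_config, self.splits)
        return EncoderDecoderResults(state, self.sessions, self.splits, self.train_config)


class EncoderDecoderResults:
    """Fitted model: trained weights plus evaluation and embedding views."""

    def __init__(self, state: ModelState, sessions: list[SessionBundle],
                 splits: dict[str, SplitIndices], train_config: TrainConfig):
        self.state = state
        self._bundles = {b.session_id: b for b in sessions}
        self.splits = splits
        self.train_config = train_config

    @property
    def session_ids(self) -> list[str]:
        return sorted(self._bundles)

    @property
    def loss_history(self) -> dict:
        return {
            "train": list(self.state.history.get("train_loss", [])),
            "valid": list(self.state.history.get("valid_loss", [])),
            "best_epoch": self.state.history.get("best_epoch"),
        }

    def _bundle(self, session_id: str) -> SessionBundle:
        if session_id not in self._bundles:
            raise ConfigError(f"no data attached for session '{session_id}'")
        return self._bundles[session_id]

    # -- evaluation --------------------------------------------------------
    def evaluate_decoding(self, session_id: str | None = None) -> list[EvalReport]:
        ids = [session_id] if session_id else self.session_ids
        return [
            evaluate_decoding(self.state, self._bundle(sid), self.splits[sid])
            for sid in ids
        ]

    def evaluate_encoding(self, conditioning="all",
                          session_id: str | None = None) -> list[EvalReport]:
        ids = [session_id] if session_id else self.session_ids
        return [
            evaluate_encoding(self.state, self._bundle(sid), self.splits[sid], conditioning)
            for sid in ids
        ]

    # -- transfer ----------------------------------------------------------
    def finetune(self, new_session: SessionBundle,
                 ft_config: TrainConfig | None = None,
                 splits: SplitIndices | None = None,
                 unfreeze_backbone: bool = False) -> "EncoderDecoderResults":
        ft_config = ft_config or self.train_config
        if splits is None:
            splits = split_trials(new_session, SplitSpec(seed=ft_config.seed))
        finetune(self.state, new_session, ft_config, splits, unfreeze_backbone)
        self._bundles[new_session.session_id] = new_session
        self.splits[new_session.session_id] = splits
        return self

    # -- neuron embeddings -------------------------------------------------
    def neuron_embeddings(self, mode: str = "multimodal",
                          session_ids: list[str] | None = None) -> list[NeuronEmbedding]:
        labels = {sid: self._bundles[sid].region_label
                  for sid in (session_ids or self.session_ids)}
        return extract_embeddings(self.state, labels, session_ids=session_ids, mode=mode)

    def classify_regions(self, n_folds: int = 5, seed: int = 0,
                         mode: str = "multimodal",
                         shuffle_labels: bool = False) -> RegionClassificationReport:
        return classify_regions(self.neuron_embeddings(mode=mode), n_folds=n_folds,
                                seed=seed, shuffle_labels=shuffle_labels)

    # -- persistence & presentation ---------------------------------------
    def save(self, path) -> None:
        from .sessionio import save_checkpoint

        save_checkpoint(self.state, path)

    def summary(self) -> str:
        """Text summary: configuration, training trace, and per-session
        held-out decoding and encoding performance."""
        cfg = self.state.cfg
        lines = [
            "Multimodal masked encoder-decoder of spikes and behavior",
            "=" * 64,
            f"sessions: {len(self.session_ids)}   "
            f"width: {cfg.width}  layers: {cfg.n_layers}  heads: {cfg.n_heads}",
            f"rate link: {cfg.rate_link}   best epoch: {self.loss_history['best_epoch']}",
            "-" * 64,
        ]
        decode = self.evaluate_decoding()
        encode = self.evaluate_encoding("all")
        lines.append(f"{'session':<24}{'choice':>8}{'block':>8}{'wheel':>8}"
                     f"{'whisker':>9}{'co-bps':>9}")
        for dr, er in zip(decode, encode):
            lines.append(
                f"{dr.session_id:<24}{dr.acc_choice:>8.3f}{dr.acc_block:>8.3f}"
                f"{dr.r2_wheel:>8.3f}{dr.r2_whisker:>9.3f}{er.co_bps['all']:>9.3f}"
            )
        lines.append("-" * 64)
        lines.append("choice/block: test accuracy; wheel/whisker: single-trial R^2;")
        lines.append("co-bps: bits/spike of encoding from all behavior variables.")
        return "\n".join(lines)

    def to_frame(self):
        return reports_to_frame(self.evaluate_decoding() + self.evaluate_encoding("all"))
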