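"""Neuron embeddings from the session weight matrices, and their use to
predict anatomical region.

Two matrices in the model store neuron-specific information: the session
input matrix (neurons x D) that maps spike counts into the model, and the
rate head (D x neurons, taken pre-link) that maps representations back to
rates.  For a multimodal model, neuron k's embedding is the concatenation of
its row in both (length 2D); unimodal variants use one matrix (length D).
A linear support-vector classifier with standardized features, under
stratified 5-fold cross-validation, tests how well these embeddings predict
the neuron's brain region — anatomy is never used during training, so any
skill is an emergent property of the learned weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import ConfigError, DataError
from .transformer import ModelState

__all__ = ["NeuronEmbedding", "RegionClassificationReport",
           "extract_embeddings", "classify_regions", "embeddings_to_matrix"]

EMBEDDING_MODES = ("multimodal", "encoding", "decoding")


@dataclass(frozen=True)
class NeuronEmbedding:
    neuron_id: int
    session_id: str
    vector: np.ndarray  # 2D for multimodal models, D for unimodal variants
    region_label: str


@dataclass
class RegionClassificationReport:
    accuracy: float
    balanced_accuracy: float
    fold_scores: list[float]
    confusion: pd.DataFrame  # rows = true regions, row-normalized
    classes: list[str]
    majority_rate: float
    n_neurons: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "fold_scores": self.fold_scores,
            "classes": self.classes,
            "majority_rate": self.majority_rate,
            "n_neurons": self.n_neurons,
            "confusion": self.confusion.to_dict(),
            **self.extras,
        }


def extract_embeddings(
    state: ModelState,
    region_labels: dict[str, np.ndarray],
    session_ids: list[str] | None = None,
    mode: str = "multimodal",
) -> list[NeuronEmbedding]:
    """One embedding per registered neuron.

    ``mode='multimodal'`` concatenates the input-matrix row and the rate-head
    row (length 2D); ``'encoding'`` uses the rate head only, ``'decoding'``
    the input matrix only (length D).  The rate-head rows are taken pre-link.
    """
    if mode not in EMBEDDING_MODES:
        raise ConfigError(f"unknown embedding mode '{mode}'")
    ids = session_ids if session_ids is not None else sorted(state.sessions)
    out = []
    for sid in ids:
        mod = state.require_session(sid)
        labels = np.asarray(region_labels[sid])
        n = mod["n_neurons"]
        if labels.shape[0] != n:
            raise DataError(
                f"session '{sid}': {labels.shape[0]} region labels for {n} neurons"
            )
        w_in = mod["adapters"].W_X_input.data  # (N, D)
        w_rate = mod["heads"].W_rate.data.T  # (N, D)
        if mode == "multimodal":
            vectors = np.concatenate([w_in, w_rate], axis=1)
        elif mode == "encoding":
            vectors = w_rate
        else:
            vectors = w_in
        out.extend(
            NeuronEmbedding(k, sid, vectors[k].copy(), str(labels[k])) for k in range(n)
        )
    return out


def embeddings_to_matrix(embeddings: list[NeuronEmbedding]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([e.vector for e in embeddings])
    y = np.array([e.region_label for e in embeddings])
    return x, y


def classify_regions(
    embeddings: list[NeuronEmbedding] | tuple[np.ndarray, np.ndarray],
    n_folds: int = 5,
    seed: int = 0,
    shuffle_labels: bool = False,
) -> RegionClassificationReport:
    """Stratified K-fold linear-SVC region classification.

    Features are standardized per dimension inside each training fold;
    sessions may span folds.  ``shuffle_labels`` permutes the labels once
    (seeded) to produce the chance-level null.
    """
    if isinstance(embeddings, tuple):
        x, y = embeddings
    else:
        x, y = embeddings_to_matrix(embeddings)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        lacking = classes[counts < n_folds]
        raise DataError(
            f"classes {lacking.tolist()} have fewer than {n_folds} neurons; "
            "merge regions or reduce n_folds"
        )
    rng = np.random.default_rng(seed)
    if shuffle_labels:
        y = y[rng.permutation(y.shape[0])]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_scores, y_true_all, y_pred_all = [], [], []
    for train_idx, test_idx in skf.split(x, y):
        clf = make_pipeline(StandardScaler(), LinearSVC(C=1.0, random_state=seed))
        clf.fit(x[train_idx], y[train_idx])
        pred = clf.predict(x[test_idx])
        fold_scores.append(float(np.mean(pred == y[test_idx])))
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)

    cm = confusion_matrix(y_true, y_pred, labels=classes).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row_sums, out=np.zeros_like(cm), where=row_sums > 0)
    confusion = pd.DataFrame(cm_norm, index=classes, columns=classes)
    return RegionClassificationReport(
        accuracy=float(np.mean(y_true == y_pred)),
        balanced_accuracy=float(np.trace(cm_norm) / classes.size),
        fold_scores=fold_scores,
        confusion=confusion,
        classes=classes.tolist(),
        majority_rate=float(counts.max() / counts.sum()),
        n_neurons=int(y.shape[0]),
    )
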