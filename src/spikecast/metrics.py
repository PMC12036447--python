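"""Training losses and evaluation metrics.

Losses: Poisson negative log-likelihood for spike counts (full constant
included via log-gamma), mean squared error for continuous behaviors, and
numerically stable cross-entropy for discrete behaviors.

Metrics: bits per spike against a constant-rate null (the co-smoothing
convention: the null is each neuron's mean training-split rate), single-trial
R-squared against the trial-averaged trace (PSTH), and classification
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_softmax

from .errors import ConfigError, DataError

__all__ = [
    "poisson_nll",
    "bits_per_spike",
    "single_trial_r2",
    "classification_accuracy",
    "cross_entropy",
    "mse",
    "LossBreakdown",
    "EvalReport",
    "reports_to_frame",
]

_LN2 = float(np.log(2.0))


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.size and not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.round(counts)):
            raise DataError("spike counts must be integers")
    if counts.size and counts.min() < 0:
        raise DataError("spike counts must be nonnegative")
    return counts.astype(np.float64)


def poisson_nll(rates: np.ndarray, counts: np.ndarray) -> float:
    """Mean Poisson negative log-likelihood per bin, in nats.

    NLL = mean over bins of [lambda - k*ln(lambda) + ln(k!)], with the
    constant computed through log-gamma.
    """
    rates = np.asarray(rates, dtype=np.float64)
    counts = _check_counts(counts)
    if rates.shape != counts.shape:
        raise DataError(f"shape mismatch: rates {rates.shape} vs counts {counts.shape}")
    if rates.size == 0:
        raise DataError("empty input")
    if rates.min() <= 0:
        raise DataError("rates must be strictly positive")
    return float(np.mean(rates - counts * np.log(rates) + gammaln(counts + 1.0)))


def bits_per_spike(pred_rates: np.ndarray, counts: np.ndarray,
                   null_rates: np.ndarray) -> float:
    """Likelihood improvement of predicted rates over a constant-rate null,
    per spike, in bits.

    bps = (LL(pred) - LL(null)) / (total spikes * ln 2), with Poisson
    log-likelihoods summed over all evaluated bins.  ``null_rates`` is the
    per-neuron mean rate estimated on the training split, broadcast over
    bins and trials.  Every bin passed in counts toward the formula; nothing
    is excluded implicitly.
    """
    pred_rates = np.asarray(pred_rates, dtype=np.float64)
    counts = _check_counts(counts)
    null_rates = np.broadcast_to(np.asarray(null_rates, dtype=np.float64), counts.shape)
    if pred_rates.shape != counts.shape:
        raise DataError(f"shape mismatch: rates {pred_rates.shape} vs counts {counts.shape}")
    if pred_rates.min() <= 0 or null_rates.min() <= 0:
        raise DataError("rates must be strictly positive")
    total_spikes = counts.sum()
    if total_spikes <= 0:
        raise DataError("bits per spike is undefined: zero spikes in the evaluated bins")
    ll_pred = np.sum(counts * np.log(pred_rates) - pred_rates)
    ll_null = np.sum(counts * np.log(null_rates) - null_rates)
    return float((ll_pred - ll_null) / (total_spikes * _LN2))


def single_trial_r2(pred: np.ndarray, truth: np.ndarray) -> float:
    """Variance explained after accounting for the trial average.

    With the PSTH ybar(t) = mean over trials of truth at bin t,
    R2 = 1 - sum (truth - pred)^2 / sum (truth - ybar)^2.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise DataError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if truth.shape[0] < 2:
        raise DataError("single-trial R2 needs at least 2 trials")
    psth = truth.mean(axis=0, keepdims=True)
    denom = np.sum((truth - psth) ** 2)
    if denom == 0:
        raise DataError("single-trial R2 is undefined: no across-trial variance in truth")
    return float(1.0 - np.sum((truth - pred) ** 2) / denom)


def classification_accuracy(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise DataError("label arrays must have equal length")
    if pred_labels.size == 0:
        raise DataError("empty label arrays")
    return float(np.mean(pred_labels == true_labels))


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy in nats (log-sum-exp stable)."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels))
    if logits.shape[0] != labels.shape[0]:
        raise DataError("one label per logit row required")
    if labels.size == 0:
        raise DataError("empty input")
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise DataError("label out of range")
    logp = log_softmax(logits, axis=-1)
    return float(-np.mean(logp[np.arange(labels.shape[0]), labels]))


def mse(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise DataError("shape mismatch")
    if pred.size == 0:
        raise DataError("empty input")
    return float(np.mean((pred - truth) ** 2))


@dataclass
class LossBreakdown:
    """Per-modality training losses, each averaged over its own loss-mask
    positions, plus the weighted total."""

    poisson_nll: float | None = None
    mse: dict = field(default_factory=dict)  # per continuous variable
    cross_entropy: dict = field(default_factory=dict)  # per discrete variable
    token_counts: dict = field(default_factory=dict)  # loss positions per modality
    total: float = 0.0


@dataclass
class EvalReport:
    """Evaluation results for one session.

    ``co_bps`` maps a conditioning subset name ('all' or a single behavior
    variable) to bits per spike; decoding fields are None when the report
    covers encoding only.
    """

    session_id: str
    task: str  # "encode" | "decode"
    co_bps: dict = field(default_factory=dict)
    r2_wheel: float | None = None
    r2_whisker: float | None = None
    acc_choice: float | None = None
    acc_block: float | None = None
    n_test_trials: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, value in (("acc_choice", self.acc_choice), ("acc_block", self.acc_block)):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")

    def decoding_metrics(self) -> dict[str, float]:
        return {
            "choice": self.acc_choice,
            "block": self.acc_block,
            "wheel": self.r2_wheel,
            "whisker": self.r2_whisker,
        }

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "task": self.task,
            "co_bps": dict(self.co_bps),
            "r2_wheel": self.r2_wheel,
            "r2_whisker": self.r2_whisker,
            "acc_choice": self.acc_choice,
            "acc_block": self.acc_block,
            "n_test_trials": self.n_test_trials,
            **self.extras,
        }


def reports_to_frame(reports: list[EvalReport]) -> pd.DataFrame:
    """One row per (session, task, conditioning/variable, metric)."""
    rows = []
    for r in reports:
        for cond, value in r.co_bps.items():
            rows.append((r.session_id, r.task, cond, "co_bps", value))
        for var, metric in (("wheel", r.r2_wheel), ("whisker", r.r2_whisker)):
            if metric is not None:
                rows.append((r.session_id, r.task, var, "single_trial_r2", metric))
        for var, metric in (("choice", r.acc_choice), ("block", r.acc_block)):
            if metric is not None:
                rows.append((r.session_id, r.task, var, "accuracy", metric))
    return pd.DataFrame(rows, columns=["session_id", "task", "variable", "metric", "value"])
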