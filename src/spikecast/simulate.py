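"""Synthetic trial-aligned neurobehavioral sessions with known ground truth.

The generator emulates the structure of a multi-animal visual decision-making
electrophysiology dataset: per-trial spike-count tensors binned at 20 ms over
2-second trials, two smooth continuous behavior traces (wheel speed and
whisker motion energy), a binary choice, a three-state "block" prior over
stimulus side, and a per-neuron anatomical region label drawn from five
areas (PO, LP, DG, CA1, VISa).

Spikes are Poisson with rates ``lambda_t = softplus(C @ z_t + b)`` where the
latent ``z_t`` follows a linear dynamical system driven by the behaviors:

    z_t = A z_{t-1} + sum_v B_v y_v(t) + eps_t,   eps_t ~ N(0, noise_sd^2 I)

Continuous behaviors are AR(1) traces; choice and block enter as
constant-in-time per-trial offsets; choice is drawn conditionally on the
block's right-side prior.  Per-neuron loading rows of ``C`` cluster by
region so that anatomy is linearly recoverable from the loadings, which sets
the ceiling for the neuron-embedding classification analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigError, DataError

__all__ = [
    "SimConfig",
    "SessionBundle",
    "SplitSpec",
    "SplitIndices",
    "REGION_NAMES",
    "TASK_VARIABLES",
    "generate_dataset",
    "sample_block_sequence",
    "filter_low_rate_neurons",
    "split_trials",
    "softplus_inv",
]

REGION_NAMES = ("PO", "LP", "DG", "CA1", "VISa")

#: the four task variables, in canonical order
TASK_VARIABLES = ("wheel", "whisker", "choice", "block")


def softplus_inv(y):
    """Inverse of log(1+exp(x)); y must be positive."""
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-y))


class SimConfig(BaseModel):
    """Configuration of the synthetic dataset generator.

    ``coupling_strength`` scales how strongly each task variable drives the
    latent state (units: latent s.d. per unit of the variable).  Defaults
    describe a high signal-to-noise regime in which both encoding and
    decoding are solvable.
    """

    model_config = ConfigDict(extra="forbid")

    n_sessions: int = Field(default=1, ge=1)
    n_neurons_per_session: int | list[int] = 60
    n_trials: int = Field(default=200, ge=1)
    n_bins: int = Field(default=100, ge=1)
    bin_width: float = Field(default=0.020, gt=0)
    latent_dim: int = Field(default=6, ge=1)
    coupling_strength: dict[str, float] = Field(
        default_factory=lambda: {"wheel": 1.0, "whisker": 1.0, "choice": 1.0, "block": 1.0}
    )
    noise_sd: float = Field(default=0.1, ge=0)
    block_priors: tuple[float, float, float] = (0.2, 0.5, 0.8)
    n_regions: int = Field(default=5, ge=1)
    seed: int = 0
    # secondary knobs of the latent model
    latent_ar: float = Field(default=0.6, ge=0, lt=1)  # spectral radius of A
    behavior_ar: float = Field(default=0.95, ge=0, lt=1)
    behavior_sd: float = Field(default=1.0, gt=0)
    baseline_rate_hz: float = Field(default=5.0, gt=0)
    baseline_jitter_sd: float = Field(default=0.3, ge=0)
    region_between_sd: float = Field(default=1.0, gt=0)
    region_within_sd: float = Field(default=0.25, gt=0)
    run_length_mean: float = Field(default=20.0, ge=1)
    store_ground_truth: bool = True

    @field_validator("block_priors")
    @classmethod
    def _priors_open_unit(cls, v):
        if not all(0.0 < p < 1.0 for p in v):
            raise ValueError("block_priors entries must lie in the open interval (0, 1)")
        return v

    @field_validator("coupling_strength")
    @classmethod
    def _coupling_nonneg(cls, v):
        unknown = set(v) - set(TASK_VARIABLES)
        if unknown:
            raise ValueError(f"unknown task variables in coupling_strength: {sorted(unknown)}")
        if any(c < 0 for c in v.values()):
            raise ValueError("coupling_strength values must be nonnegative")
        return {name: float(v.get(name, 0.0)) for name in TASK_VARIABLES}

    @field_validator("n_neurons_per_session")
    @classmethod
    def _neurons_positive(cls, v):
        vals = v if isinstance(v, list) else [v]
        if any(n < 1 for n in vals):
            raise ValueError("neuron counts must be >= 1")
        return v

    @property
    def trial_length_s(self) -> float:
        return self.n_bins * self.bin_width

    def neurons_for(self, session_index: int) -> int:
        if isinstance(self.n_neurons_per_session, list):
            if len(self.n_neurons_per_session) != self.n_sessions:
                raise ConfigError(
                    "n_neurons_per_session list length must equal n_sessions"
                )
            return self.n_neurons_per_session[session_index]
        return self.n_neurons_per_session


@dataclass
class SessionBundle:
    """One recorded session: spikes, behaviors, labels, and annotations.

    ``spikes`` has shape (trials, neurons, bins) and nonnegative integer
    counts; ``wheel``/``whisker`` have shape (trials, bins); ``choice`` is a
    binary per-trial label (0=left, 1=right); ``block`` is a three-state
    per-trial label indexing ``block_priors``.
    """

    session_id: str
    spikes: np.ndarray
    wheel: np.ndarray
    whisker: np.ndarray
    choice: np.ndarray
    block: np.ndarray
    region_label: np.ndarray
    bin_width_s: float
    trial_length_s: float
    seed: int = 0
    ground_truth: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n_trials = self.spikes.shape[0]
        for name in ("wheel", "whisker", "choice", "block"):
            if getattr(self, name).shape[0] != n_trials:
                raise DataError(f"trial count of '{name}' disagrees with spikes")
        if self.region_label.shape[0] != self.spikes.shape[1]:
            raise DataError("every neuron needs a region label")
        if np.any(self.spikes < 0):
            raise DataError("spike counts must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[2]

    def behavior(self, name: str) -> np.ndarray:
        if name not in TASK_VARIABLES:
            raise ConfigError(f"unknown task variable '{name}'")
        return getattr(self, name)


class SplitSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    train: float = 0.7
    valid: float = 0.1
    test: float = 0.2
    seed: int = 0

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.train, self.valid, self.test)


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray


def sample_block_sequence(
    n_trials: int,
    priors: tuple[float, float, float],
    run_length_mean: float,
    rng: np.random.Generator,
    init_probs=None,
) -> np.ndarray:
    """Markov block-state labels with geometric run lengths.

    The chain stays in its state with probability 1 - 1/run_length_mean and
    otherwise switches uniformly to one of the other states, giving runs of
    geometric length with the stated mean and a uniform stationary
    distribution.  ``priors`` only fixes the number of states here; its
    values are consumed when drawing choices.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    if run_length_mean < 1:
        raise ConfigError("run_length_mean must be >= 1")
    n_states = len(priors)
    p_switch = 0.0 if np.isinf(run_length_mean) else 1.0 / run_length_mean
    if init_probs is None:
        init_probs = np.full(n_states, 1.0 / n_states)
    labels = np.empty(n_trials, dtype=np.int8)
    labels[0] = rng.choice(n_states, p=np.asarray(init_probs, dtype=float))
    for t in range(1, n_trials):
        if rng.random() < p_switch and n_states > 1:
            others = [s for s in range(n_states) if s != labels[t - 1]]
            labels[t] = others[rng.integers(len(others))]
        else:
            labels[t] = labels[t - 1]
    return labels


def _random_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _ar1(rng: np.random.Generator, n_trials: int, t: int, rho: float, sd: float) -> np.ndarray:
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    out = np.empty((n_trials, t), dtype=np.float64)
    out[:, 0] = rng.normal(0.0, sd, size=n_trials)
    for k in range(1, t):
        out[:, k] = rho * out[:, k - 1] + rng.normal(0.0, innov_sd, size=n_trials)
    return out


def _generate_session(cfg: SimConfig, index: int, seed_seq: np.random.SeedSequence) -> SessionBundle:
    rng = np.random.default_rng(seed_seq)
    n_neurons = cfg.neurons_for(index)
    d = cfg.latent_dim
    t = cfg.n_bins

    if d > n_neurons:
        import warnings

        warnings.warn(
            f"latent_dim ({d}) exceeds neuron count ({n_neurons}); rates are rank-deficient",
            stacklevel=3,
        )

    # balanced-random region assignment: counts per region differ by <= 1
    region_idx = rng.permuted(np.resize(np.arange(cfg.n_regions), n_neurons))
    region_names = [
        REGION_NAMES[r] if r < len(REGION_NAMES) else f"R{r}" for r in range(cfg.n_regions)
    ]
    region_label = np.array([region_names[r] for r in region_idx])

    a_mat = cfg.latent_ar * _random_rotation(d, rng)
    b_vec = {name: cfg.coupling_strength[name] * _unit(rng.standard_normal(d))
             for name in TASK_VARIABLES}

    centers = rng.normal(0.0, cfg.region_between_sd, size=(cfg.n_regions, d))
    loadings = centers[region_idx] + rng.normal(0.0, cfg.region_within_sd, size=(n_neurons, d))
    baseline = softplus_inv(cfg.baseline_rate_hz * cfg.bin_width) + rng.normal(
        0.0, cfg.baseline_jitter_sd, size=n_neurons
    )

    block = sample_block_sequence(cfg.n_trials, cfg.block_priors, cfg.run_length_mean, rng)
    right_prior = np.asarray(cfg.block_priors)[block]
    choice = (rng.random(cfg.n_trials) < right_prior).astype(np.int8)

    wheel = _ar1(rng, cfg.n_trials, t, cfg.behavior_ar, cfg.behavior_sd)
    whisker = _ar1(rng, cfg.n_trials, t, cfg.behavior_ar, cfg.behavior_sd)

    # latent trajectories: z_t = A z_{t-1} + sum_v B_v y_v(t) + noise
    z = np.zeros((cfg.n_trials, t, d))
    choice_sign = 2.0 * choice - 1.0  # -1 left, +1 right
    block_level = block.astype(float) - 1.0  # -1, 0, +1
    drive_const = (choice_sign[:, None] * b_vec["choice"][None, :]
                   + block_level[:, None] * b_vec["block"][None, :])
    prev = np.zeros((cfg.n_trials, d))
    for k in range(t):
        drive = (prev @ a_mat.T
                 + wheel[:, k, None] * b_vec["wheel"][None, :]
                 + whisker[:, k, None] * b_vec["whisker"][None, :]
                 + drive_const)
        if cfg.noise_sd > 0:
            drive = drive + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_trials, d))
        z[:, k, :] = drive
        prev = drive

    rates = np.logaddexp(0.0, z @ loadings.T + baseline[None, None, :])  # (trials, T, N)
    spikes = rng.poisson(rates).astype(np.uint16)

    ground_truth = None
    if cfg.store_ground_truth:
        ground_truth = {
            "latents": z.astype(np.float32),
            "rates": rates.transpose(0, 2, 1).astype(np.float32),  # trials x neurons x bins
            "loadings": loadings.astype(np.float32),
            "baseline": baseline.astype(np.float32),
            "dynamics": a_mat.astype(np.float32),
            **{f"coupling_{name}": b_vec[name].astype(np.float32) for name in TASK_VARIABLES},
        }

    return SessionBundle(
        session_id=f"synthetic-{cfg.seed:04d}-{index:02d}",
        spikes=spikes.transpose(0, 2, 1),  # trials x neurons x bins
        wheel=wheel.astype(np.float32),
        whisker=whisker.astype(np.float32),
        choice=choice,
        block=block,
        region_label=region_label,
        bin_width_s=cfg.bin_width,
        trial_length_s=cfg.trial_length_s,
        seed=cfg.seed,
        ground_truth=ground_truth,
        metadata={"generator_seed": cfg.seed, "session_index": index},
    )


def generate_dataset(cfg: SimConfig) -> list[SessionBundle]:
    """Generate ``cfg.n_sessions`` independent sessions, deterministically."""
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_sessions)
    return [_generate_session(cfg, i, child) for i, child in enumerate(children)]


def filter_low_rate_neurons(bundle: SessionBundle, min_rate: float = 2.0) -> SessionBundle:
    """Drop neurons whose mean firing rate is below ``min_rate`` Hz.

    Mean rate = total spikes / (n_trials * trial length); the boundary is
    kept (``>=``).  Region labels and ground truth are sliced consistently.
    """
    totals = bundle.spikes.sum(axis=(0, 2)).astype(np.float64)
    duration = bundle.n_trials * bundle.trial_length_s
    keep = totals / duration >= min_rate
    if not keep.any():
        raise DataError(
            f"all {bundle.n_neurons} neurons fall below the {min_rate} Hz threshold"
        )
    gt = None
    if bundle.ground_truth is not None:
        gt = dict(bundle.ground_truth)
        for key in ("rates", "loadings", "baseline"):
            if key in gt:
                gt[key] = gt[key][..., keep, :] if key == "rates" else gt[key][keep]
    return SessionBundle(
        session_id=bundle.session_id,
        spikes=bundle.spikes[:, keep, :],
        wheel=bundle.wheel,
        whisker=bundle.whisker,
        choice=bundle.choice,
        block=bundle.block,
        region_label=bundle.region_label[keep],
        bin_width_s=bundle.bin_width_s,
        trial_length_s=bundle.trial_length_s,
        seed=bundle.seed,
        ground_truth=gt,
        metadata={**bundle.metadata, "min_rate_hz": min_rate},
    )


def split_trials(bundle: SessionBundle, spec: SplitSpec) -> SplitIndices:
    """Random disjoint train/valid/test trial indices (largest-remainder sizes)."""
    fracs = np.asarray(spec.fractions, dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-8:
        raise ConfigError(f"split fractions must sum to 1, got {fracs.sum():.6f}")
    n = bundle.n_trials
    if n < 10:
        raise DataError(f"need at least 10 trials to split, got {n}")
    raw = fracs * n
    sizes = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - sizes)):
        if sizes.sum() == n:
            break
        sizes[i] += 1
    if (sizes == 0).any():
        raise ConfigError(f"split of {n} trials leaves an empty part: {sizes.tolist()}")
    perm = np.random.default_rng(spec.seed).permutation(n)
    bounds = np.cumsum(sizes)[:-1]
    train, valid, test = np.split(perm, bounds)
    return SplitIndices(np.sort(train), np.sort(valid), np.sort(test))
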