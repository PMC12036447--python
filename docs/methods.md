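# Methods

`spikecast` implements a multimodal, multi-task-masked transformer that
models the bidirectional relationship between trial-aligned spiking
activity and behavior: masking the neural tokens and predicting them from
behavior performs *encoding* (E[X|Y]); masking the behavior tokens and
predicting them from spikes performs *decoding* (E[Y|X]).  A single model
serves both directions because training alternates uniformly between four
masking schemes.  This note records the model, the synthetic data it is
validated on, the numerical choices, and the known limitations.

## Data model

A session is one recording from one animal: a spike-count tensor
(trials x neurons x bins; 20 ms bins, 2 s trials, hence 100 bins by
default), two continuous behavior traces per trial (wheel speed, whisker
motion energy), two discrete trial-level variables (binary choice; a
three-state "block" prior over stimulus side with right-side probabilities
0.2 / 0.5 / 0.8), and one anatomical region label per neuron out of
{PO, LP, DG, CA1, VISa}.  Neurons with mean firing rate below 2 Hz are
excluded (`filter_low_rate_neurons`; the boundary is kept).  Trials are
split 70/10/20 into train/validation/test, at random without
stratification, seeded.

## Architecture

Each modality is tokenized separately into T tokens per trial:

* neural — a session-specific linear map `W_X_input` (neurons -> D) applied
  per 20 ms bin;
* continuous behaviors — a 1 -> D linear map per variable per bin;
* discrete behaviors — a learned per-category embedding replicated T times
  so the tokens align with the temporal grid.

Segments are concatenated in the fixed order (neural, wheel, whisker,
choice, block); the sequence length is (#present modalities) x T, and
missing modalities are dropped, not zero-filled.  Learned modality
embeddings and a session embedding are added to every token.  Temporal
position enters through rotary embeddings (RoPE) applied to queries and
keys inside attention, so the encoder sees relative time offsets and its
output is invariant to a global time shift; an additive temporal embedding
table can be switched on in `ModelConfig` instead, but only one mechanism
is active by default because the two are redundant.

The encoder is a standard pre-norm transformer (GELU feed-forward,
dropout 0.1 by default) with full bidirectional self-attention over the
unified sequence.  Output heads are linear and session-specific: a rate
head `W_rate` (D -> neurons) through a softplus link (exp available by
config; softplus is the default because a linear Poisson rate cannot
guarantee positivity), one scalar head per continuous variable per time
token, and one logit head per discrete variable whose per-token logits are
mean-pooled over the T replicas into a single per-trial decision (argmax,
ties to the lowest class index).

Because no deep-learning framework ships in the dependency set, the
transformer, its losses, and AdamW run on a compact reverse-mode autodiff
engine over numpy arrays (`spikecast.autodiff`), validated end-to-end
against finite differences (1e-7 tolerance).  All model computation is
float32; metrics are computed in float64.

## Masking schemes

* **neural** — all neural tokens masked; loss on neural tokens only.
  Conditioning alternates between ALL behavior variables and a single one
  (probability `p_all` = 0.5 each; the single variable uniform over the
  four).  Under single-variable conditioning, the non-conditioning behavior
  variables are also masked and excluded from the loss, so inference can
  rank each variable's encoding contribution.
* **behavior** — all behavior tokens masked; loss on behavior tokens.
* **within-modality random** — a fraction `mask_ratio` (default 0.3) of
  one modality's tokens, the modality drawn uniformly over those present.
* **cross-modal random** — the same fraction of all tokens, across
  modalities.

Masked positions are replaced by a single learned mask token; their
modality and session embeddings remain, announcing what is to be
reconstructed where.  Full schemes mask a discrete variable's T replicas
all-or-none; random schemes operate per token.  The loss mask is always a
subset of the mask, with at least one loss position (a ratio that selects
zero tokens is a configuration error).

## Objectives and metrics

Per-modality losses are averaged over their own loss-mask positions and
summed with unit weights (configurable): Poisson negative log-likelihood
for counts (the ln k! constant via log-gamma), mean squared error for
continuous traces, and log-sum-exp-stable cross-entropy on the pooled
logits of the masked replicas for discrete variables.

Evaluation metrics:

* **bits per spike (co-bps)** — (LL(pred) - LL(null)) / (total spikes x
  ln 2), Poisson log-likelihoods summed over evaluated bins; the null is
  each neuron's constant mean rate estimated on the training split (the
  co-smoothing convention).  Undefined (an error) when the evaluated bins
  contain zero spikes; nothing is excluded implicitly.
* **single-trial R^2** — 1 - SSE / SS(truth - PSTH), where the PSTH is the
  per-bin mean over the evaluated (test) trials; a flag switches to a
  train-split PSTH.  Undefined when truth has no across-trial variance.
* **accuracy** for choice (2-class) and block (3-class; a config option
  collapses to 2 for protocols that score only the biased states).

## Training protocol

Pretraining mixes trials from all sessions in every batch (session
adapters map to the common width D first, so no padding is needed); each
trial draws an independent masking scheme, logged for reproducibility.
AdamW (lr 3e-3, cosine decay to 0.1x, weight decay 1e-4) with early
stopping on a deterministic validation probe: the full schemes present in
the configured mixture (neural-ALL and behavior), or a fixed-seed random
mask when only random schemes are trained.  The rate-head bias is
initialized at each neuron's mean training count through the inverse link,
so encoding starts at the null model and bits/spike starts near zero
rather than far below it.

Fine-tuning on a new session registers fresh session modules (input
matrices, session embedding, heads — never reused across sessions, since
neuron identities do not transfer) and trains only those by default; the
backbone stays bit-identical unless explicitly unfrozen.  Single-task
"unimodal" variants are obtained by restricting the scheme mixture:
`scheme_kinds=("neural",)` trains an encoding-only model (its `W_X_input`
receives no gradient because neural tokens are always fully masked);
`("behavior",)` trains a decoding-only model.

## Neuron embeddings

Neuron k's embedding concatenates row k of `W_X_input` and row k of
`W_rate`-transpose (pre-link), length 2D; unimodal variants use the single
matrix that is trained (length D).  A linear SVC (C = 1.0) on standardized
features under stratified 5-fold cross-validation (sessions may span
folds; leave-session-out available by flag) predicts the region label.
Plain and balanced accuracy are both reported, since reporting conventions
for this analysis differ; the confusion matrix is row-normalized, so its
trace over 5 equals balanced accuracy.

## Synthetic-data generator

The generator emulates the statistical structure the model assumes, with
known ground truth:

    z_t = A z_{t-1} + sum_v B_v y_v(t) + eps_t,    eps ~ N(0, noise_sd^2 I)
    rates = softplus(C z_t + b),    spikes ~ Poisson(rates)

with A = latent_ar x (random rotation) (default spectral radius 0.6),
AR(1) behavior traces (autocorrelation 0.95, unit variance), choice and
block entering as constant-in-time per-trial offsets (choice as +/-1,
block as -1/0/+1), and choice drawn conditionally on the block's
right-side prior — mimicking the task logic, and the reason a variable
with zero rate coupling can still carry encoding information if it
predicts a coupled variable (block predicts choice; whisker is the
independent null variable in the tests).  Block labels switch in
contiguous runs: a Markov chain that stays with probability
1 - 1/run_length_mean (default mean run 20 trials, a config knob — the
task's true switching statistics are not modeled) and otherwise moves
uniformly to another state, giving geometric runs and a uniform stationary
distribution.  The softplus link matches the model's rate head so ground
truth is representable.

Loading rows of C cluster by region (5 Gaussian clusters, between-sd 1.0,
within-sd 0.25; balanced-random region assignment) so that region identity
is linearly recoverable from the true loadings — measured ceiling ~0.95
accuracy — which bounds what the embedding-classification analysis can
achieve.  Baseline rates default to 5 Hz with 0.3 log-scale jitter.
Everything is driven by `numpy` SeedSequence spawning, so identical seeds
give byte-identical datasets.

What the generator does **not** emulate: video-derived behavior noise,
reaction-time trial exclusions, non-stationarity within sessions,
refractory or history dependence in spiking, and realistic region-specific
firing statistics.  Passing tests therefore demonstrate that the
implementation learns the conditional structure it was designed for, not
that it matches any real dataset's numbers.

## Problem sizes used by the test suite and acceptance script

Training a transformer on one CPU constrains the scales, chosen once:

* end-to-end learning check: one high-SNR session (50 neurons, 300 trials,
  100 bins), width-64 / 2-layer encoder, 12 epochs;
* encoding-ranking check: 40 neurons, 300 trials, 60 bins, width 32,
  3 seeds;
* transfer and embedding checks: 8 pretraining sessions x 25 neurons x 80
  trials (30 bins), with a 40-neuron data-poor and a 100-neuron richer
  held-out session, width 32, 30 pretraining epochs, 3 seeds;
* acceptance script: 4 pretraining sessions x 40 neurons x 150 trials
  (50 bins), a 60-neuron held-out session, width 48, 8 epochs.

## Known limitations

* **Calibration of rarely-trained conditionings.**  Single-variable
  conditioning appears in roughly 3% of training batches under the uniform
  scheme mixture with p_all = 0.5.  At desk scale the rate map conditioned
  on an *uninformative* variable is slightly miscalibrated: instead of
  falling back to the constant null it retains spurious dependence on the
  variable's trajectory, costing typically 0.02-0.13 bits/spike.  The
  null-coupling test asserts the idealized +/-0.02 band and documents this
  bias; more epochs, more trials, stronger regularization, and
  multi-session pretraining were all tried and do not remove it (a frozen
  pretrained backbone can even worsen it, since it keeps transmitting a
  variable that was informative in the pretraining population).
* **Embedding-ordering comparisons are under-powered at desk scale.**  The
  robust emergent effect — embeddings beat a shuffled-label null by a wide
  margin — reproduces reliably.  The finer ordering (multi-session above
  single-session multimodal above single-session unimodal) involves
  margins of a few accuracy points against a cross-validation standard
  error of ~0.05 on a 100-neuron session, and flips between statistically
  equivalent runs; only the decoding-only unimodal variant is clearly
  separated.  The corresponding test documents the ordering as stated and
  is expected to be sensitive to this noise.
* The 2-vs-3-class convention for block accuracy differs across common
  protocols; both are supported, 3-class is the default.
* Desk-scale models (width 32-64) are far smaller than the multi-session
  regime these methods are designed for; all cross-model comparisons in
  the tests are therefore qualitative orderings, not effect sizes.
* Only trial-aligned data is supported; unaligned pretraining is out of
  scope.
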