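# spikecast

Multimodal masked-transformer **encoding and decoding** of trial-aligned
spiking activity and behavior, for systems neuroscientists who want one
model that translates in both directions between a neural population and
the task variables the animal is engaged with.

Classical analyses pick a direction: an encoding model predicts spike
counts from behavior (E[X|Y]); a decoding model predicts behavior from
spikes (E[Y|X]).  `spikecast` trains a single transformer to do both by
*multi-task masking*: every trial is tokenized into a unified sequence —
binned spike counts, continuous behavior traces (wheel speed, whisker
motion energy), and trial-level discrete variables (choice, block prior) —
and training alternates uniformly between four masking schemes:

| scheme | masked | predicts |
|---|---|---|
| neural | all neural tokens | E[X \| Y] (encoding; all variables or one at a time) |
| behavior | all behavior tokens | E[Y \| X] (decoding) |
| within-modality | random tokens of one modality | intra-modal structure |
| cross-modal | random tokens everywhere | joint structure |

Spike counts follow a Poisson emission `X ~ Poisson(softplus(W_rate e_X))`,
continuous behaviors a fixed-variance Gaussian (MSE), discrete behaviors a
categorical (cross-entropy).  Temporal position is rotary (RoPE) inside
attention; session-specific input matrices, session embeddings, and
session-specific linear decoders let one backbone train across many
animals, and fine-tuning a new session touches only those session-specific
parts.  Evaluation follows the field's conventions: encoding is scored in
**bits per spike** against a constant-rate null (co-bps), continuous
decoding by **single-trial R²** (variance explained beyond the PSTH),
discrete decoding by accuracy.  As a by-product, each neuron gets an
embedding — its rows of the session input matrix and the rate head — which
turns out to predict the neuron's brain region without any anatomical
supervision.

Because real multi-animal electrophysiology is not bundled here, the
package ships a first-class synthetic-data generator
(`spikecast.simulate`): Poisson spikes driven by a latent linear dynamical
system coupled to the behaviors, region-clustered loadings, blocked
discrete labels with 20/80‑80/20‑50/50 priors, and full ground truth for
parameter-recovery tests.  The transformer and its training loop run on a
small numpy autodiff engine (`spikecast.autodiff`), so the only
dependencies are the scientific-Python stack.

## Worked example

```python
import spikecast as sc

cfg = sc.SimConfig(n_sessions=2, n_neurons_per_session=40, n_trials=200,
                   n_bins=50, latent_dim=4, noise_sd=0.05, seed=7,
                   coupling_strength={"wheel": 1.5, "whisker": 1.0,
                                      "choice": 2.0, "block": 1.0})
sessions = [sc.filter_low_rate_neurons(b) for b in sc.generate_dataset(cfg)]

model = sc.EncoderDecoderModel(
    sessions,
    sc.ModelConfig(width=48, n_layers=2, n_heads=2, d_ff=192, seed=0),
    sc.TrainConfig(epochs=25, batch_size=16, lr=3e-3, seed=0),
)
results = model.fit()
print(results.summary())
```

```
Multimodal masked encoder-decoder of spikes and behavior
================================================================
sessions: 2   width: 48  layers: 2  heads: 2
rate link: softplus   best epoch: 23
----------------------------------------------------------------
session                   choice   block   wheel  whisker   co-bps
synthetic-0007-00          0.975   0.825   0.867    0.581    0.875
synthetic-0007-01          1.000   0.800   0.916    0.632    1.346
----------------------------------------------------------------
choice/block: test accuracy; wheel/whisker: single-trial R^2;
co-bps: bits/spike of encoding from all behavior variables.
```

The same fitted model ranks how strongly each task variable drives the
population (encoding conditioned on one variable at a time), and tests
whether the learned neuron embeddings predict anatomy:

```python
ranking = results.evaluate_encoding(["all", "wheel", "whisker", "choice", "block"],
                                    session_id=sessions[0].session_id)[0]
print("encoding ranking:", {k: round(v, 3) for k, v in ranking.co_bps.items()})
report = results.classify_regions(n_folds=5, seed=0)
print(f"region accuracy: {report.accuracy:.3f} (chance ~{report.majority_rate:.2f})")
```

```
encoding ranking: {'all': 0.875, 'wheel': 0.335, 'whisker': -0.077, 'choice': 0.279, 'block': 0.261}
region accuracy: 0.487 (chance ~0.20)
```

Reading the numbers: choice decodes near-perfectly and both continuous
traces decode well above the PSTH baseline; encoding from **all** variables
together (0.875 bits/spike) beats every single-variable conditioning, i.e.
the variables carry complementary information about the rates; and a
linear classifier on the neuron embeddings recovers brain region at ~2.4×
chance after only 25 epochs of training, with no anatomy in the loss.

The same pipeline is available from the shell:

```bash
spikecast simulate --config cfg.yaml --out data/
spikecast pretrain --data data/ --config cfg.yaml --out ckpt.npz
spikecast finetune --ckpt ckpt.npz --session data/new.h5 --out ckpt2.npz
spikecast eval --ckpt ckpt2.npz --session data/new.h5 --task decode --out report.json
spikecast embed-classify --ckpt ckpt2.npz --data data/ --folds 5 --out regions/
```

Every command writes a manifest (config hash, seeds, input hashes) next to
its outputs.  Sessions live in a simple HDF5 schema (`/spikes`, `/wheel`,
`/whisker`, `/choice`, `/block`, `/regions` + attributes); checkpoints are
single `.npz` archives holding the backbone, all session modules, and the
registry.

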