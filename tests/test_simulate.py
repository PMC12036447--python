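"""Tests of the synthetic-session generator against analytic oracles."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

import spikecast as sc
from spikecast.errors import ConfigError, DataError
from spikecast.simulate import REGION_NAMES, SessionBundle, softplus_inv
from spikecast.embeddings import classify_regions

from conftest import micro_sim_config


# ---------------------------------------------------------------------------
# structure & determinism


def test_default_trial_grid_is_100_bins_of_20ms():
    cfg = sc.SimConfig()
    assert cfg.n_bins == 100
    assert cfg.bin_width == pytest.approx(0.020)
    assert cfg.trial_length_s == pytest.approx(2.0)


def test_bundle_shapes_and_labels():
    cfg = micro_sim_config(n_sessions=2, n_neurons_per_session=[8, 11])
    bundles = sc.generate_dataset(cfg)
    assert [b.n_neurons for b in bundles] == [8, 11]
    for b in bundles:
        assert b.spikes.shape == (cfg.n_trials, b.n_neurons, cfg.n_bins)
        assert b.wheel.shape == b.whisker.shape == (cfg.n_trials, cfg.n_bins)
        assert set(np.unique(b.choice)) <= {0, 1}
        assert set(np.unique(b.block)) <= {0, 1, 2}
        assert set(b.region_label) <= set(REGION_NAMES)
        assert b.spikes.dtype == np.uint16


def test_same_seed_bit_identical_datasets():
    cfg = micro_sim_config(n_sessions=2, n_trials=15)
    a, b = sc.generate_dataset(cfg), sc.generate_dataset(cfg)
    for s1, s2 in zip(a, b):
        np.testing.assert_array_equal(s1.spikes, s2.spikes)
        np.testing.assert_array_equal(s1.wheel, s2.wheel)
        np.testing.assert_array_equal(s1.choice, s2.choice)
        np.testing.assert_array_equal(s1.block, s2.block)
        assert list(s1.region_label) == list(s2.region_label)


def test_invalid_configs_rejected():
    with pytest.raises(Exception):
        sc.SimConfig(block_priors=(0.0, 0.5, 0.8))
    with pytest.raises(Exception):
        sc.SimConfig(n_trials=0)
    with pytest.raises(Exception):
        sc.SimConfig(coupling_strength={"wheel": -1.0})
    with pytest.raises(Exception):
        sc.SimConfig(coupling_strength={"spout": 1.0})


def test_latent_dim_above_neuron_count_warns_but_generates():
    cfg = micro_sim_config(n_neurons_per_session=2, latent_dim=5)
    with pytest.warns(UserWarning, match="latent_dim"):
        bundles = sc.generate_dataset(cfg)
    assert bundles[0].n_neurons == 2


# ---------------------------------------------------------------------------
# Poisson fidelity


def test_homogeneous_poisson_mean_and_fano():
    """With zero coupling and zero noise the latent stays at the origin and
    every neuron is homogeneous Poisson at softplus(baseline)."""
    cfg = micro_sim_config(
        n_neurons_per_session=10,
        n_trials=200,
        n_bins=50,
        coupling_strength={v: 0.0 for v in ("wheel", "whisker", "choice", "block")},
        noise_sd=0.0,
        baseline_jitter_sd=0.0,
        baseline_rate_hz=5.0,
        seed=7,
    )
    b = sc.generate_dataset(cfg)[0]
    expected = cfg.baseline_rate_hz * cfg.bin_width  # 0.1 counts/bin
    gt_rates = b.ground_truth["rates"]
    np.testing.assert_allclose(gt_rates, expected, atol=1e-6)

    n_bins_total = b.spikes.size  # 10 neurons x 200 trials x 50 bins = 1e5
    assert n_bins_total >= 10_000
    mean = b.spikes.mean()
    se_mean = np.sqrt(expected / n_bins_total)
    assert abs(mean - expected) < 3 * se_mean
    # variance/mean ratio ~ 1 within 3 SE (Fano SE ~= sqrt(2/n) for Poisson)
    fano = b.spikes.var() / mean
    assert abs(fano - 1.0) < 3 * np.sqrt(2.0 / n_bins_total)


# ---------------------------------------------------------------------------
# block sequence & choice


def test_single_trial_uses_initial_distribution(rng):
    labels = sc.sample_block_sequence(1, (0.2, 0.5, 0.8), 10.0, rng)
    assert labels.shape == (1,)
    assert labels[0] in (0, 1, 2)


def test_degenerate_initial_state_and_no_switching(rng):
    labels = sc.sample_block_sequence(
        50, (0.2, 0.5, 0.8), np.inf, rng, init_probs=[0.0, 1.0, 0.0]
    )
    assert np.all(labels == 1)


def test_block_stationary_distribution_is_uniform(rng):
    """Symmetric switching between 3 states: stationary distribution of the
    chain is uniform; 10k trials should match within 2%."""
    labels = sc.sample_block_sequence(10_000, (0.2, 0.5, 0.8), 15.0, rng)
    freqs = np.bincount(labels, minlength=3) / labels.size
    np.testing.assert_allclose(freqs, 1.0 / 3.0, atol=0.02)


def test_run_lengths_geometric_with_stated_mean(rng):
    mean_run = 8.0
    labels = sc.sample_block_sequence(40_000, (0.2, 0.5, 0.8), mean_run, rng)
    runs = np.diff(np.flatnonzero(np.diff(labels) != 0))
    # sample mean of geometric run lengths; SE ~ mean/sqrt(k)
    assert abs(runs.mean() - mean_run) < 4 * mean_run / np.sqrt(runs.size)


def test_choice_frequency_matches_block_prior():
    cfg = micro_sim_config(n_trials=6000, n_bins=2, n_neurons_per_session=4, seed=5)
    b = sc.generate_dataset(cfg)[0]
    for state, prior in enumerate(cfg.block_priors):
        sel = b.block == state
        assert sel.sum() > 200
        p_right = b.choice[sel].mean()
        se = np.sqrt(prior * (1 - prior) / sel.sum())
        assert abs(p_right - prior) < 4 * se


def test_run_length_below_one_rejected(rng):
    with pytest.raises(ConfigError):
        sc.sample_block_sequence(10, (0.2, 0.5, 0.8), 0.5, rng)


# ---------------------------------------------------------------------------
# low-rate filtering


def _bundle_with_totals(per_neuron_totals, n_trials=100, n_bins=100, bin_width=0.02):
    """A hand-built bundle whose neurons have exact total spike counts."""
    n = len(per_neuron_totals)
    spikes = np.zeros((n_trials, n, n_bins), dtype=np.uint16)
    for j, total in enumerate(per_neuron_totals):
        flat = np.zeros(n_trials * n_bins, dtype=np.uint16)
        flat[:total] = 1
        spikes[:, j, :] = flat.reshape(n_trials, n_bins)
    return SessionBundle(
        session_id="built",
        spikes=spikes,
        wheel=np.zeros((n_trials, n_bins), np.float32),
        whisker=np.zeros((n_trials, n_bins), np.float32),
        choice=np.zeros(n_trials, np.int8),
        block=np.zeros(n_trials, np.int8),
        region_label=np.array(["PO"] * n),
        bin_width_s=bin_width,
        trial_length_s=n_bins * bin_width,
    )


def test_two_hz_threshold_boundary():
    # 100 trials x 2 s: 300 spikes = 1.5 Hz (dropped), 400 = 2.0 Hz (kept)
    bundle = _bundle_with_totals([300, 400, 500])
    filtered = sc.filter_low_rate_neurons(bundle, min_rate=2.0)
    assert filtered.n_neurons == 2
    np.testing.assert_array_equal(
        filtered.spikes.sum(axis=(0, 2)), [400, 500]
    )


def test_filter_matches_brute_force_recount():
    cfg = micro_sim_config(n_neurons_per_session=40, n_trials=50, seed=9,
                           baseline_rate_hz=2.2, baseline_jitter_sd=1.0)
    b = sc.generate_dataset(cfg)[0]
    filtered = sc.filter_low_rate_neurons(b, min_rate=2.0)
    # independent recount
    keep = []
    for j in range(b.n_neurons):
        total = 0
        for trial in range(b.n_trials):
            total += int(b.spikes[trial, j].sum())
        keep.append(total / (b.n_trials * b.trial_length_s) >= 2.0)
    assert filtered.n_neurons == sum(keep)
    np.testing.assert_array_equal(filtered.region_label, b.region_label[np.array(keep)])


def test_filter_all_removed_names_threshold():
    bundle = _bundle_with_totals([10, 20])
    with pytest.raises(DataError, match="2.0"):
        sc.filter_low_rate_neurons(bundle, min_rate=2.0)


# ---------------------------------------------------------------------------
# trial splits


@pytest.mark.parametrize("n,expected", [(100, (70, 10, 20)), (10, (7, 1, 2))])
def test_split_sizes(n, expected):
    cfg = micro_sim_config(n_trials=n, n_neurons_per_session=3, n_bins=4)
    b = sc.generate_dataset(cfg)[0]
    idx = sc.split_trials(b, sc.SplitSpec(seed=1))
    assert (idx.train.size, idx.valid.size, idx.test.size) == expected


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_split_is_a_partition(seed):
    cfg = micro_sim_config(n_trials=53, n_neurons_per_session=3, n_bins=4)
    b = sc.generate_dataset(cfg)[0]
    idx = sc.split_trials(b, sc.SplitSpec(seed=seed))
    parts = [set(idx.train), set(idx.valid), set(idx.test)]
    assert parts[0] | parts[1] | parts[2] == set(range(53))
    assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
    again = sc.split_trials(b, sc.SplitSpec(seed=seed))
    np.testing.assert_array_equal(idx.train, again.train)


def test_bad_fractions_rejected():
    cfg = micro_sim_config()
    b = sc.generate_dataset(cfg)[0]
    with pytest.raises(ConfigError):
        sc.split_trials(b, sc.SplitSpec(train=0.7, valid=0.2, test=0.2))


# ---------------------------------------------------------------------------
# recoverability & region structure


def test_ridge_recovers_coupling_signs():
    """At high coupling and zero dynamics noise, regressing the inverse-link
    rates on the behaviors recovers each neuron's coupling gain sign.

    The oracle gain is the quasi-static response C (I - A)^-1 B_v, valid
    because the AR(1) behaviors vary slowly relative to the latent dynamics.
    """
    cfg = micro_sim_config(
        n_neurons_per_session=60,
        n_trials=100,
        n_bins=50,
        latent_dim=4,
        noise_sd=0.0,
        latent_ar=0.4,
        coupling_strength={"wheel": 3.0, "whisker": 3.0, "choice": 0.0, "block": 0.0},
        seed=21,
    )
    b = sc.generate_dataset(cfg)[0]
    gt = b.ground_truth
    eta = softplus_inv(np.maximum(gt["rates"], 1e-9))  # trials x neurons x bins
    y = np.stack(
        [b.wheel.reshape(-1), b.whisker.reshape(-1)], axis=1
    )  # (trials*bins, 2)
    targets = eta.transpose(0, 2, 1).reshape(-1, b.n_neurons)
    coefs = Ridge(alpha=1e-3).fit(y, targets).coef_  # (neurons, 2)

    a_mat = gt["dynamics"].astype(np.float64)
    gain = np.linalg.solve(np.eye(cfg.latent_dim) - a_mat, np.stack(
        [gt["coupling_wheel"], gt["coupling_whisker"]], axis=1).astype(np.float64))
    oracle = gt["loadings"].astype(np.float64) @ gain  # (neurons, 2)
    agreement = np.mean(np.sign(coefs) == np.sign(oracle))
    assert agreement >= 0.95


def test_true_loadings_linearly_separate_regions():
    """Region identity is linearly recoverable from the ground-truth loading
    rows at the default cluster separation: the ceiling for the
    neuron-embedding classification analysis."""
    cfg = micro_sim_config(n_neurons_per_session=150, n_trials=12, n_bins=4, seed=3)
    b = sc.generate_dataset(cfg)[0]
    report = classify_regions((b.ground_truth["loadings"], b.region_label), n_folds=5, seed=0)
    assert report.accuracy >= 0.90
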