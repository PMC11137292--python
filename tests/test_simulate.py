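import numpy as np
import pytest
from scipy.stats import ranksums

from gcfe import (
    DEFAULT_TEMPLATES,
    SimulationConfig,
    SpikeTemplateParams,
    add_noise_at_snr,
    extract_features_batch,
    generate_spike_times,
    normalize_recording,
    segment_epochs,
    simulate_dataset1,
    simulate_eeg_surrogate,
    spike_template,
)

FS = 20_000.0


class TestSpikeTemplate:
    def test_zero_amplitude_gives_zero_template(self):
        p = SpikeTemplateParams(A=0.0, tau1=1e-3, tau2=1e-3)
        assert np.all(spike_template(p, FS, 56 / FS) == 0)

    def test_value_at_origin_is_amplitude(self):
        p = SpikeTemplateParams(A=2.5, tau1=1.5e-3, tau2=1e-3, tau_ph=0.0)
        v = spike_template(p, FS, 56 / FS)
        assert v[28] == pytest.approx(2.5)  # t = 0 lands at index n//2

    def test_bounded_by_amplitude(self, rng):
        for _ in range(10):
            p = SpikeTemplateParams(
                A=float(rng.uniform(0.1, 3)),
                tau1=float(rng.uniform(0.5e-3, 3e-3)),
                tau2=float(rng.uniform(0.5e-3, 3e-3)),
                tau_ph=float(rng.uniform(-1e-3, 1e-3)),
            )
            assert np.max(np.abs(spike_template(p, FS, 5e-3))) <= p.A + 1e-12

    def test_envelope_decays_outside_three_widths(self):
        p = SpikeTemplateParams(A=1.0, tau1=1.2e-3, tau2=0.6e-3)
        v = spike_template(p, FS, 20e-3)
        t = (np.arange(v.size) - v.size // 2) / FS
        assert np.max(np.abs(v[np.abs(t) > 3 * p.tau2])) < 1e-6 * p.A

    def test_invalid_params_error(self):
        with pytest.raises(ValueError):
            SpikeTemplateParams(A=1.0, tau1=-1.0, tau2=1.0)
        with pytest.raises(ValueError):
            spike_template(DEFAULT_TEMPLATES[0], FS, 0.0)


class TestSpikeTimes:
    def test_poisson_rate_within_tolerance(self):
        """Empirical rate across seeded runs stays within 3 sigma of 3.3 Hz."""
        rate, duration, runs = 3.3, 200.0, 50
        counts = [generate_spike_times(rate, duration, s).size for s in range(runs)]
        mean_rate = np.mean(counts) / duration
        sigma = np.sqrt(rate * duration) / duration / np.sqrt(runs)
        assert abs(mean_rate - rate) < 3 * sigma

    def test_sorted_within_horizon(self):
        t = generate_spike_times(10.0, 5.0, 1)
        assert np.all(np.diff(t) >= 0) and t.min() >= 0 and t.max() < 5.0

    def test_zero_duration_empty(self):
        assert generate_spike_times(3.3, 0.0, 0).size == 0

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(
            generate_spike_times(3.3, 50.0, 42), generate_spike_times(3.3, 50.0, 42)
        )


class TestNoise:
    def test_measured_sigma_matches_target(self):
        sig = np.zeros(1_000_000)
        sig[0] = 2.0  # peak amplitude 2 -> sigma = 2/4 = 0.5
        out = add_noise_at_snr(sig, 4.0, seed=3)
        assert np.std(out - sig) == pytest.approx(0.5, rel=0.02)

    def test_high_snr_limit_approaches_input(self, rng):
        sig = rng.normal(size=1000)
        out = add_noise_at_snr(sig, 1e9, seed=0)
        np.testing.assert_allclose(out, sig, atol=1e-6)

    def test_zero_signal_errors(self):
        with pytest.raises(ValueError):
            add_noise_at_snr(np.zeros(10), 2.0, seed=0)

    def test_deterministic_given_seed(self, rng):
        sig = rng.normal(size=100)
        np.testing.assert_array_equal(
            add_noise_at_snr(sig, 2.0, seed=5), add_noise_at_snr(sig, 2.0, seed=5)
        )


@pytest.fixture(scope="module")
def small_run():
    cfg = SimulationConfig(snr=2.0, duration=40.0, n_per_class=60, seed=9)
    return cfg, *simulate_dataset1(cfg)


class TestDataset1:
    def test_balanced_labeled_epochs(self, small_run):
        cfg, epochs, manifest = small_run
        labels = np.array([e.label for e in epochs])
        for k in (1, 2, 3, 4):
            assert (labels == k).sum() == 60
            assert manifest["class_counts"][k] == 60
        assert all(len(e) == 56 for e in epochs)
        assert all(e.q.min() >= 0 and e.q.max() <= 1 for e in epochs)

    def test_deterministic_given_config_and_seed(self, small_run):
        cfg, epochs, _ = small_run
        epochs2, _ = simulate_dataset1(cfg)
        np.testing.assert_array_equal(
            np.stack([e.q for e in epochs]), np.stack([e.q for e in epochs2])
        )

    def test_largest_unit_outranks_noise_class_in_radii(self, small_run):
        """Class 3 (largest spikes) has larger mean GC radii than noise epochs."""
        _, epochs, _ = small_run
        df = extract_features_batch(epochs, "wvg")
        y = df["label"].to_numpy()
        r = df.drop(columns=["label"]).to_numpy()[:, :56].mean(axis=1)
        p = ranksums(r[y == 3], r[y == 4], alternative="greater").pvalue
        assert p < 0.05

    def test_insufficient_duration_errors(self):
        cfg = SimulationConfig(duration=5.0, n_per_class=500, seed=0)
        with pytest.raises(ValueError, match="increase duration"):
            simulate_dataset1(cfg)

    def test_epoch_longer_than_template_support_errors(self):
        with pytest.raises(ValueError):
            simulate_dataset1(SimulationConfig(duration=0.001, epoch_len=56, seed=0))

    def test_white_noise_variant_runs(self):
        cfg = SimulationConfig(
            snr=2.0, duration=20.0, n_per_class=10, seed=3, noise_bandwidth=None
        )
        epochs, manifest = simulate_dataset1(cfg)
        assert manifest["noise_bandwidth"] is None
        assert len(epochs) == 40


class TestEEGSurrogate:
    def test_shapes_and_segmentation(self):
        recs = simulate_eeg_surrogate(10, seed=4)
        assert len(recs) == 10
        ts, cls = recs[0]
        assert len(ts) == 4096 and ts.sampling_rate == pytest.approx(173.61)
        eps = segment_epochs(normalize_recording(ts), 1024)
        assert len(eps) == 4

    def test_deterministic_given_seed(self):
        a = simulate_eeg_surrogate(5, seed=7)
        b = simulate_eeg_surrogate(5, seed=7)
        for (ta, ca), (tb, cb) in zip(a, b):
            np.testing.assert_array_equal(ta.samples, tb.samples)
            assert ca == cb

    def test_class_centers_separate_between_conditions(self):
        """GC-center medians differ across at least two surrogate classes."""
        recs = simulate_eeg_surrogate(40, n_samples=1024, seed=11)
        feats, labels = [], []
        for ts, cls in recs:
            eps = segment_epochs(normalize_recording(ts), 256)
            df = extract_features_batch(eps, "wvg")
            c = df.to_numpy()[:, 256:].mean(axis=1)
            feats.extend(c)
            labels.extend([cls] * len(eps))
        feats, labels = np.asarray(feats), np.asarray(labels)
        pvals = [
            ranksums(feats[labels == a], feats[labels == b]).pvalue
            for a in (1, 2, 3, 4, 5)
            for b in range(a + 1, 6)
        ]
        assert min(pvals) < 0.05
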