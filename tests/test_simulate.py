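"""Generator tests: network topology, VAR dynamics, hemodynamics, noise."""

import numpy as np
import pytest

from csdnet.simulate import (
    GroundTruthNetwork,
    HRFSpec,
    InstabilityError,
    NoiseSpec,
    add_observation_noise,
    companion_spectral_radius,
    convolve_hrf,
    downsample,
    gen_intrinsic_drive,
    logistic_decay,
    make_hrf,
    sample_network,
    simulate_var,
)


class TestSampleNetwork:
    def test_edge_count_matches_connection_probability(self):
        net = sample_network(100, 0.15, order=50, seed=1)
        n_edges = np.count_nonzero(net.adjacency)
        expected = 0.15 * 100 * 99  # 1485
        sd = np.sqrt(100 * 99 * 0.15 * 0.85)
        assert abs(n_edges - expected) < 4 * sd

    def test_full_connection_probability(self):
        net = sample_network(2, 1.0, order=3, seed=0)
        assert net.adjacency[0, 1] != 0 and net.adjacency[1, 0] != 0
        assert np.all(np.diag(net.adjacency) == 0)
        assert np.array_equal(net.lag_kernels[0], np.eye(2))

    def test_same_seed_is_bit_identical(self):
        a = sample_network(30, 0.15, order=10, seed=5)
        b = sample_network(30, 0.15, order=10, seed=5)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(a.lag_kernels, b.lag_kernels)

    def test_lag_kernels_share_support_and_decay(self):
        net = sample_network(20, 0.2, order=8, seed=3)
        support = net.adjacency != 0
        mags = []
        for p in range(1, 9):
            assert np.array_equal(net.lag_kernels[p] != 0, support)
            mags.append(np.abs(net.lag_kernels[p][support]).sum())
        assert all(a >= b for a, b in zip(mags, mags[1:]))  # non-increasing

    def test_emitted_network_is_stable(self):
        net = sample_network(25, 0.3, order=10, target_radius=0.9, seed=2)
        assert net.spectral_radius < 1.0
        assert abs(net.spectral_radius - 0.9) < 0.02

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_network(10, 0.0, order=5)
        with pytest.raises(ValueError):
            sample_network(1, 0.5, order=5)

    def test_subset_keeps_sub_adjacency(self):
        net = sample_network(10, 0.3, order=4, seed=0)
        sub = net.subset(np.array([1, 4, 7]))
        assert sub.n_nodes == 3
        assert sub.adjacency[0, 1] == net.adjacency[1, 4]


def test_logistic_decay_tail_is_negligible():
    d = logistic_decay(np.arange(1, 51), midpoint=5.0, steepness=0.5)
    assert d[49] / d[0] < 0.05


class TestIntrinsicDrive:
    def test_single_sinusoid_concentrates_power(self):
        f0 = 0.25
        drive = gen_intrinsic_drive(
            1, 4096, 0.1, n_harmonics=1, freq_range=(f0, f0), noise_level=0.0,
            seed=0,
        )
        spec = np.abs(np.fft.rfft(drive[0])) ** 2
        freqs = np.fft.rfftfreq(4096, 0.1)
        assert abs(freqs[np.argmax(spec)] - f0) < 2 * (freqs[1] - freqs[0])

    def test_pure_noise_drive_is_white(self):
        T = 20000
        drive = gen_intrinsic_drive(
            2, T, 0.1, n_harmonics=0, noise_level=1.0, seed=1
        )
        x = drive[0] - drive[0].mean()
        rho1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
        assert abs(rho1) < 3.0 / np.sqrt(T)

    def test_determinism_and_nyquist_guard(self):
        a = gen_intrinsic_drive(3, 100, 0.1, seed=9)
        b = gen_intrinsic_drive(3, 100, 0.1, seed=9)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            gen_intrinsic_drive(1, 100, 0.1, freq_range=(0.01, 6.0))


class TestSimulateVar:
    def test_zero_kernels_return_drive(self):
        n, order, T = 3, 4, 50
        kernels = np.zeros((order + 1, n, n))
        kernels[0] = np.eye(n)
        net = GroundTruthNetwork(n, np.zeros((n, n)), kernels, order, seed=0)
        drive = np.random.default_rng(0).standard_normal((n, T + 40))
        out = simulate_var(net, drive, T, burn_in=40)
        assert np.allclose(out, drive[:, 40:])

    @pytest.mark.parametrize("n,order,seed", [(1, 1, 0), (2, 2, 1), (3, 2, 2)])
    def test_matches_naive_scalar_recursion(self, n, order, seed):
        """Oracle: an independently written triple-loop recursion."""
        rng = np.random.default_rng(seed)
        adj = rng.uniform(-0.3, 0.3, (n, n))
        np.fill_diagonal(adj, 0.0)
        kernels = np.zeros((order + 1, n, n))
        kernels[0] = np.eye(n)
        for p in range(1, order + 1):
            kernels[p] = adj / (p + 1)
        net = GroundTruthNetwork(n, adj, kernels, order, seed=seed)
        T, burn = 40, 10
        drive = rng.standard_normal((n, T + burn))
        out = simulate_var(net, drive, T, burn_in=burn)

        y = np.zeros((n, T + burn))
        for t in range(T + burn):
            for i in range(n):
                acc = drive[i, t]
                for p in range(1, order + 1):
                    if t - p >= 0:
                        for j in range(n):
                            acc += kernels[p, i, j] * y[j, t - p]
                y[i, t] = acc
        assert np.allclose(out, y[:, burn:], atol=1e-10)

    def test_directed_edge_produces_cross_correlation(self):
        kernels = np.zeros((2, 2, 2))
        kernels[0] = np.eye(2)
        kernels[1] = np.array([[0.0, 0.8], [0.0, 0.0]])  # node 1 drives node 0
        net = GroundTruthNetwork(2, kernels[1], kernels, 1, seed=0)
        drive = np.random.default_rng(3).standard_normal((2, 5200))
        y = simulate_var(net, drive, 5000, burn_in=200)
        c = np.corrcoef(y[0, 1:], y[1, :-1])[0, 1]  # lagged source -> target
        assert c > 0.4

    def test_stationary_variance_across_halves(self, small_network):
        drive = np.random.default_rng(1).standard_normal((20, 5100))
        y = simulate_var(small_network, drive, 5000, burn_in=100)
        v1, v2 = y[:, :2500].var(), y[:, 2500:].var()
        assert abs(v1 - v2) / max(v1, v2) < 0.2

    def test_divergence_raises_named_instability(self):
        kernels = np.zeros((2, 1, 1))
        kernels[0] = np.eye(1)
        kernels[1] = np.array([[1.5]])
        net = GroundTruthNetwork(1, kernels[1], kernels, 1, seed=0)
        drive = np.ones((1, 500))
        with pytest.raises(InstabilityError, match="sample"):
            simulate_var(net, drive, 400, burn_in=0, overflow_guard=1e6)


class TestHRF:
    def test_canonical_peak_between_4_and_7_seconds(self):
        h = make_hrf(HRFSpec(kind="canonical", dt=0.1))
        assert 4.0 <= np.argmax(h) * 0.1 <= 7.0

    def test_canonical_has_positive_lobe_then_undershoot(self):
        h = make_hrf(HRFSpec(kind="canonical", dt=0.1))
        peak, trough = np.argmax(h), np.argmin(h)
        assert h[peak] > 0 and h[trough] < 0 and trough > peak
        assert 10.0 <= trough * 0.1 <= 20.0

    def test_degenerate_randomization_equals_canonical(self):
        can = make_hrf(HRFSpec(kind="canonical", dt=0.5))
        rand = make_hrf(
            HRFSpec(kind="randomized", dt=0.5, onset_bound=0.0, factor_bound=1.0,
                    seed=3)
        )
        assert np.allclose(can, rand)

    def test_different_seeds_move_the_peak(self):
        peaks = {
            np.argmax(make_hrf(HRFSpec(kind="randomized", dt=0.1, seed=s)))
            for s in range(6)
        }
        assert len(peaks) > 1


class TestConvolveHRF:
    def test_unit_impulse_kernel_is_identity(self, rng):
        x = rng.standard_normal((3, 200))
        assert np.allclose(convolve_hrf(x, np.array([1.0])), x)

    def test_canonical_kernel_attenuates_high_frequencies(self, rng):
        x = rng.standard_normal((1, 8192))
        h = make_hrf(HRFSpec(kind="canonical", dt=0.1))
        y = convolve_hrf(x, h)
        freqs = np.fft.rfftfreq(8192, 0.1)
        px = np.abs(np.fft.rfft(x[0])) ** 2
        py = np.abs(np.fft.rfft(y[0])) ** 2
        hi = freqs > 1.0
        lo = (freqs > 0.01) & (freqs < 0.1)
        gain_hi = py[hi].mean() / px[hi].mean()
        gain_lo = py[lo].mean() / px[lo].mean()
        assert gain_hi < 0.01 * gain_lo

    def test_per_node_delay_shifts_cross_correlation(self, rng):
        x = rng.standard_normal((1, 4000))
        base = make_hrf(HRFSpec(kind="canonical", dt=0.1))
        delayed = np.concatenate([np.zeros(20), base])  # 2 s onset delay
        pair = np.vstack([x, x])
        kernels = np.vstack([
            np.pad(delayed, (0, 0))[: len(delayed)],
            np.pad(base, (0, 20)),
        ])
        y = convolve_hrf(pair, kernels)
        lags = np.arange(-40, 41)
        xc = [np.corrcoef(y[0, 40 + l: 3900 + l], y[1, 40:3900])[0, 1] for l in lags]
        assert lags[np.argmax(xc)] == 20  # node 0 lags node 1 by 2 s

    def test_kernel_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="kernels"):
            convolve_hrf(rng.standard_normal((3, 100)), rng.standard_normal((2, 10)))


class TestObservationNoise:
    def test_snr_calibration(self, rng):
        x = np.cumsum(rng.standard_normal((4, 10000)), axis=1)
        y = add_observation_noise(x, NoiseSpec(kind="white", snr=5.0, seed=0))
        ratio = x.var(axis=1) / (y - x).var(axis=1)
        assert np.all((ratio > 4.5) & (ratio < 5.5))

    def test_temporal_noise_autocorrelation(self, rng):
        T = 20000
        x = rng.standard_normal((1, T))
        y = add_observation_noise(
            x, NoiseSpec(kind="temporal", snr=1.0, ar_coefficient=0.5, seed=1)
        )
        e = (y - x)[0]
        rho = np.dot(e[:-1], e[1:]) / np.dot(e, e)
        assert abs(rho - 0.5) < 3.0 / np.sqrt(T)

    def test_noiseless_configuration_is_identity(self, rng):
        x = rng.standard_normal((2, 100))
        assert np.array_equal(add_observation_noise(x, NoiseSpec(snr=None)), x)

    def test_zero_variance_row_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            add_observation_noise(np.zeros((2, 50)), NoiseSpec(snr=2.0))

    def test_mixture_uses_both_components(self, rng):
        x = rng.standard_normal((1, 20000))
        y = add_observation_noise(
            x, NoiseSpec(kind="mixture", snr=1.0, seed=2)
        )
        e = (y - x)[0]
        rho = np.dot(e[:-1], e[1:]) / np.dot(e, e)
        assert 0.05 < rho < 0.5  # between pure white (0) and pure AR(1) (0.5)


class TestDownsample:
    def test_identity_factor(self, rng):
        x = rng.standard_normal((2, 100))
        assert np.array_equal(downsample(x, 1), x)

    def test_length_bookkeeping(self, rng):
        x = rng.standard_normal((2, 1000))
        assert downsample(x, 10).shape == (2, 100)

    def test_low_frequency_sinusoid_survives(self):
        t = np.arange(4000) * 0.1
        x = np.sin(2 * np.pi * 0.2 * t)[None, :]  # 0.2 Hz < new Nyquist 0.5 Hz
        y = downsample(x, 10)
        freqs = np.fft.rfftfreq(y.shape[1], 1.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(y[0])) ** 2)]
        assert abs(peak - 0.2) < freqs[1]

    def test_factor_bounds(self, rng):
        x = rng.standard_normal((1, 50))
        with pytest.raises(ValueError):
            downsample(x, 0)
        with pytest.raises(ValueError):
            downsample(x, 50)


def test_companion_radius_matches_dense_eig_for_var1():
    a = np.array([[0.5, 0.2], [0.0, 0.3]])
    kernels = np.stack([np.eye(2), a])
    assert np.isclose(companion_spectral_radius(kernels), 0.5, atol=1e-6)
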