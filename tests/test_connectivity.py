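"""Connectivity extraction, inference, and network post-processing tests."""

import numpy as np
import pytest

from csdnet.config import RunConfig
from csdnet.connectivity import (
    ConfidenceIntervals,
    ConnectivityEstimate,
    ThresholdSet,
    apply_significance,
    band_summary,
    bootstrap_cis,
    consensus_network,
    estimate_pipeline,
    extract_connectivity,
    mirror,
    null_thresholds,
)
from csdnet.evaluate import weight_correlation
from csdnet.spectra import TimeSeriesSet


class TestExtractConnectivity:
    def test_identity_factor_gives_empty_network(self):
        g = extract_connectivity(np.eye(4, dtype=complex))
        assert np.allclose(g, 0.0)

    def test_construction_inverts_row_normalization(self, rng):
        n = 5
        g_true = np.where(rng.random((n, n)) < 0.3, rng.uniform(-0.5, 0.5, (n, n)), 0.0)
        np.fill_diagonal(g_true, 0.0)
        d = rng.uniform(0.5, 2.0, n)
        b = d[:, None] * (np.eye(n) - g_true)
        g = extract_connectivity(b.astype(complex))
        assert np.allclose(np.real(g), g_true, atol=1e-12)
        assert np.all(np.diagonal(g) == 0.0)

    def test_positive_row_scaling_is_irrelevant(self, rng):
        n = 4
        b = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        b[np.arange(n), np.arange(n)] = 2.0 + np.abs(b.diagonal())
        scaled = b.copy()
        scaled[2] *= 3.7
        assert np.allclose(extract_connectivity(b), extract_connectivity(scaled))


def _mk_estimate(weights, freqs):
    weights = np.asarray(weights, dtype=complex)
    return ConnectivityEstimate(
        weights=weights,
        signed_weights=np.real(weights).copy(),
        frequencies=np.asarray(freqs, dtype=float),
    )


class TestApplySignificance:
    def setup_method(self):
        w = np.zeros((2, 3, 3))
        w[0, 0, 1], w[0, 1, 0], w[1, 2, 0] = 0.5, -0.4, 0.05
        self.est = _mk_estimate(w, [0.1, 0.2])

    def test_infinite_thresholds_empty_network(self):
        thr = ThresholdSet(np.full(2, -np.inf), np.full(2, np.inf),
                           self.est.frequencies, 0.05, 100)
        out = apply_significance(self.est, thr)
        assert np.all(out.signed_weights == 0.0)
        assert not out.significant.any()

    def test_zero_thresholds_keep_all_nonzero(self):
        thr = ThresholdSet(np.zeros(2), np.zeros(2), self.est.frequencies, 0.05, 100)
        out = apply_significance(self.est, thr)
        assert np.array_equal(out.signed_weights, self.est.signed_weights)

    def test_ci_and_rule(self):
        thr = ThresholdSet(np.zeros(2), np.zeros(2), self.est.frequencies, 0.05, 100)
        lower = np.full((2, 3, 3), -1.0)
        upper = np.full((2, 3, 3), 1.0)  # every CI includes zero
        cis = ConfidenceIntervals(lower, upper, self.est.frequencies, 0.95, 10)
        out = apply_significance(self.est, thr, cis)
        assert np.all(out.signed_weights == 0.0)

    def test_weight_inside_thresholds_masked_despite_ci(self):
        thr = ThresholdSet(np.full(2, -0.1), np.full(2, 0.1),
                           self.est.frequencies, 0.05, 100)
        out = apply_significance(self.est, thr)
        assert out.signed_weights[1, 2, 0] == 0.0  # 0.05 inside (-0.1, 0.1)
        assert out.signed_weights[0, 0, 1] == 0.5

    def test_frequency_mismatch_rejected(self):
        thr = ThresholdSet(np.zeros(2), np.zeros(2), np.array([0.3, 0.4]), 0.05, 10)
        with pytest.raises(ValueError, match="frequencies"):
            apply_significance(self.est, thr)


class TestMirror:
    def test_antisymmetric_cancels(self):
        a = np.array([[0.0, 1.0], [-1.0, 0.0]])
        assert np.allclose(mirror(a), 0.0)

    def test_symmetric_doubles(self, rng):
        s = rng.standard_normal((3, 3))
        s = s + s.T
        assert np.allclose(mirror(s), 2 * s)

    def test_single_edge_becomes_bidirectional(self):
        a = np.zeros((3, 3))
        a[0, 2] = 0.7
        m = mirror(a)
        assert m[0, 2] == m[2, 0] == 0.7


class TestConsensus:
    def test_identical_inputs_roundtrip(self, rng):
        net = np.where(rng.random((4, 4)) < 0.4, rng.standard_normal((4, 4)), 0.0)
        out = consensus_network([net] * 5, 0.5)
        assert np.allclose(out, net)

    def test_minority_edge_dropped_at_boundary(self):
        nets = [np.zeros((2, 2)) for _ in range(20)]
        for k in range(9):  # 9/20 < 0.5
            nets[k] = nets[k].copy()
            nets[k][0, 1] = 1.0
        assert consensus_network(nets, 0.5)[0, 1] == 0.0

    def test_exact_boundary_kept(self):
        nets = [np.zeros((2, 2)) for _ in range(20)]
        for k in range(10):  # 10/20 == 0.5 -> kept
            nets[k] = nets[k].copy()
            nets[k][0, 1] = 2.0
        assert consensus_network(nets, 0.5)[0, 1] == 2.0

    def test_two_thirds_rule_on_binary_inputs(self):
        nets = [np.zeros((2, 2)) for _ in range(3)]
        for k in range(2):
            nets[k] = nets[k].copy()
            nets[k][1, 0] = 1.0
        out = consensus_network(nets, 2.0 / 3.0)
        assert out[1, 0] == 1.0

    def test_kept_weight_is_mean_of_present(self):
        a = np.zeros((2, 2)); a[0, 1] = 1.0
        b = np.zeros((2, 2)); b[0, 1] = 3.0
        c = np.zeros((2, 2))
        out = consensus_network([a, b, c], 0.5)
        assert out[0, 1] == 2.0  # mean over the two networks where present

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_network([np.zeros((2, 2)), np.zeros((3, 3))], 0.5)


class TestBandSummary:
    def test_single_bin_band_is_that_bin(self):
        w = np.random.default_rng(0).standard_normal((3, 4, 4))
        for k in range(3):
            np.fill_diagonal(w[k], 0.0)
        est = _mk_estimate(w, [0.1, 0.2, 0.3])
        out = band_summary(est, (0.05, 0.15), 1.0)
        assert np.allclose(out[(0.05, 0.15)], w[0])

    def test_two_of_three_bins_kept_at_two_thirds(self):
        w = np.zeros((3, 2, 2))
        w[0, 0, 1] = w[1, 0, 1] = 1.0  # edge in 2 of 3 bins
        est = _mk_estimate(w, [0.1, 0.2, 0.3])
        out = band_summary(est, (0.0, 0.4), 2.0 / 3.0)
        assert out[(0.0, 0.4)][0, 1] == 1.0

    def test_constant_estimate_equals_any_bin(self):
        w = np.tile(np.array([[0.0, 0.5], [-0.2, 0.0]]), (4, 1, 1))
        est = _mk_estimate(w, [0.1, 0.2, 0.3, 0.4])
        out = band_summary(est, (0.0, 0.25, 0.5), 0.5)
        for net in out.values():
            assert np.allclose(net, w[0])

    def test_empty_band_rejected(self):
        est = _mk_estimate(np.zeros((2, 2, 2)), [0.1, 0.2])
        with pytest.raises(ValueError, match="no frequency"):
            band_summary(est, (0.5, 0.9))


class TestPipelineInference:
    def test_pipeline_is_deterministic(self, small_ts, fast_config):
        a = estimate_pipeline(small_ts, fast_config)
        b = estimate_pipeline(small_ts, fast_config)
        assert np.array_equal(a.weights, b.weights)

    def test_recovers_small_network(self, small_network, small_ts, fast_config):
        """Regression floor for parameter recovery on the 10-node benchmark."""
        est = estimate_pipeline(small_ts, fast_config)
        rs = [
            weight_correlation(est.signed_weights[k], small_network.adjacency)
            for k in range(3)
        ]
        assert np.mean(rs) > 0.40  # archived floor (observed ~0.50 at this seed)

    def test_null_pool_size_and_threshold_signs(self, small_ts, fast_config):
        thr = null_thresholds(small_ts, fast_config, n_null=3, alpha=0.05, seed=0)
        assert thr.n_null_values == 3 * 20 * 19
        assert np.all(thr.lower <= 0.0) and np.all(thr.upper >= 0.0)

    def test_degenerate_alpha_thresholds_collapse_to_median(self, small_ts, fast_config):
        thr = null_thresholds(small_ts, fast_config, n_null=2, alpha=1.0, seed=0)
        assert np.allclose(thr.lower, thr.upper)

    def test_bootstrap_cis_bracket_point_estimate_mostly(self, small_ts, fast_config):
        est = estimate_pipeline(small_ts, fast_config)
        cis = bootstrap_cis(small_ts, fast_config, n_boot=12, level=0.95, seed=1)
        off = ~np.eye(est.n_nodes, dtype=bool)
        inside = (
            (est.signed_weights >= cis.lower) & (est.signed_weights <= cis.upper)
        )
        frac = np.mean([m[off].mean() for m in inside])
        assert frac > 0.6  # bootstrap spread centred near the estimate
        assert np.all(cis.lower <= cis.upper)
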