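"""Model/Results interface over the estimation pipeline.

``SparseConnectivityModel`` holds the data and configuration;
``fit()`` runs Welch CSD estimation, per-frequency sparse unitary
factorization, and (optionally) null-threshold and bootstrap inference,
returning a ``SparseConnectivityResults`` that carries the per-frequency
coupling matrices, their significance state and summary tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .connectivity import (
    ConfidenceIntervals,
    ConnectivityEstimate,
    ThresholdSet,
    apply_significance,
    band_summary,
    bootstrap_cis,
    estimate_pipeline,
    mirror,
    null_thresholds,
)
from .evaluate import evaluate_estimate, interfrequency_similarity
from .spectra import TimeSeriesSet, choose_nfft

__all__ = ["SparseConnectivityModel", "SparseConnectivityResults"]


class SparseConnectivityModel:
    """Sparse frequency-domain effective-connectivity model.

    Parameters
    ----------
    data : array_like or TimeSeriesSet
        Real multichannel time series, nodes x samples.
    dt : float
        Sampling interval in seconds (ignored if ``data`` is a
        TimeSeriesSet).
    node_labels : list of str, optional
    config : RunConfig, optional
        Full pipeline configuration; keyword overrides are applied on top.

    Examples
    --------
    >>> model = SparseConnectivityModel(series, dt=0.1, nfft=64)
    >>> res = model.fit(n_null=10, n_boot=100, seed=1)
    >>> res.summary()
    """

    def __init__(
        self,
        data,
        dt: float | None = None,
        node_labels: list[str] | None = None,
        config: RunConfig | None = None,
        **config_overrides,
    ) -> None:
        if isinstance(data, TimeSeriesSet):
            self.data = data
        else:
            if dt is None:
                raise ValueError("dt is required when data is a raw array")
            self.data = TimeSeriesSet(
                data=np.asarray(data, dtype=float), dt=dt, node_labels=node_labels
            )
        base = config or RunConfig()
        self.config = base.replace(**config_overrides) if config_overrides else base

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, dt: float, **kwargs
    ) -> "SparseConnectivityModel":
        """Build from a DataFrame with one column per node (rows = samples)."""
        return cls(
            df.to_numpy().T, dt=dt, node_labels=[str(c) for c in df.columns], **kwargs
        )

    @property
    def nfft(self) -> int:
        if self.config.nfft is not None:
            return self.config.nfft
        return choose_nfft(
            self.data.n_samples, self.data.n_nodes, self.config.hrf_correction
        )

    def fit(
        self,
        *,
        n_null: int = 0,
        n_boot: int = 0,
        alpha: float | None = None,
        seed: int | None = None,
    ) -> "SparseConnectivityResults":
        """Estimate per-frequency connectivity; optionally run inference.

        ``n_null`` > 0 adds segment-shuffle null thresholds at level
        ``alpha`` (default from config) and ``n_boot`` > 1 adds bootstrap
        confidence intervals; when either is present the significance mask
        is applied to the signed weights.
        """
        cfg = self.config
        if seed is not None:
            cfg = cfg.replace(seed=seed)
        est = estimate_pipeline(self.data, cfg)
        thresholds: ThresholdSet | None = None
        cis: ConfidenceIntervals | None = None
        if n_null > 0:
            thresholds = null_thresholds(self.data, cfg, n_null=n_null, alpha=alpha)
        if n_boot > 1:
            cis = bootstrap_cis(self.data, cfg, n_boot=n_boot)
        significant = est
        if thresholds is not None:
            significant = apply_significance(est, thresholds, cis)
        return SparseConnectivityResults(
            model=self,
            estimate=significant if thresholds is not None else est,
            raw_estimate=est,
            thresholds=thresholds,
            conf_ints=cis,
            config=cfg,
        )


class SparseConnectivityResults:
    """Fitted per-frequency directed connectivity with inference state."""

    def __init__(
        self,
        model: SparseConnectivityModel,
        estimate: ConnectivityEstimate,
        raw_estimate: ConnectivityEstimate,
        thresholds: ThresholdSet | None,
        conf_ints: ConfidenceIntervals | None,
        config: RunConfig,
    ) -> None:
        self.model = model
        self.estimate = estimate
        self.raw_estimate = raw_estimate
        self.thresholds = thresholds
        self.conf_ints = conf_ints
        self.config = config

    @property
    def frequencies(self) -> np.ndarray:
        return self.estimate.frequencies

    @property
    def weights(self) -> np.ndarray:
        """Signed (real-part) coupling weights, (F, n, n); masked if inference ran."""
        return self.estimate.signed_weights

    def mirrored(self, fi: int) -> np.ndarray:
        """Symmetrized network G + G^T at frequency index ``fi``."""
        return mirror(self.estimate.signed_weights[fi])

    def band_networks(self, band_edges=None, fraction=None) -> dict:
        cfg = self.config
        return band_summary(
            self.estimate,
            band_edges or cfg.band_edges,
            fraction if fraction is not None else cfg.band_fraction,
        )

    def interfrequency_similarity(self) -> np.ndarray:
        return interfrequency_similarity(self.estimate)

    def score(self, truth: np.ndarray, *, mirrored: bool = False) -> pd.DataFrame:
        """Correlation and AUC against a reference adjacency, per frequency."""
        reports = evaluate_estimate(self.estimate, truth, mirrored=mirrored)
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "correlation": [r.correlation for r in reports],
                "auc": [r.auc for r in reports],
                "n_edges_est": [r.n_edges_est for r in reports],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format edge list: frequency, target, source, weight, significance."""
        labels = self.model.data.node_labels
        rows = []
        F, n, _ = self.estimate.signed_weights.shape
        for fi in range(F):
            w = self.estimate.signed_weights[fi]
            sig = (
                self.estimate.significant[fi]
                if self.estimate.significant is not None
                else None
            )
            for i in range(n):
                for j in range(n):
                    if i == j or w[i, j] == 0.0:
                        continue
                    rows.append(
                        {
                            "frequency_hz": self.frequencies[fi],
                            "target": labels[i],
                            "source": labels[j],
                            "weight": w[i, j],
                            "significant": bool(sig[i, j]) if sig is not None else None,
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Text summary in the spirit of statsmodels results tables."""
        est = self.estimate
        n = est.n_nodes
        off = n * (n - 1)
        lines = [
            "Sparse CSD Effective Connectivity Results",
            "=" * 57,
            f"Nodes:                 {n}",
            f"Samples:               {self.model.data.n_samples}",
            f"Sampling interval:     {self.model.data.dt} s",
            f"NFFT:                  {self.model.nfft}",
            f"Frequencies estimated: {len(self.frequencies)} "
            f"({self.frequencies[0]:.4g}-{self.frequencies[-1]:.4g} Hz)",
            f"Config hash:           {self.config.config_hash}",
            "-" * 57,
            f"{'freq (Hz)':>10} {'cost':>10} {'conv':>5} {'n_edges':>8} "
            f"{'density':>8}",
        ]
        for fi, f in enumerate(self.frequencies):
            w = est.signed_weights[fi]
            ne = int(np.count_nonzero(w) - np.count_nonzero(np.diag(w)))
            cost = est.costs[fi] if est.costs is not None else float("nan")
            conv = (
                "yes" if est.converged is not None and est.converged[fi] else "no"
            )
            lines.append(
                f"{f:>10.4g} {cost:>10.4g} {conv:>5} {ne:>8} {ne / off:>8.3f}"
            )
        if self.thresholds is not None:
            lines.append("-" * 57)
            lines.append(
                f"Null thresholds: alpha={self.thresholds.alpha}, "
                f"{self.thresholds.n_null_values} pooled values/frequency"
            )
        if self.conf_ints is not None:
            lines.append(
                f"Bootstrap CIs:   level={self.conf_ints.level}, "
                f"n_boot={self.conf_ints.n_boot}"
            )
        return "\n".join(lines)

    def plot_connectivity(self, fi: int = 0, ax=None, cmap: str = "RdBu_r"):
        """Matrix plot of the signed network at one frequency (red = excitatory,
        blue = inhibitory; connection goes from column to row)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        w = self.estimate.signed_weights[fi]
        v = np.max(np.abs(w)) or 1.0
        im = ax.imshow(w, cmap=cmap, vmin=-v, vmax=v)
        ax.set_xlabel("source node")
        ax.set_ylabel("target node")
        ax.set_title(f"f = {self.frequencies[fi]:.3g} Hz")
        ax.figure.colorbar(im, ax=ax)
        return ax
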