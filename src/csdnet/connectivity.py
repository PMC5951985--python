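"""From optimized spectral factors to directed connectivity with inference.

The coupling matrix at each frequency is Ghat = I - Xhat^{1/2} B.  The
diagonal noise scale Xhat is unobservable, so each row of B is normalized by
its own (phase-fixed, real positive) diagonal entry; the resulting Ghat has
an exactly zero diagonal and its off-diagonal entries carry the strength,
sign (real part) and direction of the estimated couplings up to a positive
per-row factor.

Significance: a segment-shuffled null (cross-spectra destroyed, power
spectra preserved) yields two-sided per-frequency quantile thresholds, and
a segment bootstrap yields Gaussian confidence intervals per connection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm as _norm

from .config import RunConfig
from .decomp import fix_phases, initial_factor, optimize_unitary
from .spectra import (
    CrossSpectralDensity,
    TimeSeriesSet,
    bootstrap_csd,
    choose_nfft,
    shuffled_null_csd,
    welch_csd,
)

__all__ = [
    "ConnectivityEstimate",
    "ThresholdSet",
    "ConfidenceIntervals",
    "extract_connectivity",
    "estimate_from_csd",
    "estimate_pipeline",
    "null_thresholds",
    "bootstrap_cis",
    "apply_significance",
    "mirror",
    "consensus_network",
    "band_summary",
]


@dataclass
class ConnectivityEstimate:
    """Per-frequency directed coupling estimates plus significance state.

    ``weights[f, i, j]``: complex influence of node j on node i at frequency
    ``frequencies[f]`` (row = target, column = source).  ``signed_weights``
    is the real part, the view used for thresholding, plotting and scoring;
    it is zeroed outside the significance mask once one is applied.
    """

    weights: np.ndarray  # (F, n, n) complex
    signed_weights: np.ndarray  # (F, n, n) real
    frequencies: np.ndarray
    significant: np.ndarray | None = None  # (F, n, n) bool
    costs: np.ndarray | None = None
    converged: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[1]


@dataclass
class ThresholdSet:
    """Two-sided per-frequency quantile thresholds from the shuffled null."""

    lower: np.ndarray  # (F,)
    upper: np.ndarray  # (F,)
    frequencies: np.ndarray
    alpha: float
    n_null_values: int

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("lower thresholds must not exceed upper thresholds")


@dataclass
class ConfidenceIntervals:
    """Gaussian bootstrap intervals on the signed weights."""

    lower: np.ndarray  # (F, n, n)
    upper: np.ndarray  # (F, n, n)
    frequencies: np.ndarray
    level: float
    n_boot: int

    def excludes_zero(self) -> np.ndarray:
        return (self.lower > 0) | (self.upper < 0)


def extract_connectivity(factor) -> np.ndarray:
    """Coupling slice Ghat = I - B / diag(B) from an optimized factor.

    The row normalization absorbs the unknown positive diagonal noise scale;
    the diagonal of the result is exactly zero.  Rows with a vanishing
    diagonal entry cannot be normalized and are returned as NaN.
    """
    b = factor.b if hasattr(factor, "b") else np.asarray(factor)
    if b is None:
        raise ValueError("factor has no optimized b; run optimize_unitary first")
    b = fix_phases(b)
    d = np.real(np.diagonal(b)).copy()
    bad = d <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} row(s) with nonpositive diagonal; emitted as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        d[bad] = 1.0
    g = np.eye(b.shape[0], dtype=complex) - b / d[:, None]
    g[bad, :] = np.nan
    np.fill_diagonal(g, 0.0)
    return g


def _resolve_nfft(ts: TimeSeriesSet, config: RunConfig) -> int:
    if config.nfft is not None:
        return config.nfft
    return choose_nfft(ts.n_samples, ts.n_nodes, config.hrf_correction)


def estimate_from_csd(
    csd: CrossSpectralDensity,
    config: RunConfig,
    *,
    bins: np.ndarray | None = None,
) -> ConnectivityEstimate:
    """Run factorization + sparse rotation on each CSD slice independently.

    ``bins`` selects slice indices; otherwise the lowest ``config.max_bins``
    bins (or all) are processed.  Frequencies are independent, so results do
    not depend on processing order.
    """
    if bins is None:
        n_bins = len(csd.frequencies)
        if config.max_bins is not None:
            n_bins = min(n_bins, config.max_bins)
        bins = np.arange(n_bins)
    bins = np.asarray(bins, dtype=int)
    n = csd.n_nodes
    F = len(bins)
    weights = np.empty((F, n, n), dtype=complex)
    costs = np.empty(F)
    converged = np.empty(F, dtype=bool)
    for k, fi in enumerate(bins):
        try:
            fac = initial_factor(
                csd.matrices[fi], config.ridge, frequency=csd.frequencies[fi]
            )
            fac = optimize_unitary(
                fac,
                max_iter=config.max_iter,
                tol=config.tol,
                smoothing_eps=(config.eps_start, config.eps_end),
                n_stages=config.n_stages,
                restarts=config.restarts,
                seed=config.seed,
            )
        except Exception as exc:
            raise RuntimeError(
                f"estimation failed at frequency {csd.frequencies[fi]:.4g} Hz: {exc}"
            ) from exc
        weights[k] = extract_connectivity(fac)
        costs[k] = fac.cost
        converged[k] = fac.converged
    return ConnectivityEstimate(
        weights=weights,
        signed_weights=np.real(weights).copy(),
        frequencies=csd.frequencies[bins].copy(),
        costs=costs,
        converged=converged,
        provenance={"config_hash": config.config_hash, "nfft": csd.nfft},
    )


def estimate_pipeline(ts: TimeSeriesSet, config: RunConfig) -> ConnectivityEstimate:
    """Welch CSD -> per-frequency sparse factorization -> coupling matrices."""
    nfft = _resolve_nfft(ts, config)
    csd = welch_csd(
        ts, nfft, config.overlap, config.window, detrend=config.detrend
    )
    est = estimate_from_csd(csd, config)
    est.provenance["seed"] = config.seed
    return est


def null_thresholds(
    ts: TimeSeriesSet,
    config: RunConfig,
    n_null: int | None = None,
    alpha: float | None = None,
    seed: int | None = None,
) -> ThresholdSet:
    """Significance thresholds from segment-shuffled null connectivities.

    Each replicate shuffles segment order independently per channel, runs
    the full estimation, and contributes all off-diagonal signed weights to
    the per-frequency pooled null; thresholds are its alpha/2 and 1-alpha/2
    quantiles.  Failed replicates are dropped with a warning; if fewer than
    half survive the thresholds are considered unreliable and an error is
    raised.  With ``config.pool_frequencies`` the null is pooled across
    frequencies into a single pair of thresholds, repeated per frequency.
    """
    n_null = config.n_null if n_null is None else n_null
    alpha = config.alpha if alpha is None else alpha
    seed = config.seed if seed is None else seed
    if n_null < 1:
        raise ValueError("need at least one null replicate")
    nfft = _resolve_nfft(ts, config)
    rng = np.random.default_rng(seed)
    pools: list[np.ndarray] = []
    freqs = None
    for r in range(n_null):
        try:
            csd = shuffled_null_csd(
                ts,
                nfft,
                config.overlap,
                config.window,
                detrend=config.detrend,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            est = estimate_from_csd(csd, config)
        except Exception as exc:
            warnings.warn(
                f"null replicate {r} failed and was dropped: {exc}",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        freqs = est.frequencies
        off = ~np.eye(est.n_nodes, dtype=bool)
        pools.append(np.stack([w[off] for w in est.signed_weights]))  # (F, n(n-1))
    if len(pools) < max(1, n_null // 2):
        raise RuntimeError(
            f"only {len(pools)} of {n_null} null replicates survived"
        )
    null_vals = np.concatenate(pools, axis=1)  # (F, n_reps * n(n-1))
    if config.pool_frequencies:
        flat = null_vals.ravel()
        lo = np.full(null_vals.shape[0], np.quantile(flat, alpha / 2))
        hi = np.full(null_vals.shape[0], np.quantile(flat, 1 - alpha / 2))
    else:
        lo = np.quantile(null_vals, alpha / 2, axis=1)
        hi = np.quantile(null_vals, 1 - alpha / 2, axis=1)
    return ThresholdSet(
        lower=lo,
        upper=hi,
        frequencies=freqs,
        alpha=alpha,
        n_null_values=null_vals.shape[1],
    )


def bootstrap_cis(
    ts: TimeSeriesSet,
    config: RunConfig,
    n_boot: int | None = None,
    level: float | None = None,
    seed: int | None = None,
) -> ConfidenceIntervals:
    """Gaussian confidence intervals from segment-bootstrap connectivities.

    Each replicate resamples segments with replacement (same resample for
    every channel), re-estimates, and the per-connection mean and standard
    deviation across replicates give mean +/- z * sd intervals.
    """
    n_boot = config.n_boot if n_boot is None else n_boot
    level = config.ci_level if level is None else level
    seed = config.seed if seed is None else seed
    if n_boot < 2:
        raise ValueError("need at least two bootstrap replicates")
    nfft = _resolve_nfft(ts, config)
    rng = np.random.default_rng(seed)
    reps: list[np.ndarray] = []
    freqs = None
    for r in range(n_boot):
        try:
            csd = bootstrap_csd(
                ts,
                nfft,
                config.overlap,
                config.window,
                detrend=config.detrend,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            est = estimate_from_csd(csd, config)
        except Exception as exc:
            warnings.warn(
                f"bootstrap replicate {r} failed and was dropped: {exc}",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        freqs = est.frequencies
        reps.append(est.signed_weights)
    if len(reps) < max(2, n_boot // 2):
        raise RuntimeError(f"only {len(reps)} of {n_boot} bootstrap replicates survived")
    stack = np.stack(reps)  # (R, F, n, n)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    z = _norm.ppf(0.5 + level / 2)
    return ConfidenceIntervals(
        lower=mean - z * sd,
        upper=mean + z * sd,
        frequencies=freqs,
        level=level,
        n_boot=len(reps),
    )


def apply_significance(
    est: ConnectivityEstimate,
    thr: ThresholdSet,
    cis: ConfidenceIntervals | None = None,
) -> ConnectivityEstimate:
    """Mask non-significant couplings.

    A connection survives iff its signed weight falls outside the null
    thresholds AND (when intervals are supplied) its bootstrap CI excludes
    zero.  Surviving weights are kept; all others are zeroed in the signed
    view.  The complex weights are retained unmasked.
    """
    if not np.allclose(est.frequencies, thr.frequencies):
        raise ValueError("threshold frequencies do not match the estimate")
    w = est.signed_weights
    mask = (w < thr.lower[:, None, None]) | (w > thr.upper[:, None, None])
    if cis is not None:
        if not np.allclose(est.frequencies, cis.frequencies):
            raise ValueError("CI frequencies do not match the estimate")
        mask &= cis.excludes_zero()
    mask &= w != 0.0
    for m in mask:
        np.fill_diagonal(m, False)
    return ConnectivityEstimate(
        weights=est.weights.copy(),
        signed_weights=np.where(mask, w, 0.0),
        frequencies=est.frequencies.copy(),
        significant=mask,
        costs=est.costs,
        converged=est.converged,
        provenance=dict(est.provenance),
    )


def mirror(net: np.ndarray) -> np.ndarray:
    """Symmetrize a directed network: G + G^T."""
    net = np.asarray(net)
    if net.ndim != 2 or net.shape[0] != net.shape[1]:
        raise ValueError("expected a square matrix")
    return net + net.T


def consensus_network(
    nets: list[np.ndarray] | np.ndarray, min_fraction: float = 0.5
) -> np.ndarray:
    """Keep edges present (nonzero) in at least ``min_fraction`` of inputs.

    A kept edge's weight is the mean over the inputs where it is present
    (zeros excluded from the mean); ties at the boundary are kept.
    """
    stack = np.stack([np.asarray(n, dtype=float) for n in np.atleast_1d(nets)])
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("all networks must be square and equally shaped")
    present = stack != 0.0
    frac = present.mean(axis=0)
    keep = frac >= min_fraction
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_present = np.where(
            present.sum(axis=0) > 0,
            stack.sum(axis=0) / np.maximum(present.sum(axis=0), 1),
            0.0,
        )
    return np.where(keep & (present.sum(axis=0) > 0), mean_present, 0.0)


def band_summary(
    est: ConnectivityEstimate,
    band_edges: tuple[float, ...],
    within_band_fraction: float = 2.0 / 3.0,
) -> dict[tuple[float, float], np.ndarray]:
    """Consensus network per frequency band.

    Bands are the half-open intervals (lo, hi] between successive edges; an
    edge survives a band if present in at least ``within_band_fraction`` of
    the band's bins and takes the mean weight over bins where present.
    """
    out: dict[tuple[float, float], np.ndarray] = {}
    for lo, hi in zip(band_edges[:-1], band_edges[1:]):
        sel = (est.frequencies > lo) & (est.frequencies <= hi)
        if not np.any(sel):
            raise ValueError(f"band ({lo}, {hi}] contains no frequency bins")
        out[(lo, hi)] = consensus_network(
            est.signed_weights[sel], within_band_fraction
        )
    return out
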