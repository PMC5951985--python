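"""Cross-spectral density estimation and resampled CSDs for inference.

One segment-FFT core serves the plain Welch estimate, the segment-shuffled
null (which destroys cross-spectra while preserving power spectra exactly)
and the segment bootstrap, so all three share a single normalization and
their connectivity values are directly comparable.

Normalization convention: the scipy "density" convention.  Each segment is
mean-removed (by default), multiplied by the window w, and FFT'd; the CSD is
the segment average of ``Y_i(f) conj(Y_j(f)) / (fs * sum(w^2))``, doubled at
interior frequencies of the one-sided spectrum.  Under this convention the
diagonal integrates (sum over bins times the bin width) to the windowed
signal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

__all__ = [
    "TimeSeriesSet",
    "CrossSpectralDensity",
    "choose_nfft",
    "welch_csd",
    "shuffled_null_csd",
    "bootstrap_csd",
]


@dataclass
class TimeSeriesSet:
    """Multichannel real time series: nodes x samples at a fixed interval."""

    data: np.ndarray
    dt: float
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.node_labels is None:
            self.node_labels = [f"n{i}" for i in range(self.data.shape[0])]
        if len(self.node_labels) != self.data.shape[0]:
            raise ValueError("one label per node required")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class CrossSpectralDensity:
    """Per-frequency Hermitian cross-spectral matrices with metadata."""

    matrices: np.ndarray  # (F, n, n) complex
    frequencies: np.ndarray  # (F,) Hz
    nfft: int
    n_segments: int
    window: str = "hann"
    overlap: float = 0.5
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=complex)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (F, n, n)")
        if len(self.frequencies) != self.matrices.shape[0]:
            raise ValueError("one frequency per slice required")

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


def choose_nfft(n_samples: int, n_nodes: int, hrf_correction: bool = False) -> int:
    """Largest power of two strictly below n_samples / n_nodes.

    The inverse CSD only exists if the Welch average has full rank, which
    requires fewer frequency bins than time samples per node.  Convolution
    with a hemodynamic kernel costs further degrees of freedom, so
    ``hrf_correction`` steps down one more power of two.
    """
    if n_samples <= n_nodes:
        raise ValueError("need more samples than nodes")
    ratio = n_samples / n_nodes
    exp = int(np.floor(np.log2(ratio)))
    if 2**exp >= ratio:  # ratio is an exact power of two: strictly below
        exp -= 1
    if hrf_correction:
        exp -= 1
    nfft = 2**exp
    if nfft < 4:
        raise ValueError(
            f"too few samples per node: nfft rule yields {nfft} (< 4); "
            "acquire more samples or reduce nodes"
        )
    return nfft


def _segment_fft(
    ts: TimeSeriesSet,
    nfft: int,
    overlap: float,
    window: str,
    detrend: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Windowed per-segment FFTs.

    Returns (Y, freqs, scale) where Y is (n_nodes, n_segments, F) for the
    full one-sided band including DC and Nyquist, and ``scale`` maps segment
    outer products to density units (before one-sided doubling).
    """
    if nfft > ts.n_samples:
        raise ValueError("nfft exceeds the number of samples")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    hop = max(1, int(round(nfft * (1.0 - overlap))))
    n_seg = (ts.n_samples - nfft) // hop + 1
    if n_seg < 2:
        raise ValueError(
            f"only {n_seg} segment(s) of length {nfft}; need >= 2 for averaging"
        )
    win = get_window(window, nfft)
    starts = np.arange(n_seg) * hop
    idx = starts[:, None] + np.arange(nfft)[None, :]
    segs = ts.data[:, idx]  # (n, n_seg, nfft)
    if detrend:
        segs = segs - segs.mean(axis=2, keepdims=True)
    Y = np.fft.rfft(segs * win[None, None, :], n=nfft, axis=2)
    freqs = np.fft.rfftfreq(nfft, d=ts.dt)
    fs = 1.0 / ts.dt
    scale = 1.0 / (fs * np.sum(win**2))
    return Y, freqs, scale


def welch_csd(
    ts: TimeSeriesSet,
    nfft: int,
    overlap: float = 0.5,
    window: str = "hann",
    *,
    detrend: bool = True,
    keep_edges: bool = False,
) -> CrossSpectralDensity:
    """Welch estimate of the cross-spectral density matrix.

    Overlapping windowed segments are Fourier transformed and the CSD at
    each retained frequency is the segment average of outer products
    ``y(f) y*(f)``, Hermitian and positive semidefinite by construction.
    By default the DC bin and the topmost (Nyquist) bin are dropped:
    connectivity is estimated on mean-removed data at 0 < f < Nyquist.
    """
    Y, freqs, scale = _segment_fft(ts, nfft, overlap, window, detrend)
    csd, fkept = _average_csd_onesided(Y, freqs, scale, nfft, keep_edges)
    return CrossSpectralDensity(
        matrices=csd,
        frequencies=fkept,
        nfft=nfft,
        n_segments=Y.shape[1],
        window=window,
        overlap=overlap,
        dt=ts.dt,
    )


def _average_csd_onesided(
    Y: np.ndarray, freqs: np.ndarray, scale: float, nfft: int, keep_edges: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Average segment outer products into one-sided density CSD slices.

    Interior bins are doubled; DC and (for even nfft) the Nyquist bin are
    not, matching the scipy one-sided density convention.
    """
    n, n_seg, F = Y.shape
    csd = np.empty((F, n, n), dtype=complex)
    for f in range(F):
        Yf = Y[:, :, f]
        csd[f] = (Yf @ Yf.conj().T) * (scale / n_seg)
    factor = np.full(F, 2.0)
    factor[0] = 1.0
    if nfft % 2 == 0:
        factor[-1] = 1.0
    csd *= factor[:, None, None]
    if not keep_edges:
        keep = np.ones(F, dtype=bool)
        keep[0] = False
        if nfft % 2 == 0:
            keep[-1] = False
        return csd[keep], freqs[keep]
    return csd, freqs


def _resampled_csd(
    ts: TimeSeriesSet,
    nfft: int,
    overlap: float,
    window: str,
    detrend: bool,
    keep_edges: bool,
    reindex,  # callable (n_nodes, n_segments) -> (n, K) integer index array
    exact_diagonal: bool = False,
) -> CrossSpectralDensity:
    Y, freqs, scale = _segment_fft(ts, nfft, overlap, window, detrend)
    n, n_seg, F = Y.shape
    idx = reindex(n, n_seg)
    Yr = np.take_along_axis(Y, idx[:, :, None], axis=1)
    csd, fkept = _average_csd_onesided(Yr, freqs, scale, nfft, keep_edges)
    if exact_diagonal:
        # a permutation only reorders each channel's own segments, so the
        # power spectra are mathematically unchanged; recompute them in the
        # un-shuffled summation order so they are bit-identical to Welch
        keep = np.ones(F, dtype=bool)
        if not keep_edges:
            keep[0] = False
            if nfft % 2 == 0:
                keep[-1] = False
        factor = np.full(F, 2.0)
        factor[0] = 1.0
        if nfft % 2 == 0:
            factor[-1] = 1.0
        for f_out, f_in in enumerate(np.flatnonzero(keep)):
            Yf = Y[:, :, f_in]
            diag = (Yf @ Yf.conj().T).diagonal() * (scale / n_seg) * factor[f_in]
            csd[f_out, np.arange(n), np.arange(n)] = diag
    return CrossSpectralDensity(
        matrices=csd,
        frequencies=fkept,
        nfft=nfft,
        n_segments=n_seg,
        window=window,
        overlap=overlap,
        dt=ts.dt,
    )


def shuffled_null_csd(
    ts: TimeSeriesSet,
    nfft: int,
    overlap: float = 0.5,
    window: str = "hann",
    *,
    detrend: bool = True,
    keep_edges: bool = False,
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> CrossSpectralDensity:
    """Null CSD: each channel's segment order permuted independently.

    Cross-spectral terms then average products of mismatched segments and
    decorrelate, while each power spectrum (diagonal) is a sum over the same
    set of segments and is preserved exactly.  ``permutations`` (n x K) is a
    test hook overriding the random permutations.
    """

    def reindex(n: int, n_seg: int) -> np.ndarray:
        if permutations is not None:
            p = np.asarray(permutations, dtype=int)
            if p.shape != (n, n_seg):
                raise ValueError("permutations must be (n_nodes, n_segments)")
            return p
        rng = np.random.default_rng(seed)
        return np.stack([rng.permutation(n_seg) for _ in range(n)])

    return _resampled_csd(
        ts, nfft, overlap, window, detrend, keep_edges, reindex,
        exact_diagonal=True,
    )


def bootstrap_csd(
    ts: TimeSeriesSet,
    nfft: int,
    overlap: float = 0.5,
    window: str = "hann",
    *,
    detrend: bool = True,
    keep_edges: bool = False,
    seed: int = 0,
    indices: np.ndarray | None = None,
) -> CrossSpectralDensity:
    """Bootstrap CSD: one segment resample (with replacement) shared by all
    channels, preserving within-segment cross-channel alignment.

    ``indices`` (length K) is a test hook overriding the random resample.
    """

    def reindex(n: int, n_seg: int) -> np.ndarray:
        if indices is not None:
            ix = np.asarray(indices, dtype=int)
            if ix.ndim != 1 or len(ix) != n_seg:
                raise ValueError("indices must be a length-n_segments vector")
            return np.tile(ix, (n, 1))
        rng = np.random.default_rng(seed)
        ix = rng.integers(0, n_seg, size=n_seg)
        return np.tile(ix, (n, 1))

    return _resampled_csd(ts, nfft, overlap, window, detrend, keep_edges, reindex)
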