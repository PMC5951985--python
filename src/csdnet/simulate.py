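"""Synthetic BOLD-like benchmark data with known directed ground truth.

The generative model is the one the estimator assumes: a sparse directed
VAR(p) network of neuronal populations driven by independent intrinsic
activity, observed through a hemodynamic response kernel with additive
observation noise,

    y(t) = e(t) + sum_{p=1..P} G(p) y(t-p)        (neuronal dynamics)
    b(t) = (h * y)(t) + noise(t)                  (BOLD observation)

where ``G(p)_{ij}`` is the influence of node j on node i at lag p.  The
lag-zero kernel is the identity (standard VAR normalization) and is stored
but never applied in the recursion.  All topology lives in a single signed
Erdős–Rényi adjacency; the lag kernels share that support and decay
logistically with lag.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import sparse
from scipy.sparse.linalg import eigs as _eigs
from scipy.special import gammaln

__all__ = [
    "GroundTruthNetwork",
    "HRFSpec",
    "NoiseSpec",
    "sample_network",
    "gen_intrinsic_drive",
    "simulate_var",
    "make_hrf",
    "convolve_hrf",
    "add_observation_noise",
    "downsample",
    "simulate_benchmark",
]


class InstabilityError(RuntimeError):
    """Raised when a VAR network is (or becomes) dynamically unstable."""


# ---------------------------------------------------------------------------
# ground-truth network


@dataclass
class GroundTruthNetwork:
    """Directed weighted network plus its lagged coupling kernels.

    ``adjacency[i, j]`` is the signed influence of node j on node i
    (row = target, column = source).  ``lag_kernels[p]`` is ``G(p)``;
    ``lag_kernels[0]`` is the identity and ``lag_kernels[p >= 1]`` equal the
    adjacency scaled by the logistic decay factor at lag p.
    """

    n_nodes: int
    adjacency: np.ndarray
    lag_kernels: np.ndarray  # (order + 1, n, n)
    order: int
    seed: int
    rescale_factor: float = 1.0
    spectral_radius: float = float("nan")

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.lag_kernels = np.asarray(self.lag_kernels, dtype=float)
        n = self.n_nodes
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be n_nodes x n_nodes")
        if self.lag_kernels.shape != (self.order + 1, n, n):
            raise ValueError("lag_kernels must have shape (order+1, n, n)")

    def subset(self, nodes: np.ndarray) -> "GroundTruthNetwork":
        """Restrict the network to the given node indices (missing-node study)."""
        nodes = np.asarray(nodes, dtype=int)
        return GroundTruthNetwork(
            n_nodes=len(nodes),
            adjacency=self.adjacency[np.ix_(nodes, nodes)],
            lag_kernels=self.lag_kernels[:, nodes][:, :, nodes],
            order=self.order,
            seed=self.seed,
            rescale_factor=self.rescale_factor,
            spectral_radius=float("nan"),
        )


def logistic_decay(lags: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    """Decreasing logistic profile 1 / (1 + exp(steepness * (lag - midpoint)))."""
    lags = np.asarray(lags, dtype=float)
    return 1.0 / (1.0 + np.exp(steepness * (lags - midpoint)))


def companion_spectral_radius(lag_kernels: np.ndarray, tol: float = 1e-7) -> float:
    """Spectral radius of the VAR companion matrix, via sparse Arnoldi.

    The companion matrix of a VAR(P) with n nodes is (nP x nP); for the
    benchmark scale (n=100, P=50) a dense eigendecomposition is infeasible,
    so the largest-magnitude eigenvalue is found with ARPACK on the sparse
    companion.
    """
    order_p1, n, _ = lag_kernels.shape
    order = order_p1 - 1
    if order == 0 or not np.any(lag_kernels[1:]):
        return 0.0
    if order == 1:
        return float(np.max(np.abs(np.linalg.eigvals(lag_kernels[1]))))
    if n * order <= 500:
        # small companion: dense eigenvalues are exact (ARPACK is unreliable
        # for nilpotent companions, e.g. acyclic networks with radius 0)
        top = np.hstack([lag_kernels[p] for p in range(1, order + 1)])
        comp_d = np.vstack([top, np.eye(n * (order - 1), n * order)])
        return float(np.max(np.abs(np.linalg.eigvals(comp_d))))
    top = sparse.hstack([sparse.csr_matrix(lag_kernels[p]) for p in range(1, order + 1)])
    shift = sparse.eye(n * (order - 1), n * order, k=0, format="csr")
    comp = sparse.vstack([top, shift]).tocsr()
    try:
        vals = _eigs(comp, k=1, which="LM", return_eigenvectors=False, tol=tol,
                     maxiter=5000, v0=np.ones(comp.shape[0]))
        return float(np.abs(vals[0]))
    except Exception:
        # ARPACK can struggle on defective companions; fall back to power iteration
        rng = np.random.default_rng(0)
        v = rng.standard_normal(comp.shape[0])
        r = 0.0
        for _ in range(2000):
            v = comp @ v
            nv = np.linalg.norm(v)
            if nv == 0:
                return 0.0
            r, v = nv, v / nv
        return float(r)


def sample_network(
    n_nodes: int,
    p_connect: float,
    order: int = 50,
    *,
    weight_range: tuple[float, float] = (0.5, 1.0),
    inhibitory_fraction: float = 0.5,
    decay_midpoint: float = 5.0,
    decay_steepness: float = 0.5,
    target_radius: float = 0.95,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Sample a directed Erdős–Rényi VAR network with logistic lag decay.

    Each ordered off-diagonal pair is connected independently with
    probability ``p_connect``.  Connected entries draw a magnitude uniformly
    from ``weight_range`` and are negative (inhibitory) with probability
    ``inhibitory_fraction``.  The lag kernels are the adjacency times a
    logistic decay over lags 1..order, globally rescaled so the companion
    spectral radius equals ``target_radius`` (< 1, guaranteeing stability);
    the applied factor is recorded on the result.
    """
    if not 0.0 < p_connect <= 1.0:
        raise ValueError(f"p_connect must be in (0, 1], got {p_connect}")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0.0 < target_radius < 1.0:
        raise ValueError("target_radius must be in (0, 1)")

    rng = np.random.default_rng(seed)
    n = n_nodes
    mask = rng.random((n, n)) < p_connect
    np.fill_diagonal(mask, False)
    lo, hi = weight_range
    weights = rng.uniform(lo, hi, size=(n, n))
    signs = np.where(rng.random((n, n)) < inhibitory_fraction, -1.0, 1.0)
    adjacency = np.where(mask, weights * signs, 0.0)

    decay = logistic_decay(np.arange(1, order + 1), decay_midpoint, decay_steepness)
    kernels = np.empty((order + 1, n, n))
    kernels[0] = np.eye(n)
    kernels[1:] = decay[:, None, None] * adjacency[None, :, :]

    radius = companion_spectral_radius(kernels)
    factor = 1.0
    if radius > 1e-9:  # acyclic networks have radius 0: stable at any scale

        def radius_at(s: float) -> float:
            k = kernels.copy()
            k[1:] *= s
            return companion_spectral_radius(k)

        # the companion radius is continuous and strictly increasing in a
        # global kernel scale; bracket the target then bisect
        hi = target_radius / radius  # exact for order 1, a guess otherwise
        r_hi = radius_at(hi)
        for _ in range(60):
            if r_hi >= target_radius:
                break
            hi *= 1.5
            r_hi = radius_at(hi)
        lo, r_lo = 0.0, 0.0
        for _ in range(40):
            if abs(r_hi - target_radius) < 1e-3:
                break
            mid = 0.5 * (lo + hi)
            r_mid = radius_at(mid)
            if r_mid < target_radius:
                lo, r_lo = mid, r_mid
            else:
                hi, r_hi = mid, r_mid
        factor = hi  # upper end: radius within tolerance of (or just above) target
        kernels[1:] *= factor
        radius = r_hi
        if radius >= 1.0:
            raise InstabilityError(
                f"network still unstable after rescaling (radius={radius:.4f})"
            )
        adjacency = adjacency * factor

    return GroundTruthNetwork(
        n_nodes=n,
        adjacency=adjacency,
        lag_kernels=kernels,
        order=order,
        seed=seed,
        rescale_factor=factor,
        spectral_radius=radius,
    )


# ---------------------------------------------------------------------------
# intrinsic drive


def gen_intrinsic_drive(
    n_nodes: int,
    n_samples: int,
    dt: float,
    *,
    n_harmonics: int = 3,
    freq_range: tuple[float, float] = (0.01, 0.5),
    amplitude: float = 1.0,
    noise_level: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Noisy superposition of harmonic oscillations, independent per node.

    Each node receives ``n_harmonics`` sinusoids with node-specific random
    frequencies (uniform in ``freq_range``) and phases, plus i.i.d. Gaussian
    noise of standard deviation ``noise_level``.  The white component keeps
    the drive spectrum full-rank at every frequency, which the estimator's
    diagonal-noise assumption requires.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    nyquist = 0.5 / dt
    if freq_range[1] > nyquist:
        raise ValueError(
            f"drive frequencies up to {freq_range[1]} Hz exceed Nyquist {nyquist} Hz"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * dt
    drive = np.zeros((n_nodes, n_samples))
    if n_harmonics > 0:
        freqs = rng.uniform(freq_range[0], freq_range[1], size=(n_nodes, n_harmonics))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_nodes, n_harmonics))
        # (n, K, T) would be large for benchmark sizes; accumulate per harmonic
        for k in range(n_harmonics):
            drive += amplitude * np.sin(
                2.0 * np.pi * freqs[:, k][:, None] * t[None, :] + phases[:, k][:, None]
            )
    if noise_level > 0:
        drive += noise_level * rng.standard_normal((n_nodes, n_samples))
    return drive


# ---------------------------------------------------------------------------
# VAR recursion


def simulate_var(
    network: GroundTruthNetwork,
    drive: np.ndarray,
    n_samples: int,
    *,
    burn_in: int | None = None,
    overflow_guard: float = 1e8,
) -> np.ndarray:
    """Run the VAR recursion y(t) = e(t) + sum_p G(p) y(t-p).

    History before t=0 is zero; ``burn_in`` leading samples (default
    10 x order) are simulated and discarded so the returned ``n_samples``
    columns are approximately stationary.  ``drive`` must provide at least
    ``burn_in + n_samples`` columns of e(t).
    """
    n = network.n_nodes
    order = network.order
    if burn_in is None:
        burn_in = 10 * order
    total = burn_in + n_samples
    if drive.shape[0] != n:
        raise ValueError("drive row count must equal n_nodes")
    if drive.shape[1] < total:
        raise ValueError(
            f"drive must have >= burn_in + n_samples = {total} columns, "
            f"got {drive.shape[1]}"
        )
    # Flatten kernels to one (n, order*n) matrix so each step is a single GEMV
    # against the stacked recent history [y(t-1); ...; y(t-order)].
    gflat = np.ascontiguousarray(
        network.lag_kernels[1:].transpose(1, 0, 2).reshape(n, order * n)
    )
    hist = np.zeros(order * n)  # most recent sample first
    y = np.empty((n, total))
    for t in range(total):
        yt = drive[:, t] + gflat @ hist
        m = np.max(np.abs(yt))
        if not np.isfinite(m) or m > overflow_guard:
            raise InstabilityError(
                f"VAR recursion diverged at sample {t} (|y| = {m:.3g})"
            )
        y[:, t] = yt
        hist[n:] = hist[:-n]
        hist[:n] = yt
    return y[:, burn_in:]


# ---------------------------------------------------------------------------
# hemodynamics


@dataclass
class HRFSpec:
    """Parameters of a (possibly perturbed) double-gamma response kernel.

    The canonical kernel is the difference of two gamma densities, peaking
    near 5 s with an undershoot near 15 s.  The randomized kind shifts each
    gamma's onset by up to ``onset_bound`` seconds and scales dispersions and
    amplitudes by log-uniform factors in [1/factor_bound, factor_bound].
    """

    kind: str = "canonical"  # "canonical" | "randomized"
    dt: float = 0.1
    duration: float = 32.0
    onset_bound: float = 5.0
    factor_bound: float = 5.0
    seed: int = 0
    # canonical double-gamma parameters (shape/scale in seconds, ratio unitless)
    peak_shape: float = 6.0
    undershoot_shape: float = 16.0
    scale: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kind not in ("canonical", "randomized"):
            raise ValueError(f"unknown HRF kind {self.kind!r}")
        if self.duration < 30.0:
            raise ValueError("HRF duration must cover >= 30 s")
        if self.factor_bound < 1.0:
            raise ValueError("factor_bound must be >= 1")


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1.0) * np.log(tp) - tp / scale - gammaln(shape) - shape * math.log(scale)
    )
    return out


def make_hrf(spec: HRFSpec) -> np.ndarray:
    """Evaluate the double-gamma hemodynamic kernel on the spec's grid."""
    t = np.arange(0.0, spec.duration, spec.dt)
    if spec.kind == "canonical":
        d1 = d2 = spec.scale
        a1, a2 = 1.0, spec.undershoot_ratio
        o1 = o2 = 0.0
    else:
        rng = np.random.default_rng(spec.seed)
        o1, o2 = rng.uniform(-spec.onset_bound, spec.onset_bound, size=2)
        logb = math.log(spec.factor_bound)
        f = np.exp(rng.uniform(-logb, logb, size=4))
        d1, d2 = spec.scale * f[0], spec.scale * f[1]
        a1, a2 = f[2], spec.undershoot_ratio * f[3]
        if d1 <= 0 or d2 <= 0:  # cannot occur with log-uniform factors; guard anyway
            raise ValueError("nonpositive dispersion after perturbation")
    h = a1 * _gamma_pdf(t - o1, spec.peak_shape, d1) - a2 * _gamma_pdf(
        t - o2, spec.undershoot_shape, d2
    )
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h / peak
    return h


def convolve_hrf(series: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Causal convolution of each node's series with its hemodynamic kernel.

    ``kernels`` is either one kernel (applied to every node) or an
    (n_nodes, L) stack of per-node kernels.  Output is truncated to the
    input length.
    """
    series = np.asarray(series, dtype=float)
    n, T = series.shape
    kernels = np.asarray(kernels, dtype=float)
    if kernels.ndim == 1:
        if len(kernels) > T:
            raise ValueError("kernel longer than the time series")
        out = _signal.fftconvolve(series, kernels[None, :], axes=1)
        return out[:, :T]
    if kernels.shape[0] != n:
        raise ValueError(
            f"got {kernels.shape[0]} kernels for {n} nodes; counts must match"
        )
    if kernels.shape[1] > T:
        raise ValueError("kernel longer than the time series")
    out = np.empty_like(series)
    for i in range(n):
        out[i] = _signal.fftconvolve(series[i], kernels[i])[:T]
    return out


# ---------------------------------------------------------------------------
# observation noise


@dataclass
class NoiseSpec:
    """Observation-noise model: white, AR(1) "temporal", or their mixture.

    ``snr`` is the per-node ratio of signal variance to noise variance.  The
    mixture combines the two sources with weights ``mix_white`` = 0.3 and
    ``mix_temporal`` = 0.7 before the SNR scaling.  ``snr=None`` means
    noiseless observation.
    """

    kind: str = "white"  # "white" | "temporal" | "mixture"
    snr: float | None = 5.0
    ar_coefficient: float = 0.5
    mix_white: float = 0.3
    mix_temporal: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "temporal", "mixture"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in (-1, 1)")


def _ar1(rng: np.random.Generator, shape: tuple[int, int], coeff: float) -> np.ndarray:
    """Unit-variance AR(1) noise rows via lfilter, stationary initial state."""
    n, T = shape
    innov = rng.standard_normal((n, T)) * math.sqrt(1.0 - coeff**2)
    x0 = rng.standard_normal(n)  # stationary start, unit variance
    zi = (coeff * x0)[:, None]
    out, _ = _signal.lfilter([1.0], [1.0, -coeff], innov, axis=1, zi=zi)
    return out


def add_observation_noise(series: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Add observation noise scaled per node to the requested SNR."""
    series = np.asarray(series, dtype=float)
    if spec.snr is None:
        return series.copy()
    n, T = series.shape
    sig_var = series.var(axis=1)
    if np.any(sig_var == 0):
        bad = int(np.argmin(sig_var))
        raise ValueError(f"signal row {bad} has zero variance; SNR undefined")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "white":
        noise = rng.standard_normal((n, T))
    elif spec.kind == "temporal":
        noise = _ar1(rng, (n, T), spec.ar_coefficient)
    else:
        noise = spec.mix_white * rng.standard_normal((n, T)) + spec.mix_temporal * _ar1(
            rng, (n, T), spec.ar_coefficient
        )
    noise_var = noise.var(axis=1)
    scale = np.sqrt(sig_var / (spec.snr * noise_var))
    return series + scale[:, None] * noise


# ---------------------------------------------------------------------------
# downsampling


def downsample(
    series: np.ndarray, factor: int, *, anti_alias: bool = True
) -> np.ndarray:
    """Keep every ``factor``-th sample, low-pass filtering first by default."""
    series = np.asarray(series, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return series.copy()
    if factor >= series.shape[1]:
        raise ValueError("factor must be smaller than the series length")
    if anti_alias:
        return _signal.decimate(series, factor, axis=1, ftype="fir", zero_phase=True)
    return series[:, ::factor].copy()


# ---------------------------------------------------------------------------
# end-to-end convenience


@dataclass
class BenchmarkData:
    """One simulated realization: observed BOLD plus everything upstream."""

    network: GroundTruthNetwork
    observed: np.ndarray  # (n, T) after HRF + noise
    neuronal: np.ndarray  # (n, T) before HRF
    dt: float
    noise: NoiseSpec
    hrf: HRFSpec | None
    seed: int


def simulate_benchmark(
    network: GroundTruthNetwork,
    n_samples: int,
    dt: float = 0.1,
    *,
    noise: NoiseSpec | None = None,
    hrf: HRFSpec | str | None = "canonical",
    noise_stage: str = "pre_hrf",
    drive_kwargs: dict | None = None,
    seed: int = 0,
) -> BenchmarkData:
    """Simulate one BOLD-like realization of the given ground-truth network.

    Pipeline: harmonic-plus-noise intrinsic drive -> VAR recursion ->
    observation noise at the requested SNR -> HRF convolution (the
    convolution is the last step).  With ``noise_stage="pre_hrf"`` (default)
    the noise is added to the neuronal series and passes through the
    hemodynamic kernel with it, so the signal-to-noise variance ratio holds
    at every frequency, not just in total; ``"post_hrf"`` adds noise to the
    convolved series instead (flat noise floor against a low-passed signal).
    Sub-seeds for drive and noise are derived deterministically from
    ``seed``.
    """
    if noise_stage not in ("pre_hrf", "post_hrf"):
        raise ValueError(f"unknown noise_stage {noise_stage!r}")
    ss = np.random.SeedSequence(seed)
    drive_seed, noise_seed = [int(s) for s in ss.generate_state(2) >> np.uint32(1)]
    burn_in = 10 * network.order
    drive = gen_intrinsic_drive(
        network.n_nodes,
        n_samples + burn_in,
        dt,
        seed=drive_seed,
        **(drive_kwargs or {}),
    )
    neuronal = simulate_var(network, drive, n_samples, burn_in=burn_in)
    if noise is None:
        noise = NoiseSpec(kind="white", snr=5.0)
    noise = dataclasses.replace(noise, seed=noise_seed)
    observed = neuronal
    if noise_stage == "pre_hrf":
        observed = add_observation_noise(observed, noise)
    if hrf is not None:
        if isinstance(hrf, str):
            hrf = HRFSpec(kind=hrf, dt=dt)
        observed = convolve_hrf(observed, make_hrf(hrf))
    if noise_stage == "post_hrf":
        observed = add_observation_noise(observed, noise)
    return BenchmarkData(
        network=network,
        observed=observed,
        neuronal=neuronal,
        dt=dt,
        noise=noise,
        hrf=hrf if not isinstance(hrf, str) else None,
        seed=seed,
    )
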