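# Methods

## Model

Node signals are modeled as a stationary multivariate autoregressive (VAR)
process. In discrete time with sampling interval `dt`,

    y(t) = e(t) + Σ_{p=1}^{P} G(p) y(t−p),

where `G(p)_{ij}` is the influence of node *j* on node *i* at lag *p* and
`e(t)` is intrinsic drive, independent across nodes. (The lag-zero kernel is
the identity — the standard VAR normalization; it never enters the
recursion.) Fourier transforming gives `ŷ = ê + Ĝ(f) ŷ` with
`Ĝ(f) = Σ_p G(p) e^{−2πi f p·dt}`, hence the cross-spectral density

    C(f) = (I − Ĝ)⁻¹ X (I − Ĝ*)⁻¹,     X(f) = ⟨ê ê*⟩ diagonal.

Inverting and factoring, `C⁻¹ = B* B` with `B = X^{−1/2}(I − Ĝ)`. Every
`U B` with unitary `U` is an equally valid factor; the estimator resolves
the ambiguity with a sparsity prior, minimizing the off-diagonal L1 norm
`Γ(U B₀) = Σ_{i≠j} |(U B₀)_{ij}|` over the unitary group, starting from the
Hermitian positive-definite square root `B₀ = (C⁻¹)^{1/2}`. The unknown
positive diagonal `X^{1/2}` is removed by normalizing each row of the
optimal `B` by its diagonal entry (after fixing row phases to make the
diagonal real positive), so self-connections are not estimated and the
reported `Ĝ` has an exactly zero diagonal. The signed weight is the real
part of `Ĝ_{ij}`; magnitudes are used for ROC ranking.

Assumptions that matter: stationarity, linear dynamics, *diagonal* drive
spectrum (independent intrinsic noise), and a network sparse enough that the
L1-minimal factor coincides with the generating one. Direction is identified
only through collider structure: an isolated single edge has no collider,
and the L1 minimum may then legitimately select the reversed orientation —
identifiability improves with network size and density of such motifs, which
is why recovery at 100 nodes is far better than at 10–20.

## Estimation pipeline

1. **Welch CSD.** Hann-windowed segments of `nfft` samples, 50% overlap,
   per-segment mean removal, one-sided density normalization (`scipy`
   convention: the diagonal integrates to the windowed variance). DC and
   Nyquist bins are dropped; the entry convention is
   `C_ij = ⟨ŷ_i conj(ŷ_j)⟩`. The helper `choose_nfft` implements the
   rank rule — largest power of two strictly below `T/n`, one power lower
   when the data passed a hemodynamic filter — but `nfft` is ultimately a
   config choice (see *Benchmark* below).
2. **Factorization.** Per frequency, eigendecompose the slice; a ridge of
   `1e−8 · trace/n` is added only if the slice is numerically singular (the
   applied value and condition number are recorded).
3. **Sparse rotation.** Riemannian conjugate gradient on U(n): the Euclidean
   gradient of the smoothed cost `Σ_{i≠j} √(|M_{ij}|² + ε)` is projected to
   the skew-Hermitian tangent space, combined Polak–Ribière (reset on
   non-descent or every n² steps), and the iterate moves along geodesics
   `U ← exp(−μH)U` computed by eigendecomposition of `iH`, with Armijo
   backtracking (c₁ = 1e−4, halving, adaptive initial step). ε is annealed
   geometrically over 3 stages from `1e−4` to `1e−8` relative to the mean
   squared entry of `B₀` — weak enough not to distort basins (a coarser
   anneal demonstrably funnels the optimizer into non-global minima on 2×2
   instances), strong enough to keep the gradient Lipschitz near the kinks.
   Iterates re-unitarize every 100 steps; tolerance `1e−6` on the relative
   cost drop, `max_iter` 2000, and by default 3 starts (identity first, then
   Haar-random). Because the landscape has several basins at small n while a
   descent there costs microseconds, the start count is automatically raised
   to at least 48/n (capped at 24) whenever more than one start is
   requested; `restarts=1` always means exactly the identity start. The
   reported cost is the un-smoothed Γ. Each frequency is processed
   independently.
4. **Inference.** *Null:* each channel's segment order is permuted
   independently; cross-spectra decorrelate while power spectra are
   preserved exactly; the full estimation is rerun per replicate and all
   off-diagonal signed weights pool into a per-frequency empirical null
   whose α/2 and 1−α/2 quantiles give two-sided thresholds (10 replicates ×
   n(n−1) values ≈ 10⁵ at n = 100). Pooling across frequencies is available
   but off by default. *Bootstrap:* segments resampled with replacement,
   identically across channels; per-connection mean ± z·sd Gaussian
   intervals. A connection survives iff it exceeds the null thresholds AND
   (when intervals are computed) its CI excludes zero.

## Synthetic data generator

Emulates resting-state-like BOLD with known directed ground truth:

- **Topology:** directed Erdős–Rényi, each ordered pair connected with
  probability 0.15 (benchmark), signed weights — magnitude uniform on
  [0.5, 1], 50% inhibitory. Nothing in the estimator sees these choices.
- **Lag kernels:** one adjacency shared by all lags, scaled by a decreasing
  logistic `1/(1+exp(s(p−m)))` with midpoint m = 5 lags and steepness
  s = 0.5 by default. With TR = 0.1 s this concentrates interaction delays
  below ~1 s, consistent with neuronal conduction delays of tens to
  hundreds of milliseconds, and keeps the real part of the kernel's
  frequency response positive across the analyzed 0–0.47 Hz band — a longer
  (multi-second) kernel would flip the sign of the band's effective
  coupling between bins and make a single signed ground-truth matrix
  meaningless for scoring.
- **Stability:** the whole kernel stack is rescaled (bracketing + bisection
  on the companion spectral radius; dense eigenvalues for small problems,
  ARPACK for the 5000-dimensional benchmark companion) to a radius of 0.95.
  The factor is recorded; acyclic networks (radius 0) are left unscaled.
- **Drive:** per node, 3 sinusoids with node-specific frequencies uniform in
  0.01–0.5 Hz and random phases, plus unit-variance white noise. The white
  floor keeps the drive spectrum full-rank at every frequency, which the
  estimator's diagonal-X assumption needs; the harmonics supply the
  oscillatory, line-like structure of resting-state signals.
- **Hemodynamics:** canonical double-gamma kernel (gamma shapes 6 and 16,
  unit scale, undershoot ratio 1/6, peak ≈ 5 s, undershoot ≈ 15 s, 32 s
  support, peak-normalized). The randomized variant shifts each gamma's
  onset by up to ±5 s and scales dispersion/amplitude by log-uniform factors
  in [1/5, 5].
- **Observation noise:** white, AR(1) with coefficient 0.5, or the mixture
  0.3·white + 0.7·AR(1), scaled per node so signal-variance/noise-variance
  equals the requested SNR exactly. **Ordering:** by default noise is added
  to the neuronal series and then convolved with the HRF ("pre-HRF"). This
  keeps the variance ratio at every frequency, not just in total — with a
  flat noise floor added after the hemodynamic low-pass, the per-frequency
  SNR above ~0.3 Hz collapses by three orders of magnitude and coupling
  recovery there becomes impossible, contradicting the benchmark behavior
  this generator is built to emulate. A `post_hrf` mode is available.
- **Burn-in** of 10× the VAR order is discarded; an overflow guard names the
  first diverging sample for unstable inputs.

What the generator does **not** emulate: physiological (cardiac/
respiratory) noise, nonlinear neural-mass dynamics, regionally varying HRFs
in the default benchmark, scanner drift, or motion. Passing tests therefore
demonstrate correct recovery under the model's own assumptions — linear
stationary dynamics with independent drive — not robustness to every
violation real recordings exhibit.

## Benchmark

The full study (`csdnet.benchmark`, exercised by `scripts/acceptance.py` and
the acceptance tests): one 100-node network, reused across realizations;
40,000 (or 20,000) samples at TR = 0.1 s; white/AR(1) noise at SNR 5 or 1.
Estimation uses `nfft = 64`, so the three analyzed low-frequency bins sit at
0.156, 0.3125 and 0.469 Hz — spanning the sub-0.5 Hz band — and Welch
averages ~1250 segments. (The literal rank rule would allow `nfft = 128`
here; 64 matches the three-bins-to-~0.45 Hz analysis band the benchmark is
defined on, and both satisfy the rank requirement comfortably.) Scoring is
off-diagonal Pearson correlation between the signed weights and the true
adjacency — zeros included — and ranking AUC on magnitudes. The acceptance
script runs 5 realizations per condition (the paper-scale study used 20)
with 10 shuffled-null replicates each for the consensus analysis; the
optimizer uses the identity start only, which is where the PD-root
initialization puts the descent anyway. One realization (simulate + estimate
3 bins) takes ~20 s on one CPU; the full script ~8–12 minutes.

## Numerical notes and edge cases

- `welch_csd` requires ≥ 2 segments; the shuffled null copies the Welch
  diagonal bit-exactly (same summation order) so the power-spectrum
  preservation is literal, not approximate.
- `initial_factor` rejects non-Hermitian slices (relative asymmetry
  > 1e−8) and singular slices when an explicit ridge of 0 is forced.
- Unitarity and factor conservation (`‖B*B − B₀*B₀‖/‖B₀*B₀‖ < 1e−8`) hold on
  every accepted iterate; the cost trace is non-increasing within and across
  annealing stages (smaller ε lowers the smoothed cost pointwise).
- `fix_phases` is idempotent, modulus-preserving, and leaves rows with an
  exactly zero diagonal untouched (with a warning); `extract_connectivity`
  emits NaN rows when a diagonal entry is nonpositive.
- Consensus keeps ties (`≥ min_fraction`); kept weights are means over the
  inputs where the edge is present.
- Correlation against truth includes zero entries by design; restricting to
  the union support would overstate agreement.

## Known limitations

- The sparsity prior identifies direction only where collider structure
  exists; antiparallel reciprocal pairs and isolated edges remain ambiguous.
- Weights are estimated up to a positive per-row factor; absolute coupling
  strengths are not comparable across rows.
- The bootstrap reruns the full optimization per replicate; at
  `n_boot = 1000` and 100 nodes this is hours of CPU — the default exists
  for fidelity, small `n_boot` for practice.
- Local minima of the L1 cost exist; multiple starts mitigate but do not
  eliminate them (the 2×2 oracle bounds the risk at small n only).
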