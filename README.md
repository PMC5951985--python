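# csdnet

Sparse estimation of directed ("effective") connectivity from the
cross-spectral density of multichannel time series — without relying on
temporal precedence.

## The problem

Correlations between signals (functional connectivity) are symmetric: they
say nothing about the direction of an interaction, and lag-based directed
measures (Granger-type) break down when the signals reach the sensor through
slow, spatially variable filters — the situation in BOLD fMRI, where the
hemodynamic response differs across brain regions. Yet an undirected
covariance structure still constrains the directed network that generated
it, through *collider* structures: a node receiving input from two otherwise
unconnected nodes leaves an asymmetric fingerprint in the correlations.

`csdnet` exploits this. Model the node signals as a stationary multivariate
autoregressive process `y(t) = x(t) + (G * y)(t)` with independent intrinsic
noise `x`. In the frequency domain the inverse cross-spectral density
factorizes as

    C⁻¹(f) = B*(f) B(f),        B(f) = X^{-1/2}(f) (I − Ĝ(f)),

where `Ĝ(f)` is the directed coupling matrix at frequency `f` and `X(f)` is
the (unknown, diagonal) noise spectrum. The factor `B` is only identified up
to a unitary rotation `B → U B`. Assuming the true network is **sparse**
selects a representative: find the unitary `U` minimizing the off-diagonal
L1 norm

    Γ(U B₀) = Σ_{i≠j} |(U B₀)_{ij}|,     B₀ = (C⁻¹)^{1/2}  (Hermitian PD root),

by Riemannian conjugate-gradient descent on the unitary group. Row-
normalizing the optimal `B` by its diagonal removes the unknown noise scale
and yields `Ĝ(f) = I − B/diag(B)`: a signed, directed coupling matrix per
frequency. Significance is assessed with a segment-shuffled null (destroys
cross-spectra, preserves power spectra exactly) and a segment bootstrap.

The package ships the complete synthetic benchmark used to validate the
method — sparse VAR(50) networks with logistic lag decay, harmonic intrinsic
drive, canonical double-gamma HRF, and SNR-calibrated white/AR(1)/mixture
observation noise — plus evaluation utilities (weight correlation, ROC/AUC,
consensus networks, band summaries, coincidence maps).

## Worked example

```python
import numpy as np
import csdnet as cn

# ground truth: 20 nodes, 20% directed connectivity, VAR order 5
net = cn.sample_network(20, 0.2, order=5, seed=42)

# one noisy BOLD-like realization: 20,000 samples at TR = 0.1 s, SNR 5
data = cn.simulate_benchmark(net, 20000, 0.1,
                             noise=cn.NoiseSpec(kind="white", snr=5.0),
                             hrf="canonical", seed=7)

model = cn.SparseConnectivityModel(data.observed, dt=0.1,
                                   nfft=64, max_bins=3, restarts=1)
res = model.fit(n_null=10, seed=0)      # estimation + null thresholds
print(res.score(net.adjacency))
```

prints (columns: frequency in Hz, off-diagonal Pearson correlation with the
true adjacency, ranking AUC, significant edges kept):

```
   frequency_hz  correlation       auc  n_edges_est
0       0.15625     0.469531  0.587625          142
1       0.31250     0.556888  0.679086          159
2       0.46875     0.406501  0.621124          148
```

The correlation is computed over all off-diagonal entries (zeros included),
so ~0.5 at only 20 observed nodes and 35 minutes of data is substantial —
small networks carry little collider information, and recovery climbs with
node count and duration (at 100 nodes / 40,000 samples the same pipeline
reaches r ≈ 0.7 per realization; see the benchmark below). `res.summary()`
gives a per-frequency fit table; `res.to_frame()` a tidy edge list.

A command-line interface mirrors the library:

```sh
csdnet simulate --n-nodes 100 --length 40000 --snr 5 --seed 1 --out-prefix sim
csdnet estimate sim_timeseries.tsv --nfft 64 --max-bins 3 --seed 0 --out-prefix est
csdnet evaluate est_f0.1562Hz.tsv sim_truth.tsv
```

All interchange formats are delimited text; matrices are row = target,
column = source (a connection goes from column to row).

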