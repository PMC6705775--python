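# Methods

## The graph-to-signal transform

For a connected weighted graph with symmetric non-negative weight
matrix `W` (zero diagonal), the combinatorial Laplacian is
`L = Δ − W` with `Δ_ii = Σ_j W_ij`. The resistance distance
`R_ij = L†_ii + L†_jj − 2 L†_ij` (Moore–Penrose pseudoinverse) is the
effective resistance between nodes when each edge is a resistor of
resistance `1/W_ij`. It is a metric, a valid squared-Euclidean distance,
and for binary graphs it is bounded above by the hop-count shortest-path
distance, with equality exactly when a unique path exists (hence on
every tree).

Classical multidimensional scaling turns `R` into node coordinates:
`B = −½ J R J` with `J = I − 11ᵀ/N`. For resistance input this equals
`L†`, which is PSD with rank `N − 1` on a connected graph. The signals
are the columns of `X = P Λ^{1/2}` from `B = P Λ Pᵀ`, eigenvalues in
descending order. Each column is zero-mean (orthogonal to the all-ones
null vector of `L`), columns are mutually orthogonal with squared norms
equal to their eigenvalues.

Because no eigenvalue of a connected graph's `L†` is discarded at the
default relative rank tolerance (1e-9), the transform is lossless:
squared Euclidean distances between rows of `X` reproduce `R` to
machine precision, and `W` is recovered from `R̂` by re-centering,
pseudoinverting, and negating the off-diagonal (entries below a relative
tolerance of 1e-6 are clipped to zero; significantly negative recovered
weights raise an error, since they mean the input was not a resistance
matrix). Disconnected graphs are rejected outright: the pseudoinverse
formula would silently produce finite but meaningless cross-component
values.

For binary graphs an adjacency-derived distance is also provided:
`D` = hop-count shortest-path distance (adjacent pairs at distance 1,
others at their path length), squared entrywise before double
centering as in classical MDS of a plain metric. The hop-count dialect
keeps `D` a finite metric and reproduces the qualitative behaviour
expected of the binary branch (sinusoids for rings, unstructured
signals for random graphs); disconnected binary graphs are rejected.

**Determinism.** Eigenvector signs are fixed by making each column's
largest-magnitude entry positive (ties broken by lowest node index).
Within a degenerate eigenvalue group (equal within the rank tolerance)
eigenvectors are ordered by the index of their largest-magnitude entry.
Downstream spectral features are invariant to rotations inside a
degenerate eigenspace, which the test suite asserts on ring lattices.

**Stress.** The misfit between original and reconstructed distances is
reported as Kruskal stress-1,
`sqrt(Σ_{i<j}(r̂−r)² / Σ_{i<j} r²)`; the raw residual sum of squares is
exposed alongside. At full rank both are machine noise (~1e-15).

## Graph-signal features

Per network, four features:

* **Shannon entropy** (bits) of each signal's value histogram
  (equal-width bins over [min, max], default `⌈√N⌉` bins), averaged
  over all signals.
* **Skewness** `μ₃/σ³` and **kurtosis** `μ₄/σ⁴` of the signal-value
  distribution, averaged over all signals. Moments are computed over
  the empirical distribution (each sample weighted 1/N); a
  histogram-bin-center variant is available as `method="binned"`. The
  empirical form is the fine-bin limit of the binned form and gives the
  exact textbook values on discrete signals (a ±1 two-point signal has
  variance exactly 1).
* **Graph spectral entropy (GSE)**: for each of the `C̃` highest-energy
  signals, the one-sided normalized power spectrum
  `P[k] = |FFT(x)[k]|² / Σ, k = 0…⌊(N−1)/2⌋` has Shannon entropy
  (base 2) normalized by `log2(⌊(N−1)/2⌋)` — the entropy of a spectrum
  flat over the positive-frequency bins. (The DC bin is numerically
  empty because CMDS signals are zero-mean, so ⌊(N−1)/2⌋ is the number
  of informative bins; the value is clamped to [0, 1] to guard the
  degenerate DC-loaded case, which cannot arise from the transform.)
  Each entropy is weighted by the signal's energy-compactness
  `w_i = ‖x_i‖₁/(√N ‖x_i‖₂) ∈ [1/√N, 1]` (1 for a spread,
  constant-magnitude signal; 1/√N for an impulse), normalized as
  `w̃ = w/(√C̃ ‖w‖₂)` so that `Σ w̃² = 1/C̃`, and
  `GSE = Σ_{i≤C̃} w̃_i H_i`.

`C̃` defaults to the smallest count whose cumulative eigenvalue
fraction reaches 0.95 (the usual PCA scree cutoff) and can be
overridden (e.g. a fixed 6 when comparing networks of equal size).

A ring lattice's signals are exact sampled sinusoids, so its spectra
are impulses and GSE ≈ 0; random graphs give broadband signals and GSE
near 1; Watts–Strogatz graphs interpolate monotonically in the rewiring
probability. **Node-order dependence:** the spectra are DFTs of the
signals *in node index order*, so GSE is not invariant to relabeling —
the ring's near-zero entropy exists only under its canonical ordering.
This is intrinsic to the measure and harmless in the intended
application, where the electrode order is identical across all networks
being compared; the eigenvalue spectrum and energy weights are exactly
relabeling-invariant, and for unstructured graphs GSE varies only
within Monte-Carlo noise across relabelings.

### Block-structure readout

For stochastic block models whose nodes are ordered by block, the
leading signals are approximately piecewise constant with plateau
supports equal to block sizes. `segment_plateaus` fits exactly K
contiguous segments by dynamic programming (minimizing within-segment
sum of squares) over the `K − 1` most *spread* signals (highest
`w_i`) among the leading `2K`; the spread criterion excludes
impulse-like signals localized on single low-degree nodes, which can
interleave with the plateau signals when eigenvalues are close. At the
study condition (N = 200, three blocks, within-block attachment 0.3,
between-block 0.05, uniform(0,1] weights) this recovers the exact
partition on 20/20 seeds.

## Time-frequency phase synchrony

FCN edge weights are phase-locking values from a reduced-interference
Rihaczek distribution. Discretization: trials are made analytic
(Hilbert transform); the discrete Rihaczek distribution
`C[n,k] = x[n] X*[k] e^(−j2πnk/N)` is carried to the ambiguity plane by
a 2-D DFT, giving the asymmetric ambiguity
`A[p,m] = Σ_u x[u]x*[u−m] e^(jθ_p u)` (Doppler θ in rad/sample, lag in
samples); the symmetric ambiguity is `A · e^(−jθτ/2)`. The
Choi-Williams kernel `exp(−(θ̂τ̂)²/σ)` is applied with both axes
normalized to [−1, 1] (θ̂ = θ/π, τ̂ = τ/(N/2)) — the common discrete
convention, which keeps σ's meaning independent of the trial length;
with axes in raw units a σ of 0.01 would suppress essentially the whole
ambiguity plane and destroy the phase structure. The Rihaczek kernel
`e^(jθτ/2)` (in raw units — it must exactly cancel the symmetrization
factor) completes the distribution, which is transformed back to the
(time, frequency) plane and truncated to non-negative frequency bins.
Default σ = 0.01 (strong cross-term suppression). Phases below a TFD
magnitude floor of 1e-12 are defined as 0.

Per channel pair, `PLV(t,f) = |K⁻¹ Σ_k e^(jφ_k(t,f))|` over the K
trials' phase differences `φ = arg[C_i C_j*/(|C_i||C_j|)]`; an FCN
weight is the mean PLV over a time window × frequency band (default
25–75 ms, 4–8 Hz). PLV is 1 for identical channels and has the Rayleigh
floor `√π/2 · K^(−1/2)` for independent channels (0.125 at K = 50,
reproduced to within 3% by the calibration run).

**A property worth knowing:** any bilinear time-frequency distribution
is invariant to a constant per-channel phase rotation (it multiplies
both `x(t)` and `X(f)` and cancels in `x(t)X*(f)`), so a fixed phase
offset between two otherwise identical pure tones is invisible to this
measure. Synchrony is detected through the *joint time-frequency
structure*: channels driven by the same underlying oscillation (shared
per-trial frequency and phase trajectory) yield consistent phase
differences across trials, while independent processes yield uniform
ones. The synthetic trial generator is built accordingly: each coupled
group shares one theta oscillator per trial (frequency uniform in the
band, default 4–8 Hz; phase uniform), each channel adds a slow
random-walk phase perturbation (RMS `phase_jitter_sd`, default
0.1 rad — a time-varying jitter the measure does see, and which
decreases within-group PLV monotonically) and white noise
(`noise_sd`, default 0.1 relative to unit oscillator amplitude).
Ungrouped channels get independent oscillators. What this generator
does **not** emulate: 1/f background spectra, evoked transients,
volume conduction, or electrode-specific noise topographies — so
passing calibrations show the estimator is correct, not that real EEG
would behave this cleanly.

## Synthetic networks

Ring lattices (degree k, k/2 neighbours each way), Erdős–Rényi G(n,p),
classic Watts–Strogatz rewiring (each lattice edge's far endpoint
rewired with probability p, rejecting self-loops and duplicates; edge
count conserved; p = 0 reproduces the ring bit-for-bit), and a weighted
stochastic block model (pair (i,j) present with probability
`connect_probs[z_i, z_j]`). Weighted variants draw i.i.d. uniform(0, 1]
weights on existing edges — the one weight law the weighted-SBM
description fixes, adopted everywhere for consistency. Generators are
deterministic in their seed (topology and weight streams are separate
seed children), and can retry with derived seeds until connected
(`require_connected`).

The two-class ensemble stands in for the error-trial vs correct-trial
cohort: "structured" = weighted Watts–Strogatz (k = 6, p = 0.1),
"random" = weighted Erdős–Rényi matched in expected density
(p = k/(n−1)), default 18 networks per class of 58 nodes, all
connected; per-instance seeds provide the weight jitter that makes
instances differ.

## Graph-theoretic baseline metrics

* Clustering `C^w`: mean over nodes of `2t_i/(k_i(k_i−1))` with
  geometric-mean triangle intensity
  `t_i = ½ Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}`, weights rescaled by the
  maximum first (a no-op for PLV weights ≤ 1); degree-<2 nodes
  contribute 0. Reduces to the binary clustering coefficient on 0/1
  graphs (cross-checked against networkx).
* Characteristic path length `L^w` and global efficiency `E^w` from
  Dijkstra shortest paths with edge length `1/w`; path length requires
  connectivity, efficiency counts disconnected pairs as 0.
* Small-world parameter `σ = (C/C_rand)/(L/L_rand)` against the mean of
  `n_reference` (default 20) Erdős–Rényi surrogates with the *same edge
  count* (G(n, m) variant, so the observed weight multiset can be
  shuffled 1:1 onto the surrogate topology); surrogates are redrawn
  until connected. Self-consistency: an ER graph scores σ ≈ 1 in the
  Monte-Carlo mean.
* Small-world propensity `SWP = 1 − sqrt((ΔC² + ΔL²)/2)` with
  `ΔC = (C_lat − C)/(C_lat − C_rand)`,
  `ΔL = (L − L_rand)/(L_lat − L_rand)`, both clamped to [0, 1]. The
  lattice null is a ring lattice matched in node and edge count with
  the strongest observed weights placed on the shortest circular
  distances; the random null is a degree-preserving double-edge-swap
  randomization (10·|E| attempted swaps, weights shuffled onto the
  rewired topology, redrawn until connected), averaged over
  `n_reference` draws. A ring lattice scores `1 − 1/√2 ≈ 0.29`
  (ΔC = 0, ΔL = 1); coincident nulls raise an error.

## Classification harness

Leave-one-out cross-validation at the row (network) level: each row is
predicted by a model trained on the remaining rows, with features
standardized using training-fold statistics only. Classifiers: linear
SVM (C = 1), LDA, logistic regression (scikit-learn defaults), kNN with
k = 20 and uniform votes (k shrinks with a warning when the training
fold is smaller). Decision scores for ROC are the signed distance to
the separating hyperplane (SVM/LDA/logistic) or the positive-class vote
fraction (kNN). The ROC sweeps a grid of 101 score quantiles (plus ±∞);
with `n_thresholds=None` every distinct score is used, making the
trapezoidal AUC exactly the Mann-Whitney U statistic over n₁n₂ (ties
credited ½). The rank-sum comparison uses exact enumeration for
tie-free samples up to n = 25 and the tie-corrected normal
approximation otherwise. Note that LOO with balanced classes is
slightly anti-biased under a permutation null (removing a row makes its
class the training minority), so null accuracies sit a few points below
50%.

## Problem sizes and defaults

Canonical topology experiments use N = 128 (N = 200 for the
three-block SBM), 20 Monte-Carlo seeds for ordering claims, 100 random
connected graphs (N ∈ [5, 60]) for the lossless-transform sweep, and 10
ensemble seeds × 36 networks for the classification experiment — sizes
chosen to make every Monte-Carlo claim decisively significant while a
full verification run completes in minutes on one core. PLV
calibrations use 128-sample trials at 256 Hz with K = 10 (locked) and
K = 50 (independent) trials.

## Known limitations

* GSE (and any spectral feature of the signals) depends on the node
  ordering; compare networks only under a common labeling.
* The resistance-distance branch requires connected graphs; use the
  efficiency metric or the binary adjacency branch for fragmented
  networks.
* The PLV estimator inherits the bilinear-TFD invariances described
  above: constant phase offsets and pure time shifts of an otherwise
  identical signal are invisible; what is measured is trial-to-trial
  consistency of the joint time-frequency phase structure.
* The synthetic generators are idealized (uniform weights, stationary
  oscillators, white noise); conclusions about real EEG require real
  data.
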