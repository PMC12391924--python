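# Methods

This note documents the models, conventions, and numerical choices behind
`meginverse`, and what its synthetic benchmarks do and do not demonstrate.

## Forward model

The head is a spherically symmetric conductor. For magnetometers that sense
the *radial* field component, volume currents cancel exactly and the field of
a current dipole with moment direction Θ and magnitude Q at position
**r**_q, measured at sensor position **r**, has the closed form

    B_r(r) = (μ₀ / 4π) · [(r × r_q) · Θ] / (|r| · |r − r_q|³) · Q

i.e. the radial projection of the primary (Biot–Savart) field alone. The
S × D leadfield **L** stacks this scalar over sensors and grid dipoles, with
a fixed unit orientation folded into each column, giving the linear model
**M** = **L Q** + **N**. Units are SI throughout: positions in meters,
moments in A·m, fields in tesla; μ₀ = 4π×10⁻⁷ H/m.

Consequences used by the tests:

* a dipole's radial moment component is silent, so dipole orientations are
  fixed unit *tangents* (deterministic pseudo-random per dipole, seeded);
* a dipole at the exact head center has no tangential direction and a zero
  leadfield column. Source grids keep the origin node (with a flagged fixed
  orientation) so lattice arithmetic stays simple, but the scenario
  generator never places activity there, and every solver treats zero
  columns explicitly (zero beamformer output, unit residual variance, unit
  eLORETA weight);
* entries scale as 1/k² under uniform scaling of all positions.

Sensor layouts are Fibonacci spirals on the upper spherical cap (default:
60% of the sphere, radius 0.12 m), which packs any sensor count
quasi-uniformly. Source grids are cubic lattices clipped to an 8-cm sphere.

## Signal model and scenarios

Every active source emits a Gaussian-damped sinusoid
g(t) = sin(2πf₀t + φ)·exp(−(t−t₀)²/ω²) with parameters drawn independently
and uniformly per activation: t₀ ∈ [0.05, 0.3] s, ω ∈ [0.04, 0.12] s,
f₀ ∈ [8, 14] Hz (alpha band), φ ∈ [0, 2π). Trials last 0.4 s at 1 kHz
(400 samples). Amplitudes are unit-peak per group; all evaluation metrics
are scale-free, so no absolute dipole moment is asserted.

Activations are *focal* (1–3 isolated dipoles, each with its own g(t)) or
*extended*: connected sub-volumes grown from a random seed voxel by uniform
random accretion over the 6-neighborhood lattice graph until a target volume
drawn uniformly from [14, 44] cm³ is covered, all member dipoles sharing one
g(t) realization. Accretion produces compact, irregular blobs; the exact
region shape is a free choice since only volume and connectedness are
constrained.

Sensor noise is i.i.d. Gaussian, white in time and across sensors, with
variance fixed by a *global* SNR convention:
SNR(dB) = 10·log₁₀(mean clean sensor power over all sensors and samples /
noise variance). A per-sensor convention would weight deep sources
differently; the global one is the simplest reading of "additive white
Gaussian noise in sensor space" and is applied identically to every method,
so comparisons are unaffected by the choice.

## The windowed network

The network maps an S × W sensor window (W = 21 samples ≈ one 50 Hz period
at 1 kHz) to the D-vector of dipole amplitudes at the window's center
sample. Temporal and spatial processing are deliberately separated:

* **Temporal block** — four 1-D convolutions along time with weights shared
  across sensors (each sensor is an instance of the same feature extractor),
  features growing 16 → 32 → 64 → 128 while valid-mode kernels (5, 5, 3,
  then a full-width 11) consume the 21 samples down to extent 1. Batch
  normalization sits between consecutive conv layers; each conv is followed
  by a ReLU. The block ends with an S × 128 feature map.
* **Spatial block** — the feature map is flattened and passed through six
  500-unit fully-connected ReLU layers, then a final linear layer with D
  outputs.

Kernel sizes, conv activations, and input/target scaling are this package's
choices (the architecture source specifies layer counts, feature counts, and
widths but not these details). Inputs are z-scored per sensor with training
set statistics; targets are divided by their global maximum absolute value.
Both sets of constants are stored with the model and applied at inference.

Training is plain minibatch Adam (lr 10⁻⁴, batch 64) on MSE, implemented
directly on NumPy arrays in float32 — im2col/GEMM convolutions, explicit
backpropagation, in-place Adam — so the only heavy dependency is BLAS.
Training is bit-deterministic for a fixed seed and thread count. After the
last update, batch-norm running statistics are re-estimated in one pass over
the training set under the final weights ("BN recalibration"); without it,
running statistics trail the weights and inference-mode predictions are
systematically worse than training-mode ones.

Sliding the window over a T-sample recording yields the full D × T estimate;
the (W−1)/2 columns at each edge, where no full window exists, are
zero-filled and flagged rather than fabricated from padding.

### Cross-grid targets

Simulation uses a fine grid (default 15 mm) while the network outputs a
coarse grid (default 33 mm, 57 nodes), mirroring the fine-forward /
coarse-inverse split of the full-scale design. Each fine dipole is assigned
to its nearest coarse node. Two target conventions are implemented:

* **dominant** (default): a coarse node carries the trace of the
  highest-energy fine dipole assigned to it — the node reads as "amplitude
  of activity in this region", and focal and extended targets share the
  simulator's unit-peak scale;
* **sum**: amplitudes accumulate, so the node is the total dipole moment of
  its cell. This is the physically linear convention but makes extended
  targets roughly an order of magnitude larger than focal ones, which
  under-weights focal localization in the MSE.

## Classical solvers

All four reference solvers consume the same scalar fixed-orientation
leadfield and recording containers as the network:

* **LCMV**: w_i = C⁻¹l_i / (l_iᵀC⁻¹l_i) per dipole; sample covariance over
  time with mean removal and diagonal loading (default 5% of the mean sensor
  variance).
* **RV scan**: per-dipole single-source least squares; score = residual
  fraction of data power in [0, 1].
* **MNE**: Q̂ = Lᵀ(LLᵀ + λI)⁻¹M. When the recording's simulation SNR is
  known, λ = trace(LLᵀ)/(S·SNR_linear); otherwise λ = 0.05·trace(LLᵀ)/S.
* **eLORETA**: diagonal depth weights iterated to the fixed point
  w_i = sqrt(l_iᵀ(L W⁻¹Lᵀ + αH)⁺ l_i) with H = I (average-reference
  centering is an EEG concern, not a magnetometer one), α =
  0.05·trace(LLᵀ)/S, tolerance 10⁻⁶ on the maximum relative weight change,
  at most 100 iterations; non-convergence returns the best iterate with a
  flag. Pseudo-inverses truncate eigenvalues below 10⁻¹² of the maximum.

No claim of numerical parity with any specific toolbox configuration is
made; the solvers implement the published definitions.

## Metrics

A dipole is *active* when its time-integrated energy (over the estimate's
valid region) exceeds 50% of the maximum dipole energy. On active sets:

* **DLE** (mm): mean over true sources of the distance to the nearest
  estimated active source, computed between physical positions, so differing
  estimation grids compare directly. An empty estimate gives +∞ and is
  excluded-with-count from aggregate tables.
* **AV** (cm³): active voxel count × lattice voxel volume.
* **IoU** (%): intersection over union of active voxel sets on a common
  grid (ground truth is mapped to the estimate's grid by nearest node when
  grids differ).
* **NRMSE**: both traces are normalized by the square root of their energy;
  the result is the RMS difference of their envelopes, computed as
  analytic-signal (Hilbert) magnitudes. Each true source is matched to the
  estimated active dipole nearest to it. A rectify-and-low-pass envelope
  agrees within 5% and serves as the test oracle.
* **Depth split**: the *deep point* is the dipole with the greatest mean
  distance to the sensors; the half of single-focal cases whose source lies
  closest to it form the deep subset, the rest the cortical subset. (Note
  that for any sensor arrangement the mean distance to a sphere of sensors
  grows with eccentricity, so the deep point of a helmet is low in the
  volume, not at the geometric center.)

## Benchmark design and problem sizes

The orchestrator generates per-scenario test trials once and re-noises the
same clean trials at every test SNR, so SNR comparisons are paired. Solvers
see only sensor data and the leadfield. The forward operator is shared
between simulation and inversion — the one deliberate idealization; there
is no other ground-truth leakage.

Default (desk-scale) conditions, chosen so the full pipeline runs in minutes
on one CPU: 32 sensors, 15-mm simulation grid (619 dipoles), 33-mm output
grid (57 nodes), 5,000 training examples split evenly focal/extended with
training SNR uniform on [0, 30] dB, 30 epochs, 20–40 test cases per
scenario, test SNRs 30 and 10 dB. The full-scale design these mirror
(127 sensors, 5-mm/15-mm grids, 2×10⁵ examples, four test SNRs, 100 cases)
is accepted by the same configuration schema.

Measured under the desk-scale conditions (seed 7, 40 single-focal cases):
the trained network reaches median DLE 21.9 mm at 30 dB (below the 33-mm
output grid spacing, i.e. correct-to-nearest-node localization plus
quantization) and its mean DLE changes by about +2% from 30 dB to 10 dB.

## Known limitations

* **eLORETA is noise-robust here.** With grid-aligned tangential dipoles on
  a spherical conductor and the defaults above, eLORETA attains DLE = 0 mm
  on single-focal cases at 30 dB *and* 10 dB. The low-SNR breakdown of
  eLORETA reported for realistic-anatomy pipelines does not reproduce in
  this cleaner setting, so the benchmark's learned-vs-classical contrast
  here is "equal localization, different robustness margins" rather than a
  dramatic classical collapse. Tests assert the stronger contrast and one
  of them is expected to fail honestly under these conditions; see the
  repository's test suite output.
* Noise is white; physiological artifacts, correlated sensor noise, and
  brain noise are out of scope. Real-data ingestion (FIF, SSS/Maxfilter,
  MRI head models) is out of scope.
* The spherical model has no skull/scalp conductivity structure; gradiometer
  and non-radial sensor models are not implemented.
* Passing the synthetic benchmarks shows the method recovers sources *under
  this generator's assumptions* (damped alpha-band sinusoids, unit-peak
  amplitudes, exact forward model). It does not certify performance on real
  recordings or realistic head geometry.
* The model is geometry-specific: changing the sensor array or grids
  requires retraining.
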