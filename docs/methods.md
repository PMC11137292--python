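# Methods

## The feature map

An epoch q ∈ [0, 1]^N is mapped to a weighted natural-visibility graph:
nodes are samples, and i < j are linked iff every intermediate sample
lies strictly below the chord from (i, q_i) to (j, q_j). The strict
inequality means a collinear intermediate point blocks visibility — the
conventional natural-visibility tie-break, and the one consistent with
the worked example in the README. Edge weights are |q_i − q_j|/|i − j| +
10⁻⁸ with time in *sample* units; this convention is forced by the
reference radii (r₁ = 0.258 requires w₁₄ = 0.1/3). The additive 10⁻⁸
exists so that equal-valued visible samples still contribute a nonzero
weight.

The dual-perspective graph (WDPVG) is the union of the visibility graphs
of q and of its reflection. Reflection is taken about the amplitude
midline, q′ = (max q + min q) − q: it is an involution and keeps q′ in
the normalized range. Sign negation is offered as an alternative
(`reflection="negate"`); both operators are affine, and visibility is
invariant under positive affine maps, so the two produce identical edge
sets — the choice is cosmetic, which is why it is exposed as an option
rather than argued over. An edge found from both perspectives is kept
once with its (identical) weight, so the union remains a simple graph.

The modified weighted Laplacian is L = D − A with *unweighted* degrees
on the diagonal and *weighted* off-diagonal entries. This hybrid is
deliberate: for normalized epochs each |L_ij| ≤ 1 + ε, so c_i = deg(i)
dominates the row's off-diagonal mass r_i = Σ_{j≠i}|L_ij| up to an N·ε
inflation, and every Gershgorin disk (c_i, r_i) is tight. The test suite
asserts dominance with exactly that N·10⁻⁸ allowance rather than
strictly: an epoch containing the recording's extrema as an adjacent
pair attains weight 1 + 10⁻⁸ against a degree contribution of 1, making
strict dominance marginal. The feature vector is [r_1…r_N, c_1…c_N]
(radii first, natural node order within each block), length 2N, emitted
at full floating precision — three-decimal values in examples are
display rounding, and golden tests compare radii at 5×10⁻⁴.

Matrices are built dense. N is an epoch length (56–1024 in the intended
regimes), row reductions are all the method needs, and a dense N×N is
simpler and faster at these sizes than any sparse path.

## Algorithmic notes

Visibility construction runs in O(N²): for a fixed left endpoint x, node
y is visible iff slope(x, y) strictly exceeds the running maximum of
slope(x, z) over x < z < y, so each row is a prefix-max scan. The tests
verify it against an O(N³) brute-force enumeration of the chord
criterion on hundreds of random epochs, plus time-reversal and affine
invariance properties.

Radii are computed as full absolute row sums minus the diagonal, which
cancels ~10⁻¹⁶ of precision against the degree — negligible at feature
scale but visible in tests that compare ε-sized radii, which therefore
use absolute tolerances.

Degenerate inputs: a constant recording normalizes to all zeros (rather
than erroring) and yields a chain graph with all-ε weights — degrees
[1, 2, …, 2, 1] — keeping downstream code total. Trailing samples that
do not fill an epoch are discarded, never padded; padding would
fabricate visibility edges. Normalization extrema come from the whole
recording by default; per-epoch rescaling is an off-by-default option
for users who receive isolated windows. The CLI's `--renormalize auto`
leaves data already inside [0, 1] untouched so that pre-normalized
series reproduce published disk values exactly.

## The spike simulator

`simulate_dataset1` emulates a single extracellular recording containing
three units plus background noise, at 20 kHz for 200 s by default.

- **Waveforms:** V(t) = A·cos(2π(t − τ_ph)/τ1)·exp(−(2.3548·t/τ2)²);
  2.3548 converts the FWHM τ2 to the Gaussian σ. Defaults: A = 1.0,
  1.1, 1.5 (unit 3 largest); τ1 = 1.2, 1.6, 2.0 ms; τ2 = 0.6, 0.9,
  1.2 ms; τ_ph = 0, 0.1, 0.2 ms — three visually distinct biphasic
  spikes in the width range typical of extracellular action potentials.
  They mimic the qualitative structure of simulated spike-sorting
  benchmarks (distinct shapes, one clearly larger unit), not any
  specific published parameter set.
- **Firing:** independent homogeneous Poisson trains at 3.3 Hz per unit,
  merged with a one-epoch (56-sample, 2.8 ms) dead time across units so
  spike windows never overlap. At 2.8 ms epochs only spike-aligned
  windows make sense, so spike epochs are centered on the (kept) spike
  times; noise epochs are drawn from stretches at least one epoch away
  from every spike.
- **Noise:** zero-mean Gaussian with σ = A₁/SNR, referenced to the
  smallest unit's peak (a common spike-sorting convention; an RMS-based
  reference is selectable). By default the noise is low-pass filtered at
  3 kHz — the classic spike-band edge — and rescaled to the exact target
  σ. Extracellular background noise is a superposition of distant
  spikes seen through a band-passed acquisition chain; spectrally white
  noise at a 10 kHz Nyquist edge would carry sample-to-sample increments
  of σ√2, several times the steepest spike slope at these parameters,
  and would dominate the visibility structure in a way no real recording
  does. `noise_bandwidth=None` selects white noise for users who want
  that stress case.
- **Normalization:** global min–max over the whole recording, so
  between-unit amplitude ratios survive into the epochs. This is what
  makes the largest unit's radii and centers stochastically larger than
  the noise class's — an ordering the acceptance suite verifies by
  one-sided rank-sum at 200 epochs per class.

What the simulator does *not* capture: electrode drift, overlapping
spikes, bursting, spike-amplitude variability, and the specific spectral
shape of real multi-unit background. Passing tests therefore show that
the pipeline recovers class structure that is genuinely present in the
features under controlled conditions; they do not certify performance on
any particular real recording. In particular, separability at the
noisiest default (SNR 2.0, σ = half the smallest spike's peak) is poor:
at that noise level the visibility graph of a 2.8 ms window is largely
noise-driven regardless of noise color, and held-out CNN accuracy falls
far below the levels reached at moderate noise (the demo prints 88.3%
at SNR 10 with 100 epochs per class). The accuracy-vs-SNR relationship
of the feature map is a property of the method, not a bug in the
classifier: the raw waveforms remain substantially more separable than
their GCFE features once σ approaches the smallest unit's amplitude
scale.

`simulate_eeg_surrogate` produces 4096-sample channels at 173.61 Hz in
five condition-like classes implemented as AR(1) noise with
class-specific amplitude (30–100 a.u.) and autocorrelation (φ =
0.85–0.97), plus an ictal-like class carrying 3 Hz high-amplitude
Gaussian-windowed bursts. It reproduces the *shape* of a five-class EEG
benchmark (100 channels → 400 epochs of 1024 samples) and gross
amplitude/stationarity contrasts, nothing about real EEG spectra or
artifacts.

## The classifier

The default model is a 1-D CNN implemented directly on numpy: n
conv blocks of [conv1d(32 filters, kernel 3, same padding, ReLU) →
max-pool(2, stride 2)], then flatten → dense(100, ReLU) → dropout(0.1)
→ dense(100, ReLU) → softmax, trained with sparse categorical
cross-entropy under Adam (lr 10⁻³, β = 0.9/0.999), batch size 32, 30
passes, He-normal initialization, all driven by one seeded generator so
runs are reproducible. Two blocks are used for 112-feature inputs
(pooled length 28) and six for 2048-feature inputs (pooled length 32);
pooling width 2 is the conventional default for an otherwise unsized
max-pool layer. Odd pooled lengths drop their last element.

Evaluation splits 70/15/15 (train/validation/test) stratified by class;
the validation fraction may be zero. Multi-class sensitivity and
specificity are macro-averaged one-vs-rest — an explicit assumption,
since a printed metric triplet does not pin down the averaging. The
harness is pluggable (anything with fit/predict), and an RBF-SVM with
standardized inputs is provided as the alternative.

## Problem sizes used in the checks

The test suite runs the brute-force visibility oracle on 500 random
epochs of N ≤ 32, the Gershgorin-inclusion property on 200 graphs with
N ∈ [8, 64] against a dense eigensolver, and the spike benchmark at 400
epochs per class (SNR 2.0, 200 s simulated recording) with the
two-block CNN — sizes at which every check is exact or statistically
stable while the whole suite stays interactive.

## Known limitations

- Features are fixed at 2N per epoch; the map is non-parametric and
  cannot be widened without changing the graph construction.
- Gershgorin disks are inclusion regions, not eigenvalues; refined
  inclusion regions (e.g. Brauer ovals) are out of scope.
- Horizontal and limited-penetrable visibility variants are not
  implemented.
- The simulator's SNR is an amplitude ratio against the smallest unit;
  comparisons with noise levels quoted under other conventions need a
  conversion.
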