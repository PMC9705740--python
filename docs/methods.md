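# Methods

## The NNLU activation

The package's activation is the Gaussian-density bump

    μ_α(x) = exp(−x² / 4α) / (2√(απ)),   α > 0,

a normal density in `x` with variance `2α`. It is strictly positive, even,
bounded by its peak `1/(2√(απ))`, and integrates to one (verified by
quadrature to 1e−8 in the tests). Its exact derivatives are

    μ′_α(x) = −x · μ_α(x) / (2α)                       (odd)
    μ″_α(x) = (x² − 2α) · μ_α(x) / (4α²)               (even, roots ±√(2α))

Some presentations of the second derivative render the numerator with an
ambiguous sign ("−x² + 2α"); neither sign variant of that form equals the
analytic second derivative of the bump for all `x`, so the package
implements the derivative itself, written above in factored form and
validated against second-order central differences (max relative error
below 1e−4 over [−10, 10]). Backpropagation uses only `μ′`; the second
derivative ships as a diagnostic (curvature, inflection points).

Two descriptive caveats are inherited and intentionally not "fixed": the
function is sometimes described as taking negative values and as
non-saturated, but the bump as defined is strictly positive and decays to
zero for large |x|; the implementation follows the formula literally.
Underflow for |x| ≳ 100√α relies on IEEE gradual underflow to 0.0 — no
clamping, never NaN/Inf.

Default `α = 0.333`, configurable per network. ReLU and the logistic
sigmoid are included as baselines; the activation is a network-wide switch.

### Trainability: the variance-collapse regime

Because μ_α is even and strictly positive, a layer of NNLU units behaves
very differently from ReLU at Xavier initialization. With zero-mean
weights, pre-activations concentrate near 0 — the *flat top* of the bump —
so post-activation outputs are almost constant across samples: the
sample-to-sample signal that survives is second order (∝ x²) and roughly
four orders of magnitude smaller than the constant offset. Max pooling
makes this worse (the window maximum saturates at the peak value), and a
GAP head then produces features of the form "large constant + tiny
signal". Probing those frozen features shows they remain perfectly
linearly separable once standardized — the information is intact, but the
optimization problem is badly conditioned: Adam's second-moment estimate is
dominated by the constant direction, and at conventional learning rates
(1e−3) the signal direction grows too slowly to matter.

Escape is a feedback loop — larger weights spread pre-activations across
the bump, which enlarges the feature variance, which accelerates learning —
and the time to ignition depends strongly on the step size. The desk-scale
training benchmark therefore uses Adam with learning rate 5e−2, at which
ignition occurs within a few dozen epochs for every initialization seed
probed, while the published defaults (Xavier weights, bias 0.1, α = 0.333,
dropout 0.5 available) are left untouched. Inputs in [0, 1] are affinely
centered to [−1, 1] inside `fit`/`predict` — a fixed preprocessing step,
applied identically at train and test time, that keeps first-layer
pre-activations balanced around zero.

## Network architecture

`NetworkSpec` is an ordered stack of layer declarations (conv, maxpool,
norm, dense, gap, dropout, activation, softmax) plus an input shape and a
class count, serializable to YAML. Conventions:

* tensor layout `(N, H, W, C)`, 0-based indices, float64 arithmetic;
* convolution is cross-correlation with `same` (ceil(H/stride)), `valid`,
  or explicit symmetric padding; stride 1 for conv layers, 2 for pools;
* max-pool padding is `same`-style with −∞ fill; ties go to the first
  (row-major) window position;
* LRN is cross-channel: `y_c = x_c / (k0 + a Σ_{|j−c|≤r} x_j²)^b` with
  AlexNet-style defaults (r = 2, k0 = 2, a = 1e−4, b = 0.75), configurable
  on the spec — the published description names the normalization layers
  but not their parameters;
* dropout is inverted (survivors scaled by 1/(1−rate); inference is the
  identity), with masks drawn from counter-based Philox streams keyed by
  (root seed, layer index, *global* sample index) so that re-sharding a
  batch across workers cannot change the effective mask;
* weights are Xavier-uniform (limit √(6/(fan_in+fan_out))), biases
  constant 0.1, seeded;
* GAP contributes no parameters — the classification head's parameter
  count is exactly the dense weights plus biases.

The full published stack (224×224×3; 11×11, 5×5, 3×3, 3×3, 6×6, 6×6 convs;
3×3/2×2 stride-2 pools; two LRN layers; GAP; 4096-unit dense with dropout
0.5; 3-way softmax) ships as `configs/table1.yaml`, and the shape-inference
engine reproduces every unambiguous row of its printed output-size table
(Pool 1 → 112×112×64, Pool 3 → 28×28×4096, Pool 4 → 14×14×4096,
Fc 1 → 4096). Three printed rows are internally inconsistent and are
resolved as follows: the first conv's output is read as 224×224×64 (forced
by the pool below it), the second conv uses stride 1 (matching its own
printed output), and the final dense layer emits the 3 class logits. The
printed table places GAP between the two dense layers, but its own row
arithmetic (a flat 4,096 output directly from a 14×14×4096 map) would
require ~3.3 × 10⁹ parameters and contradicts the stated point of GAP;
this package places GAP directly after the last pool, so the head is
1×1-scale (16.8 M parameters at full width). A uniform "padding of width 1"
is also described for all layers; it cannot reproduce the printed output
sizes (an 11×11 stride-1 conv needs padding 5), so `same` padding is used
throughout. The full-width stack is shape-checked, not trained, in tests;
a `width_divisor` argument scales channel widths down for executable
desk-scale variants, and the test-suite smoke network is a two-block
32×32 GAP net (`tiny_spec`).

## Optimizers

SGD, Adam and AMSGrad with community defaults (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8); Adam is the default rule. AMSGrad keeps the elementwise maximum
of the bias-corrected second moment, making it non-decreasing (asserted in
tests over oscillating gradients). The learning-rate sweep surface defaults
to {1e−4, 2e−4, 5e−4}; note that the literature this package follows uses
α both for the activation scale and for the learning rate — here α always
means the activation scale and `learning_rate` is always spelled out.

## Simulated parallelism

All workers are virtual (a sequential loop); correctness of the
partitioning algebra, not speed, is the contract. Three modes, all
required to match serial execution:

* **data parallel** — shard the batch (near-equal shards, remainder spread
  over the first shards), run forward/backward per shard, combine with
  weights mᵢ/n. Since the loss is a sample mean, the weighted combination
  *is* the full-batch gradient; the tests verify this both on a
  closed-form one-parameter model (exact) and against the serial oracle on
  networks (observed ≲ 1e−15 relative).
* **model parallel** — dense-layer output neurons are partitioned into
  contiguous column blocks; per-block matmuls concatenate to the exact
  unpartitioned product, block weight-gradients concatenate, and input
  gradients sum across blocks.
* **hybrid** — conv/pool/GAP stages run data-parallel over micro-batches
  of `m` samples; their activations accumulate in a buffer consumed by the
  model-parallel dense stages in fc batches of `n_fc` samples. Per-fc-batch
  loss gradients are rescaled by the batch's sample share so all
  contributions sum to the gradient of the global mean loss; backward flows
  through the buffer into the retained conv caches. The (m, n_fc)
  accumulation mechanism is this package's construction — the source
  material names the two batch sizes but never defines how they mesh.

Parameter-server averaging is folded into the aggregation step; there is no
network transport and no process pool — a single sequential loop stands in
for all workers.

## Cost model

Analytic calculators with unit big-O constants and base-2 logarithms
(binary reduction trees); outputs are model units, not seconds:

* rounds `⌈log₂ k⌉`; computation `P/N + ⌈log₂ k⌉ + P log₂(1/ε)`;
* communication cost `L Σᵢ₌₁..ᵣ k/2ⁱ + (kP/B) Σᵢ₌₁..ᵣ 1/2ⁱ`, which
  approaches its envelope `Lk + kP/B` from below as k grows;
* multi-server totals `Nk + Pk` (cost) and `k/N` (time).

The comparison report evaluates a baseline all-to-all scheme
(`P log₂k log₂(1/ε) + P log₂(1/ε)`; `P k log₂(1/ε)`;
`P log₂(1/ε)/log₂ k`, undefined at k = 1 and reported as such). The
proposed computation time beats the baseline whenever
`P log₂k log₂(1/ε) > P/N + ⌈log₂ k⌉`, which holds throughout the tested
grid (P ≥ 10³, ε ≤ 0.01, k ≥ 2) but can fail for very small P with ε near
0.5. One source equation overloads N (processors vs parameter servers) and
defines "N = DK" ambiguously; the module treats k as the single worker
count, N as the single server/processor count, and reports D/k only as a
footnote, never inside a formula.

## Synthetic phantoms

Each phantom is a grayscale slice in [0, 1] on a [−1, 1]² grid: brain disc
(intensity 0.35, radius 0.80), skull ring (0.90, radii 0.80–0.92), plus one
class-specific contrast-enhancing lesion:

* label 0, meningioma-like: one large homogeneous disc (radius 0.19–0.21)
  attached at the inner skull margin — meningiomas are extra-axial, dural,
  homogeneously enhancing;
* label 1, glioma-like: four overlapping lobes (radii 0.11–0.13) at
  mid-radius with a bright rim (0.90) and a darker heterogeneous core
  (0.55 ± sinusoidal texture) — rim-enhancing, irregular, intra-axial;
* label 2, pituitary-like: one small moderate blob (radius 0.055–0.075,
  intensity 0.80) just below the midline center — sellar region.

Classes therefore differ in lesion *size, position and enhancement
pattern*, which makes them separable both pixel-wise (a 5-NN probe on raw
32×32 pixels reaches ≥ 95% held-out accuracy) and through a GAP head
(spatially-averaged features differ across classes). Optional Gaussian
noise is added then clipped to [0, 1]. Generation is a pure function of the
config: per-image seeds are drawn once from the dataset seed, recorded in
the manifest, and reused, so re-runs are byte-identical.

Default class counts are 7,080 : 14,260 : 9,300 (meningioma : glioma :
pituitary — 30,640 slices at scale 1), scaled by a factor with
round-half-up per class; splits are stratified 70/15/15 by
largest-remainder allocation within each class. Augmentation: rotation
about the center (bilinear, zero fill), integer-pixel translation (zero
fill), and brightness/contrast jitter about the image mean (clipped); the
default training angle set is {±10°, ±20°, ±30°}.

What the phantoms do *not* emulate: scanner noise statistics, anatomy,
partial-volume effects, patient variability, or any radiological realism —
passing tests show the pipeline machinery works end-to-end on learnable
data, and say nothing about clinical performance. Real-data headline
accuracies and wall-clock speedups are out of scope by design; an optional
read-only loader for the public figshare brain-tumor HDF5 archive exists
purely as a convenience.

## Training orchestration

`GAPCNN.fit` runs the epoch loop under any parallel mode with a single
integer seed driving weight init, batch order and dropout streams; batch
order and dropout are independent of the mode, so hybrid training
reproduces serial parameters to ~1e−15 relative (asserted to 1e−5 over
3-step training across a (k, m, n_fc) grid). Per-epoch metrics are
evaluated in inference mode; non-finite losses abort with the offending
epoch. History CSVs are byte-identical across re-runs except for the
informational wall-clock column. Checkpoints are a named-array `.npz` plus
a JSON manifest (spec, spec hash, seed, epoch).

Problem sizes in the test-suite and acceptance script: 16×16–32×32
phantoms, a few hundred images, networks of ~10³–10⁴ parameters, 100-epoch
smoke runs — chosen so the full suite completes in well under a minute of
compute per module on a single CPU while still exercising every code path
at float64 precision.

## Known limitations

* No GPU kernels, no autodiff, no batch normalization, no learning-rate
  schedules, no early stopping, no real multi-device placement.
* The NNLU conditioning analysis above means NNLU networks need unusually
  large Adam steps at Xavier init; an activation-aware initialization would
  be the principled fix but is deliberately out of scope.
* `same` conv padding plus `same`-style pool padding is the only
  configuration that reproduces the published output-size table; the
  uniform padding-of-1 description is unreproducible as printed.
* The (m, n_fc) buffer semantics in hybrid mode are this package's own
  construction and other readings of the two batch sizes are possible.
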