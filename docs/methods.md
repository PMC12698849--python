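# Methods

## Protocol model

The simulator implements split federated learning over `k` in-process
clients, one main server and one federation server. The full classifier is
a single CNN stack cut at `cut_index`; the default architecture is

```
Conv(8, 3x3, pad 1) → ReLU → MaxPool(2) → Conv(16, 3x3, pad 1) → ReLU →
MaxPool(2) → [cut] → Flatten → FC(64) → ReLU → FC(n_classes)
```

so the transmitted smashed data is a 16×8×8 spatial activation map for
32×32 inputs. The client part ends at the cut; the server part completes
the network. Some descriptions of this design call the two parts
"architecturally identical"; a single split stack cannot satisfy that
literally, and we implement the split-network reading: composing the two
parts is bit-for-bit the un-split network, which the test suite verifies
against a monolithic oracle (forward ≤ 1e−6; parameter gradients vs.
central finite differences, relative error ≤ 1e−4).

One round: for each client and each batch, client forward → transmit
smashed data (labels ride along in the default wiring) → server forward,
mean cross-entropy, server backward and optimizer step → return ∂L/∂h →
client backward and optimizer step. After each round the federation server
replaces every client part with the n_i-weighted FedAvg mean. The loss is
cross-entropy; some write-ups of this protocol print the per-client updates
as an n_i-weighted sum inside each step, but we update each party
sequentially and let n_i enter only at aggregation, which keeps k = 1
exactly equal to centralized training (an invariant the suite checks to
1e−5 after an epoch; in practice the trajectories are bitwise equal because
the batch schedule, initialization and Adam state are shared).

Where labels live is configurable: the default transmits them with the
smashed data (loss computed server-side); a client-side wiring keeps them
local and returns score gradients instead. Both run the same arithmetic.

## Optimizers

Adam with AMSGrad, lr 1e−3, batch 64 is the default training configuration.
Plain SGD is provided because the protocol's update equations are written
as gradient descent; equation-level tests (e.g. the noisy update rule) use
SGD mode. Optimizer state is positional and parameter arrays are rewritten
in place by aggregation, so momentum statistics survive averaging.

## The attack

Granularity is one sample per observation: batched gradients would sum over
labels and change the inference problem. The observed quantity is the flat
concatenation of all attacked-part parameter gradients (weights before
biases, layer order); the MSE is taken over that full vector, not a single
layer. Ties in the argmin break toward the lowest label index. The clone is
an exact copy of the attacked part by default (`clone="reinit"` gives a
degraded-knowledge adversary for sensitivity analysis). Either side can be
attacked; the default target is the client part, whose per-sample parameter
gradients are exactly what a curious aggregation server receives.

Soundness: with an exact clone and no noise, the candidate gradient at the
true label is computed by the same code path as the observation, so its MSE
is exactly 0.0 and the attack is correct whenever distinct labels give
distinct gradients — on trained models this holds for every sample we have
ever evaluated, hence the 1.0 attack accuracy without a defense.

## Noise defense

`NoiseSpec` = family ∈ {gaussian, laplace, cauchy, exponential}, location
γ (default 0), scale σ > 0, and injection targets ⊆ {parameters,
activations, gradients}. Exponential draws are γ + Exp(mean = σ), making σ
the mean of the shifted draw; this convention is stated explicitly because
"exponential scale" is dialect-prone. All injections are additive and the
record of a noisy transmission satisfies noisy == original + noise exactly.

Parameter restoration: noise on the *parameters* target is applied to the
outbound copies only; each client keeps a pristine copy and restores it
after the exchange, so noise never accumulates in local state and the
training trajectory with parameters-only noise equals the no-noise
trajectory (a tested property). Restoring the *initial* parameters every
iteration would nullify learning and was rejected.

The noisy plain-SGD update rule θ ← θ − η∇L + noise is exposed as
`dp.noisy_update` for SGD mode; the three injection targets are independent
config switches because deployments differ in which they use.

Adversary model: the mechanism (family, γ, σ) is public, so before matching
the attacker subtracts the noise mean where one exists — γ for Gaussian and
Laplace, γ + σ for the one-sided Exponential, and nothing beyond the
location for the mean-free Cauchy. Without this correction the Exponential
bias drags the naive argmin *below* chance, which overstates a weak
mechanism; with it, the family ordering of attack accuracy at matched σ is
Cauchy < Laplace < Gaussian < Exponential, i.e. heavy tails protect best
and bounded one-sided noise worst. Debiasing is a flag (`debias`, default
on).

No (ε, δ) is computed or claimed anywhere: there is no sensitivity bound or
clipping, so the mechanism is calibrated-noise obfuscation, not accounted
differential privacy.

## Synthetic data

The generator emulates the *structure* of a four-class brain-MRI corpus:
grayscale squares with a noisy elliptical "brain" (background 20, tissue
110, pixel noise sd 12 on a 0–255 scale); class 0 has no lesion; classes
1–3 add a bright ellipse whose center region (upper-left / central /
lower-right), radius range and intensity are class-specific, with uniform
positional jitter. Preprocessing resizes and min-max normalizes each image
to [−1, 1] per image (a constant image maps to all zeros — the midpoint —
keeping the map total); per-image rather than per-dataset scaling matches
common image practice and needs no global pass.

What it does *not* emulate: intra-class anatomical variability, scanner
artifacts, class imbalance, or any real lesion morphology. The classes are
deliberately well-separated so a small CNN exceeds 0.90 held-out accuracy
within a few epochs; in our runs it reaches 1.00 in one. Passing tests
therefore demonstrate the *mechanics* — protocol correctness, perfect
gradient-matching leakage, and the response of that leakage to noise — not
clinical-grade classification difficulty. The attack's perfection does not
depend on the data being easy (it is exact-match driven), but absolute
model accuracies on real data will differ.

Partitioning is IID with near-equal shards (sizes differ by ≤ 1);
real-world non-IID skew is out of scope. The train/test split is stratified
with a default test fraction of 0.2.

## Experiment sizes and numerical choices

- Reference run: 200 images/class × 4 classes at 32×32, 2 clients, trained
  until held-out accuracy ≥ 0.90 (≤ 15 epochs), attack on 100 held-out
  samples. This runs in seconds on one CPU.
- Noise sweep: 5 seeds × families × σ ∈ {0.01, 0.1, 1, 10}, 100 attacked
  samples. The default sweep mode trains once per seed and applies fresh
  noise to the recorded clean observations per configuration — identical in
  distribution to recording noisy gradients directly, since the observation
  is the last element of the transmission chain; `mode="retrain"` trains
  per configuration with noise active inside training for studies of the
  utility cost.
- Max-pool ties route gradient to the first maximal element; all arithmetic
  is float64; cross-entropy is computed from shifted logits; Adam uses
  betas (0.9, 0.999), eps 1e−8.
- Seeding: every stochastic component (generator, partition, shuffling,
  noise, attack subset) derives from explicit integer seeds; identical
  seeds give bitwise-identical runs.

## Known limitations

- In-process simulation only: no networking, encryption, asynchrony, or
  client dropout.
- The defense is evaluated against this enumeration attack only; input
  reconstruction and membership inference are out of scope.
- Checkpoints are spec JSON + npz arrays; bit-for-bit reproducibility of
  forwards is platform-dependent in the usual BLAS sense.
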