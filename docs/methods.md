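# Methods

## Problem setting

Antibody language models (AbLMs) are increasingly pre-trained on a mixture of
unpaired sequences (a single heavy or light chain, available in the hundreds
of millions) and natively paired heavy+light sequences (available in the low
millions). Training only on unpaired data misses cross-chain features;
training only on paired data overfits quickly for lack of scale; naive
mixing or a hard pretrain-then-finetune handoff risks catastrophic
forgetting of whichever data type training ends on. This package implements
a curriculum strategy: the probability that a training example is drawn from
the unpaired pool starts high and decays smoothly, so training ends with an
emphasis on paired sequences while both data types remain present
throughout.

## The unpaired-probability curve

The per-step unpaired sampling probability is a sigmoid decay

    P(t) = B - A / (1 + exp(-k (t - shift))),      t = step / total_steps

* `B` — upper bound of the curve (probability, default 0.7),
* `A` — curve height, so P decays from near `B` toward near `B - A`
  (default 0.4, i.e. a 0.7 → 0.3 range),
* `k` — slope of the transition (dimensionless, default 15),
* `shift` — midpoint of the transition (fraction of training).

A quoted range "0.7 to 0.3" refers to the sigmoid's asymptotic bounds; for
moderate `k` the values actually reached at t = 0 and t = 1 are close to but
not exactly the bounds.

`shift` is never set by hand. It is solved so that the discrete mean of
P(t) over steps 0..N-1 equals a target total unpaired fraction (default
0.625, i.e. 62.5% of all training examples drawn from the unpaired pool).
The mean is strictly increasing in `shift`, so the solver is a bisection on
shift ∈ [-1, 2] (wide enough to cover saturated curves), run to a mean
tolerance of 1e-9 with at most 200 iterations. Unattainable targets
(outside [B - A, B], or outside what the bisection interval can reach for
very small k) raise a calibration error naming the attainable interval.
The "total unpaired percentage" is interpreted as the mean over steps of the
per-batch unpaired sampling probability, equivalently the expected fraction
of training examples that are unpaired; the discrete-vs-continuous choice of
the mean matters only at O(1/total_steps).

Five strategies share one interface: `curriculum` (calibrated sigmoid),
`constant` (P ≡ target), `finetuned` (P = 1 for the first
round(target·N) steps, then 0 — unpaired pretraining followed by paired
finetuning), and the degenerate controls `unpaired_only` / `paired_only`.
All three mixed strategies are matched on the same discrete mean, so equal
step budgets consume the same total amount of each data type.

Learning-rate schedules: linear (ramp 0 → peak over the warmup, linear decay
to 0), WSD (constant at peak after warmup, linear decay over the final 20%
of steps by default) and SGDR (cosine annealing with warm restarts, 3 equal
cycles by default). The WSD decay fraction and SGDR cycle count are
explicit config values; the literature does not pin a single convention, so
the defaults are ordinary choices, not claims.

## Batch composition and MLM collation

At step s the number of unpaired examples in a batch of size n is a binomial
draw with probability P(s) — per-slot Bernoulli sampling is unbiased for any
probability, unlike deterministic rounding. Within a pool, indices come
from a per-epoch permutation consumed without replacement and reshuffled on
exhaustion; the reshuffle seed derives deterministically from (base seed,
pool name, epoch), so a run is reproducible across restarts and each pool
element appears exactly once per epoch.

The collator selects eligible positions independently with probability 0.15;
of the selected, 80% become the mask token, 10% a uniformly random residue
token, and 10% keep their id. Two deliberate interpretations:

* Eligibility excludes cls/sep/eos/pad. Evaluation excludes separator
  tokens from all metrics, so training on them would be inconsistent.
* Random replacement draws only from the 20 residue tokens, never from
  special tokens, to avoid teaching the model to emit structural tokens
  mid-sequence. A random draw can coincide with the original residue
  (probability 1/20), so the observed "changed to a non-mask token" rate is
  0.10 · 19/20 = 9.5% of selected positions even though 10% are assigned the
  random-replacement action.

## Tokenization

The vocabulary is the 33-token ESM-2 alphabet. In `sep` mode the base
vocabulary's unused `<null_1>` placeholder is replaced by `<sep>`, keeping
the size at 33 and every other id unchanged; in `cls` mode `<cls>` doubles
as the separator; `none` omits separators. Placement: between the chains of
a paired input, at the end of an unpaired heavy chain, at the beginning of
an unpaired light chain — the separator then always marks the heavy/light
boundary. Inputs are padded to a fixed 320 tokens (the longest paired
sequence plus structural tokens). Region annotations are carried into token
coordinates (0-based half-open, H-/L- prefixed) by shifting for the leading
cls and, for light regions of paired inputs, the heavy chain and separator.

## Synthetic repertoires

The generator stands in for large public repertoire datasets and produces
the structure the framework needs, not biological realism. Chains are
assembled from a built-in germline library (4 V and 2 J segments per chain
type, framework/CDR layout fixed per chain type) around a uniform-random
CDR3 junction of 5-20 residues, emulating the non-templated junction.
Heavy chains span ~112-127 aa, light chains ~101-116 aa, so paired inputs
are roughly twice unpaired length — the length asymmetry that motivates
rotary embeddings. Defaults: a record is naive with probability 0.5
(mutation count 0 on all chains); memory chains draw a per-chain mutation
count from a zero-truncated Poisson with rate 6 (a realistic per-chain
amino-acid replacement load for memory B cells) and mutate that many
positions uniformly, each to one of the 19 other residues. Specificity
pools (HD / Flu / CoV) plant a class-specific CDR3 3-mer and a biased heavy
V-gene choice with probability 0.8 in the antigen-specific classes, giving
classifiers a learnable but synthetic signal.

What the generator does not emulate: germline allele frequencies, SHM
hotspot biology, indels, clonal lineage structure, nucleotide-level
recombination, or real epitope-driven convergence. Tests passing on this
data show the pipeline's statistical machinery is correct; they say nothing
about absolute model quality on real repertoires.

## Encoder

A pre-norm bidirectional transformer encoder written in NumPy with explicit
forward and backward passes: tied input/output embedding over the 33-token
vocabulary, per-layer multi-head self-attention and GELU MLP blocks with
residual connections, final layer norm, and either rotary position
embeddings (queries/keys rotated pairwise with base 10,000 over the full
head dimension) or a learned absolute position table. Optimization is Adam
(β₁ 0.9, β₂ 0.98, ε 1e-8) with decoupled weight decay 0.01 on matrix-shaped
parameters. Parameters are float32 by default; a float64 mode supports the
finite-difference gradient checks in the test suite. Training batches and
evaluation inputs are cropped to the longest real sequence in the batch
(rounded up to a multiple of 8) — padding keys are masked out of attention,
so cropping is exact, and it is what makes CPU runs practical.

The default desk-scale configuration is 2 layers, 4 heads, hidden size 64,
intermediate size 256; the ~55M-parameter pilot shape (5 layers, 20 heads,
960/3840) and larger shapes are expressible through the same config but are
not CPU-practical. The end-to-end demo exercised by the tests trains the
default shape for 2,000 steps at batch size 8 on ~2,000 synthetic chains —
sizes chosen so the whole suite runs in minutes on one core while still
showing clear training progress (CE falling from ~ln 33 ≈ 3.5).

## Evaluation

All metrics average over labeled positions only, so separator/cls/eos/pad
positions can never affect a number. Per-region CE and CDRH3 accuracy mask
one position at a time with the rest of the sequence visible, predict it,
and pool over (sequence, position) pairs; CDRH3 accuracy is micro-averaged
by default (per-sequence macro averaging is an option). An untrained model
scores CE ≈ ln 33 ≈ 3.497, the uniform baseline over the vocabulary.

## Downstream tasks

Pair classification labels each native pair 1 and builds an equal number of
label-0 examples by a seeded derangement of light chains (rejection-sampled
permutation with no fixed points), guaranteeing no accidental native pair
and an exact 50/50 balance. Each example carries a mutation subset —
mutated (both chains ≥ 1 mutation), unmutated (both 0), different
(one of each) — for stratified reporting.

Specificity tasks cluster each class with the greedy identity stand-in
(identity = positional matches over the shorter prefix divided by the longer
length; no alignment — sufficient for dedup semantics at desk scale, not a
CD-HIT replacement), downsample every class to the smallest, and assign
stratified k-fold (default 5) cross-validation folds. The unpaired variant
keeps heavy chains only.

Classifiers are scored per fold with accuracy, F1 (binary, or macro for >2
classes), AUC and AUPR (one-vs-rest macro for >2 classes) and MCC, reported
as mean ± standard error (sample SD across folds / √k). Folds where AUC or
AUPR are undefined (a single class present) are excluded from those two
means only. `finetune_classifier` trains, per fold, a two-layer
(dense → tanh → dense) softmax head with warmup + linear-decay SGD on
mean-pooled final hidden states; the encoder stays frozen. Head-only
probing keeps desk-scale runs in seconds and is the package's default
notion of "finetuning"; it consequently measures representation quality,
not full finetuning ceilings, and uses a correspondingly higher default head
learning rate (5e-2) than whole-model finetuning would.

## Numerical and design notes

* Bisection tolerance 1e-9 on the schedule mean; the curriculum invariant
  tests require calibrated means within 1e-6 of target across 100 random
  attainable configurations.
* Attention masking uses an additive -1e9 key bias; with max-subtraction
  softmax this underflows pad weights to exactly zero, which is why cropping
  and padding-invariance tests hold to float precision.
* The train/eval/test split shuffles with a seeded permutation, rounds the
  train fraction, and halves the holdout (eval gets ⌊holdout/2⌋); a 96%
  train fraction on 10,000 items yields 9,600/200/200.
* Zero-truncated Poisson is parameterized by its untruncated rate λ; the
  realized mean is λ/(1 - e^-λ), indistinguishable from λ at the default
  λ = 6.
* The derangement sampler rejection-samples permutations (acceptance
  probability → 1/e), which is exact and fast for any n ≥ 2.
* Degenerate inputs raise typed errors: empty germline libraries, >320-token
  streams, unattainable calibration targets, empty pools, datasets without
  labels or H-CDR3 annotations, classes smaller than k.

## Known limitations

* The encoder is CPU-sized; nothing here demonstrates large-scale training
  dynamics (loss scaling, overfitting onset, checkpoint selection).
* The greedy identity clustering is order-dependent and alignment-free.
* The synthetic specificity signal is planted, so downstream-task accuracy
  on it has no biological meaning beyond pipeline correctness.
* Only substitution mutations are modeled; region annotations are inherited
  from the generator rather than computed by a numbering scheme.
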