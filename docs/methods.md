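# Methods

## Problem setting

At each order time during an inpatient stay, a TCM physician issues a
prescription: a set of herb (or Western-drug) ingredients. Different
physicians routinely substitute herbs within the same therapeutic class, so
exact ingredient match is the wrong target; the package therefore predicts,
and scores against, the set of *first-category* classes obtained by rolling
each drug up a three-level hierarchy (leaf drug → category-II formula group
→ first category). Western drugs without a hierarchy are parentless leaves
that form singleton categories.

## Featurization

A record's facts are flattened into one chronological token stream.
Demographics are emitted first at t=0 (sex plus decade-binned age,
height/weight bins, BMI class). Each clinical fact contributes up to three
tokens — its name, a name-qualified binned value (`glucose:high`), and its
unit — so numeric measurements enter a finite vocabulary. Value tokens are
name-qualified (rather than bare `high`/`low`) so a bag-of-tokens pooling
cannot confuse which measurement was abnormal. Prescriptions issued
*before* the cutoff appear as `taken:<drug>` tokens; the order being
predicted at the cutoff itself never does (configurable via
`include_prior_orders`). Simultaneous facts are ordered by chart-section
rank then name, which makes truncation at an earlier cutoff a strict prefix
of a later one — the mechanism behind improving performance across order
times.

Quality control discards records that are incomplete (missing demographics
or any admission-time fact), internally inconsistent (same fact key with
two values), nonstandard (tokens outside the `[a-z0-9_:.=+-]` alphabet), or
marked with special circumstances (chemotherapy, post-operation,
fracture-setting removal), each tagged with its reason. The filter is
idempotent.

## Embeddings

Tokens are embedded with skip-gram trained by negative sampling: dynamic
context window, unigram^0.75 noise distribution, linearly decaying learning
rate (start 0.025), 5 negatives. Defaults mirror the standard clinical-corpus
recipe (`min_count=2`, `vector_size=100`, `window=5`, 50 epochs); the
desk-scale presets use `vector_size=32` (the embedding width must equal the
transformer's model width) and 25 epochs. Updates are applied in 64-pair
chunks with summed `np.add.at` scatter — small enough that a token rarely
recurs within a chunk, keeping the procedure in the stable regime of
sequential SGD even on the tiny vocabularies of synthetic cohorts. (Large
chunks diverge at this learning rate; per-occurrence gradient averaging is
also wrong, as it dilutes negative-sample repulsion and collapses the space
onto one direction.)

`vectorize` produces the fixed `max_num_tokens × vector_size` input: rows in
sequence order, zero rows with a false mask for padding *and* for
out-of-vocabulary tokens (the mask disambiguates them from genuine zero
vectors); overflow drops the oldest-timestamp tokens so the most recent
evidence survives. Default cap 759 at full scale, 64 in the desk presets.

## Classifier

Two identical cascaded encoders; each runs multihead self-attention
(4 heads × dimension 8; per-head projections map the model width down to 8,
and the concatenated 32-dim output is projected back up before the residual
add, the standard resolution when heads do not tile the width), then
residual + layer normalisation, a position-wise feedforward, and a second
residual + normalisation. Padded positions are masked out of attention (a
−1e9 score bias) and out of the pooling, so the content of padded rows
provably never reaches the output. Position information is the fixed
sinusoidal code.

The head pools token positions by masked mean (an attention-style readout
against a learned end-of-sequence embedding is available via
`pooling="eos"`), then linear → feedforward → 128-unit hidden layer with
dropout (rate 0.4740 at full scale) and normalisation → sigmoid output per
label. Decoding thresholds the probabilities at 0.5 by default; the
threshold is monotone (lowering it can only grow the set).

Training minimises the label-averaged binary log loss (averaging keeps the
scale independent of the label-space size) with L2 penalty 1.566e-6,
Adam, and global gradient-norm clipping at 0.1245. A previously
reported tuned learning rate of 0.4375 is recorded in the config
(`reference_learning_rate`, opt-in) but is implausibly large for Adam; the default step size is 1e-3 at full scale and 3e-3 in the
desk-scale preset, where smaller batches (32) supply enough optimizer steps
on cohorts of a few hundred patients. "Vector loss rate" 0.4410 is
interpreted as dropout on the input embedding layer, distinct from the
hidden-layer dropout. Grid-search tuning is 10-fold cross-validated with
the per-fold winners averaged (majority vote for categoricals) — an unusual
protocol, but the one this pipeline specifies; with a single grid point it
degenerates to that point.

Averaging same-type, same-timestamp vectors with learned weights would be a
conceivable alternative readout, but it has no well-defined placement in
this architecture and is not implemented; the optional EOS readout is the
nearest well-defined relative.

## GAN augmentation

The generator adds i.i.d. Gaussian noise (σ=0.1) to the real rows of an
embedding matrix and passes it through two width-279 LSTM layers, each with
residual + layer normalisation, bracketed by 100↔279 linear projections;
the output is a residual perturbation of the input (identity-initialised
output projection ⇒ early fakes are small jitters), with padded rows forced
to zero and the mask preserved. The discriminator is an LSTM (width 279)
read at each sample's last real token, a residual+normalisation block at
width 100, a width-256 fully connected layer, and a sigmoid.

Training alternates: the discriminator learns on balanced 2×batch batches
(originals vs fresh fakes) until its binary cross-entropy plateaus
(relative tolerance 1e-3 over 5 evaluations), then the generator trains
against the frozen discriminator (non-saturating objective) until the
discriminator's loss on fakes stops increasing; the pair of phases is one
epoch. The run stops when the discriminator's balanced accuracy stays in
[0.45, 0.55] for 5 consecutive epochs, or at the epoch cap — in which case
the most recent state observed *inside* that band is restored, because the
alternation keeps oscillating through equilibrium and a hard cap would
otherwise strand the model at an arbitrary phase of the oscillation.
Augmentation then emits exactly one generated sample per original, with the
original's label vector attached unchanged (the only labelling under which
the doubled set is usable for supervised training), and the originals pass
through untouched.

Generator conditioning on the label is reserved (`conditional` flag,
default off). The width-560 token cap mentioned alongside the GAN at full
scale is treated as an illustrative alternative to 759, not a second
pipeline constant; both are reachable through `max_num_tokens`.

## Synthetic cohorts

The generator emulates the statistical structure the model assumes, not any
real pharmacopeia. Each patient draws 1–3 latent syndromes. A syndrome owns
`symptoms_per_syndrome` symptom tokens and targets a distinct primary
first-category plus two secondaries (injective map ⇒ the planted rule is
identifiable). Reference orders at admission/24 h/48 h/72 h/1 week pick,
per target category, one uniformly random leaf of that category — so two
orders for the same patient can differ in every leaf yet agree after
rollup. Background vitals/labs arrive as a Poisson stream (default 1
fact/day, chosen so a week-long desk-scale stay lands near the 64-token cap,
mirroring real charts where the cap is set near the upper percentile of
week-long token counts) with values binned into low/normal/high.

Noise controls: `label_noise` swaps a target category per order;
`symptom_noise` injects other syndromes' symptoms; `qc_corrupt_frac` plants
one of the four QC defect kinds per flagged record. Evidence timing:
`admission_symptom_frac` fixes how much symptom evidence exists at t=0;
`shared_symptom_frac` draws part of each syndrome's symptoms from a common
pool of nonspecific complaints which surface *first*, so admission evidence
is ambiguous and discriminative findings accrue; `symptom_time_dist=
"per_interval"` spreads the post-admission symptoms evenly across the
intervals between order reviews. The noiseless default cohort is perfectly
learnable in principle: the Bayes-optimal category set given the symptoms
equals the planted rule.

What the generator does **not** emulate: free-text narratives, real symptom
co-occurrence statistics, class imbalance of real formularies (frequencies
are uniform by default; a Zipf option exists), comorbidity structure, or
dosage. Passing recovery/ablation/timeline experiments therefore shows the
pipeline is correct and well-behaved under its own assumptions — not that
it attains any particular accuracy on hospital data.

## Reference experiments and problem sizes

All sizes are chosen to run on one CPU in minutes:

* **Recovery** — 500 noiseless patients, 10 categories × 5 leaves, reduced
  dims (model 32, FFN 128, cap 64), admission slice only; held-out
  precision/recall should exceed 0.9 (observed ≈ 1.0).
* **Timeline** — 300 patients, 8 symptoms/syndrome with 5 from the shared
  pool, a quarter present at admission, remainder per-interval, prior
  orders excluded from inputs; held-out precision/recall should be
  non-decreasing across the five slices.
* **Ablation** — 150 patients, `label_noise=0.2`, `symptom_noise=0.2`,
  cap 48; mean held-out precision/recall over 5 seeds, GAN-doubled vs
  plain.
* **Equilibrium** — 256 i.i.d. Gaussian toy embeddings (8×4); the
  discriminator's held-out balanced accuracy should sit near 0.5.

## Numerical choices

Float64 throughout. Sigmoid/BCE computed in the stable softplus form;
output probabilities clipped to (1e-12, 1−1e-12) to honour the open-interval
contract under saturation. Zero-denominator convention: precision 1.0 when
nothing is predicted, recall 1.0 when nothing is referenced (empty-vs-empty
is perfect, not an error). Aggregation is micro (counts summed over
patients before the ratio); macro is a flag. Ties at identical timestamps
break by chart-section order then token name. Divergent training (non-finite
loss) aborts with a diagnostic rather than returning a model. Every
stochastic stage takes its own seed derived from one pipeline seed;
single-threaded NumPy makes runs bit-reproducible.

## Known limitations

The autodiff engine is eager and Python-looped over LSTM timesteps, so
full-scale dimensions (759×100 inputs, width-2048 FFN, 819 labels) train
slowly on CPU — the architecture supports them, the presets do not exercise
them. Skip-gram uses negative sampling rather than hierarchical softmax.
Dosage and decoction instructions are out of scope, as is the upstream NLP
that would produce structured facts from raw Chinese narratives.
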