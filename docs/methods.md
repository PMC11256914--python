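# Methods

This note records the models implemented in `phylaugment`, the choices
made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Data model

An OTU table is a samples × OTUs matrix of non-negative abundances,
either integer counts or relative abundances (rows on the probability
simplex, validated to 1e-6). All generative and predictive stages
operate on relative abundances; Chao1 richness alone requires counts
(`counts_from_relative` scales by a nominal depth, default 10 000, and
rounds). Zeros are kept exact everywhere — per-sample sparsity (the
zero fraction) is a first-class evaluation quantity, so no pseudocounts
are introduced at any stage. OTUs that are zero in every sample are
removed before modelling.

## Synthetic cohorts

`synth_data.simulate_dataset` draws case/control cohorts from a
zero-inflated log-normal model with phylum-block correlation:

1. per-OTU log-means ~ Normal(0, `dispersion`), default dispersion 2.0 —
   heavy-tailed mean profiles, abundance variance large relative to the
   mean, as in real genus tables;
2. per-sample latent vectors from a multivariate normal with unit
   marginal variance and correlation exactly `block_correlation`
   (default 0.5) within a phylum block, 0 across blocks, via the
   one-shared-factor construction;
3. softmax-style closure: exponentiate and renormalise each row;
4. planted effect: in cases, `n_differential` OTUs (default 10) are
   multiplied by `2**effect_log2fc` (default 1) before renormalising;
5. value-independent Bernoulli zero-masking with probability
   `target_sparsity` (default 0.75) per entry, then renormalisation of
   the survivors. The expected zero fraction equals the target exactly;
   rows that would become all-zero keep their largest entry.

Defaults emulate a 120-genus cohort over the three dominant phyla
(Firmicutes 50, Proteobacteria 40, Actinobacteria 30). The zero mask
being independent of abundance means presence/absence carries no class
signal in simulated cohorts; all planted signal lives in the nonzero
magnitudes. Real data differ in several respects the simulator does not
model — taxon-specific detection limits (zeros correlated with low
abundance), overdispersed sequencing noise, nonlinear taxon–taxon
interactions, and batch effects — so passing benchmarks here shows the
machinery works under the stated statistical structure, not that any
real cohort will behave identically.

## Conditional GAN

Generator and discriminator are MLPs (generator noise 64 + one-hot →
128 → 256 → features; discriminator features + one-hot → 256 → 128 → 1,
LeakyReLU 0.2, sigmoid head), trained with SGD at the reference
protocol defaults: 400 epochs, batch 5, learning rate 1e-3,
one discriminator step per generator step. The generator objective is
the non-saturating form −E[log D(G(z))] by default (the saturating form
E[log(1 − D(G(z)))] is available behind `saturating_g_loss`); the
saturating form's early-training gradients vanish, which at these data
sizes prevented training entirely.

Four numerical choices matter at n ≈ 100–400, and all are
config-exposed:

* **Discriminator input transform.** Relative abundances average
  1/n_otus, so the discriminator's inputs are nearly zero and SGD
  barely moves it (it stayed at chance in ablations). It therefore sees
  sqrt-transformed abundances — the standard variance stabiliser for
  proportions. The generator's gradient chains through the transform.
* **Class-conditional output bias.** The generator's softmax logits
  receive an additive per-class bias, initialised to the log of the
  per-class mean training composition and trained further. At
  initialisation the generated class contrast equals the empirical one;
  without this, the conditioning path never learned the case/control
  difference from small cohorts.
* **Calibrated sparsifier.** A softmax never emits exact zeros, so
  sampling applies a zeroing step calibrated to the training table's
  observed zero fraction. The default mode ("quantile") zeroes the
  generated values below the quantile matching that fraction — the
  zero pattern then follows the generator's learned magnitude ordering,
  and the post-mask diversity distribution tracks the raw output
  closely, which is what lets checkpoint selection find a
  Shannon-matched state reliably. The alternative "bernoulli" mode
  zeroes entries with a value-independent mask (the mechanism the
  simulator itself uses); it avoids tying presence/absence to
  magnitude, but the double masking (learned near-zeros plus a random
  mask) distorts the diversity distribution enough that some training
  runs never pass through a matching state. A fixed numeric threshold
  is also available.
* **Checkpoint selection.** Adversarial SGD oscillates and can collapse
  (in ablations roughly nine of ten runs ended in a low-diversity
  state). Every 2 epochs the trainer scores the current generator on a
  fixed evaluation batch — |rank-sum z| between generated and training
  per-sample Shannon indices, plus a small multiple (0.5 by default) of
  the relative L2 mismatch of the case-minus-control mean sqrt-profiles
  — and the best-scoring checkpoint is returned. This is the tabular analogue of FID-based
  generator selection; the score uses training data only.
  `checkpoint_every = 0` disables it.

## Common-subspace autoencoder

Encoder `features → 2·latent → latent` (tanh, linear head) and decoder
`latent → 2·latent → features` (tanh, softmax head — reconstructions
stay compositional), latent 32 by default. Each real sample is paired
with a GAN-generated sample of the same class — nearest Euclidean
neighbour by default, ties to the lower generated index; seeded random
pairing available — and training minimises the squared distance between
the decoded real sample and its generated target. With generated ≡
real and the identity pairing this is exactly a standard autoencoder (a
tested equivalence). Encoder inputs are scaled by n_otus so tanh units
operate at O(1); the decoder's output bias starts at the mean target
composition. Only real samples are encoder inputs during training;
generated samples are encoded post hoc.

## Phylum-stratified CNN ensemble

OTU indices are grouped by phylum; the `top_k` (default 3) largest
phyla become clusters and the remainder is dropped with a warning or
kept as an "Other" cluster (`keep_other`). Within each cluster the
Spearman matrix is computed (average ranks for ties; constant columns
get correlation 0 by convention so the geometric mean annihilates
uninformative OTUs rather than erroring), each OTU receives the
geometric mean of its absolute correlations (self term included), and
columns are sorted by decreasing coefficient with a stable tie rule.
Each cluster feeds a 1-D CNN — 32 filters, kernel 5, stride 1, ReLU,
max-pool 2, flatten; clusters narrower than the kernel fall back to a
dense layer with a warning — and the flattened maps are concatenated
into a single fully connected softmax head. Training is SGD (batch 5,
lr 1e-3) on class-weighted cross-entropy with weights inversely
proportional to class frequency, normalised to w0 + w1 = 2. By default
inputs are standardised per feature using training-set statistics
stored on the model — raw relative abundances have tiny magnitudes
that leave the conv filters nearly untrained at these step counts;
`standardize=False` recovers the raw-input recipe. The decision
threshold for sensitivity/specificity/PPV/NPV is 0.5 (configurable).

Integrated-gradients attributions use a midpoint Riemann sum along the
straight path from an all-zeros baseline; because IG is invariant to
affine reparametrisation, attributions are computed in the standardised
coordinates the network sees and mapped back to input order.

When the subspace autoencoder is active, the default pipeline trains
one autoencoder per phylum cluster on the cluster's subcomposition
(columns renormalised to sum 1; all-zero rows fall back to uniform) and
the correlation ordering is then applied to each cluster's latent
block with the same Spearman machinery. The `feature_space: otu`
setting skips the autoencoder and runs the ensemble on raw OTU columns;
both modes are first-class.

## Evaluation harness

AUC uses the rank (Mann–Whitney) formula with average-rank tie
correction; it is tested against exhaustive pair counting. The
Wilcoxon comparison of real vs generated summaries is the two-sided
rank-sum test (exact for small untied samples, tie-corrected normal
approximation otherwise). Cross-validation is repeated stratified
k-fold (default 10 × 10 → 100 AUC values) with the 95 % CI taken as
the empirical 2.5/97.5 percentiles under the linear-interpolation
definition; point metrics come from pooled out-of-fold predictions of
the first repeat. Any augmentation callable runs inside each training
fold only, so generated samples never reach validation folds
(generation before splitting is deliberately not the default).

## Benchmark protocols and problem sizes

All benchmarks live in `phylaugment.benchmarks`, are fully seeded, and
use desk-scale sizes chosen once:

* **Realism / common subspace** — one cohort of n = 200, 120 OTUs,
  sparsity 0.75; GAN at the full 400-epoch protocol; 200 generated
  samples compared on sparsity and Shannon diversity; a
  logistic-regression probe (70/30 split) measures real-vs-generated
  separability on raw vs latent (AE, latent 32, 200 epochs) features.
* **Augmentation benefit** — n = 100 cohort with a strong planted
  effect (effect_log2fc = 2, the regime where a cohort of this size
  carries learnable signal); three 70/30 splits per seed; per split the
  GAN (200 epochs) trains on the 70 real samples and emits 600 + 600;
  the ensemble trains 200 epochs on the original arm and 60 epochs on
  the ~18×-larger augmented arm (several times more SGD steps, the same
  asymmetry an equal-epoch protocol produces); per-seed AUC is the mean
  over splits.
* **Label-permutation null** — the n = 200 cohort with shuffled labels,
  5-fold CV of the ensemble (100 epochs).
* **Transfer** — one simulated population (n = 440, strong effect)
  split into disjoint siblings: n = 400 trains the GAN (150 epochs),
  n = 40 is the target cohort; 300 + 300 transferred samples join each
  of 3 CV training folds only. Transfer to a cohort with a different
  OTU set is refused with a diagnostic listing the symmetric
  difference, since a frozen generator is only meaningful when both
  cohorts come from the same processing pipeline.

## Known limitations

Adversarial training at these sizes depends on the stabilisers above;
with `checkpoint_every = 0` expect frequent collapse.

The GAN's conditional fidelity is bounded by the empirical class
contrast of its (small) training cohort: a generator fit on the
training split cannot add information beyond what that split contains.
Consequently, on the simulated benchmarks, *same-cohort* augmentation
(GAN trained on the 70-sample training split of the same cohort it
augments) does not improve a converged classifier under leakage-free
evaluation — the augmented arm trails the original by a few hundredths
of AUC in most seeds, with the generator's estimation error outweighing
any regularisation benefit. The *transfer* setting behaves very
differently: a generator trained on a large sibling cohort injects
genuine extra information into a tiny cohort's training folds and
improves its CV AUC by wide margins in every seed tested. The package
keeps both benchmarks so the boundary of the mechanism is measured, not
assumed; evaluation always keeps generated samples out of validation
folds, and the laxer generate-before-split protocol is deliberately not
used anywhere.

Model files are version-tagged `.npz` archives with feature checksums;
loading refuses mismatched versions, types or feature sets. The CLI is
a thin layer over the library; exit code 2 marks validation errors and
3 a failed pipeline stage.
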