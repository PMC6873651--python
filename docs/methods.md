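# Methods

## Problem and model

A selective sweep — the rapid rise of a beneficial allele — drags linked
variation to high frequency, so a population sample near the selected site
contains one common extended haplotype surrounded by rarer ones, and
reduced local diversity. sweepnet frames the detection and quantification
of this signature as image classification: a sample of n haplotypes over
the segregating sites of a genomic window is a binary matrix (rows =
haplotypes, columns = sites), which a convolutional neural network (CNN)
classifies as neutral vs swept, or into K discretized classes of the
selection coefficient S (in 2·Ne units). Because the softmax output is a
probability vector over classes, the multiclass route yields a posterior
distribution for S from which point estimates, credible intervals and a
Bayes factor for selection follow.

Training data comes from coalescent simulations. The package builds
msms-dialect command lines for a user-specified parameterization and
parses the resulting ms-format text; it does not run the simulator itself.
The default parameterization describes an 80 kb window in a sample of 128
chromosomes from a human-like population: mutation rate 1.5e-8 and
recombination rate 1.0e-8 per base per generation, reference Ne = 10,000,
hence θ = 4·Ne·μ·L = 48 and ρ = 32; a beneficial allele arising from a 1%
starting frequency 15,000 years before present (600 generations at the
configurable 25 years/generation, i.e. 0.015 units of 4·Ne generations);
semidominant selection encoded as msms homozygote/heterozygote
coefficients (S, S/2). The exact msms flags for onset conditioning follow
the msms documentation conventions; the shipped 3-epoch demography
(bottleneck at 2,000 generations to 0.2·Ne, recovery at 3,500) is an
illustrative placeholder, not an estimate for any real population —
supply your own epochs for real analyses.

## Image processing

Alignments become fixed-size images through four steps, always in this
order: polarize → MAF filter → sort → resize.

- **Polarization** (major/minor): per column, the commoner allele becomes
  0 and the rarer 1, for data whose ancestral state is unknown. Exact
  50/50 ties are left unflipped — deterministic and order-independent.
- **MAF filter**: columns with minor-allele frequency strictly below the
  threshold (default 0.01) are removed; a frequency exactly at the
  threshold is kept. At n = 128 this removes singletons (1/128 ≈ 0.0078)
  and keeps doubletons (0.0156).
- **Sorting**: rows (and/or columns) are grouped by identical pattern and
  groups ordered by decreasing multiplicity, ties broken lexicographically
  descending on the pattern so the sort is a pure function. Each
  single-axis sort is idempotent. The combined "rows then columns" sort is
  deterministic and content-preserving but not strictly idempotent: the
  column permutation can change lexicographic tie-breaks among
  equal-multiplicity row groups on a second application. An alternative
  criterion (count of 1-alleles) is available by configuration; the
  pattern-multiplicity criterion is the default.
- **Resize**: nearest-neighbour index mapping (output pixel centre i maps
  to source index ⌊(i+0.5)·src/dst⌋), which preserves binary values, is
  the identity at native resolution, and maps constants to constants.
  Bilinear interpolation (scikit-image) is available when non-binary
  output is acceptable. The target width may also be set to the rounded
  mean post-filter column count of the training set.

Replicates emptied by the filter are dropped and counted. Batches persist
to HDF5 (float32 pixels, integer labels, full configuration and seed as
attributes) and reload bit-exactly.

## Labels

The S range [0, 400] is divided into K = 11 linearly spaced classes whose
midpoints include both bounds (0, 40, …, 400), so neutrality is its own
class. A value maps to the nearest midpoint; half-way ties go to the
lower class. Targets for training are one of:

- **categorical** — one-hot;
- **Gaussian** — weights exp(−(k−c)²/(2σ²)) at the integer class indices,
  renormalized (σ default 0.5 class widths; at c = 5 the centre carries
  ≈ 0.7866 and each neighbour ≈ 0.1065). Density-at-index rather than
  bin-integral: the two differ negligibly at this σ;
- **perturbed categorical** — the true class shifted uniformly over the
  *valid* subset of {−1, 0, +1} (invalid shifts are excluded from the
  draw, not clamped, so boundary classes gain no extra mass), then
  one-hot encoded. Perturbation happens once per dataset; per-epoch
  re-perturbation amounts to refitting with freshly drawn targets.

Datasets are shuffled and split test-first (default 10% of the whole),
then validation (10% of the remainder): 1000 examples give 100/90/810.
Split indices and the seed are persisted so any split is reconstructible.

## Network and training

Architectures follow a fixed family: two-dimensional convolutions with
stride 1 and no zero-padding, each followed by 2×2 max pooling and ReLU;
then an optional 64-unit dense ReLU layer; then a softmax over classes.
Default filter counts (32, 32, 32) with 3×3 kernels; (32, 64, 64) and
(32, 64, 128), and 5×5 kernels, are supported variants. At 128×128 input
the feature maps run 126→63→61→30→28→14, flattening to 6,272 features.
For double-sorted images the dense layer is omitted by default in the
experiment drivers, since the sorted layout preserves the spatial feature
arrangement.

The loss is cross-entropy against the (possibly soft) target
distribution, with predictions clipped at 1e-7 before the log. The
optimizer is Adam at learning rate 1e-3 (configurable) with mini-batches
of 32. Two schedules exist: standard multi-epoch passes over a fixed set,
and a one-pass mode that partitions the set into chunks each visited
exactly once — the reproducible surrogate for simulation-on-the-fly
training. Training aborts with a diagnostic on non-finite loss.

The layers are implemented directly on NumPy arrays (im2col matrix
products for the convolutions, index-scatter for their gradients), so
runs are single-threaded-deterministic for a fixed seed: weight
initialization (He normal) and batch shuffling flow from one seeded
generator, and repeated runs reproduce the final loss to float tolerance.
Checkpoints are .npz archives holding every weight plus the constructor
parameters; training histories export to CSV with a JSON sidecar
recording spec, seed and schedule.

## Posterior summaries

With midpoints m_k and class probabilities p_k: the MAP estimate is the
midpoint of the argmax class (ties → lower); the posterior mean is
Σ p_k·m_k. The highest-posterior-density interval at level 1−α (default
α = 0.05) is computed by Monte Carlo: 100,000 midpoints are drawn with
replacement from p, classes are added in decreasing empirical-frequency
order until their cumulative mass reaches 1−α, and the interval is the
(min, max) midpoint of that set. An exact greedy computation on p itself
serves as the cross-check; the two agree except when the cumulative mass
crosses 1−α within Monte-Carlo error of the threshold. The Bayes factor
for selection versus neutrality is the posterior-to-prior odds ratio
[(1−p₀)/p₀] / [(1−π₀)/π₀] with class 0 neutral; the training prior is
uniform over classes by default (matching a uniform simulation prior
over S) but is an explicit argument. p₀ is floored at 1e-12 and the
summary flags the BF as a lower bound when the floor binds.

## Synthetic fixtures

The fixture generator emulates the image-level sweep signature without an
external simulator. Neutral columns draw a derived-allele count i from
the standard neutral site-frequency spectrum, P(i) ∝ 1/i on {1, …, n−1},
with carriers placed uniformly — so every column segregates by
construction and no rejection loop is needed. A sweep of intensity s
plants a core (central fraction of columns, default 0.3) where a fixed
set of round(s·n) rows — capped at n−1 so columns stay segregating —
shares one identical haplotype pattern, drawn as a fair coin per core
column; the remaining rows carry neutral draws. The shared pattern mixes
both alleles deliberately: a swept haplotype carries ancestral as well as
derived alleles, and an all-derived core would fold under major/minor
polarization into near-empty rows that mimic neutral backgrounds,
weakening the signature exactly where it should be strongest. Positions
are sorted uniforms on [0, 1].

The experiment drivers use a footprint spanning the whole window
(core_width = 1): a strong sweep in the recent past — the regime of
interest here — leaves carrier haplotypes identical over a region the
size of the analysis window, and it is precisely this whole-row identity
that frequency-of-occurrence row sorting exposes as a solid block at the
top of the image. With a partial footprint the carriers differ in the
flanking columns, every whole-row pattern is unique, and row sorting has
nothing to group; the generator keeps core_width as a free parameter for
such partial-footprint scenarios. Intensity is then the frequency the
swept haplotype has reached, which grows with the selection coefficient.

What the fixtures do emulate: a large identical-haplotype block whose
size grows with intensity, reduced heterozygosity in the swept region,
and an excess of intermediate-frequency alleles — the features the CNN
exploits in real sweeps. What they do not: linkage disequilibrium decay
with distance, recombination breakpoints, realistic coalescent
correlation structure among neutral columns, or any demography. Passing
end-to-end tests on fixtures therefore demonstrates that the pipeline
learns and ranks the planted signature correctly, not that the trained
weights transfer to coalescent or real data — for that, train on
simulator output via the `simulate → images → train` stages.

## Experiment scale and defaults

The canned experiments train on 1,000 images per class of 64 haplotypes ×
96 sites, resized to 64×64, with a (32, 32, 32)/3×3 network, chosen so a
full detection experiment runs in a couple of minutes on one CPU core.
Six epochs at learning rate 1e-3 give stable held-out accuracy. On
sorted images the detection contrast is essentially saturated at every
tested intensity — the planted block is unambiguous once rows are
grouped — while unsorted images at low intensity are not, which is what
makes the comparison across sorting configurations informative at this
scale.

## Known limitations

- The CNN runs on a single CPU thread; it is sized for desk-scale
  experiments, not the multi-million-simulation training regimes of
  production analyses.
- Strict reproducibility is per-platform: BLAS reduction order may differ
  across builds, so cross-machine bit-identity is not guaranteed.
- Multi-population images, ancestral/derived color channels, ordinal
  regression labels and parametric posterior fitting are out of scope.
- The combined row-and-column sort is deterministic but not idempotent
  (see above); single-axis sorts are.
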