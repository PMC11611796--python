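# Methods

This note records the statistical model behind the package, the
conventions and defaults it commits to, what the synthetic-data generator
does and does not emulate, and the numerical and design choices a
maintainer would want spelled out.

## The WEAT

A bias benchmark is a tuple (X, Y, A, B) of term sets: two *targets* (the
concepts under test) and two *attributes* (the poles they may associate
with).  Given an embedding e(·), with cos the cosine similarity,

- association: `s(w,A,B) = mean_{a∈A} cos(e(w),e(a)) − mean_{b∈B} cos(e(w),e(b))`,
  bounded in [−2, 2];
- effect size: `d = [mean_X s − mean_Y s] / std_{X∪Y} s`;
- test statistic: `s(X,Y,A,B) = Σ_X s − Σ_Y s`;
- p-value: the fraction of all partitions of X∪Y into two equal halves
  whose statistic *strictly* exceeds the observed one (one-sided).

**SD convention of the denominator.** `std` is population (divide by n).
This yields the canonical bound |d| ≤ 2 for |X| = |Y| (extremal case: the
associations take two values ±s₀ split evenly) and reproduces the effect
sizes conventionally published for the classic benchmarks.  The sample
(n−1) convention is available via `sd_convention="sample"` for sensitivity
analysis; every result records which was used.

**Ties and degeneracy.** Ties with the observed statistic (within 1e−12)
count as non-exceedances, per the strict inequality in the definition.
When more than 1% of partitions tie, a `DegenerateTiesWarning` is raised —
the all-vectors-identical case yields p = 0 with this warning rather than
an error.  A degenerate effect size (all associations identical, hence SD
zero and numerator zero) is defined as 0.

**Exact vs. Monte-Carlo p.** Exact enumeration is used when
C(|X∪Y|, |X∪Y|/2) ≤ 200,000 (sub-second at desk scale; covers the
bundled benchmarks with up to 16 targets, while the large name-based ones
— up to 64 targets — fall back automatically), otherwise 10,000 uniform
random equal-size partitions.  Both thresholds are arguments.  An odd union
admits no equal-size partition and is an error; unequal target sets (a
possibility after out-of-vocabulary skipping) still yield d, the
statistic, and a p-value over equal halves of the union, with a warning
and a `balanced=False` flag.

**Permutation scheme.** The permutation is over *targets* (partitions of
X∪Y), matching the definition of the test statistic's null distribution;
descriptions of the test sometimes speak loosely of permuting attribute
words, but the partition formula is what is implemented.

## The SD-WEAT

The two attribute sets are pooled (A then B, order preserved, duplicates
removed) and K tests are drawn: each picks 2m distinct terms uniformly
without replacement from the pool, the first m forming A′ and the last m
forming B′.  Draws are i.i.d. across tests — with small pools (e.g. the
4-term minimum) repeats across tests are unavoidable, and i.i.d. sampling
keeps the SD estimator's sampling law simple.  Each test's effect size d_i
is computed against the original targets; the score is

```
SD_WEAT = SD(d_1, …, d_K)
```

**Score SD convention.** Sample SD (n−1): the score estimates the
dispersion of a sampled population of attribute splits, unlike the effect
size's denominator, which normalizes over a fixed finite set.  Both
conventions are switchable and recorded in every result.

**Defaults.** m = 2 (the minimum that defines an effect size) and K = 100,
the method's standard operating point; m = 3 and 5 give near-identical
score profiles (tested), and the bundled benchmarks cannot support m > 5
(smallest pool: 14 terms).

**Negative control.** For significance, the same targets are scored
against attribute pairs drawn from general vocabulary: n = 10,000 tests in
G = 100 groups of 100 (in draw order).  The SD of each group gives a null
sample {SD₁, …, SD_G}; μ and σ are its mean and SD, and
`z = (SD_WEAT − μ)/σ` with a right-tailed normal p.  The group size
matches K so that μ estimates the null expectation of the score itself.
σ uses the same convention as the score (sample SD).  G < 2 or σ = 0 are
errors (degenerate control).  The normal approximation follows the
method's definition; the group SDs are exposed on the `NullCalibration`
object so empirical quantiles can be used for sensitivity analysis.

**Control vocabulary.** "General vocabulary" is operationalized as up to
50,000 purely alphabetic terms of length ≥ 2, taken in file order (which
proxies frequency rank in standard vector releases) and sampled uniformly
without replacement.  Filter, cap and sample size are all arguments.

**Controls are per-benchmark.** The control distribution depends on the
targets, so each benchmark gets its own calibration by default; an option
shares one calibration across benchmarks with identical target sets (the
WEAT-4/5 pair).

**Out-of-vocabulary policy.** Single WEAT runs default to `error` — a
benchmark score should not silently change meaning when terms are missing.
SD-WEAT runs default to `lowercase_fallback` (exact match, then lowercase,
then skip-with-report): resampling tolerates missing pool words.  The
pooled list and the control vocabulary are resolved once up front and
sampling is restricted to the resolved terms, which induces the same
sampling law as dropping individual failed tests while keeping K exact;
more than 20% unresolved terms in any term set aborts the run.  Multi-word
terms (spaces or hyphens) resolve to the mean of their token vectors — the
standard context-free composition — and a contextual encoder can
participate by wrapping its term→vector map in an `EmbeddingStore`; no
sentence context is used, since the benchmarks are single or compound
words.

## Calibration caveat: attribute-pool size

For a *fixed* store, the SD-WEAT score estimates the dispersion of effect
sizes over the benchmark's own finite attribute pool.  The realized
geometry of a small pool (16–50 vectors) varies from store to store much
more than that of a large control vocabulary, so under the null the score
fluctuates more across models than the control's group SDs predict: the
z-calibration is anti-conservative for small pools (measured here: a
16-term pool fails a Kolmogorov–Smirnov uniformity check of the null
right-tailed p decisively; even 600-term pools retain visible distortion
against a disjoint control vocabulary).  The calibration machinery itself
is verified on a wide-pool null benchmark (150 terms per side) with the
control vocabulary equal to the pooled attribute list, which makes the
control distribution match the score's null distribution exactly under
exchangeability.  Practically: treat small-pool z-scores as a ranking
device rather than exact tail probabilities — consistent with using the
score, not the p-value, as the primary bias measure.

## Synthetic embeddings

The generator plants a latent bias axis: a fixed unit vector u (drawn from
the store's seed), with each term's raw vector `pole·β·u + ε`, ε isotropic
Gaussian with per-component scale `noise_scale`, then normalized to unit
length.  Default poles put X and A at +1, Y and B at −1, and filler terms
(pure noise, alphabetic names, for control-vocabulary sampling) at 0.
Defaults: dimension 50 — large enough that random cosines concentrate near
0 (SD ≈ 1/√50), small enough to be fast; noise_scale 1, with β the single
effective dial since cosine statistics depend only on β/noise_scale.
β = 0 makes all groups exchangeable (the null); β→∞ drives d to its
maximum of 2.  Replicate families re-derive axis and noise from seed
base+i per replicate — a rotated axis is the identical bias structure for
every cosine-based statistic, so replicates share structure with
independent noise, emulating retraining an embedding method under
different seeds.

What this does *not* emulate: real embeddings have anisotropic geometry,
frequency-correlated vector norms, heavy-tailed neighbourhood structure,
and bias that is distributed over many directions with term-specific
loadings.  Passing tests on synthetic stores therefore validate the
*statistics* — estimator definitions, calibration, invariances, relative
behaviour of WEAT vs. SD-WEAT — not the magnitude of bias any particular
pretrained model would show.  Scoring real vector files is supported
directly (`read_word_vectors` handles GloVe- and word2vec-style text, and
published GloVe scores for the classic benchmarks can be reproduced that
way), but no multi-gigabyte model is bundled or downloaded.

## Stability analysis

A method's replicates are scored per benchmark with either metric; the
stability report gives per-benchmark min/max/SD (sample SD across
replicates, of the *signed* score — a sign flip between replicates is
itself instability), per-method mean-of-SDs, and a ranking (lower = more
stable).  SD-WEAT resampling seeds are per-replicate (base + index) by
default, so panels reflect model variability plus resampling noise;
`freeze_resample_seed=True` isolates model variability, and is the mode
used when comparing the two metrics' spreads (otherwise the WEAT, which has
no resampling noise at all, would be at an unfair advantage).  Reports are
invariant to panel, replicate and benchmark ordering.

## Problem sizes used by the tests and acceptance script

All statistical checks run on synthetic stores at the sizes the package
considers its desk-scale operating point: dimension 50; K = 100 resampled
tests; 10,000-test/100-group negative controls; 100–500 replicate stores
for null and power checks; 9 replicates × 3 noise levels (0.9/1.3/1.8 at
β = 1, chosen inside the non-saturated response range) for stability;
10,000 random instances for the bound search; 20 instances × 5,000 draws
for Monte-Carlo-vs-exact agreement; a graded family (β = 0 … 1.8 across
the ten bundled benchmarks) for the attribute-size and cross-method
correlation checks.  The whole suite and the acceptance script each
complete in well under a minute on one CPU.

## Known limitations

- The z-based p assumes the group SDs are approximately normal; for very
  small pools the score's null distribution is wider than the control's
  (see the calibration caveat above).
- The exact p-value enumerates C(n, n/2) partitions in Python; beyond the
  200,000-partition cap only Monte-Carlo is practical.
- Benchmarks with very small pools cap the usable attribute size m.
- Subword/fastText-style synthesis of out-of-vocabulary vectors and binary
  word2vec files are not supported; the term lists bundled for the ten
  classic benchmarks follow the original publication's supplementary
  materials (documented in the data file header).
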