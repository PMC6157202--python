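# Methods

## The MSLD transform

The multidistance signal level difference of a series `x(1..N)` at
distance `d` is `y_d(i) = |x(i) − x(i+d)|` for `i = 1..N−d`, a
one-dimensional analogue of the gray-level difference texture statistic.
The printed definition of the transform is sometimes given without the
absolute value; we implement the absolute-value form, which is the one the
method actually uses (the levels are non-negative by construction and that
is what makes them comparable across records).

The admissible distance range is `1 ≤ d ≤ N−2` rather than `N−1`: each
level must keep at least two samples so a downstream entropy estimate with
`m ≥ 1` is at least formally possible. The default range is `d = 1..20`,
the widest range in the experimental grid. Empirically the transform is
most informative for `d ≤ 15`; nothing enforces this, it simply shows up
as flatter curves at large `d`.

In contrast to the coarse-graining step of multiscale entropy, which
averages non-overlapping windows and therefore shrinks the variance of a
white signal like `1/scale`, the MSLD transform keeps each level at full
sampling resolution; for white noise `var(y_d)/var(x) = 2(1 − 2/π) ≈ 0.73`
at every `d`. The test suite asserts both behaviours side by side.

## Sample entropy

`SampEn(m, r, N) = −ln(A/B)` with both template counts taken over
`i = 1..N−m` (the Richman–Moorman convention implied by the symmetric
`(N−m)(N−m−1)/2` normalisation, which cancels in the ratio and is never
computed). A pair matches at length `L` when the Chebyshev (max-norm)
distance of the two templates is `≤ tol` (inclusive — this matters for
integer-valued EEG samples, where exact ties occur). Self-matches are
excluded, so `A ≤ B` and the estimate is non-negative whenever defined.

Parameters:

* `m` (embedding length, default 2). The source study does not state `m`;
  2 is the standard choice in the sample-entropy literature and is
  configurable everywhere.
* `r` (tolerance, default 0.25). Interpreted as a fraction of the
  **population SD of the series being analysed** — here each MSLD level's
  own SD (`tolerance_mode="relative_sd"`), which makes features exactly
  invariant to amplitude scaling and offset of the record. Whether the
  original experiments scaled by the raw record's SD instead is not
  stated; an `absolute` mode is provided so either convention can be
  composed by the caller. One printed figure caption reads `r = 2.5`; the
  accompanying text says 0.25, which is the value used (2.5 SDs would
  admit nearly every template pair).

Degenerate cases:

* A **constant series** returns 0 (the limit where all pairs match at all
  lengths), decided before SD scaling so the relative mode is total.
* **No matches** (`B = 0`, or `B > 0` with `A = 0`) returns `None` rather
  than infinity. The feature layer substitutes the finite ceiling
  `ln((N−m)(N−m−1)/2)` — the largest value a defined estimate could take,
  reached when exactly one pair matches at both lengths — so feature
  vectors stay finite while preserving "maximally irregular" ordering.
  Substitutions are counted and logged.

The optimized estimator counts matching pairs with a k-d tree under the
max-norm (`scipy.spatial.cKDTree.query_pairs`) and extends the matched
pairs by one sample vectorially. Because both paths count the same integer
pairs, the optimized estimator and the pure-Python triple-loop
`sample_entropy_bruteforce` agree bit-for-bit; the suite asserts agreement
to 1e−12 across random lengths, `m ∈ {1,2,3}`, `r ∈ [0.1, 0.5]` and both
tolerance modes. The brute-force twin refuses series longer than 2000
samples (it is quadratic and exists for verification only).

## Features and classification

A record's feature vector is `SampEn(y_d)` for `d = d_min..d_max`
(default 1..20, so 20 features for a 4096-sample record). Each distance is
computed independently, so a wide table restricted to a narrower
contiguous range (`restrict_scales`) is identical to re-extraction at that
range; the grid driver exploits this and extracts once per tolerance.

Classification uses scikit-learn behind the module surface: features are
standardized (training-fold statistics only — the suite asserts no
leakage), then fit with `SVC`. Kernels: linear `x·y`, polynomial
`(x·y + coef0)^degree` with degree 2 or 3. The homogeneous polynomial form
(`coef0 = 0`) is available, but the default is `coef0 = 1` on standardized
features: a homogeneous cubic on unstandardized entropy features is
numerically pathological, and an inhomogeneous kernel is what standard SVM
toolchains use. The box constraint defaults to `C = 1`; the multiclass
reduction is one-vs-one. None of these three choices is stated in the
source experiments; they are this package's declared defaults, not
inferred ones. Cross-validation is stratified 5-fold (balanced classes
make stratification the faithful, lower-variance reading of plain 5-fold),
shuffled deterministically by a seed; a non-stratified mode exists.

Accuracies are reported in percent to one decimal in the grid tables. The
grid covers r ∈ {0.1, 0.15, 0.2, 0.25} × scale ranges 1–20/1–15/1–10/1–5 ×
three kernels. Cell-exact reproduction of the published accuracy tables is
out of scope: it would require the Bonn archive download, and the fold
assignment and SVM hyperparameters behind those tables are unstated. With
a local copy of the archive the same grid driver applies unchanged; the
expectation at r = 0.25, d = 1–20, cubic kernel is mean CV accuracy in the
mid-to-high 90s (peak published value 97.7%).

## The synthetic generator

`gen_labeled_set` emulates the *study conditions* — three classes, 100
records per class, 4096 samples at 173.61 Hz — with generators chosen for
their complexity ordering, not for physiological realism of amplitude
distributions or spectra:

| class | generator | frozen parameters |
|---|---|---|
| ictal-like | spike_wave | 3 Hz base (amp 1) + white noise SD 3 + 7 Hz bursts (amp 4, 0.2 s every 1.2 s, Hann-windowed, random onset phase) |
| normal-like | sine_plus_noise | 10 Hz alpha sine (amp 1) + AR(1) φ=0.7 noise, innovation SD 0.05 |
| interictal-like | sine_plus_noise | 4 Hz sine (amp 3) + AR(1) φ=0.95 noise, innovation SD 0.02 |

Design notes. The entropy of an MSLD level at `d = 1` is governed by the
short-lag structure of the differenced noise: first differences of white
noise are anticorrelated (lag-1 ρ = −0.5), which *depresses* their sample
entropy below that of differenced AR(0.7) noise (ρ = −0.15). A plain AR(1)
"normal" class therefore cannot sit below a noise-dominated ictal class at
`d = 1`. Giving the normal class a dominant alpha-band rhythm — the
defining feature of closed-eye resting EEG in any case — moves it into the
mid-entropy band at every distance. What orders the classes is the ratio
of sine-difference amplitude to noise-difference SD per level: the
interictal class is the most sine-dominated (most regular), the ictal
class is noise-dominated with burst morphology (most irregular). The
parameters above were tuned once against the ordering and separability
requirements and then frozen; with them the mean curves are strictly
ordered at every `d ∈ 1..20` with a worst-case gap of ≈0.15 entropy units,
and the classes are separable at ≈100% CV accuracy.

Each record's RNG is seeded by `SeedSequence(master, spawn_key=(class,
index))`, so sets are reproducible and any record can be regenerated in
isolation, independent of generation order. AR(1) series discard a
200-sample burn-in.

What passing the synthetic tests shows: the pipeline is wired correctly,
the estimator matches its definition, the feature geometry that the method
relies on (ordered, well-separated entropy curves) is detected and
classified as intended. What it does not show: performance on real EEG,
whose classes overlap far more — the published real-data accuracies are in
the 73–98% range, not 100%.

## Problem sizes and numerical choices

The end-to-end checks run at the study size (3 × 100 records × 4096
samples; ≈80 s of feature extraction per master seed) for five seeds; the
entropy-ordering check uses 20 records per class, the statistical
tolerance a one-sided rank test at p < 0.01. The chance-level null
(permuted labels, 20 permutations) is asserted within three binomial SDs
of 1/3 at n = 300. Feature CSVs round-trip exactly: values are written
with the shortest round-tripping decimal representation and read back with
round-trip float parsing.
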