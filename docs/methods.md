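# Methods

## Sensor-noise model and the adaptive band

The descriptor rests on a two-regime model of 8-bit sensor noise. Above
a boundary intensity `R`, photon shot noise dominates and the noise SD
grows as `√i`; this approximation is valid whenever the signal-to-noise
ratio `γ = f/δ` satisfies `f ≤ γ² + γ`, i.e. `γ ≥ (−1+√(1+4f))/2`,
which at `f = 255` is 15.47655 — a condition ordinary photographs meet.
Below `R`, signal-independent sources (read noise, dark current) set a
constant floor `τ`. The adaptive noise band is therefore `τ` below `R`
and `√i` at or above it, evaluated always at the *center* pixel's
intensity so that one pixel applies one threshold to all of its
neighbour differences. The band is kept continuous (`√50 ≈ 7.07`);
worked displays that show "≈ 7" are rounding only, and bit outcomes are
identical either way at the relevant intensities.

Defaults `τ = 5` and `R = 26` are the empirical values for the 8-bit
dynamic range; both are exposed as parameters (`--tau`, `--R`) and a
`constant` band mode overrides the whole branch structure with a fixed
width `β`, which is the oracle hook collapsing NTTP onto LBP (`β = 0`,
upper code) and LTP (`β = α`).

## Estimating R from one image

Classical signal-dependent-noise estimation uses Skellam statistics of
paired exposures; with a single image we instead reconstruct the same
geometric picture — a horizontal constant-noise line and a rising
signal-dependent curve whose crossing is `R` — from patch statistics.
The image is tiled into `patch_size` squares (default 8); within each of
16 intensity strata only the lowest-SD fraction (`homogeneity_quantile`,
default 0.5) is kept, so textured patches do not inflate the noise
estimate. The floor `σ_c` is the mean SD of homogeneous patches in the
lowest intensity decile; the curve `σ = a√i` is fitted through the
origin to homogeneous patches in the upper intensity half whose SD
exceeds `1.5 σ_c` — patches clearly in the signal-dependent regime.
If fewer than five such patches exist, the curves are deemed
non-intersecting within the dynamic range and `R̂ = 255`; otherwise
`R̂ = (σ_c/a)²`, clamped to [0, 255]. Degenerate inputs (too few
patches, no intensity spread, a noiseless image) raise
`NoiseEstimationError` with a diagnostic message rather than returning a
fabricated boundary.

Tests validate the estimator on simulated piecewise-constant images with
a known SD breakpoint at 25, using 192×192 images (576 patches): the
extra patches stabilise the low-decile floor estimate, and the estimator
recovers the breakpoint within ±5 intensity levels in 20/20 seeded
replicates, cross-checked against an exhaustive breakpoint scan that
minimises the piecewise-fit residual.

## Code generation and the feature vector

Sampling geometry: `n ∈ {4, 8, 16, 24}` neighbours on a circle of
radius `r ∈ {1, 2, 3, 4}` (defaults `n = 8`, `r = 2`), neighbour 0 due
east of the center and subsequent neighbours counter-clockwise, bit `l`
weighted `2^l`. Images are (row, col) arrays, row increasing downward.
Off-grid samples use bilinear interpolation in nested-lerp form, which
is exact on constant and affine patches and therefore keeps the
flat-image identities (all-ones LBP codes, zero LBPV weight) exact in
floating point. Near-integer sample offsets are snapped so axial
neighbours are read directly. Pixels within `⌈r⌉` of a border are not
coded; the whole-image mean used by the center bit includes every pixel,
border included.

Threshold comparisons are inclusive (`≥ band`, `≤ −band`). The lower
code's condition is `diff ≤ −ANB` — the sign mirrors the ternary −1
branch, which is what makes the upper/lower split lossless (a property
tests verify by reconstructing ternary digits from the split and
comparing with a direct three-way evaluation).

Histogram assembly: each of the two joint histograms (center bit ×
uniform index) is flattened center-major, bin-minor, normalised to unit
sum, and the upper part concatenated before the lower part. Uniform
bins are indexed by ascending numeric code value with the non-uniform
catch-all last. Normalising per segment makes vectors comparable across
image sizes, which matters because the chi-square distance is
scale-sensitive. Length for `n = 8`: 2 × 2 × 59 = 236.

## Baselines

LBP, LTP, LBPV and CLBP share the sampling and bit conventions above,
so cross-descriptor equalities are bit-exact rather than approximate.
LTP uses the fixed threshold `α = 5` and concatenates its two uniform
histograms (118-dim); the preprocessing chain sometimes attached to LTP
(difference-of-Gaussian filtering etc.) is deliberately omitted — it
removes micro-patterns the classifier needs. LBPV weights each pixel's
histogram contribution by the population variance (divisor `n`) of its
sampled neighbour intensities and returns the all-zero vector for a
flat image. CLBP's magnitude threshold `t` is the mean |difference|
over all coded pixels' neighbour differences (differences are undefined
in the margin); its center bit compares with the whole-image mean.
Combination schemes: the joint 3-D histogram C×S×M (default, full
2·2ⁿ·2ⁿ codes as originally proposed), the 2-D joints S/C and M/C, and
the concatenated forms M_S/C and S_M/C; a uniform encoding option is
provided for memory-constrained use. Per-segment unit normalisation
applies throughout.

The LBP monotone-illumination invariance property is tested at
`n = 4, r = 1`, where all samples fall on exact pixels: a strictly
increasing intensity remap commutes with sampling only when no bilinear
interpolation is involved, so exact invariance is a property of
integer-offset geometries. The same geometry carries the
single-neighbour fluctuation-absorption property, so a perturbation
cannot leak into other samples through shared interpolation cells.

## Classification

Chi-square distance with 0/0 terms defined as 0 (the standard
convention for sparse histograms; the distance is symmetric and
non-negative but not a metric — no triangle inequality is claimed).
Nearest neighbour runs over individual training exemplars, ties broken
by lowest training index. Cross-validation uses a seeded stratified
k-fold partition (fold sizes per class differ by at most one) and
reports per-fold percent-correct; the partition is delegated to
scikit-learn's `StratifiedKFold`, while the distance and decision rule
are implemented here. An SVM comparison can be run externally on the
exported feature CSVs; kernel machinery is out of scope.

## Synthetic benchmark

The generator emulates the *structure* of texture-classification
benchmarks, not their imagery: four parametric families (sinusoidal
gratings, checkerboards, Gaussian random fields, blob fields) stand in
for photographic texture classes, with per-sample nuisance jitter
(phase, grid offset, field realisation) playing the role of crops of a
larger source texture. Sensor noise is Gaussian (`σ`), shot
(`gain · Poisson(i/gain)`, SD ≈ `√(gain·i)` — the regime the band is
built for) or both; outputs are clamped to [0, 255] since the target
imagery is 8-bit, and noise is added after the clean image is formed,
without requantisation, so a zero-noise spec is an exact identity.

The noise-robustness experiment fixes its study conditions as: 4
classes × 40 samples per class at 64×64, base intensity 128 and
contrast 60 (mid-range 8-bit textures whose shot noise at `i ≈ 128`,
SD ≈ 11, sits right at the band `√128 ≈ 11.3`), clean training half,
test half corrupted with shot noise at gain 1 plus Gaussian `σ = 8`,
five seeds. The claim asserted is an *ordering* — mean NTTP accuracy at
or above LBP's — not any particular magnitude; measured values are
printed by `examples/noise_robustness.py`. What passing shows: the
adaptive band absorbs realistic signal-dependent fluctuations that flip
zero- and fixed-threshold codes. What it does not show: performance on
photographic textures, whose structures are richer than any parametric
family, or robustness to noise far outside the band's validity regime.

## Numerical and design notes

- Sample-offset snapping tolerance 1e−9; histogram normalisation checked
  to 1e−9 in tests; chi-square agreement with a naive-loop oracle to
  1e−12.
- Full-code CLBP S/M/C at `n = 8` is a 131072-dim histogram; for
  `n = 16` or 24 only the uniform encoding is practical.
- 16-bit inputs are rescaled to [0, 255] with a warning: the band's
  derivation assumes the 8-bit dynamic range.
- Feature CSVs carry the layout in the header (`segment:center:bin`), so
  a round-trip restores both values (to float repr precision) and
  layout; mismatched layouts are detected on read and on classify.
- Known limitations: no rotation-invariant (riu2) code variants, no
  multi-scale fusion, no colour texture, and the single-image boundary
  estimator needs homogeneous patches spanning both intensity regimes —
  a low-dynamic-range image yields the clamped `R̂ = 255` rather than an
  extrapolated crossing.
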