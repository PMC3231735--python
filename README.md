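# nttp — noise tolerant ternary pattern texture descriptors

Local-pattern texture codes (LBP and friends) describe the micro-pattern
around a pixel by thresholding its intensity against its circular
neighbours. They are cheap and illumination-robust, but they threshold at
zero, so the signal-dependent noise every CCD/CMOS sensor injects flips
code bits in near-uniform regions and corrupts the texture histogram.
This package implements the **noise tolerant ternary pattern (NTTP)**:
a ternary local code whose threshold is an **adaptive noise band (ANB)**
sized to the expected noise at the center pixel's intensity, rather than
zero (LBP) or a fixed margin (LTP). It is aimed at texture classification
of 8-bit imagery — biological and biomedical image analysis included —
where sensor noise is the rule, not the exception.

## The model

An observed pixel is signal plus noise, `g = f + δ`. Photon shot noise
gives `sd(δ) ≈ √g` once the signal-to-noise ratio `γ = f/δ` exceeds
`(−1 + √(1 + 4f))/2` (15.47655 at the 8-bit maximum `f = 255`), while a
constant noise floor dominates at low intensity. The band is therefore

```
ANB(i) = τ      if i <  R        (defaults τ = 5, R = 26)
ANB(i) = √i     otherwise
```

`R` can also be estimated from a single image: the mean SD of
homogeneous low-intensity patches gives the constant-noise line, a
`σ = a√i` fit over the brighter homogeneous patches gives the
signal-dependent line, and `R̂` is where they cross.

The NTTP code at pixel `c` with neighbours `g_l`, `l = 0..n−1`, is

```
q(g_l − g_c) = +1  if g_l − g_c ≥  ANB(g_c)
               −1  if g_l − g_c ≤ −ANB(g_c)
                0  otherwise
```

split losslessly into an upper binary code (the +1 bits) and a lower
binary code (the −1 bits). Each is mapped through the uniform-pattern
lookup (codes with ≤ 2 circular bit transitions; 58 such codes + 1
catch-all bin for n = 8), joined with a center bit (`g_c ≥` image mean)
into two 2 × 59 joint histograms, which are flattened, normalised and
concatenated into a 236-dimensional feature vector. Classification uses
the chi-square distance `D(X,Y) = Σ (X_i−Y_i)²/(X_i+Y_i)` with a
nearest-neighbour rule.

The baselines it is compared against — LBP, uniform-LBP histograms,
LTP split codes (α = 5), variance-weighted LBPV and the CLBP
sign/magnitude/center family with its combination schemes — share the
same sampling geometry and bit order, so NTTP with a constant band of 0
reproduces LBP exactly and with a constant band of 5 reproduces LTP.

## Worked example

```
$ python examples/noise_robustness.py
descriptor  mean%   per-seed accuracies
nttp         74.0    75.0  73.8  73.8  75.0  72.5
ltp          52.0    50.0  50.0  55.0  55.0  50.0
lbp          50.0    50.0  50.0  50.0  50.0  50.0
-> percent of noisy test images assigned to their true texture class
```

Four synthetic texture classes (grating, checkerboard, Gaussian random
field, blobs), 40 samples each; the training half is clean, the test
half carries shot noise (gain 1) plus Gaussian noise of SD 8. The
numbers are chi-square nearest-neighbour accuracies per seed and their
mean: the adaptive band keeps NTTP well ahead of the fixed-threshold
LTP and the zero-threshold LBP under a train/test noise mismatch, while
all three reach 100% on the noiseless version of the same benchmark.

`examples/adaptive_noise_band.py` evaluates the band and recovers a
known noise-regime boundary from patch statistics;
`examples/extract_and_compare.py` contrasts chi-square distances between
clean, noisy and genuinely different textures.

A CLI mirrors the library:

```
nttp extract --input images/ --descriptor nttp --tau 5 --R 26 -o features.csv
nttp crossval --features features.csv --folds 10 --seed 42
nttp synth --family grating --size 64 --noise gaussian:8 --seed 1 -o out/
nttp benchmark --seed 1 --descriptors nttp,ltp,lbp
```

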