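# Methods

## Spectral model and the synthetic generator

A Z-spectrum is modelled as unity minus a sum of Lorentzian saturation
pools evaluated at the B0-shifted offset:

    Z(Δω) = 1 − Σ_i A_i · (Γ_i/2)² / ((Γ_i/2)² + (Δω − b0 − δ_i)²) + ε,
    ε ~ N(0, σ²)

with amplitude A_i (unitless depth), center δ_i (ppm) and full width at
half maximum Γ_i (ppm). This is a lineshape model, not a Bloch–McConnell
exchange simulation: saturation power, exchange rates and relaxation do
not appear explicitly; their net effect is folded into (A, Γ). Default
pools emulate mouse brain at moderate saturation power:

| pool  | A    | δ (ppm) | Γ (ppm) |
|-------|------|---------|---------|
| water | 0.80 | 0.0     | 1.4     |
| amide | 0.05 | +3.5    | 1.0     |
| NOE   | 0.06 | −3.5    | 2.0     |
| MT    | 0.06 | −1.0    | 8.0     |
| amine | 0.03 | +2.0    | 1.2     |

Amplitudes sum to exactly 1.0, the largest total for which a noise-free
spectrum is guaranteed non-negative; amplitude sums above 1 are rejected.
The defaults are deliberately uncalibrated to any in vivo dataset — they
reproduce the qualitative shape (deep direct-saturation dip, small
exchange dips, broad MT background), not quantitative tissue parameters.
Noise is additive Gaussian on the normalized signal with σ = 0.01 by
default (matching the corpus-augmentation noise level); Rician bias at
low SNR is not modelled, which is acceptable because Z-values stay well
above zero.

`simulate_corpus` draws per-spectrum variability: a global amplitude
scale in [0.75, 1], per-pool amplitude factors in [0.7, 1.3] (capped at
the base amplitude), ±0.2 ppm center jitter for exchange pools, width
factors in [0.8, 1.3], and a uniform B0 shift in ±0.3 ppm. The ranges
were chosen once so that a 10-offset sparse sampling no longer fully
determines the spectrum — otherwise the 10/20/30% budgets would be
indistinguishable and reconstruction comparisons meaningless.

Phantoms are 4D (x, y, slice, offset) with per-slice smooth random B0
fields (low-order cosine mixtures, ±0.2 ppm by default), a full-frame or
elliptical "brain" mask, and i.i.d. pixel noise. The default cohort is
19 subjects × 2 slices at 48×48 pixels, giving 38 slice-average spectra;
the two augmentation schemes are noise replication (30 bases × 100 copies
= 3000 rows) and without-replacement pixel sub-sampling with the size
ladder 800:50:1550 (16 sizes; 38 × 16 = 608 spectra, 128 held out). The
sub-sampling is independent per (slice, size) with seeds spawned from a
master seed; the replacement policy is a package choice.

What the generator does **not** emulate: motion, eddy currents, Rician
noise, partial-volume anatomy, spatially structured pool variation, or
inter-scan B0 drift. Passing tests therefore demonstrate correctness of
the algorithms under a controlled spectral family, not in vivo
performance.

## Preprocessing

The per-pixel (or per-slice) B0 shift is read off the direct water
saturation dip. Two estimators are provided: the minimizer of a cubic
spline upsampled at 0.01 ppm resolution (default), and the center of a
single-Lorentzian least-squares fit within ±1.5 ppm of the raw minimum.
The WASSR idea — estimate the water center on a low-power water-only
scan — is realized by running the estimator on a water-only simulated
spectrum when one is available, else on the CEST spectrum itself; the
original maximum-symmetry WASSR algorithm is not reproduced. Correction
resamples the spectrum at (offsets + shift) with a cubic spline and
nearest-value edge extension. Correction happens on the acquired 51-point
grid, then linear interpolation takes the spectrum to the 101-point
analysis grid (the opposite order is defensible; this one avoids
resampling noise twice).

## Genetic algorithm

The encoding is a set of k distinct grid indices (k fixed by the budget
p). Operators: tournament selection of size 3; crossover forms the union
of two parents and draws k genes from it uniformly without replacement;
mutation replaces each gene with probability `mutation_rate` (default
0.1) by a uniformly drawn unselected index. Both operators preserve
cardinality and distinctness by construction, which the property tests
assert. Elitism (default 1) carries the best chromosome forward, making
the best-fitness trace non-increasing; it can be disabled. Termination:
target loss reached, improvement < 1e-6 RMSE for `patience` (default 20)
consecutive generations, or `max_generations` (default 300). Population
defaults to 60; a seed is required for reproducibility. No offsets are
force-included: the GA discovers the ±water-dip and amide placements on
its own, which is itself a useful sanity check.

The fitness is the RMSE between the dense spectrum and a not-a-knot cubic
spline through the selected points, evaluated on all grid offsets with
constant extension beyond the selected hull. Subsets below 4 points are
infeasible (cubic minimum).

Where several per-spectrum GA runs compete, `select_best_candidate`
offers two criteria: lowest fitness on the candidate's own source
spectrum ("own", default), or lowest mean RMSE across all spectra
("cross-mean"). Both are exposed because either reading is plausible for
a cohort-level selection.

## Reconstruction networks

All three networks share the encoder–decoder skeleton: two resolution
levels (2× max-pool down, 2× nearest-neighbour up), kernel size 3,
"same" zero padding, ReLU activations, channel plan 32→64 mirrored in
the decoder, and a linear 1-channel output convolution.

* autoencoder: 1 conv per level + bottleneck + 1 conv per decoder level
  + output = 6 convolutions, no skips;
* unet1: same budget with channel-concatenation skips at both levels;
* unet2: double convolutions per level = 10 convolutions, 2 skips.

Input length 101 is not divisible by 4, so the input is replicate-padded
to 104 inside the model and cropped back at the output; this is invisible
at the interface. The sparse input is zero-filled at unsampled offsets
(single channel); an optional second mask channel is available behind a
flag but off by default, matching the "sparse masked" reading.

Training: Adam (initial lr 1e-3), MAE loss, validation split 0.2,
reduce-on-plateau (factor 0.5, patience 10 epochs) with floor 1e-6,
default 300 epochs and batch 16. The layers are implemented directly on
numpy with hand-derived gradients (verified against finite differences in
the tests); runs are single-threaded-deterministic, so identical seeds
give identical histories on one machine.

None of the kernel sizes, channel widths or optimizer settings beyond
loss/optimizer/lr-floor/validation-split are externally constrained;
the choices above are conventional for small 1D signal models and are
fixed as package defaults.

## Metrics

Spectrum metrics are RMSE, MAE and Pearson's r (undefined and rejected
for constant references). RMSE ≥ MAE is asserted suite-wide. MTR maps at
3.5 ppm support two conventions — asymmetry Z(−Δω) − Z(+Δω) (default)
and plain depth 1 − Z(+Δω) — and every report records which was used,
since the asymmetry form cancels symmetric direct saturation while the
depth form does not. Map comparisons report PSNR = 10·log10(range²/MSE)
(infinite for identical maps; closed-form cross-checked against
scikit-image), MAE, and SSIM with a 7×7 Gaussian window (σ 1.5,
K1 = 0.01, K2 = 0.03) on a declared data range of 1.0 for normalized
maps.

Scan-time accounting uses T_A = TR·(N_PE/ETL)·N_offs; the acceleration
factor of a sparse protocol is N_full/N_sparse (101/10 = 10.1 at the 10%
budget), since TR, N_PE and ETL are unchanged by offset selection.

## Problem sizes and numerical choices

Desk-scale defaults keep every experiment single-CPU-friendly: GA
exhaustive-search comparisons run on toy grids of ≤ 14 points with k = 4
(where all C(n,4) subsets can be enumerated); selector comparisons use 20
synthetic spectra; network studies use a 200-train/30-test corpus at 150
epochs, where all nine (architecture × budget) runs finish in a few
minutes. Grid equality uses a 1e-9 ppm tolerance, ppm matching in
`fixed_select` 1e-6, GA stall detection 1e-6 RMSE, and spline/linear
resampling inherit scipy's float64 arithmetic. Degenerate inputs
(empty masks, constant references, sub-4-point subsets, amplitude sums
above 1, out-of-range targets) raise `ValueError` rather than returning
sentinel values.

## Known limitations

* The Lorentzian-sum generator cannot validate exchange-rate or
  saturation-power dependence; conclusions about those require
  Bloch–McConnell simulation or real data.
* The GA fitness targets a single dense spectrum; cohort-level selection
  aggregates per-spectrum runs rather than optimizing a pooled loss.
* The networks are intentionally small and CPU-trainable; they are not
  tuned for, nor tested on, human-brain spectral families or other field
  strengths.
* B0 correction assumes the water dip is the global minimum and within
  ±1 ppm; severe inhomogeneity or very low saturation power breaks that
  assumption.
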