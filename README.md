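# zspeed — accelerated CEST MRI by sparse offset selection and learned Z-spectrum reconstruction

Chemical exchange saturation transfer (CEST) MRI detects dilute metabolites
(amide protons, amines, NOE-coupled lipids) by saturating them at their
chemical shift and measuring the transferred signal loss in water. The
resulting **Z-spectrum** — normalized signal S/S0 versus saturation offset
Δω in ppm — must be densely sampled over a broad range (here −5…+5 ppm),
and scan time grows linearly with the number of offsets:

    T_A = TR · (N_PE / ETL) · N_offs

for a RARE readout with repetition time TR, N_PE phase-encoding lines and
echo train length ETL. `zspeed` shortens the scan with a two-stage scheme:

1. **Offset selection.** A genetic algorithm searches for the subset
   F_selected ⊆ F_N of fixed size k = round(p% · N) that minimizes the loss
   L(F_selected) — the RMSE between the dense Z-spectrum and its cubic-spline
   reconstruction from only the selected offsets:

       F_optimal = argmin_{F_selected ⊆ F_N} L(F_selected)

   Chromosomes are fixed-cardinality index sets; tournament selection,
   union-then-subsample crossover and replacement mutation preserve the
   subset size, and elitism makes the best loss monotone.

2. **Learned reconstruction.** A small 1D convolutional network — an
   autoencoder (6 conv / 2 pool / 2 upsample layers), a U-Net with skip
   connections at both resolution levels, or a deeper 10-conv U-Net — maps
   the zero-filled sparse spectrum back to the dense 101-point spectrum.
   Training uses Adam with mean-absolute-error loss, a 20% validation split
   and a reduce-on-plateau learning-rate schedule floored at 1e-6.

At a 10% budget (10 of 101 offsets) this yields a **10.1× acceleration**
while the learned reconstruction keeps the spectrum error on the order of
the acquisition noise.

Because raw animal CEST data are expensive and rarely shared, the package
ships a synthetic generator (`zspeed.simulate`) that emulates mouse-brain
Z-spectra as 1 − Σ Lorentzian pools (direct water saturation, amide at
+3.5 ppm, NOE at −3.5 ppm, a broad MT component, amines at +2 ppm) with
per-pixel B0 shifts and additive Gaussian noise, plus the two corpus
augmentation schemes (noise replication and pixel sub-sampling) and 4D
phantom cohorts. Preprocessing (`zspeed.preprocess`) provides WASSR-style
B0 correction and 51→101 resampling; `zspeed.evaluate` provides
RMSE/MAE/Pearson, MTR maps at ±3.5 ppm, and PSNR/MAE/SSIM map comparisons.

## Worked example

```python
import numpy as np
from zspeed import (GAConfig, ModelSpec, TrainConfig, ZSpectrum, build_model,
                    ga_select, make_offset_grid, predict, simulate_corpus,
                    spectrum_metrics, train)
from zspeed.reconstruct import encode_sparse_table

grid = make_offset_grid(-5, 5, 0.1)           # dense 101-point grid
corpus = simulate_corpus(230, grid, seed=42)  # synthetic brain-like spectra
train_vals, test_vals = corpus.values[:200], corpus.values[200:]

mean_spectrum = ZSpectrum(grid, train_vals.mean(axis=0))
result = ga_select(mean_spectrum, p=10, config=GAConfig(seed=110, max_generations=80))
print("selected offsets (ppm):", np.round(result.best.ppm, 1))
print("spline fitness (RMSE): %.4f" % result.best.fitness)

X_train = encode_sparse_table(train_vals, result.best)
X_test = encode_sparse_table(test_vals, result.best)
model = train(build_model(ModelSpec("autoencoder"), seed=7), X_train, train_vals,
              TrainConfig(epochs=150, batch_size=16, seed=3))
recon = predict(model, X_test)

rmse = [spectrum_metrics(r, t)[0] for r, t in zip(recon, test_vals)]
print("held-out RMSE  min %.4f  max %.4f  mean %.4f"
      % (np.min(rmse), np.max(rmse), np.mean(rmse)))
```

Output (a couple of minutes on one CPU core):

```
selected offsets (ppm): [-4.6 -3.8 -2.9 -0.5 -0.1  0.2  0.8  1.2  3.5  4.3]
spline fitness (RMSE): 0.0068
held-out RMSE  min 0.0029  max 0.0156  mean 0.0071
```

The GA concentrates offsets around the steep water dip (−0.5…+1.2 ppm) and
places one at the amide resonance (+3.5 ppm) — exactly where a spectroscopist
would sample by hand. The spline fitness (0.0068) is the stage-1 loss being
minimized; the held-out RMSEs show the stage-2 network reconstructing dense
spectra from 10 offsets at roughly the same error, i.e. a 10.1× faster scan
at near-noise-level spectral fidelity.

## Command line

```bash
zspeed simulate --subjects 19 --slices 2 --grid -5:5:0.2 --seed 1 --out vols/
zspeed preprocess --input vols/subject00.nii.gz --out dense.csv
zspeed select --p 10 --input dense.csv --seed 1 --out subset.json
zspeed train --arch unet2 --subset subset.json --data dense.csv --seed 1 --out model/
zspeed reconstruct --model model/ --input dense.csv --subset subset.json --out recon.csv
zspeed evaluate --recon recon.csv --ref dense.csv --out report.json
zspeed run --seed 1 --out experiment/      # full pipeline in one go
```

Exit codes: 0 success, 1 user error, 2 internal error.

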