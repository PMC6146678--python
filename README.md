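# ffasr — example-based super-resolution for fundus fluorescein angiography

Fundus fluorescein angiography (FFA) is a mainstay of retinal diagnostics,
but many clinics acquire only low-resolution angiograms (modest sensors,
pixel binning to recover SNR from the faint fluorescence signal). `ffasr` is
a toolkit for *single-image super-resolution* (SISR) of such images: it
learns a mapping from low-resolution (LR) to high-resolution (HR) patches on
a training set of HR/LR image pairs and reconstructs an HR image from a
single LR input. It is aimed at researchers comparing classical
patch-regression SR families on retinal imagery, and ships a synthetic
fundus phantom generator so the full pipeline is reproducible without
clinical data.

## The model

Training pairs come from the degradation model `x_l = G x_h`, where `G` is a
bicubic downsampler at upscaling factor M ∈ {2, 4}. Both images are cut into
dense overlapping patches — LR 3×3 at stride 2, HR 3M×3M at stride 2M — and
every method learns, in its own way, a map from the mean-removed LR patch
`y_l ∈ R^9` to its HR counterpart `y_h ∈ R^{9M²}`:

| method | mapping |
|---|---|
| `ne_ls`, `ne_nnls` | weights over the K=24 nearest LR training patches (sum-to-one LS / NNLS), applied to the paired HR patches |
| `sb_yang` | coupled dictionaries `D_l, D_h` with a shared sparse code: `α = argmin ‖y_l − D_l α‖² + λ‖α‖₁`, `y_h = D_h α` |
| `sb_zeyde` | K-SVD dictionary + OMP coding, HR dictionary by pseudo-inverse |
| `anr`, `aplus` | precomputed per-atom ridge projections `y_h = P_j y_l`, neighborhoods from dictionary atoms (ANR) or the training pool (A+) |
| `jor` | O=32 ridge regressors jointly fit with an EM-style clustering; kNN vote selects the regressor at test time |
| `srf` | random forest with ridge leaf maps; splits scored by `E = mean(‖x_h − m(x_l)‖² + κ‖x_l − x̄_l‖²)` |

Reconstructed patches are overlap-averaged into the output image and scored
with PSNR/SSIM against the HR ground truth. See `docs/methods.md` for every
convention and default.

## Worked example

Generate a small synthetic dataset (3 simulated eyes × 4 homologous frames),
train a super-resolution forest, and evaluate on the held-out frames:

```bash
ffasr make-dataset --out data --groups 3 --per-group 4 --size 96 --seed 7
ffasr train --dataset data --method srf --out srf.joblib --seed 7
ffasr eval  --dataset data --model srf.joblib --out report
```

which prints

```
method,mean_psnr_db,mean_ssim,n_images
srf,28.9661,0.924791,6
bicubic,26.9624,0.896941,6
```

The forest reconstructs the six held-out test frames at a mean 28.97 dB
PSNR / 0.925 SSIM versus their ground truth, a 2 dB gain over plain bicubic
interpolation of the same LR inputs — the learned LR→HR patch map is
recovering detail the interpolation baseline cannot. `ffasr sr --model
srf.joblib --input lr.png --out sr.png` applies the trained model to a
single image. The same operations are available as library calls
(`ffasr.train_model`, `ffasr.super_resolve_image`, `ffasr.evaluate`), and
`ffasr benchmark` runs all nine methods end-to-end.

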