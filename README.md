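# lu177planar

Scan-time reduction in Lu-177 planar scintigraphy, studied end to end in
simulation: digital phantoms, an analytic gamma-camera projector, Poisson
counting with binomial scan-time thinning, a densely-connected CNN
denoiser, whole-image fidelity metrics, per-ROI significance tests, and
MIRD conjugate-view dosimetry.

**For whom.** Medical-physics and image-analysis researchers who want a
self-contained, reproducible desk-scale testbed for the question: *how
much can the scan time of a Lu-177 planar acquisition be cut if a CNN
restores the reduced-count image — without breaking organ-level activity
quantification?*

## The science in brief

A planar scan of duration `T` detects Poisson counts; scanning for
`f·T` is statistically identical to keeping each detected photon with
probability `f` (binomial thinning), so nested reduced-count images are
simulated exactly. A denoising network (one low-level convolution,
dense blocks whose layers receive the concatenation of all preceding
feature maps, a 1×1 bottleneck, two stride-1 reconstruction stages) is
trained with an RMSE loss and Adam on 25×25 patch pairs: input = the
reduced-count image divided by its known fraction `f`, label = the
full-count image. Fidelity is scored by RMSE, PSNR
`= 20·log10(I_max/RMSE)` and a global SSIM; ROI agreement by
two-sample t-tests of pixel intensities (α = 0.01) between each image
and the full-count reference. Organ activity follows the MIRD
conjugate-view estimator

    A = F · sqrt(I_A · I_P / T) · f / C,

and absorbed doses `D_j = Σ_k Ã_k · S(j←k)` with cumulated activities
`Ã` integrated from the organ time–activity curves.

The headline finding this package reproduces in structure: every
reduced-count image differs significantly from the full-count reference
in every ROI, while denoised images containing ≥ 30% of the counts are
statistically indistinguishable for all rods ≥ 13 mm and all source
organs — a 70% scan-time reduction.

## Worked example

```python
from lu177planar import experiments as ex
from lu177planar.phantoms import RodSpec, make_derenzo, total_activity

# activity bookkeeping of the hot-rod phantom
p5, labels = make_derenzo(RodSpec(tbr=5))
print(total_activity(p5))          # 15.44  (MBq; 180 cm^3 rods at 10 MBq/kg,
                                   #         background at 1/5 in 7000 cm^3)

# train the desk-scale denoiser (~10 min, 1 CPU)
model, history, dataset = ex.train_desk_model(seed=0)
print(len(dataset), round(history[-1], 4))   # 1172 patches, final loss 0.0068

# held-out denoising quality at 30% of the counts
ev = ex.heldout_evaluation(model, seed=1000)
sub = ev[ev.fraction == 0.3]
print(round((sub.psnr_out - sub.psnr_in).mean(), 2))   # 3.42 dB PSNR gain
```

The numbers mean: the generated rod phantom carries exactly the booked
15.44 MBq; training converges from a normalized RMSE of 0.10 to ~0.007;
and denoised 30%-count images are ~3.4 dB closer to the full-count
reference than their (scale-corrected) inputs.

The numbered scripts under `analysis/` run the full study and write
tables under `results/`:

```bash
python analysis/01_make_phantoms.py      # phantoms + activity bookkeeping
python analysis/02_simulate_scans.py     # full and thinned planar scans
python analysis/03_train_denoiser.py     # 2000-iteration training
python analysis/04_evaluate_denoising.py # RMSE/PSNR/SSIM vs count fraction
python analysis/05_significance_tables.py# per-ROI t-test tables
python analysis/06_dosimetry.py          # conjugate view, cumulated activity, dose
```

A `lu177planar` console command exposes the same steps
(`phantoms`, `simulate`, `train`, `denoise`, `run-all`, `report`).

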