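# scdiff

Unsupervised artifact correction for cone-beam CT (CBCT) slices with a
cycle-consistent match module and a large-step conditional adversarial
diffusion module, plus a synthetic CBCT/pCT phantom simulator and the
standard image-quality metrics — everything needed to train and verify the
method at desk scale on a single CPU.

## Who this is for

Researchers in CT/CBCT image restoration who want a transparent, fully
testable reference implementation of an adversarial-diffusion corrector:
the training loop, the k-stride sampler, the SCConv feature-reconvolution
blocks and the evaluation protocol are all plain Python on numpy, with no
GPU framework required.

## The model in brief

CBCT slices x<sup>cbct</sup> and planning-CT slices x<sup>ct</sup> are
*unpaired*.  A translation generator G<sub>β</sub> fabricates a fake CBCT
ŷ<sup>cbct</sup>₀ = G<sub>β</sub>(x<sup>ct</sup>₀) (with a cycle partner
G<sub>β'</sub> and discriminators D<sub>β</sub>, D<sub>β'</sub> under
non-saturating adversarial + ℓ1 cycle losses), giving every pCT slice a
paired condition.  The diffusive module corrupts the pCT with the forward
process

    x_t = sqrt(1 - θ_t) x_{t-1} + sqrt(θ_t) ε,   ε ~ N(0, I)

and trains a conditional generator G<sub>α</sub>(x_t, ŷ<sup>cbct</sup>₀, t)
to predict the clean slice, scored by a conditional discriminator
D<sub>α</sub> with an R1 gradient penalty, under the total objective
L = λ₃ L_match + λ₄ L_diff + L_cyc.  Sampling runs the reverse process in
strides of k through the exact Gaussian posterior of the forward marginals,
so correcting a slice costs just T/k = 4 generator calls with the default
schedule (T = 1000, k = 250).  At inference the real CBCT slice replaces
the fake one as the condition.  See `docs/methods.md` for the full account.

## Worked example

```python
from pathlib import Path
from scdiff.demo import run_demo

report = run_demo(Path("demo_out"), seed=1)
print(report[["subject_id", "mae", "rmse", "psnr", "ssim"]].to_string(index=False))
```

This fabricates an unpaired synthetic thorax dataset (100 pCT + 100 CBCT
training slices at 64×64 from disjoint subjects), trains the full
six-network model for 350 iterations, corrects 20 held-out paired test
slices, and prints:

```
subject_id       mae      rmse      psnr     ssim
      cbct 43.713054 57.143852 30.884285 0.992001
     scbct 40.401491 55.822623 31.087561 0.992717
```

The `cbct` row measures the uncorrected CBCT against its ground-truth pCT
(streaks, shading, offset and noise put it ~44 HU MAE away); the `scbct`
row measures the corrected output.  Lower MAE/RMSE and higher PSNR/SSIM
for `scbct` is the desk-scale version of the method's claim: the
correction moves CBCT toward its planning CT.

The same loop is scriptable from the shell:

```sh
scdiff simulate --subjects 5 --slices 50 --size 64 --seed 1 --out data/
scdiff train --preset desk --data data/ --out run/ --seed 1
scdiff infer --checkpoint run/checkpoint_final.npz --in cbct.nii.gz --out scbct.nii.gz
scdiff evaluate --pred pred/ --ref ref/ --out report/
scdiff demo --seed 1 --out demo_out      # all of the above at once
```

## Package layout

| Module | Contents |
|---|---|
| `scdiff.volumes` | HU image I/O (NPZ, NIfTI, 16-bit PNG + sidecar, DICOM series), intensity windows, [−1, 1] normalization |
| `scdiff.schedule` | noise schedule, forward corruption, k-stride posterior sampler, single-step oracle |
| `scdiff.autodiff` / `scdiff.nn` | numpy reverse-mode autodiff (with grad-of-grad) and the layer/optimizer toolkit |
| `scdiff.scconv` | spatial + channel reconstruction units (SRU/CRU) |
| `scdiff.networks` | the six networks and the model bundle |
| `scdiff.losses` | non-saturating adversarial, R1 penalty, ℓ1 cycle, total objective |
| `scdiff.phantom` | ellipse phantoms, Radon/FBP, artifact synthesis, unpaired dataset builder |
| `scdiff.training` | joint alternating training loop, presets, checkpoints |
| `scdiff.inference` | slice/volume correction over the reverse trajectory |
| `scdiff.metrics` | MAE/RMSE/PSNR/SSIM, line profiles, ROI statistics, report tables |
| `scdiff.cli` | `scdiff simulate / train / infer / evaluate / demo` |
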