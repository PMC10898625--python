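# styleharm

Unpaired multi-site harmonization of MR images by content–style
disentangled cycle translation.

## The problem

Large imaging studies pool MRI from many sites and scanner vendors.  Images
of the same anatomy then differ in intensity, contrast and sharpness for
purely non-biological reasons, which biases every downstream measurement
(segmentation, tissue volumes, group statistics).  Supervised harmonization
needs *traveling phantoms* — the same subjects scanned at every site —
which is costly and usually unavailable.  `styleharm` implements a
harmonization model that needs only **site-labelled, unpaired** images.

## The method

Every image x_i from site i is split by two encoders into a site-invariant
spatial **content code** c_i = E^C(x_i) and a site-specific **style code**
s_i = E^S_i(x_i); a shared generator G(c, s) recombines them.  Styles for a
target site j can be *sampled* (a mapping network maps z ~ N(0, I) to a
site-j style) or *extracted* from a reference image.  Training performs
cycle translation x_i → x̃_j = G(c_i, s_j) → x̂_i = G(E^C(x̃_j), s_i) with
per-site discriminators and seven losses (adversarial, content/style
consistency, content alignment KL, style diversity, pixel+gradient cycle,
identity; weights λ = 1, 10, 10, 0.01, 1, 10, 10 — see
`docs/methods.md`).  One model harmonizes all N sites simultaneously and
supports continuous intermediate styles (1−β)s_A + βs_B.

Everything runs on a small numpy reverse-mode autodiff engine shipped with
the package — no deep-learning framework required — and every run is
bit-reproducible from its seed.

Since real multi-site MRI is access-restricted, the package includes a
first-class synthetic data module (`synthetic_sites`): nested-ellipse head
phantoms with known tissue masks, rendered under per-site intensity /
contrast / bias-field / blur / noise styles, including paired
traveling-phantom test sets that real studies lack.

## Worked example

```python
import numpy as np
import styleharm as sh
from styleharm import experiments as ex, evaluation as ev

study = ex.make_study(seed=0)                  # 3 sites, 50 train/site, 10 paired
bundle, history = ex.train_study(study, seed=0, total_steps=1500)
metrics = ex.evaluate_study(bundle, study, seed=0)

print(f"cross-site MAE unharmonized: {metrics['mean_unharmonized_mae']:.3f}")
print(f"cross-site MAE harmonized:   {metrics['mean_harmonized_mae']:.3f}")
print(f"identity-translation MAE:    {metrics['identity_mae']:.3f}")
```

On one CPU this trains in about twelve minutes and prints

```
cross-site MAE unharmonized: 0.131
cross-site MAE harmonized:   0.072
identity-translation MAE:    0.066
```

meaning: before harmonization, paired renderings of the *same anatomy* at
two sites differ by 0.131 mean absolute intensity (on the [−1, 1] scale);
after translating each image into the target site's style the difference
roughly halves, while translating an image to *its own* site changes it by
far less — appearance is transferred, anatomy is kept.

The command line mirrors the library:

```bash
styleharm simulate --sites 3 --n-train 50 --n-paired 10 --seed 1 --out data/
styleharm train    --data data/ --steps 1500 --seed 1 --out model/
styleharm harmonize --model model/model.npz --input vol.nii.gz \
                    --mode site --target-site 2 --n-styles 10 --seed 1 --out harm/
styleharm evaluate --data data/ --model model/model.npz --seed 1 --out report/
```

## Layout

| module | role |
|---|---|
| `styleharm.synthetic_sites` | multi-site phantom generator, paired test sets |
| `styleharm.volume_io` | NIfTI I/O, 2.5D slice extraction/normalization/padding with exact inversion |
| `styleharm.networks` | the five network roles on the numpy autodiff engine |
| `styleharm.losses` | the seven loss terms with oracle-tested closed forms |
| `styleharm.training` | cycle-translation training loop, checkpointing |
| `styleharm.harmonize` | site / reference / identity / interpolation inference |
| `styleharm.evaluation` | MAE, PSNR, MS-SSIM, DSC + phantom segmenter, FID/KID, volumetrics |
| `styleharm.experiments` | the end-to-end desk-scale study harness |
| `styleharm.cli` | `styleharm` command with simulate / train / harmonize / evaluate |
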