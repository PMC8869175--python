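# cytogan

Class-conditional synthesis of single-cell microscopy images for
balancing imbalanced cytology datasets, with the preparation and
evaluation tooling around it.

Hematological image collections (bone-marrow aspirate smears, peripheral
blood) are dominated by common cell families — neutrophils and
lymphocytes in the thousands — while the classes that matter most for
leukemia diagnosis (monoblasts, promyelocytes, smudge cells) may have
only tens of images. `cytogan` trains a conditional generative model and
synthesizes images for the underrepresented classes so that downstream
cell-type classifiers see a balanced training set.

## The model

The generative model is a **Wasserstein GAN with gradient penalty whose
critic carries an auxiliary classifier head**. The critic `D` minimizes

    E[D(G(z,c))] − E[D(x)] + σ·E[(‖∇x̂ D(x̂)‖₂ − 1)²] − λ·C_L,   σ = 10

with `x̂` a random interpolate between real and generated batches, and

    C_L = E[log P(C=c | x_real)] + E[log P(C=c | x_synth)]

the class log-likelihood of the auxiliary head (the critic never sees
labels as input). The generator receives noise `z` and a class embedding
for `c` and minimizes `−E[D(G(z,c))] − λ·E[log P(C=c | G(z,c))]`. Both
networks are residual up/down-sampling stacks; outputs are tanh-bounded
RGB images. Everything runs on a small NumPy autodiff engine with
second-order gradients (needed to optimize the gradient penalty), so the
package has no deep-learning framework dependency.

The package also provides:

* **dataset** — CSV manifests; cell-family merging (19 source labels →
  12 families by default), content-hash deduplication with exclusion
  lists, Reinhard stain normalization, stratified 70/30 (+20% val)
  splitting, per-class balancing deficits;
* **fixtures** — a generated "toy cell" dataset whose class identity is
  carried by nucleus hue, making class recovery measurable without any
  learned model;
* **metrics** — inception score, Fréchet distance with pluggable feature
  backbones, LPIPS-style perceptual distance, l1/l2, MSE/PSNR, SSIM,
  explicit real↔synthetic pairing strategies, and macro/per-class
  classification summaries;
* **downstream** — equally sized training conditions (original /
  synthetic / three augmentation recipes / original+synthetic) compared
  with one shared test split and one small CNN classifier.

## Worked example

```python
import numpy as np
from cytogan.fixtures import FixtureSpec, generate_fixture_dataset
from cytogan.dataset import SplitSpec, stratified_split, class_deficits
from cytogan.networks import GanConfig
from cytogan.training import TrainConfig, train, synthesize_balanced

root = "scratch/cells"
spec = FixtureSpec(image_size=32, seed=7)       # 200/200/200/10 images
manifest = stratified_split(generate_fixture_dataset(spec, root),
                            SplitSpec(seed=1))

ckpt, history = train(manifest,
                      GanConfig(n_classes=4, image_size=32, noise_dim=32,
                                base_channels=8),
                      TrainConfig(batch_size=16, epochs=6, n_critic=2,
                                  seed=11),
                      root=root)
print(len(history), history.aux_accuracy_real.tail(10).mean().round(2))

deficits = class_deficits(manifest, "max")       # {'class3': 190, ...}
synth = synthesize_balanced(ckpt, deficits, seed=17,
                            out_dir=f"{root}/synthetic",
                            class_names=manifest.labels())
counts = manifest.concat(synth).class_counts
print(dict(counts))
```

This prints `126 0.89` — 126 generator iterations were recorded and the
auxiliary classifier identifies the cell class of ~89% of real images in
the final epoch — followed by
`{'class0': 200, 'class1': 200, 'class2': 200, 'class3': 200}`: the
minority class has been filled to exactly the largest class count.
During this run the median hue error of class-conditional samples
(measured by the fixture's hue oracle) falls from ~84° at epoch 1 to
~24° at epoch 6, i.e., the generator learns to produce the right class.

The same flow is available from the shell:

```
cytogan fixtures --classes 4 --counts 200,200,200,10 --size 32 --seed 7 --out cells/
cytogan prepare  --sources cells/manifest.csv --root cells --out manifest.csv
cytogan train    --manifest manifest.csv --root cells --config cfg.yaml --out runs/exp1
cytogan synthesize --checkpoint runs/exp1/checkpoint_epoch006.npz \
                   --manifest manifest.csv --deficits auto --seed 17 --out synth/
cytogan evaluate --real manifest.csv --synthetic synth/manifest.csv \
                 --real-root cells --synth-root synth --out report.json
cytogan classify --original manifest.csv --synthetic synth/manifest.csv \
                 --target-n 280 --root cells --seed 0 --out comparison.json
```

See `docs/methods.md` for the model details, the evaluation conventions
(covariance normalization, SSIM window, pairing strategies) and the
desk-scale study conditions.

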