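"""Downstream classification comparison across dataset conditions.

Trains one small classifier per condition — original, synthetic,
three named augmentation recipes, and original+synthetic — on equally
sized, class-stratified training sets, and evaluates every condition on
one shared held-out test split.  This is the desk-scale analog of
comparing transfer-learning backbones on original versus GAN-balanced
data: the point is the relative ordering of conditions, in particular
whether adding balanced synthetic images raises minority-class
sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from PIL import Image
from skimage import color as skcolor
from skimage import transform as sktransform

from . import metrics
from .dataset import ConfigError, DatasetManifest, ImageRecord
from .engine import nn
from .engine import tensor as T
from .networks import Batch

KNOWN_OPS = ("scaling", "rotation", "color-jitter", "translation",
             "contrast", "saturation")

#: Named augmentation recipes (op order matters; parameters drawn from the
#: ranges in DEFAULT_RANGES).
RECIPES: dict[str, tuple[str, ...]] = {
    "none": (),
    "augmentation-1": ("scaling", "rotation", "color-jitter"),
    "augmentation-2": ("translation", "contrast", "scaling"),
    "augmentation-3": ("saturation", "scaling", "rotation"),
}

DEFAULT_RANGES = {
    "scaling": (0.8, 1.2),        # zoom factor
    "rotation": (-30.0, 30.0),    # degrees
    "color-jitter": (-10.0, 10.0),  # hue shift, degrees
    "translation": (-0.1, 0.1),   # fraction of image size
    "contrast": (0.8, 1.2),       # gain about the mean
    "saturation": (0.8, 1.2),     # HSV saturation gain
}


@dataclass
class AugmentationSpec:
    name: str
    ops: tuple[str, ...] = ()
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name in RECIPES and not self.ops:
            self.ops = RECIPES[self.name]
        unknown = set(self.ops) - set(KNOWN_OPS)
        if unknown:
            raise ConfigError(f"unknown augmentation ops: {sorted(unknown)}")
        for op in self.ops:
            self.ranges.setdefault(op, DEFAULT_RANGES[op])


def _apply_op(img: np.ndarray, op: str, lo: float, hi: float,
              rng: np.random.Generator) -> np.ndarray:
    """Apply one label-preserving transform to an HWC image in [0, 1]."""
    if op == "scaling":
        f = rng.uniform(lo, hi)
        h = img.shape[0]
        zoomed = sktransform.rescale(img, f, channel_axis=-1, mode="edge",
                                     anti_aliasing=f < 1)
        zh = zoomed.shape[0]
        if zh >= h:
            off = (zh - h) // 2
            return zoomed[off:off + h, off:off + h]
        pad = (h - zh) // 2
        out = np.pad(zoomed, ((pad, h - zh - pad), (pad, h - zh - pad),
                              (0, 0)), mode="edge")
        return out
    if op == "rotation":
        return sktransform.rotate(img, rng.uniform(lo, hi), mode="edge")
    if op == "translation":
        h = img.shape[0]
        dy, dx = rng.uniform(lo, hi, size=2) * h
        tf = sktransform.AffineTransform(translation=(dx, dy))
        return sktransform.warp(img, tf.inverse, mode="edge")
    if op == "contrast":
        gain = rng.uniform(lo, hi)
        mean = img.mean(axis=(0, 1), keepdims=True)
        return np.clip((img - mean) * gain + mean, 0, 1)
    if op == "color-jitter":
        hsv = skcolor.rgb2hsv(img)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(lo, hi) / 360.0) % 1.0
        return skcolor.hsv2rgb(hsv)
    if op == "saturation":
        hsv = skcolor.rgb2hsv(img)
        hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(lo, hi), 0, 1)
        return skcolor.hsv2rgb(hsv)
    raise ConfigError(f"unknown op {op!r}")


def augment(batch: Batch, spec: AugmentationSpec) -> Batch:
    """Apply the recipe to every image; deterministic given spec.seed."""
    if not spec.ops:
        return Batch(images=batch.images.copy(), labels=batch.labels.copy())
    rng = np.random.default_rng(spec.seed)
    out = np.empty_like(batch.images)
    for i in range(len(batch)):
        img = (batch.images[i].astype(np.float64) + 1.0) / 2.0
        for op in spec.ops:
            lo, hi = spec.ranges[op]
            img = _apply_op(img, op, lo, hi, rng)
        out[i] = np.clip(img, 0, 1) * 2.0 - 1.0
    return Batch(images=out, labels=batch.labels.copy())


# ---------------------------------------------------------------------------
# condition construction
# ---------------------------------------------------------------------------

def _stratified_take(manifest: DatasetManifest, target_n: int,
                     rng: np.random.Generator) -> DatasetManifest:
    """Sample target_n records keeping the manifest's class proportions
    (largest-remainder rounding, so totals are exact)."""
    counts = manifest.class_counts
    total = manifest.total()
    if target_n > total:
        raise ConfigError(f"target_n {target_n} exceeds pool size {total}")
    labels = sorted(counts)
    quota = {c: target_n * counts[c] / total for c in labels}
    take = {c: int(np.floor(quota[c])) for c in labels}
    remainder = target_n - sum(take.values())
    for c in sorted(labels, key=lambda c: quota[c] - take[c],
                    reverse=True)[:remainder]:
        take[c] += 1
    by_class: dict[str, list[ImageRecord]] = {c: [] for c in labels}
    for r in manifest.records:
        by_class[r.label].append(r)
    chosen: list[ImageRecord] = []
    for c in labels:
        idx = rng.choice(len(by_class[c]), size=take[c], replace=False)
        chosen.extend(by_class[c][i] for i in sorted(idx))
    return DatasetManifest(chosen)


def build_conditions(original: DatasetManifest, synthetic: DatasetManifest,
                     target_n: int, seed: int = 0,
                     aug_names: tuple[str, ...] = ("augmentation-1",
                                                   "augmentation-2",
                                                   "augmentation-3"),
                     ) -> dict[str, DatasetManifest]:
    """Build equally sized training conditions.

    original / augmentation-k conditions are stratified subsamples of the
    original pool (augmentation recipes are applied at training time);
    the synthetic condition draws from the synthetic pool; the
    original+synthetic condition draws from the union of both pools, so
    when the synthetic pool was produced by balanced synthesis the class
    mix of the combined condition moves toward balance while the total
    stays fixed.
    """
    rng = np.random.default_rng(seed)
    conditions: dict[str, DatasetManifest] = {}
    conditions["original"] = _stratified_take(original, target_n, rng)
    conditions["synthetic"] = _stratified_take(synthetic, target_n, rng)
    for name in aug_names:
        conditions[name] = _stratified_take(original, target_n, rng)
    conditions["original+synthetic"] = _stratified_take(
        original.concat(synthetic), target_n, rng)
    for name, man in conditions.items():
        assert man.total() == target_n, name
    return conditions


# ---------------------------------------------------------------------------
# small classifier
# ---------------------------------------------------------------------------

class SmallCNN(nn.Module):
    """Three conv blocks (conv-BN-ReLU-avgpool) and a linear head."""

    def __init__(self, n_classes: int, rng: np.random.Generator,
                 channels: tuple[int, int, int] = (8, 16, 32)):
        super().__init__()
        chans = [3, *channels]
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], 3, rng)
                      for i in range(3)]
        self.bns = [nn.BatchNorm2d(c) for c in channels]
        self.head: nn.Linear | None = None
        self._rng = rng
        self.n_classes = n_classes

    def forward(self, x: T.Tensor) -> T.Tensor:
        h = x
        for conv, bn in zip(self.convs, self.bns):
            h = T.avgpool2x(T.relu(bn(conv(h))))
        h = T.mean_(h, axis=(1, 2))
        if self.head is None:
            self.head = nn.Linear(h.shape[1], self.n_classes, self._rng)
        return self.head(h)


@dataclass
class TrainedClassifier:
    model: SmallCNN
    classes: list[str]
    input_size: int
    history: list[dict]

    def predict(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        self.model.eval()
        preds = []
        with T.no_grad():
            for i in range(0, len(images), batch_size):
                x = T.Tensor(np.asarray(images[i:i + batch_size],
                                        dtype=np.float32))
                preds.append(np.argmax(self.model(x).data, axis=1))
        self.model.train()
        return np.concatenate(preds)


ARCH_REGISTRY: dict[str, Callable] = {}


def register_arch(name: str):
    def deco(fn):
        ARCH_REGISTRY[name] = fn
        return fn
    return deco


@register_arch("small-cnn")
def _small_cnn(n_classes: int, rng: np.random.Generator) -> SmallCNN:
    return SmallCNN(n_classes, rng)


def _resize_batch(images: np.ndarray, size: int) -> np.ndarray:
    if images.shape[1] == size:
        return images
    out = np.empty((len(images), size, size, 3), dtype=np.float32)
    for i, img in enumerate(images):
        arr = ((img + 1) / 2 * 255).astype(np.uint8)
        im = Image.fromarray(arr).resize((size, size), Image.BILINEAR)
        out[i] = np.asarray(im, dtype=np.float32) / 255.0 * 2 - 1
    return out


def train_classifier(train_man: DatasetManifest, val_man: DatasetManifest,
                     arch: str = "small-cnn", root=".", seed: int = 0,
                     input_size: int = 32, epochs: int = 30,
                     batch_size: int = 64, lr: float = 2e-3,
                     patience: int = 5,
                     augmentation: AugmentationSpec | None = None,
                     ) -> TrainedClassifier:
    """Train a classifier with early stopping on validation loss."""
    from .training import load_images

    classes = sorted(set(train_man.labels()) | set(val_man.labels()))
    if len(classes) < 2:
        raise ValueError("at least 2 classes required for training")
    if arch not in ARCH_REGISTRY:
        raise ConfigError(f"unknown classifier arch {arch!r}; "
                          f"registered: {sorted(ARCH_REGISTRY)}")
    rng = np.random.default_rng(seed)
    tb = load_images(train_man, input_size, root)
    vb = load_images(val_man, input_size, root)
    # load_images indexes labels by each manifest's own sorted label set;
    # re-index both against the union so indices agree
    tr_labels = np.array([classes.index(r.label) for r in train_man.records])
    va_labels = np.array([classes.index(r.label) for r in val_man.records])
    x_train = _resize_batch(tb.images, input_size)
    x_val = _resize_batch(vb.images, input_size)
    if augmentation is not None and augmentation.ops:
        x_train = augment(Batch(images=x_train, labels=tr_labels),
                          augmentation).images

    model = ARCH_REGISTRY[arch](len(classes), rng)
    model(T.Tensor(x_train[:1]))  # materialize lazy head
    opt = nn.Adam(model.parameters(), lr=lr, betas=(0.9, 0.999))
    n = len(x_train)
    best_val = np.inf
    best_state: dict | None = None
    bad_epochs = 0
    history: list[dict] = []
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            x = T.Tensor(x_train[idx])
            logits = model(x)
            logp = T.log_softmax(logits, axis=1)
            rows = T.take_rows(
                T.reshape(logp, (-1,)),
                np.arange(len(idx)) * len(classes) + tr_labels[idx])
            loss = -T.mean_(rows)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss = _nll(model, x_val, va_labels, len(classes))
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-5:
            best_val = val_loss
            best_state = model.named_state()
            best_state = {k: v.copy() for k, v in best_state.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    if best_state is not None:
        model.load_state(best_state)
    return TrainedClassifier(model=model, classes=classes,
                             input_size=input_size, history=history)


def _nll(model: SmallCNN, x: np.ndarray, y: np.ndarray, k: int) -> float:
    model.eval()
    with T.no_grad():
        total, count = 0.0, 0
        for i in range(0, len(x), 256):
            logits = model(T.Tensor(x[i:i + 256]))
            logp = T.log_softmax(logits, axis=1).data
            total += -logp[np.arange(len(logp)), y[i:i + 256]].sum()
            count += len(logp)
    model.train()
    return float(total / count)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    conditions: dict[str, dict]
    classes: list[str]
    condition_sizes: dict[str, int]

    def as_dict(self) -> dict:
        return {"classes": self.classes,
                "condition_sizes": self.condition_sizes,
                "conditions": self.conditions}


def compare_conditions(conditions: dict[str, DatasetManifest],
                       test_man: DatasetManifest, val_man: DatasetManifest,
                       arch: str = "small-cnn", seed: int = 0, root=".",
                       roots: dict[str, object] | None = None,
                       input_size: int = 32,
                       epochs: int = 30) -> ComparisonReport:
    """Train one classifier per condition, evaluate all on one test set.

    ``roots`` optionally maps condition names to image roots (needed when
    synthetic images live in a different directory).
    """
    from .training import load_images

    classes = sorted(test_man.labels())
    test_batch = load_images(test_man, input_size, root)
    test_labels = np.array([classes.index(r.label)
                            for r in test_man.records])
    x_test = _resize_batch(test_batch.images, input_size)
    out: dict[str, dict] = {}
    sizes: dict[str, int] = {}
    for name, man in conditions.items():
        cond_root = (roots or {}).get(name, root)
        aug = (AugmentationSpec(name=name, seed=seed)
               if name in RECIPES and name != "none" else None)
        clf = train_classifier(man, val_man, arch=arch, root=cond_root,
                               seed=seed, input_size=input_size,
                               epochs=epochs, augmentation=aug)
        pred = clf.predict(x_test)
        cm = np.zeros((len(classes), len(classes)), dtype=int)
        np.add.at(cm, (test_labels, pred), 1)
        out[name] = metrics.prf(cm)
        out[name]["confusion"] = cm.tolist()
        sizes[name] = man.total()
    return ComparisonReport(conditions=out, classes=classes,
                            condition_sizes=sizes)
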