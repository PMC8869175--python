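"""Alternating WGAN-GP training with an auxiliary-classifier critic, and
class-balancing synthesis from a trained checkpoint."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from PIL import Image

from . import losses
from .dataset import DatasetManifest, ImageRecord, TaxonomyError
from .engine import nn
from .engine import tensor as T
from .engine.tensor import Tensor
from .networks import (Batch, Checkpoint, Critic, GanConfig, Generator,
                       build_critic, build_generator)

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow common conditional-WGAN-GP practice for this problem:
    learning rate 1e-3, batch size 64, 50 epochs, gradient-penalty
    coefficient sigma=10, equal class-loss weight, five critic steps per
    generator step, Adam with betas (0.5, 0.9).
    """

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    n_critic: int = 5
    sigma: float = 10.0
    lambda_cls: float = 1.0
    seed: int = 0
    betas: tuple[float, float] = (0.5, 0.9)
    uniform_class_sampling: bool = False
    iterations_per_epoch: int | None = None  # default: derived from data

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size, epochs must be > 0")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.sigma < 0 or self.lambda_cls < 0:
            raise ValueError("sigma and lambda_cls must be >= 0")


class TrainingDiverged(FloatingPointError):
    def __init__(self, term: str, epoch: int, iteration: int):
        super().__init__(
            f"non-finite loss term {term!r} at epoch {epoch}, "
            f"iteration {iteration}")
        self.term, self.epoch, self.iteration = term, epoch, iteration


def load_images(manifest: DatasetManifest, image_size: int,
                root=".") -> Batch:
    """Load manifest images as an NHWC batch in [-1, 1].

    Images are resized (bilinear) when their size differs from the GAN
    resolution.  Labels are indexed by the manifest's sorted label set.
    """
    root = Path(root)
    labels = manifest.labels()
    label_to_idx = {c: i for i, c in enumerate(labels)}
    imgs = np.empty((len(manifest), image_size, image_size, 3),
                    dtype=np.float32)
    y = np.empty(len(manifest), dtype=np.int64)
    for i, r in enumerate(manifest.records):
        with Image.open(root / r.path) as im:
            im = im.convert("RGB")
            if im.size != (image_size, image_size):
                im = im.resize((image_size, image_size), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float32) / 255.0
        imgs[i] = arr * 2.0 - 1.0
        y[i] = label_to_idx[r.label]
    return Batch(images=imgs, labels=y)


def train(data: DatasetManifest, gan_cfg: GanConfig, train_cfg: TrainConfig,
          root=".", out_dir=None,
          epoch_hook: Callable[[int, Generator], None] | None = None,
          ) -> tuple[Checkpoint, pd.DataFrame]:
    """Train the conditional GAN on the manifest's train split.

    Returns the final checkpoint and a history frame with one row per
    generator iteration (all loss terms plus auxiliary-classifier
    accuracy on the real batch).  Fully deterministic given the seed.
    """
    train_split = data.subset("train")
    if len(train_split) == 0:
        # accept unsplit manifests: train on everything
        train_split = data
    class_names = data.labels()
    if len(class_names) != gan_cfg.n_classes:
        raise ValueError(
            f"manifest has {len(class_names)} classes, config expects "
            f"{gan_cfg.n_classes}")

    rng = np.random.default_rng(train_cfg.seed)
    batch = load_images(train_split, gan_cfg.image_size, root)
    n = len(batch)
    bs = min(train_cfg.batch_size, n)

    generator = build_generator(gan_cfg, seed=int(rng.integers(2 ** 31)))
    critic = build_critic(gan_cfg, seed=int(rng.integers(2 ** 31)))
    opt_g = nn.Adam(generator.parameters(), lr=train_cfg.learning_rate,
                    betas=train_cfg.betas)
    opt_c = nn.Adam(critic.parameters(), lr=train_cfg.learning_rate,
                    betas=train_cfg.betas)

    # fake labels drawn from empirical class frequencies (or uniform)
    class_freq = np.bincount(batch.labels, minlength=gan_cfg.n_classes)
    probs = (np.full(gan_cfg.n_classes, 1 / gan_cfg.n_classes)
             if train_cfg.uniform_class_sampling
             else class_freq / class_freq.sum())

    iters = train_cfg.iterations_per_epoch or max(1, n // bs)
    history: list[dict] = []

    def real_batch():
        idx = rng.choice(n, size=bs, replace=False)
        return Tensor(batch.images[idx]), batch.labels[idx]

    def fake_batch(for_generator: bool):
        y = rng.choice(gan_cfg.n_classes, size=bs, p=probs)
        z = rng.standard_normal((bs, gan_cfg.noise_dim)).astype(np.float32)
        if for_generator:
            return generator(Tensor(z), y), y
        with T.no_grad():
            return Tensor(generator(Tensor(z), y).data), y

    ckpt = Checkpoint(generator=generator, critic=critic, gan_cfg=gan_cfg,
                      train_cfg=asdict(train_cfg))
    for epoch in range(1, train_cfg.epochs + 1):
        for it in range(1, iters + 1):
            c_terms: dict[str, float] = {}
            for _ in range(train_cfg.n_critic):
                xr, yr = real_batch()
                xf, yf = fake_batch(for_generator=False)
                eps = rng.uniform(size=bs)
                critic.zero_grad()
                loss_c, c_terms = losses.critic_loss(
                    critic, xr, yr, xf, yf, train_cfg.sigma,
                    train_cfg.lambda_cls, eps)
                loss_c.backward()
                opt_c.step()

            xf, yf = fake_batch(for_generator=True)
            generator.zero_grad()
            critic.zero_grad()  # graph reaches critic params; discard grads
            loss_g, g_terms = losses.generator_loss(
                critic, xf, yf, train_cfg.lambda_cls)
            loss_g.backward()
            opt_g.step()

            row = {"epoch": epoch, "iteration": it, **c_terms, **g_terms}
            for term, value in row.items():
                if term in ("epoch", "iteration"):
                    continue
                if not np.isfinite(value):
                    raise TrainingDiverged(term, epoch, it)
            history.append(row)

        ckpt.epoch = epoch
        if out_dir is not None:
            ckpt.opt_state = {"generator": opt_g.state(),
                              "critic": opt_c.state()}
            ckpt.save(Path(out_dir) / f"checkpoint_epoch{epoch:03d}.npz")
        if epoch_hook is not None:
            epoch_hook(epoch, generator)
        log.info("epoch %d/%d done", epoch, train_cfg.epochs)

    ckpt.opt_state = {"generator": opt_g.state(), "critic": opt_c.state()}
    hist = pd.DataFrame(history)
    if out_dir is not None:
        hist.to_csv(Path(out_dir) / "history.csv", index=False)
    return ckpt, hist


def synthesize_balanced(checkpoint: Checkpoint,
                        deficits: Mapping[str, int], seed: int,
                        out_dir, class_names: list[str] | None = None,
                        batch_size: int = 64) -> DatasetManifest:
    """Generate ``deficits[label]`` images per class from the checkpoint.

    Class indices follow the sorted label order used at training time.
    Returns a manifest whose records carry source="synthetic".
    """
    out_dir = Path(out_dir)
    generator = checkpoint.generator.eval()
    if class_names is None:
        class_names = [f"class{k}"
                       for k in range(checkpoint.gan_cfg.n_classes)]
    name_to_idx = {c: i for i, c in enumerate(sorted(class_names))}
    unknown = set(deficits) - set(name_to_idx)
    if unknown:
        raise TaxonomyError(f"unknown classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    records: list[ImageRecord] = []
    for label in sorted(deficits):
        count = int(deficits[label])
        if count == 0:
            continue
        (out_dir / label).mkdir(parents=True, exist_ok=True)
        made = 0
        while made < count:
            m = min(batch_size, count - made)
            imgs = generator.sample(np.full(m, name_to_idx[label]), rng)
            imgs = (imgs + 1.0) / 2.0 * 255.0
            for j in range(m):
                rel = f"{label}/synthetic_{label}_{made + j:05d}.png"
                Image.fromarray(np.clip(imgs[j], 0, 255).astype(np.uint8)
                                ).save(out_dir / rel)
                records.append(ImageRecord(path=rel, label=label,
                                           source="synthetic"))
            made += m
    generator.train()
    return DatasetManifest(records)
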