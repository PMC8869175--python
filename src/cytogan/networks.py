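"""Conditional generator and auxiliary-classifier critic architectures.

The generator maps (noise, class label) to an RGB image in [-1, 1]: the
noise vector and a learned class embedding are each densely projected and
reshaped to 4x4 feature maps, concatenated channel-wise, passed through a
stack of residual upsampling blocks, batch-normalized, and finished with a
3x3 convolution and tanh.

The critic is label-blind: it receives only images and produces two heads,
an unbounded Wasserstein realness score and class logits from an auxiliary
classifier.  It uses layer normalization rather than batch normalization
because the gradient penalty is a per-sample statement and must not couple
samples through batch statistics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .engine import nn
from .engine import tensor as T
from .engine.tensor import Tensor


@dataclass
class GanConfig:
    """Architecture hyperparameters.

    image_size must be a power of two >= 16; the number of residual
    up/down blocks is derived as log2(image_size / 4).
    """

    n_classes: int
    image_size: int = 128
    noise_dim: int = 128
    base_channels: int = 64
    embed_dim: int | None = None

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        n = self.image_size
        if n < 16 or (n & (n - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 16")
        if self.embed_dim is None:
            self.embed_dim = self.noise_dim

    @property
    def n_resblocks(self) -> int:
        return int(np.log2(self.image_size // 4))

    def channel_widths(self) -> list[int]:
        """Channel count at each resolution from 4x4 up to image_size."""
        n = self.n_resblocks
        return [self.base_channels * 2 ** min(n - i, 3) for i in range(n + 1)]


@dataclass
class Batch:
    """Images as float NHWC in [-1, 1] with integer class labels."""

    images: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError("images must be (N, H, W, 3)")
        if self.labels.shape != (self.images.shape[0],):
            raise ValueError("labels must be one per image")

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class CriticOutput:
    source_score: Tensor  # (N,) unbounded Wasserstein scores
    class_logits: Tensor  # (N, K)


class ResBlockUp(nn.Module):
    """Pre-activation residual block that doubles H and W.

    Main path: BN - ReLU - upsample - conv3x3 - BN - ReLU - conv3x3.
    Skip path: upsample (+ 1x1 projection when channel counts differ).
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.bn1 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.proj = (nn.Conv2d(in_ch, out_ch, 1, rng)
                     if in_ch != out_ch else None)

    def forward(self, x: Tensor) -> Tensor:
        h = T.relu(self.bn1(x))
        h = self.conv1(T.upsample2x(h))
        h = self.conv2(T.relu(self.bn2(h)))
        skip = T.upsample2x(x)
        if self.proj is not None:
            skip = self.proj(skip)
        return h + skip


class ResBlockDown(nn.Module):
    """Pre-activation residual block that halves H and W.

    Main path: LN - LeakyReLU - conv3x3 - LN - LeakyReLU - conv3x3 - avgpool.
    Skip path: avgpool (+ 1x1 projection when channel counts differ).
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = nn.LayerNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.ln2 = nn.LayerNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.proj = (nn.Conv2d(in_ch, out_ch, 1, rng)
                     if in_ch != out_ch else None)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] % 2 or x.shape[2] % 2:
            raise ValueError(
                f"odd spatial size {x.shape[1:3]} into down block")
        h = T.leaky_relu(self.ln1(x), 0.2)
        h = self.conv1(h)
        h = self.conv2(T.leaky_relu(self.ln2(h), 0.2))
        h = T.avgpool2x(h)
        skip = T.avgpool2x(x)
        if self.proj is not None:
            skip = self.proj(skip)
        return h + skip


class Generator(nn.Module):
    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        widths = cfg.channel_widths()
        ch0 = widths[0]
        self.label_ch = max(ch0 // 4, 1)
        self.noise_ch = ch0 - self.label_ch
        self.fc_noise = nn.Linear(cfg.noise_dim, self.noise_ch * 16, rng)
        self.embed = nn.Embedding(cfg.n_classes, cfg.embed_dim, rng)
        self.fc_label = nn.Linear(cfg.embed_dim, self.label_ch * 16, rng)
        self.blocks = [ResBlockUp(widths[i], widths[i + 1], rng)
                       for i in range(cfg.n_resblocks)]
        self.bn_out = nn.BatchNorm2d(widths[-1])
        self.conv_out = nn.Conv2d(widths[-1], 3, 3, rng)

    def forward(self, noise, labels) -> Tensor:
        labels = np.asarray(labels)
        if labels.min() < 0 or labels.max() >= self.cfg.n_classes:
            raise ValueError("label out of range")
        z = (noise if isinstance(noise, Tensor)
             else Tensor(np.asarray(noise, dtype=np.float32)))
        n = z.shape[0]
        hz = T.reshape(self.fc_noise(z), (n, 4, 4, self.noise_ch))
        he = T.reshape(self.fc_label(self.embed(labels)),
                       (n, 4, 4, self.label_ch))
        h = T.concat([hz, he], axis=3)
        for block in self.blocks:
            h = block(h)
        h = T.relu(self.bn_out(h))
        return T.tanh(self.conv_out(h))

    def sample(self, labels, rng: np.random.Generator) -> np.ndarray:
        """Generate images for the given labels; returns NHWC in [-1, 1]."""
        labels = np.asarray(labels)
        with T.no_grad():
            z = rng.standard_normal((len(labels), self.cfg.noise_dim))
            return self.forward(z.astype(np.float32), labels).data


class Critic(nn.Module):
    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        widths = cfg.channel_widths()[::-1]  # image_size down to 4x4
        self.conv_in = nn.Conv2d(3, widths[0], 3, rng)
        self.blocks = [ResBlockDown(widths[i], widths[i + 1], rng)
                       for i in range(cfg.n_resblocks)]
        self.head_source = nn.Linear(widths[-1], 1, rng)
        self.head_class = nn.Linear(widths[-1], cfg.n_classes, rng)

    def features(self, images) -> Tensor:
        """Penultimate pooled features (N, C); label-blind."""
        x = T.as_tensor(images)
        if x.shape[1:] != (self.cfg.image_size, self.cfg.image_size, 3):
            raise ValueError(
                f"expected (N, {self.cfg.image_size}, "
                f"{self.cfg.image_size}, 3), got {x.shape}")
        h = self.conv_in(x)
        for block in self.blocks:
            h = block(h)
        h = T.leaky_relu(h, 0.2)
        return T.mean_(h, axis=(1, 2))

    def forward(self, images) -> CriticOutput:
        feats = self.features(images)
        score = T.reshape(self.head_source(feats), (-1,))
        logits = self.head_class(feats)
        return CriticOutput(source_score=score, class_logits=logits)


def build_generator(cfg: GanConfig, seed: int = 0) -> Generator:
    return Generator(cfg, np.random.default_rng(seed))


def build_critic(cfg: GanConfig, seed: int = 0) -> Critic:
    return Critic(cfg, np.random.default_rng(seed))


CHECKPOINT_VERSION = 1


@dataclass
class Checkpoint:
    """Persisted generator/critic state plus configuration and progress."""

    generator: Generator
    critic: Critic
    gan_cfg: GanConfig
    train_cfg: dict = field(default_factory=dict)
    epoch: int = 0
    opt_state: dict = field(default_factory=dict)

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for k, v in self.generator.named_state().items():
            arrays[f"gen/{k}"] = v
        for k, v in self.critic.named_state().items():
            arrays[f"crit/{k}"] = v
        for group, state in self.opt_state.items():
            for k, v in state.items():
                arrays[f"opt/{group}/{k}"] = v
        header = json.dumps({
            "version": CHECKPOINT_VERSION,
            "epoch": self.epoch,
            "gan_cfg": asdict(self.gan_cfg),
            "train_cfg": self.train_cfg,
        })
        np.savez_compressed(path, __header__=np.frombuffer(
            header.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as npz:
            header = json.loads(bytes(npz["__header__"]).decode())
            if header["version"] != CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {header['version']}")
            cfg = GanConfig(**header["gan_cfg"])
            gen = build_generator(cfg)
            crit = build_critic(cfg)
            gen.load_state({k[4:]: npz[k] for k in npz.files
                            if k.startswith("gen/")})
            crit.load_state({k[5:]: npz[k] for k in npz.files
                             if k.startswith("crit/")})
            opt_state: dict = {}
            for k in npz.files:
                if k.startswith("opt/"):
                    _, group, name = k.split("/", 2)
                    opt_state.setdefault(group, {})[name] = npz[k]
        return cls(generator=gen, critic=crit, gan_cfg=cfg,
                   train_cfg=header["train_cfg"], epoch=header["epoch"],
                   opt_state=opt_state)
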