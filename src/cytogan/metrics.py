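"""Generative-image evaluation suite.

Distribution-level metrics (inception score, Fréchet distance) operate on
features from a pluggable backbone; paired metrics (l1/l2, MSE/PSNR, SSIM,
perceptual distance) operate on real/synthetic image pairs formed by a
recorded pairing strategy, since a GAN produces unpaired samples.
Classification quality is summarized by macro precision/recall/F1 and
per-class one-vs-rest accuracy/sensitivity/specificity.

Conventions (documented because the literature varies): Fréchet moments
use the maximum-likelihood covariance (divide by N); SSIM uses an 8-bit
dynamic range, K1=0.01, K2=0.03 and a 7x7 uniform window with unbiased
local covariances; PSNR of identical images is reported as +inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
from scipy.ndimage import uniform_filter

from .dataset import DatasetManifest
from .engine import tensor as T

__all__ = [
    "GaussianMoments", "MetricReport", "PairedBatch",
    "inception_score", "gaussian_moments", "fid", "perceptual_distance",
    "l1_l2", "mse_psnr", "ssim", "pair_images", "prf",
    "PixelBackbone", "CriticBackbone",
]


@dataclass
class GaussianMoments:
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64).ravel()
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=np.float64))
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma must be d x d for a d-dim mean")


@dataclass
class MetricReport:
    """Named scalar metrics plus the provenance needed to interpret them."""

    scalars: dict[str, float]
    provenance: dict[str, object] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {**self.scalars, "provenance": dict(self.provenance)}


@dataclass
class PairedBatch:
    """Real and synthetic images in 1-1 correspondence, same class."""

    real: np.ndarray        # (N, H, W, C) or (N, d)
    synthetic: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.real = np.asarray(self.real, dtype=np.float64)
        self.synthetic = np.asarray(self.synthetic, dtype=np.float64)
        if self.real.shape != self.synthetic.shape:
            raise ValueError("paired arrays must have equal shapes")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.real):
                raise ValueError("one label per pair required")

    def __len__(self):
        return len(self.real)


# ---------------------------------------------------------------------------
# distribution metrics
# ---------------------------------------------------------------------------

def inception_score(cond_probs: np.ndarray,
                    n_splits: int = 10) -> tuple[float, float]:
    """Exponentiated mean KL divergence between p(y|x) and p(y).

    Rows of ``cond_probs`` are per-sample class distributions.  The score
    is computed on ``n_splits`` contiguous chunks (the standard protocol)
    and reported as (mean, sd) across chunks.
    """
    p = np.asarray(cond_probs, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("cond_probs must be a non-empty N x K matrix")
    if np.any(p < -1e-12) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows must be probability vectors summing to 1")
    n_splits = max(1, min(n_splits, p.shape[0]))
    scores = []
    for chunk in np.array_split(p, n_splits):
        marginal = chunk.mean(axis=0, keepdims=True)
        kl = np.sum(chunk * (np.log(chunk + 1e-16)
                             - np.log(marginal + 1e-16)), axis=1)
        scores.append(np.exp(kl.mean()))
    return float(np.mean(scores)), float(np.std(scores))


def gaussian_moments(features: np.ndarray) -> GaussianMoments:
    """Sample mean and maximum-likelihood covariance of N x d features."""
    f = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if f.shape[0] < 2:
        raise ValueError("at least 2 samples required")
    mu = f.mean(axis=0)
    centered = f - mu
    sigma = centered.T @ centered / f.shape[0]
    return GaussianMoments(mu=mu, sigma=sigma)


def fid(a: GaussianMoments, b: GaussianMoments) -> float:
    """Fréchet distance ||mu_a - mu_b||^2 + Tr(Sa + Sb - 2(Sa Sb)^1/2).

    The matrix square root is the principal root; small negative
    eigenvalue noise from finite samples is clipped so the result is
    always >= 0.
    """
    if a.mu.size != b.mu.size:
        raise ValueError("moment dimensions differ")
    diff = a.mu - b.mu
    prod = a.sigma @ b.sigma
    covmean = np.real(scipy.linalg.sqrtm(prod))
    value = (diff @ diff + np.trace(a.sigma) + np.trace(b.sigma)
             - 2.0 * np.trace(covmean))
    return float(max(value, 0.0))


# ---------------------------------------------------------------------------
# feature backbones
# ---------------------------------------------------------------------------

class PixelBackbone:
    """Downsampled-pixel features; no pretrained weights involved.

    ``layers`` returns a coarse-to-fine pyramid of average-pooled maps so
    the perceptual distance has multiple scales to compare.
    """

    id = "pixel"

    def __init__(self, feature_size: int = 8):
        self.feature_size = feature_size

    def _pool(self, images: np.ndarray, size: int) -> np.ndarray:
        n, h, w, c = images.shape
        f = max(1, h // size)
        hh = (h // f) * f
        x = images[:, :hh, :hh, :]
        return x.reshape(n, hh // f, f, hh // f, f, c).mean(axis=(2, 4))

    def features(self, images: np.ndarray) -> np.ndarray:
        x = self._pool(np.asarray(images, dtype=np.float64),
                       self.feature_size)
        return x.reshape(len(x), -1)

    def layers(self, images: np.ndarray) -> list[np.ndarray]:
        x = np.asarray(images, dtype=np.float64)
        return [self._pool(x, s) for s in (x.shape[1], x.shape[1] // 2,
                                           self.feature_size)]

    def class_probs(self, images: np.ndarray) -> np.ndarray:
        raise NotImplementedError(
            "pixel backbone has no classifier head; use a trained critic")


class CriticBackbone:
    """Features and class probabilities from a trained critic."""

    def __init__(self, critic, batch_size: int = 64):
        self.critic = critic
        self.batch_size = batch_size
        self.id = "aux-critic"

    def _batched(self, images, fn):
        out = []
        with T.no_grad():
            for i in range(0, len(images), self.batch_size):
                out.append(fn(np.asarray(images[i:i + self.batch_size],
                                         dtype=np.float32)))
        return np.concatenate(out, axis=0)

    def features(self, images: np.ndarray) -> np.ndarray:
        return self._batched(
            images, lambda x: self.critic.features(x).data.astype(np.float64))

    def layers(self, images: np.ndarray) -> list[np.ndarray]:
        layers: list[list[np.ndarray]] = []
        with T.no_grad():
            for i in range(0, len(images), self.batch_size):
                x = T.Tensor(np.asarray(images[i:i + self.batch_size],
                                        dtype=np.float32))
                h = self.critic.conv_in(x)
                acts = []
                for block in self.critic.blocks:
                    h = block(h)
                    acts.append(h.data.astype(np.float64))
                layers.append(acts)
        return [np.concatenate([chunk[j] for chunk in layers], axis=0)
                for j in range(len(layers[0]))]

    def class_probs(self, images: np.ndarray) -> np.ndarray:
        def fn(x):
            logits = self.critic(x).class_logits.data
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            return (e / e.sum(axis=1, keepdims=True)).astype(np.float64)
        return self._batched(images, fn)


def frechet_distance(real_features: np.ndarray,
                     synth_features: np.ndarray) -> float:
    return fid(gaussian_moments(real_features),
               gaussian_moments(synth_features))


# ---------------------------------------------------------------------------
# paired metrics
# ---------------------------------------------------------------------------

def perceptual_distance(pairs: PairedBatch, backbone) -> float:
    """LPIPS-style distance: per-layer channel-normalized feature
    differences, averaged over space, layers and pairs."""
    layers_r = backbone.layers(pairs.real)
    layers_s = backbone.layers(pairs.synthetic)
    total = 0.0
    for fr, fs in zip(layers_r, layers_s):
        fr = _unit_normalize(fr)
        fs = _unit_normalize(fs)
        total += float(np.mean(np.sum((fr - fs) ** 2, axis=-1)))
    return total / len(layers_r)


def _unit_normalize(feats: np.ndarray) -> np.ndarray:
    norm = np.sqrt(np.sum(feats ** 2, axis=-1, keepdims=True)) + 1e-10
    return feats / norm


def l1_l2(pairs: PairedBatch) -> tuple[float, float]:
    """Sum of absolute and of squared differences over all pairs."""
    diff = pairs.real - pairs.synthetic
    return float(np.abs(diff).sum()), float((diff ** 2).sum())


def l1_l2_normalized(pairs: PairedBatch) -> tuple[float, float]:
    """Per-element l1 and l2, convenient for size-independent reporting."""
    l1, l2 = l1_l2(pairs)
    n = pairs.real.size
    return l1 / n, l2 / n


def mse_psnr(pairs: PairedBatch, R: float = 255.0) -> tuple[float, float]:
    """Mean squared error and PSNR = 10 log10(R^2 / MSE) in dB.

    Identical images report PSNR = +inf.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    mse = float(np.mean((pairs.real - pairs.synthetic) ** 2))
    if mse == 0.0:
        return 0.0, float("inf")
    return mse, float(10.0 * np.log10(R * R / mse))


def ssim(pairs: PairedBatch, window: int = 7, K1: float = 0.01,
         K2: float = 0.03, R: float = 255.0) -> float:
    """Mean structural similarity over pairs.

    Luminance, contrast and structure are combined as L*C*S with
    C1=(K1*R)^2, C2=(K2*R)^2, C3=C2/2 over a uniform ``window``; local
    covariances use the unbiased normalization.  Color images are scored
    per channel and averaged.
    """
    vals = [structural_similarity(r, s, window, K1, K2, R)
            for r, s in zip(pairs.real, pairs.synthetic)]
    return float(np.mean(vals))


def structural_similarity(x: np.ndarray, y: np.ndarray, window: int = 7,
                          K1: float = 0.01, K2: float = 0.03,
                          R: float = 255.0) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim == 3:  # per-channel mean
        return float(np.mean([structural_similarity(
            x[..., c], y[..., c], window, K1, K2, R)
            for c in range(x.shape[-1])]))
    if window > min(x.shape):
        raise ValueError("window larger than image")
    C1, C2 = (K1 * R) ** 2, (K2 * R) ** 2
    C3 = C2 / 2.0
    cov_norm = window ** 2 / (window ** 2 - 1)  # unbiased
    ux = uniform_filter(x, window)
    uy = uniform_filter(y, window)
    uxx = uniform_filter(x * x, window)
    uyy = uniform_filter(y * y, window)
    uxy = uniform_filter(x * y, window)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    # guard tiny negative variance from rounding
    vx = np.maximum(vx, 0.0)
    vy = np.maximum(vy, 0.0)
    sx, sy = np.sqrt(vx), np.sqrt(vy)
    L = (2 * ux * uy + C1) / (ux ** 2 + uy ** 2 + C1)
    C = (2 * sx * sy + C2) / (vx + vy + C2)
    S = (vxy + C3) / (sx * sy + C3)
    pad = window // 2
    core = (L * C * S)[pad:-pad, pad:-pad] if pad else L * C * S
    return float(core.mean())


# ---------------------------------------------------------------------------
# pairing and classification summaries
# ---------------------------------------------------------------------------

def pair_images(real: DatasetManifest, synth: DatasetManifest,
                strategy: str = "nn-within-class", seed: int = 0,
                real_root=".", synth_root=".",
                image_size: int | None = None) -> PairedBatch:
    """Pair each synthetic image with a same-class real image.

    "nn-within-class" picks the MSE-nearest real image; the alternative
    "random-within-class" draws uniformly.  Deterministic given seed.
    """
    from .training import load_images  # local import to avoid cycle

    real_classes = set(real.class_counts)
    missing = set(synth.class_counts) - real_classes
    if missing:
        raise ValueError(f"classes missing from real data: {sorted(missing)}")
    if image_size is None:
        image_size = _first_image_size(real, real_root)
    rb = load_images(real, image_size, real_root)
    sb = load_images(synth, image_size, synth_root)
    real_labels = np.array([r.label for r in real.records])
    synth_labels = np.array([r.label for r in synth.records])
    rng = np.random.default_rng(seed)
    pairs_r, pairs_s, labels = [], [], []
    for label in sorted(set(synth_labels)):
        ridx = np.flatnonzero(real_labels == label)
        sidx = np.flatnonzero(synth_labels == label)
        rimgs = rb.images[ridx].astype(np.float64)
        simgs = sb.images[sidx].astype(np.float64)
        if strategy == "nn-within-class":
            rflat = rimgs.reshape(len(rimgs), -1)
            sflat = simgs.reshape(len(simgs), -1)
            # argmin over squared distance via ||r||^2 - 2 s.r
            r2 = (rflat ** 2).sum(axis=1)
            nn = np.argmin(r2[None, :] - 2.0 * sflat @ rflat.T, axis=1)
        elif strategy == "random-within-class":
            nn = rng.integers(len(rimgs), size=len(simgs))
        else:
            raise ValueError(f"unknown pairing strategy {strategy!r}")
        pairs_r.append(rimgs[nn])
        pairs_s.append(simgs)
        labels.extend([label] * len(simgs))
    return PairedBatch(real=np.concatenate(pairs_r),
                       synthetic=np.concatenate(pairs_s),
                       labels=np.array(labels))


def _first_image_size(manifest: DatasetManifest, root) -> int:
    from PIL import Image

    with Image.open(Path(root) / manifest.records[0].path) as im:
        return im.size[0]


def prf(confusion: np.ndarray) -> dict:
    """Macro precision/recall/F1 and per-class one-vs-rest rates.

    ``confusion[i, j]`` counts samples of true class i predicted as j.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if cm.sum() == 0:
        raise ValueError("confusion matrix is all zero")
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision_c = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall_c = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        specificity_c = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
    accuracy_c = (tp + tn) / cm.sum()
    precision = float(precision_c.mean())
    recall = float(recall_c.mean())
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {
        "precision": precision,
        "recall": recall,
        "f1": float(f1),
        "per_class": {
            "precision": precision_c.tolist(),
            "recall": recall_c.tolist(),
            "sensitivity": recall_c.tolist(),
            "specificity": specificity_c.tolist(),
            "accuracy": accuracy_c.tolist(),
        },
    }


def evaluate_pair_metrics(pairs: PairedBatch, backbone=None,
                          R: float = 2.0) -> dict[str, float]:
    """All paired metrics on images in [-1, 1] (dynamic range R=2)."""
    l1n, l2n = l1_l2_normalized(pairs)
    mse, psnr = mse_psnr(pairs, R=R)
    out = {
        "l1": l1n,
        "l2": l2n,
        "mse": mse,
        "psnr": psnr,
        "ssim": ssim(pairs, R=R),
    }
    if backbone is not None:
        out["lpips"] = perceptual_distance(pairs, backbone)
    return out
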