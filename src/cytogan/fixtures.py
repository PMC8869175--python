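"""Synthetic "toy cell" image datasets with class-dependent appearance.

Each image contains one elliptical nucleus whose hue identifies the class,
drawn on a tinted background with band-limited texture.  Classes are
separable in mean-color space by construction, so conditional generators
and classifiers trained on a fixture have recoverable class structure, and
a hue-measurement oracle can score how well class-conditional samples
match their class.  This is deliberately not a cytomorphology simulation:
it provides learnable class signal, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import color as skcolor

from .dataset import DatasetManifest, ImageRecord


@dataclass
class ClassParams:
    hue: float                    # degrees in [0, 360)
    nucleus_radius_mean: float    # pixels
    nucleus_radius_sd: float      # pixels
    texture_freq: float           # cycles per image
    texture_amp: float = 0.08
    noise_sd: float = 0.02
    background_tint: tuple[float, float, float] = (0.92, 0.90, 0.95)


def default_class_params(n_classes: int,
                         image_size: int = 64) -> list[ClassParams]:
    """Evenly spaced hues (>= 60 degrees apart for <= 6 classes), radii
    spanning 8-14 px at 64 px and scaled with image size."""
    scale = image_size / 64.0
    radii = np.linspace(8, 14, n_classes) * scale
    return [ClassParams(hue=(360.0 * k / n_classes) % 360.0,
                        nucleus_radius_mean=float(radii[k]),
                        nucleus_radius_sd=1.0 * scale,
                        texture_freq=3.0 + 2.0 * k)
            for k in range(n_classes)]


@dataclass
class FixtureSpec:
    n_classes: int = 4
    per_class_counts: list[int] = field(
        default_factory=lambda: [200, 200, 200, 10])
    image_size: int = 64
    seed: int = 0
    class_params: list[ClassParams] | None = None

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if len(self.per_class_counts) != self.n_classes:
            raise ValueError("one count per class required")
        if any(c < 0 for c in self.per_class_counts):
            raise ValueError("counts must be non-negative")
        if self.class_params is None:
            self.class_params = default_class_params(self.n_classes,
                                                     self.image_size)

    def class_names(self) -> list[str]:
        return [f"class{k}" for k in range(self.n_classes)]


def render_cell(params: ClassParams, image_size: int,
                seed: int) -> np.ndarray:
    """Render one toy cell as (H, W, 3) float RGB in [0, 1].

    Deterministic given (params, image_size, seed).
    """
    rng = np.random.default_rng(seed)
    radius = float(np.clip(rng.normal(params.nucleus_radius_mean,
                                      params.nucleus_radius_sd),
                           2.0, image_size / 2 - 1))
    if params.nucleus_radius_mean >= image_size / 2:
        raise ValueError("nucleus radius exceeds image half-size")
    h = image_size
    img = np.broadcast_to(np.asarray(params.background_tint, dtype=np.float64),
                          (h, h, 3)).copy()

    # band-limited texture: sinusoid at the class frequency, random phase
    yy, xx = np.mgrid[0:h, 0:h] / h
    phase = rng.uniform(0, 2 * np.pi, size=2)
    tex = params.texture_amp * np.sin(
        2 * np.pi * params.texture_freq * xx + phase[0]) * np.sin(
        2 * np.pi * params.texture_freq * yy + phase[1])
    img += tex[..., None]

    # elliptical nucleus with class hue
    cy, cx = h / 2 + rng.uniform(-h / 8, h / 8, size=2)
    aspect = rng.uniform(0.7, 1.0)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx * h - cx) * ct + (yy * h - cy) * st
    v = -(xx * h - cx) * st + (yy * h - cy) * ct
    mask = (u / radius) ** 2 + (v / (radius * aspect)) ** 2 <= 1.0
    nucleus_rgb = skcolor.hsv2rgb(
        np.array([[[params.hue / 360.0, 0.85, 0.75]]]))[0, 0]
    img[mask] = nucleus_rgb + tex[mask, None] * 0.5

    img += rng.normal(0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def measure_hue(image: np.ndarray, saturation_min: float = 0.4) -> float:
    """Circular mean hue (degrees) of saturated pixels — the class oracle.

    Works on (H,W,3) RGB in [0,1].  Returns NaN when no pixel is
    saturated enough to belong to a nucleus.
    """
    hsv = skcolor.rgb2hsv(np.clip(image, 0, 1))
    sel = hsv[..., 1] >= saturation_min
    if not np.any(sel):
        return float("nan")
    ang = hsv[..., 0][sel] * 2 * np.pi
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float(np.degrees(mean) % 360.0)


def hue_distance(a: float, b: float) -> float:
    """Circular distance between two hues in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def generate_fixture_dataset(spec: FixtureSpec,
                             out_dir) -> DatasetManifest:
    """Write PNG images per class and return the matching manifest."""
    from pathlib import Path

    out_dir = Path(out_dir)
    records: list[ImageRecord] = []
    names = spec.class_names()
    for k, count in enumerate(spec.per_class_counts):
        cls_dir = out_dir / names[k]
        if count > 0:
            cls_dir.mkdir(parents=True, exist_ok=True)
        for j in range(count):
            img = render_cell(spec.class_params[k], spec.image_size,
                              seed=spec.seed * 1_000_003 + k * 10_007 + j)
            rel = f"{names[k]}/{names[k]}_{j:04d}.png"
            Image.fromarray((img * 255).astype(np.uint8)).save(out_dir / rel)
            records.append(ImageRecord(path=rel, label=names[k],
                                       source="fixture"))
    return DatasetManifest(records)
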