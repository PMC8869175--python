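"""Image manifests and dataset preparation.

A manifest is a CSV table with columns ``path,label,source,split`` (UTF-8,
paths relative to a configurable root).  Preparation follows the curation
pipeline of multi-source cytology collections: merge morphological
sub-labels into cell families, drop byte-identical duplicates and listed
exclusions, Reinhard stain normalization against a reference image, and a
stratified 70/30 train/test split with 20% of the training data held out
for validation.  Per-class synthesis deficits for dataset balancing are
computed against the largest (or a given target) class count.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from skimage import color

log = logging.getLogger(__name__)

SPLITS = ("train", "val", "test", "unassigned")


class ManifestFormatError(ValueError):
    """A manifest file does not have the required columns."""


class TaxonomyError(KeyError):
    """A label is not covered by the active merge taxonomy."""


class SplitError(ValueError):
    """A class is too small to be split."""


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass(frozen=True)
class ImageRecord:
    path: str
    label: str
    source: str
    split: str = "unassigned"

    def __post_init__(self):
        if self.split not in SPLITS:
            raise ValueError(f"invalid split {self.split!r}")


class DatasetManifest:
    """An ordered collection of labeled image records."""

    def __init__(self, records: Iterable[ImageRecord] = ()):
        self.records: list[ImageRecord] = list(records)

    @property
    def class_counts(self) -> Counter:
        return Counter(r.label for r in self.records)

    def total(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> list[str]:
        return sorted(self.class_counts)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(r for r in self.records if r.split == split)

    def concat(self, other: "DatasetManifest") -> "DatasetManifest":
        return DatasetManifest([*self.records, *other.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.path, r.label, r.source, r.split) for r in self.records],
            columns=["path", "label", "source", "split"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DatasetManifest":
        missing = {"path", "label"} - set(df.columns)
        if missing:
            raise ManifestFormatError(f"missing columns: {sorted(missing)}")
        if "source" not in df.columns:
            raise ManifestFormatError("missing columns: ['source']")
        split = df["split"] if "split" in df.columns else "unassigned"
        df = df.assign(split=split)
        return cls(ImageRecord(str(r.path), str(r.label), str(r.source),
                               str(r.split))
                   for r in df.itertuples(index=False))

    def write_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "DatasetManifest":
        return cls.from_frame(pd.read_csv(path, dtype=str))


def load_manifest(paths: Sequence, taxonomy: "MergeTaxonomy | None" = None,
                  strict: bool = False) -> DatasetManifest:
    """Concatenate delimited manifest files (columns path,label,source)."""
    manifest = DatasetManifest()
    for p in paths:
        part = DatasetManifest.read_csv(p)
        if strict and taxonomy is not None:
            unknown = set(part.class_counts) - set(taxonomy.source_labels())
            if unknown:
                raise TaxonomyError(
                    f"labels not in taxonomy: {sorted(unknown)}")
        manifest = manifest.concat(part)
    return manifest


@dataclass
class MergeTaxonomy:
    """Mapping from source cell-type labels to merged cell families."""

    groups: dict[str, list[str]] = field(default_factory=dict)
    passthrough: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen: Counter = Counter(self.passthrough)
        for members in self.groups.values():
            seen.update(members)
        dups = [label for label, n in seen.items() if n > 1]
        if dups:
            raise TaxonomyError(f"labels in more than one group: {dups}")

    def source_labels(self) -> set[str]:
        out = set(self.passthrough)
        for members in self.groups.values():
            out.update(members)
        return out

    def mapping(self) -> dict[str, str]:
        out = {label: label for label in self.passthrough}
        for merged, members in self.groups.items():
            for m in members:
                out[m] = merged
        return out

    def merged_labels(self) -> list[str]:
        return sorted(set(self.groups) | set(self.passthrough))

    @classmethod
    def from_yaml(cls, path) -> "MergeTaxonomy":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(groups={k: list(v) for k, v in (raw.get("groups") or {}).items()},
                   passthrough=list(raw.get("passthrough") or []))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"groups": self.groups,
                            "passthrough": self.passthrough}, fh)


#: Default cell-family merge rules: lymphocyte variants, neutrophil
#: maturation stages, bilobed promyelocytes, and the early granulocyte
#: precursors are each collapsed to one family; all other labels pass
#: through unchanged.
DEFAULT_TAXONOMY = MergeTaxonomy(
    groups={
        "lymphocyte": ["lymphocyte", "lymphocyte_atypical",
                       "lymphocyte_typical"],
        "neutrophil": ["neutrophil", "neutrophil_band",
                       "neutrophil_segmented"],
        "promyelocyte": ["promyelocyte", "promyelocyte_bilobed"],
        "immature_granulocytes": ["immature_granulocytes", "myelocyte",
                                  "metamyelocyte"],
    },
    passthrough=["basophil", "eosinophil", "erythroblast", "monoblast",
                 "monocyte", "myeloblast", "platelet", "smudge_cells"],
)


def merge_cell_types(m: DatasetManifest,
                     taxonomy: MergeTaxonomy) -> DatasetManifest:
    """Relabel records to their merged cell family; count is conserved."""
    mapping = taxonomy.mapping()
    unknown = set(m.class_counts) - set(mapping)
    if unknown:
        raise TaxonomyError(f"labels not in taxonomy: {sorted(unknown)}")
    return DatasetManifest(replace(r, label=mapping[r.label])
                           for r in m.records)


def _content_hash(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()


def dedupe(m: DatasetManifest, exclusions: Sequence[str] = (),
           root=None) -> DatasetManifest:
    """Collapse byte-identical images and drop listed exclusions.

    Exclusions may name a record path or a content hash.  Unknown
    exclusion ids are ignored with a warning.  Records whose file does
    not exist are kept (they cannot be hashed) unless excluded by path.
    """
    root = Path(root) if root is not None else Path(".")
    excl = set(exclusions)
    known: set[str] = set()
    seen_hashes: set[str] = set()
    kept: list[ImageRecord] = []
    for r in m.records:
        known.add(r.path)
        if r.path in excl:
            continue
        f = root / r.path
        if f.is_file():
            h = _content_hash(f)
            known.add(h)
            if h in excl or h in seen_hashes:
                continue
            seen_hashes.add(h)
        kept.append(r)
    unknown = excl - known
    if unknown:
        log.warning("ignoring %d unknown exclusion ids", len(unknown))
    return DatasetManifest(kept)


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    test_fraction: float = 0.30
    val_fraction_of_train: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1 and 0 < self.test_fraction < 1
                and 0 < self.val_fraction_of_train < 1):
            raise ConfigError("fractions must lie in (0, 1)")
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ConfigError("train_fraction + test_fraction must equal 1")


def stratified_split(m: DatasetManifest, spec: SplitSpec) -> DatasetManifest:
    """Assign train/val/test per class with deterministic floor rounding.

    Per class of size n: floor(n * test_fraction) test records, then
    floor(val_fraction_of_train * remainder) validation records, the rest
    train.  Identical seed gives identical assignment.
    """
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(m.records):
        by_class.setdefault(r.label, []).append(i)
    rng = np.random.default_rng(spec.seed)
    split_of = np.array(["unassigned"] * len(m.records), dtype=object)
    for label in sorted(by_class):
        idx = np.asarray(by_class[label])
        n = len(idx)
        if n < 3:
            raise SplitError(
                f"class {label!r} has {n} records; at least 3 required")
        perm = idx[rng.permutation(n)]
        n_test = int(np.floor(n * spec.test_fraction))
        n_val = int(np.floor((n - n_test) * spec.val_fraction_of_train))
        split_of[perm[:n_test]] = "test"
        split_of[perm[n_test:n_test + n_val]] = "val"
        split_of[perm[n_test + n_val:]] = "train"
    return DatasetManifest(replace(r, split=split_of[i])
                           for i, r in enumerate(m.records))


def reinhard_transfer(lab: np.ndarray, ref_mean: np.ndarray,
                      ref_std: np.ndarray) -> np.ndarray:
    """Match per-channel mean/std of a LAB image to reference statistics."""
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    std = np.where(std < 1e-8, 1.0, std)
    return (lab - mean) / std * ref_std + ref_mean


def lab_stats(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel LAB mean and std of an RGB image in [0, 1]."""
    lab = color.rgb2lab(rgb)
    flat = lab.reshape(-1, 3)
    return flat.mean(axis=0), flat.std(axis=0)


def stain_normalize(images: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Reinhard color transfer in LAB space against a reference image.

    ``images`` is (H,W,3) or (N,H,W,3) RGB in [0, 1]; ``reference`` is a
    single RGB image in [0, 1].  Output is clipped to [0, 1].
    """
    images = np.asarray(images, dtype=np.float64)
    single = images.ndim == 3
    if single:
        images = images[None]
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ConfigError("RGB input required (grayscale not supported)")
    reference = np.asarray(reference, dtype=np.float64)
    if reference.ndim != 3 or reference.shape[-1] != 3:
        raise ConfigError("RGB reference required")
    ref_mean, ref_std = lab_stats(reference)
    ref_std = np.where(ref_std < 1e-8, 1.0, ref_std)
    out = np.empty_like(images)
    for i, img in enumerate(images):
        lab = reinhard_transfer(color.rgb2lab(img), ref_mean, ref_std)
        out[i] = np.clip(color.lab2rgb(lab), 0.0, 1.0)
    return out[0] if single else out


def class_deficits(m: DatasetManifest,
                   target: int | str = "max") -> dict[str, int]:
    """Images to synthesize per class to reach the target count."""
    counts = m.class_counts
    if not counts:
        return {}
    max_count = max(counts.values())
    if target == "max":
        goal = max_count
    else:
        goal = int(target)
        if goal < max_count:
            raise ConfigError(
                f"target {goal} below largest class count {max_count}")
    return {label: goal - n for label, n in sorted(counts.items())}
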