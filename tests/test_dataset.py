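"""Manifest arithmetic, cell-family merging, splitting, dedupe, stain
normalization and balancing deficits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytogan import tables
from cytogan.dataset import (DEFAULT_TAXONOMY, ConfigError, DatasetManifest,
                             ImageRecord, ManifestFormatError, MergeTaxonomy,
                             SplitError, SplitSpec, TaxonomyError,
                             class_deficits, dedupe, lab_stats, load_manifest,
                             merge_cell_types, stain_normalize,
                             stratified_split)


def make_manifest(counts: dict, source: str = "1") -> DatasetManifest:
    records = []
    for label, n in counts.items():
        records.extend(
            ImageRecord(path=f"{source}/{label}_{i:05d}.png", label=label,
                        source=source)
            for i in range(n))
    return DatasetManifest(records)


def write_source_csvs(tmp_path):
    """Per-source manifests using the reference cytology counts."""
    paths = []
    for s in range(3):
        records = []
        for label, per_source in tables.SOURCE_COUNTS.items():
            n = per_source[s]
            for i in range(n or 0):
                records.append(ImageRecord(
                    path=f"src{s + 1}/{label}_{i:05d}.png", label=label,
                    source=str(s + 1)))
        p = tmp_path / f"source{s + 1}.csv"
        DatasetManifest(records).write_csv(p)
        paths.append(p)
    return paths


class TestLoadManifest:
    def test_counts_concatenate_across_sources(self, tmp_path):
        manifest = load_manifest(write_source_csvs(tmp_path))
        assert manifest.class_counts["eosinophil"] == 1061 + 1356 + 1121
        assert manifest.class_counts["eosinophil"] == 3538

    def test_empty_file_list_gives_empty_manifest(self):
        assert load_manifest([]).total() == 0

    def test_loading_twice_doubles_counts(self, tmp_path):
        m = make_manifest({"basophil": 5, "platelet": 3})
        p = tmp_path / "m.csv"
        m.write_csv(p)
        doubled = load_manifest([p, p])
        assert doubled.total() == 2 * m.total()
        assert doubled.class_counts["basophil"] == 10

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("path,label\na.png,basophil\n")
        with pytest.raises(ManifestFormatError):
            load_manifest([p])

    def test_strict_mode_rejects_unknown_label(self, tmp_path):
        p = tmp_path / "odd.csv"
        make_manifest({"megakaryocyte": 1}).write_csv(p)
        with pytest.raises(TaxonomyError):
            load_manifest([p], taxonomy=DEFAULT_TAXONOMY, strict=True)


class TestMergeCellTypes:
    def test_lymphocyte_family_merges(self):
        m = make_manifest({"lymphocyte": 1213, "lymphocyte_atypical": 7,
                           "lymphocyte_typical": 3818})
        merged = merge_cell_types(m, DEFAULT_TAXONOMY)
        assert merged.class_counts == {"lymphocyte": 5038}

    def test_promyelocyte_family_merges(self):
        m = make_manifest({"promyelocyte": 69, "promyelocyte_bilobed": 18})
        merged = merge_cell_types(m, DEFAULT_TAXONOMY)
        assert merged.class_counts == {"promyelocyte": 87}

    def test_passthrough_label_unchanged(self):
        m = make_manifest({"basophil": 1224})
        assert merge_cell_types(m, DEFAULT_TAXONOMY).class_counts == {
            "basophil": 1224}

    def test_full_reference_table_merges_19_labels_to_12(self):
        m = make_manifest(tables.totals_by_label())
        assert len(m.class_counts) == 19
        merged = merge_cell_types(m, DEFAULT_TAXONOMY)
        assert len(merged.class_counts) == 12
        assert merged.total() == m.total()

    def test_unknown_label_raises(self):
        with pytest.raises(TaxonomyError):
            merge_cell_types(make_manifest({"mystery": 1}), DEFAULT_TAXONOMY)

    def test_label_in_two_groups_rejected(self):
        with pytest.raises(TaxonomyError):
            MergeTaxonomy(groups={"a": ["x"], "b": ["x"]})

    @given(st.dictionaries(
        st.sampled_from(sorted(DEFAULT_TAXONOMY.source_labels())),
        st.integers(0, 50), min_size=1))
    @settings(max_examples=25, deadline=None)
    def test_merge_conserves_total(self, counts):
        m = make_manifest(counts)
        assert merge_cell_types(m, DEFAULT_TAXONOMY).total() == m.total()


class TestDedupe:
    def test_byte_identical_files_collapse(self, tmp_path):
        (tmp_path / "a.png").write_bytes(b"samebytes")
        (tmp_path / "b.png").write_bytes(b"samebytes")
        m = DatasetManifest([ImageRecord("a.png", "basophil", "1"),
                             ImageRecord("b.png", "basophil", "1")])
        assert dedupe(m, root=tmp_path).total() == 1

    def test_identity_without_duplicates(self, tmp_path):
        (tmp_path / "a.png").write_bytes(b"x")
        (tmp_path / "b.png").write_bytes(b"y")
        m = DatasetManifest([ImageRecord("a.png", "basophil", "1"),
                             ImageRecord("b.png", "basophil", "1")])
        assert dedupe(m, root=tmp_path).total() == 2

    def test_exclusion_by_path_drops_one(self):
        m = make_manifest({"basophil": 10})
        out = dedupe(m, exclusions=[m.records[3].path])
        assert out.total() == 9

    def test_idempotent(self, tmp_path):
        (tmp_path / "a.png").write_bytes(b"samebytes")
        (tmp_path / "b.png").write_bytes(b"samebytes")
        m = DatasetManifest([ImageRecord("a.png", "basophil", "1"),
                             ImageRecord("b.png", "basophil", "1")])
        once = dedupe(m, root=tmp_path)
        twice = dedupe(once, root=tmp_path)
        assert [r.path for r in once] == [r.path for r in twice]


class TestStratifiedSplit:
    def test_100_records_split_56_14_30(self):
        m = make_manifest({"basophil": 100})
        out = stratified_split(m, SplitSpec(seed=0))
        counts = {s: sum(r.split == s for r in out) for s in
                  ("train", "val", "test")}
        assert counts == {"train": 56, "val": 14, "test": 30}

    def test_deterministic_given_seed(self):
        m = make_manifest({"basophil": 50, "platelet": 20})
        a = stratified_split(m, SplitSpec(seed=3))
        b = stratified_split(m, SplitSpec(seed=3))
        assert [r.split for r in a] == [r.split for r in b]

    def test_partition_conserves_class_counts(self):
        m = make_manifest({"basophil": 37, "platelet": 11, "monocyte": 5})
        out = stratified_split(m, SplitSpec(seed=1))
        for label, n in m.class_counts.items():
            per_split = sum(r.label == label for r in out
                            if r.split in ("train", "val", "test"))
            assert per_split == n

    def test_small_class_raises_naming_it(self):
        m = make_manifest({"basophil": 10, "monoblast": 2})
        with pytest.raises(SplitError, match="monoblast"):
            stratified_split(m, SplitSpec(seed=0))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigError):
            SplitSpec(train_fraction=0.8, test_fraction=0.3)


class TestStainNormalize:
    def test_self_reference_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.2, 0.8, size=(16, 16, 3))
        out = stain_normalize(img, img)
        assert np.allclose(out, img, atol=1e-4)

    def test_constant_image_matches_constant_reference(self):
        img = np.full((8, 8, 3), 0.3)
        ref = np.full((8, 8, 3), [0.6, 0.5, 0.4])
        out = stain_normalize(img, ref)
        assert np.allclose(out, ref[0, 0], atol=1e-4)

    def test_output_lab_moments_match_reference(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.25, 0.75, size=(32, 32, 3))
        ref = rng.uniform(0.3, 0.7, size=(32, 32, 3))
        out = stain_normalize(img, ref)
        ref_mean, _ = lab_stats(ref)
        out_mean, _ = lab_stats(out)
        # in-gamut transfer: means agree closely after the rgb round-trip
        assert np.allclose(out_mean, ref_mean, atol=0.05)

    def test_grayscale_input_rejected(self):
        with pytest.raises(ConfigError):
            stain_normalize(np.zeros((8, 8)), np.zeros((8, 8, 3)))


class TestClassDeficits:
    def test_reference_counts_deficit_to_largest_class(self):
        m = make_manifest(tables.MERGED_COUNTS)
        deficits = class_deficits(m, "max")
        assert deficits["monoblast"] == 10743 - 26 == 10717
        assert deficits["neutrophil"] == 0

    def test_balanced_manifest_has_zero_deficits(self):
        m = make_manifest({"a": 5, "b": 5})
        assert set(class_deficits(m, "max").values()) == {0}

    def test_numeric_target_below_max_rejected(self):
        with pytest.raises(ConfigError):
            class_deficits(make_manifest({"a": 10, "b": 2}), 5)

    @given(st.dictionaries(st.sampled_from("abcdef"), st.integers(1, 500),
                           min_size=1))
    @settings(max_examples=25, deadline=None)
    def test_deficit_plus_count_equals_target(self, counts):
        m = make_manifest(counts)
        target = max(counts.values()) + 7
        deficits = class_deficits(m, target)
        for label, n in counts.items():
            assert deficits[label] + n == target


def test_reinhard_moment_transfer_is_exact():
    """The LAB-space moment matching itself is exact to float precision."""
    from cytogan.dataset import reinhard_transfer

    rng = np.random.default_rng(2)
    lab = rng.normal(50, 10, size=(24, 24, 3))
    ref_mean = np.array([60.0, 5.0, -3.0])
    ref_std = np.array([8.0, 4.0, 2.0])
    out = reinhard_transfer(lab, ref_mean, ref_std)
    flat = out.reshape(-1, 3)
    assert np.allclose(flat.mean(axis=0), ref_mean, atol=1e-6)
    assert np.allclose(flat.std(axis=0), ref_std, atol=1e-6)
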