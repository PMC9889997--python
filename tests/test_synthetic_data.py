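"""Synthetic corpus: rendering, augmentation, split hygiene, separability."""

import numpy as np
import pytest

from jujubenet.synthetic_data import (
    AUGMENTATION_TAGS,
    CLASS_NAMES,
    AugmentConfig,
    apply_augmentation,
    build_dataset,
    load_manifest,
    load_split,
    render_base_image,
    split_dataset,
)

# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def test_render_is_deterministic_and_sized():
    a = render_base_image("moldy", 5, 11, 64)
    b = render_base_image("moldy", 5, 11, 64)
    assert np.array_equal(a, b)
    assert a.shape == (64, 64, 3) and a.dtype == np.uint8
    assert render_base_image("normal", 0, 0, 96).shape == (96, 96, 3)


def test_render_rejects_bad_inputs():
    with pytest.raises(ValueError, match="unknown class"):
        render_base_image("rotten", 0, 0)
    with pytest.raises(ValueError, match="at least 32"):
        render_base_image("normal", 0, 0, size=16)


@pytest.mark.parametrize("label", [c for c in CLASS_NAMES if c != "normal"])
def test_defect_classes_differ_from_normal(label):
    defect = render_base_image(label, 2, 5, 64)
    normal = render_base_image("normal", 2, 5, 64)
    frac = (defect != normal).any(axis=2).mean()
    assert frac > 0.005


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def test_flip_twice_with_same_draw_restores_original(rng):
    img = render_base_image("cracked", 0, 1, 64)
    once = apply_augmentation(img, "flip", np.random.default_rng(3))
    twice = apply_augmentation(once, "flip", np.random.default_rng(3))
    assert np.array_equal(twice, img)


def test_gaussian_noise_moments(rng):
    img = np.full((224, 224, 3), 128, dtype=np.uint8)
    cfg = AugmentConfig(noise_sigma=8.0)
    noisy = apply_augmentation(img, "gaussian_noise", rng, cfg)
    deltas = noisy.astype(np.float64) - 128.0
    assert abs(deltas.std() - 8.0) / 8.0 < 0.05
    assert abs(deltas.mean()) < 0.5
    clean = apply_augmentation(img, "gaussian_noise", rng, AugmentConfig(noise_sigma=0.0))
    assert np.array_equal(clean, img)


def test_crop_and_hybrid_preserve_shape(rng):
    img = render_base_image("wrinkled", 1, 2, 64)
    for method in ("random_crop", "hybrid"):
        out = apply_augmentation(img, method, rng)
        assert out.shape == img.shape and out.dtype == np.uint8


def test_original_tag_is_not_a_transform(rng):
    with pytest.raises(ValueError, match="copied"):
        apply_augmentation(np.zeros((32, 32, 3), np.uint8), "original", rng)


# ---------------------------------------------------------------------------
# Corpus assembly and split hygiene
# ---------------------------------------------------------------------------

def test_small_corpus_counts_and_files(corpus10, tmp_path):
    m = corpus10
    assert len(m.records) == 300  # 6 classes * 10 bases * 5 files
    assert m.counts_by_split() == {"train": 210, "test": 60, "val": 30}
    from pathlib import Path
    for r in m.records[:10]:
        assert (Path(m.root) / r.path).exists()


def test_rebuild_same_seed_is_byte_identical(tmp_path):
    m1 = build_dataset(10, tmp_path / "a", seed=5, image_size=32)
    m2 = build_dataset(10, tmp_path / "b", seed=5, image_size=32)
    csv_a = (tmp_path / "a" / "manifest.csv").read_bytes()
    csv_b = (tmp_path / "b" / "manifest.csv").read_bytes()
    assert csv_a == csv_b
    r = m1.records[17]
    img_a = (tmp_path / "a" / r.path).read_bytes()
    img_b = (tmp_path / "b" / r.path).read_bytes()
    assert img_a == img_b


def test_split_is_a_stratified_partition_without_leakage(corpus10):
    m = corpus10
    # every base has exactly 5 records, one per tag, all in one split
    by_base = {}
    for r in m.records:
        by_base.setdefault((r.label, r.base_id), []).append(r)
    for recs in by_base.values():
        assert sorted(r.tag for r in recs) == sorted(AUGMENTATION_TAGS)
        assert len({r.split for r in recs}) == 1
    # class balance inside every split
    for split, want in (("train", 35), ("test", 10), ("val", 5)):
        recs = m.select(split)
        for label in CLASS_NAMES:
            assert sum(1 for r in recs if r.label == label) == want
    # base-id sets pairwise disjoint per class
    for label in CLASS_NAMES:
        sets = [
            {r.base_id for r in m.records if r.label == label and r.split == s}
            for s in ("train", "test", "val")
        ]
        assert sets[0] | sets[1] | sets[2] == set(range(10))
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])


def test_indivisible_base_count_is_rejected():
    with pytest.raises(ValueError, match="divisible by 10"):
        build_dataset(15, materialize=False)
    manifest = build_dataset(10, materialize=False)
    with pytest.raises(ValueError, match="not divisible"):
        split_dataset(manifest, ratios=(5, 2, 1))  # 10 bases over total 8


def test_full_scale_manifest_counts():
    m = build_dataset(2000, materialize=False)
    assert len(m.records) == 60_000
    assert m.counts_by_split() == {"train": 42_000, "test": 12_000, "val": 6_000}


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def test_load_split_counts_and_noop_resize(corpus10):
    items = list(load_split(corpus10, "test"))
    assert len(items) == 60
    img, label = items[0]
    assert img.shape == (32, 32, 3) and 0 <= label < 6
    # stored at 32 and loaded at 32: byte-identical pixels
    from pathlib import Path
    from PIL import Image
    rec = corpus10.select("test")[0]
    raw = np.asarray(Image.open(Path(corpus10.root) / rec.path))
    assert np.array_equal(items[0][0], raw)


def test_load_split_shuffle_is_deterministic(corpus10):
    a = [lab for _, lab in load_split(corpus10, "val", shuffle_seed=4)]
    b = [lab for _, lab in load_split(corpus10, "val", shuffle_seed=4)]
    c = [lab for _, lab in load_split(corpus10, "val", shuffle_seed=5)]
    assert a == b
    assert a != c


def test_manifest_csv_roundtrip(corpus10, tmp_path):
    path = tmp_path / "m.csv"
    corpus10.to_csv(path)
    loaded = load_manifest(path, root=corpus10.root)
    assert [vars(r) for r in loaded.records] == [vars(r) for r in corpus10.records]


def test_missing_file_is_named(corpus10):
    m = build_dataset(10, materialize=False, seed=corpus10.seed)
    m.root = corpus10.root
    m.records[0] = type(m.records[0])("train/normal/999999_original.png", "normal",
                                      "train", 999999, "original")
    with pytest.raises(FileNotFoundError, match="999999"):
        next(iter(load_split(m, "train")))
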