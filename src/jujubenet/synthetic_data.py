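"""Procedural stand-in for a six-class fruit surface-defect image corpus.

Real acquisition-platform data (single jujube per frame on a roller
conveyor) is emulated by drawing a shaded red-brown ellipse on a dark
textured background and stamping one of five defect signatures on it:

* ``deformed`` — low-frequency radial perturbation of the fruit boundary;
* ``wrinkled`` — high-frequency sinusoidal luminance ridges;
* ``cracked`` — a dark connected polyline across the fruit;
* ``moldy`` — a cluster of desaturated gray-green blotches;
* ``bird_pecked`` — a small near-circular dark excision at the fruit edge;
* ``normal`` — no signature.

Every base image receives random pose, scale and hue jitter from a
generator seeded by ``(seed, class, base_id)``, so the corpus is a pure
function of its configuration. Each base image contributes itself plus one
image per augmentation method (Gaussian noise, random crop, hybrid
photometric jitter, random flip), a 5x enhancement; splits are assigned at
base-image level, stratified per class in a 7:2:1 train/test/val ratio, so
augmented near-duplicates never straddle splits.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "CLASS_NAMES",
    "AUGMENTATION_TAGS",
    "AugmentConfig",
    "DatasetManifest",
    "ManifestRecord",
    "render_base_image",
    "apply_augmentation",
    "build_dataset",
    "split_dataset",
    "load_split",
    "load_manifest",
]

CLASS_NAMES = ("deformed", "wrinkled", "cracked", "moldy", "bird_pecked", "normal")
CLASS_CODES = {name: i for i, name in enumerate(CLASS_NAMES)}
AUGMENTATION_TAGS = ("original", "gaussian_noise", "random_crop", "hybrid", "flip")
SPLITS = ("train", "test", "val")
SPLIT_RATIOS = (7, 2, 1)


@dataclass(frozen=True)
class AugmentConfig:
    """Magnitudes of the four enhancement methods."""

    noise_sigma: float = 8.0           # intensity levels on the 0..255 scale
    crop_fraction: tuple = (0.70, 0.95)
    jitter_range: tuple = (0.8, 1.2)   # contrast/brightness/saturation factors


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: str
    split: str
    base_id: int
    tag: str


@dataclass
class DatasetManifest:
    records: list = field(default_factory=list)
    seed: int = 0
    image_size: int = 224
    root: str = "."

    def counts_by_split(self) -> dict:
        out = {s: 0 for s in SPLITS}
        for r in self.records:
            out[r.split] += 1
        return out

    def select(self, split: str) -> list:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}; choose from {SPLITS}")
        return [r for r in self.records if r.split == split]

    def to_csv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label", "split", "base_id", "tag"])
            for r in self.records:
                writer.writerow([r.path, r.label, r.split, r.base_id, r.tag])


def load_manifest(path, root: str | None = None, seed: int = 0,
                  image_size: int = 224) -> DatasetManifest:
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(ManifestRecord(row["path"], row["label"], row["split"],
                                          int(row["base_id"]), row["tag"]))
    return DatasetManifest(records, seed=seed, image_size=image_size,
                           root=root if root is not None else str(path.parent))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, size: int, scale: float, sigma: float):
    return gaussian_filter(rng.normal(0.0, scale, (size, size)), sigma, mode="reflect")


def render_base_image(label: str, base_id: int, seed: int, size: int = 224) -> np.ndarray:
    """Deterministically render one synthetic fruit image (H x W x 3 uint8)."""
    if label not in CLASS_CODES:
        raise ValueError(f"unknown class label {label!r}; choose from {CLASS_NAMES}")
    if size < 32:
        raise ValueError(f"image size must be at least 32, got {size}")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, CLASS_CODES[label], base_id])
    )
    S = size
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float32)

    # dark textured conveyor background
    base = rng.uniform(28, 40)
    img = np.empty((S, S, 3), dtype=np.float32)
    tex = _smooth_noise(rng, S, 6.0, S / 24)
    img[..., 0] = base + 6 + tex
    img[..., 1] = base + tex
    img[..., 2] = base - 4 + tex

    # fruit pose: center, axes, rotation
    cx, cy = S / 2 + rng.uniform(-S / 16, S / 16, 2)
    a = S * rng.uniform(0.27, 0.34)
    b = a * rng.uniform(0.72, 0.92)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)  # 1.0 on the ellipse boundary
    phi = np.arctan2(yr / b, xr / a)

    boundary = np.ones_like(rho)
    if label == "deformed":
        # strong low-frequency radial dents
        n_lobes = int(rng.integers(2, 4))
        phase = rng.uniform(0, 2 * np.pi)
        boundary += 0.22 * np.sin(n_lobes * phi + phase) + 0.10 * np.sin(
            (n_lobes + 1) * phi - phase
        )
    mask = rho < boundary
    rho_n = np.clip(rho / np.maximum(boundary, 1e-6), 0, 1)

    # shaded red-brown skin with hue jitter and a specular highlight
    r0 = 150 + rng.uniform(-18, 18)
    g0 = 36 + rng.uniform(-8, 8)
    b0 = 30 + rng.uniform(-8, 8)
    shade = 1.0 - 0.55 * rho_n**2
    hx, hy = cx - a * 0.3, cy - b * 0.3
    spec = 40 * np.exp(-(((xx - hx) ** 2 + (yy - hy) ** 2) / (0.02 * S * S)))
    skin_tex = _smooth_noise(rng, S, 5.0, S / 40)
    fr = r0 * shade + spec + skin_tex
    fg = g0 * shade + 0.5 * spec + 0.5 * skin_tex
    fb = b0 * shade + 0.5 * spec + 0.5 * skin_tex

    if label == "wrinkled":
        alpha = rng.uniform(0, np.pi)
        freq = rng.uniform(10, 16) * 2 * np.pi / S
        ridges = 1.0 + 0.28 * np.sin(freq * (xx * np.cos(alpha) + yy * np.sin(alpha)))
        fr, fg, fb = fr * ridges, fg * ridges, fb * ridges

    img[mask, 0] = fr[mask]
    img[mask, 1] = fg[mask]
    img[mask, 2] = fb[mask]

    if label == "cracked":
        # dark connected polyline across the fruit
        t = np.linspace(-1.0, 1.0, 160)
        wobble = np.cumsum(rng.normal(0, 0.05, t.size))
        wobble -= np.linspace(wobble[0], wobble[-1], t.size)
        ang = rng.uniform(0, np.pi)
        px = cx + t * a * 0.9 * np.cos(ang) - wobble * a * 0.5 * np.sin(ang)
        py = cy + t * a * 0.9 * np.sin(ang) + wobble * a * 0.5 * np.cos(ang)
        width = max(1.2, S / 56)
        crack = np.zeros((S, S), dtype=bool)
        for x0, y0 in zip(px, py):
            lo_y, hi_y = int(max(0, y0 - width - 1)), int(min(S, y0 + width + 2))
            lo_x, hi_x = int(max(0, x0 - width - 1)), int(min(S, x0 + width + 2))
            if lo_y >= hi_y or lo_x >= hi_x:
                continue
            sub = (yy[lo_y:hi_y, lo_x:hi_x] - y0) ** 2 + (xx[lo_y:hi_y, lo_x:hi_x] - x0) ** 2
            crack[lo_y:hi_y, lo_x:hi_x] |= sub < width**2
        crack &= mask
        img[crack] = img[crack] * 0.22

    elif label == "moldy":
        blotch = np.zeros((S, S), dtype=np.float32)
        n_blotch = int(rng.integers(4, 8))
        inside = np.argwhere(rho_n < 0.7)
        for _ in range(n_blotch):
            cyb, cxb = inside[rng.integers(len(inside))]
            rad = S * rng.uniform(0.04, 0.08)
            blotch += np.exp(-(((xx - cxb) ** 2 + (yy - cyb) ** 2) / (0.5 * rad**2)))
        blotch = np.clip(blotch, 0, 1) * mask
        mold_color = np.array([110.0, 118.0, 96.0], dtype=np.float32)  # gray-green
        w = blotch[..., None] * 0.85
        img = img * (1 - w) + mold_color * w

    elif label == "bird_pecked":
        edge_phi = rng.uniform(0, 2 * np.pi)
        ex = cx + a * 0.92 * np.cos(edge_phi) * ct - b * 0.92 * np.sin(edge_phi) * st
        ey = cy + a * 0.92 * np.cos(edge_phi) * st + b * 0.92 * np.sin(edge_phi) * ct
        rad = S * rng.uniform(0.05, 0.08)
        peck = ((xx - ex) ** 2 + (yy - ey) ** 2) < rad**2
        peck &= mask
        img[peck, 0] = 55 + 0.2 * skin_tex[peck]
        img[peck, 1] = 30
        img[peck, 2] = 22
        rim = (((xx - ex) ** 2 + (yy - ey) ** 2) < (rad * 1.25) ** 2) & ~peck & mask
        img[rim] *= 0.6

    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _resize(img: np.ndarray, size: int) -> np.ndarray:
    pil = Image.fromarray(img).resize((size, size), Image.BILINEAR)
    return np.asarray(pil)


def apply_augmentation(img: np.ndarray, method: str, rng: np.random.Generator,
                       config: AugmentConfig | None = None) -> np.ndarray:
    """Apply one enhancement method; output shape equals input shape."""
    cfg = config or AugmentConfig()
    if method == "original":
        raise ValueError("originals are copied, not transformed")
    if method not in AUGMENTATION_TAGS:
        raise ValueError(f"unknown augmentation {method!r}; choose from {AUGMENTATION_TAGS[1:]}")
    H, W = img.shape[:2]
    if method == "gaussian_noise":
        noise = rng.normal(0.0, cfg.noise_sigma, img.shape)
        return np.clip(np.round(img.astype(np.float64) + noise), 0, 255).astype(np.uint8)
    if method == "random_crop":
        fh = rng.uniform(*cfg.crop_fraction)
        fw = rng.uniform(*cfg.crop_fraction)
        ch, cw = max(1, int(round(H * fh))), max(1, int(round(W * fw)))
        top = int(rng.integers(0, H - ch + 1))
        left = int(rng.integers(0, W - cw + 1))
        crop = img[top : top + ch, left : left + cw]
        pil = Image.fromarray(crop).resize((W, H), Image.BILINEAR)
        return np.asarray(pil)
    if method == "hybrid":
        x = img.astype(np.float32)
        contrast, brightness, saturation = rng.uniform(*cfg.jitter_range, size=3)
        x = (x - x.mean()) * contrast + x.mean()
        x = x * brightness
        gray = x.mean(axis=2, keepdims=True)
        x = gray + (x - gray) * saturation
        return np.clip(np.round(x), 0, 255).astype(np.uint8)
    # flip: horizontal or vertical with probability 1/2 each
    axis = 1 if rng.random() < 0.5 else 0
    return np.ascontiguousarray(np.flip(img, axis=axis))


# ---------------------------------------------------------------------------
# Corpus assembly
# ---------------------------------------------------------------------------

def split_dataset(manifest: DatasetManifest, ratios: tuple = SPLIT_RATIOS,
                  seed: int | None = None) -> DatasetManifest:
    """Assign 7:2:1 splits at base-image level, stratified per class.

    All augmented records of a base image inherit its split, so
    near-duplicates never leak between train and test.
    """
    seed = manifest.seed if seed is None else seed
    total = sum(ratios)
    by_class: dict[str, list[int]] = {}
    for r in manifest.records:
        by_class.setdefault(r.label, [])
        if r.base_id not in by_class[r.label]:
            by_class[r.label].append(r.base_id)
    assignment: dict[tuple, str] = {}
    for label in sorted(by_class):
        bases = sorted(set(by_class[label]))
        if len(bases) % total:
            raise ValueError(
                f"class {label!r} has {len(bases)} base images, not divisible by "
                f"{total}; adjust n_per_class to a multiple of {total}"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, CLASS_CODES[label], 9999])
        )
        order = rng.permutation(len(bases))
        n_train = len(bases) * ratios[0] // total
        n_test = len(bases) * ratios[1] // total
        for rank, idx in enumerate(order):
            split = "train" if rank < n_train else ("test" if rank < n_train + n_test else "val")
            assignment[(label, bases[idx])] = split
    new_records = [
        ManifestRecord(
            _record_path(assignment[(r.label, r.base_id)], r.label, r.base_id, r.tag),
            r.label, assignment[(r.label, r.base_id)], r.base_id, r.tag,
        )
        for r in manifest.records
    ]
    return DatasetManifest(new_records, seed=seed, image_size=manifest.image_size,
                           root=manifest.root)


def _record_path(split: str, label: str, base_id: int, tag: str) -> str:
    return f"{split}/{label}/{base_id:06d}_{tag}.png"


def _augmentation_rng(seed: int, label: str, base_id: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [seed & 0x7FFFFFFF, CLASS_CODES[label], base_id, AUGMENTATION_TAGS.index(tag)]
        )
    )


def build_dataset(n_per_class: int = 2000, out_dir: str | Path = ".", seed: int = 0,
                  image_size: int = 224, augment_config: AugmentConfig | None = None,
                  materialize: bool = True) -> DatasetManifest:
    """Render the full corpus: ``6 * n_per_class`` bases, 5 files per base.

    With ``materialize=False`` only the manifest is computed (no images are
    written); record counts, splits and paths are identical either way.
    """
    if n_per_class < 5:
        raise ValueError("n_per_class must be at least 5")
    if n_per_class % 10:
        raise ValueError(
            f"n_per_class={n_per_class} is not divisible by 10, so an exact 7:2:1 "
            f"base-level split is impossible; choose a multiple of 10"
        )
    out_dir = Path(out_dir)
    records = [
        ManifestRecord(_record_path("train", label, i, tag), label, "train", i, tag)
        for label in CLASS_NAMES
        for i in range(n_per_class)
        for tag in AUGMENTATION_TAGS
    ]
    manifest = DatasetManifest(records, seed=seed, image_size=image_size, root=str(out_dir))
    manifest = split_dataset(manifest, seed=seed)

    if materialize:
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg = augment_config or AugmentConfig()
        base_cache: dict[tuple, np.ndarray] = {}
        for r in manifest.records:
            key = (r.label, r.base_id)
            if key not in base_cache:
                base_cache.clear()  # records are grouped per base; keep one
                base_cache[key] = render_base_image(r.label, r.base_id, seed, image_size)
            base = base_cache[key]
            if r.tag == "original":
                img = base
            else:
                img = apply_augmentation(base, r.tag, _augmentation_rng(seed, r.label, r.base_id, r.tag), cfg)
            dest = out_dir / r.path
            dest.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(img).save(dest)
        (out_dir / "generator_config.json").write_text(json.dumps({
            "n_per_class": n_per_class,
            "seed": seed,
            "image_size": image_size,
            "classes": list(CLASS_NAMES),
            "augmentations": list(AUGMENTATION_TAGS),
            "augment_config": vars(cfg) if not hasattr(cfg, "__dataclass_fields__")
            else {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
            "split_ratios": list(SPLIT_RATIOS),
        }, indent=2, default=list))
        manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def load_split(manifest: DatasetManifest, split: str, image_size: int | None = None,
               shuffle_seed: int | None = None):
    """Yield ``(image uint8 HxWx3, integer label)`` pairs for one split.

    Order is the manifest order, or a deterministic shuffle when
    ``shuffle_seed`` is given. Images are resized bilinearly if needed.
    """
    image_size = image_size if image_size is not None else manifest.image_size
    records = manifest.select(split)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed & 0x7FFFFFFF).permutation(len(records))
        records = [records[i] for i in order]
    root = Path(manifest.root)
    for r in records:
        path = root / r.path
        if not path.exists():
            raise FileNotFoundError(f"manifest image missing on disk: {path}")
        img = np.asarray(Image.open(path).convert("RGB"))
        if img.shape[0] != image_size:
            img = _resize(img, image_size)
        yield img, CLASS_CODES[r.label]
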