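"""Palette label codec, random cropping, 4:1:1 splits and the 7-method augmentation.

Labels travel on disk as palette-coded RGB PNGs: tree blue (0,0,255), shrub
green (0,255,0), grass red (255,0,0), NVA magenta (255,0,255). In memory a
label is a 1-based uint8 class map.

Augmentation expands every source sample to ``expansion_factor`` outputs
(default 6: the original plus 5 variants, matching a 2,500 -> 15,000
expansion). Each variant composes 1-3 of the seven methods drawn uniformly
without replacement: x-symmetry, y-symmetry, panning (±5% of the edge), HSV
channel jitter (x0.9-1.1 per channel), scaling (x0.9-1.1), rotation (±5°
about the centre) and Gaussian noise (mean 0, variance 0.1 on intensities
scaled to [0,1]). All selected geometric methods are composed into a single
affine resampling pass — image bilinear, label nearest-neighbour — and any
content moved beyond the frame is cropped while exposed regions are filled
(label -> NVA, image -> the NVA base colour), so output size never changes.
Photometric methods never touch the label. Every variant carries a
transform log from which the geometric part can be replayed exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._kernels import hsv_scale, warp_bilinear, warp_nearest
from .scene_sim import _BASE_COLORS, MIN_IMAGE_SIZE, N_CLASSES, Scene

logger = logging.getLogger(__name__)

#: class id -> RGB triple (bijective)
PALETTE = {1: (0, 0, 255), 2: (0, 255, 0), 3: (255, 0, 0), 4: (255, 0, 255)}

NVA_CLASS = 4
NVA_FILL = _BASE_COLORS[NVA_CLASS - 1]

AUGMENT_METHODS = ("sym_x", "sym_y", "pan", "hsv", "scale", "rotate", "noise")
_GEOMETRIC = frozenset({"sym_x", "sym_y", "pan", "scale", "rotate"})


class CodecError(ValueError):
    pass


@dataclass(frozen=True)
class AugmentConfig:
    pan_range: float = 0.05          # ± fraction of the image edge
    hsv_range: tuple = (0.9, 1.1)    # multiplicative, per HSV channel
    rot_range: float = 5.0           # ± degrees
    noise_mean: float = 0.0
    noise_var: float = 0.1           # on [0,1]-scaled intensities
    scale_range: tuple = (0.9, 1.1)
    expansion_factor: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")


@dataclass
class Dataset:
    """A list of scenes with a role and source/augmented bookkeeping counts."""

    samples: list
    role: str = "train"  # train | validation | test | transfer
    m_source: int = 0
    m_augmented: int = 0

    def __post_init__(self):
        if self.role not in ("train", "validation", "test", "transfer"):
            raise ValueError(f"unknown dataset role {self.role!r}")
        if not self.m_source:
            self.m_source = len(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


# --------------------------------------------------------------- label codec

_ENCODE_LUT = np.zeros((N_CLASSES + 1, 3), dtype=np.uint8)
for _cid, _rgb in PALETTE.items():
    _ENCODE_LUT[_cid] = _rgb

_DECODE_LUT = {}
for _cid, (_r, _g, _b) in PALETTE.items():
    _DECODE_LUT[(_r << 16) | (_g << 8) | _b] = _cid


def encode_label(class_map: np.ndarray) -> np.ndarray:
    """Class map (values 1..4) -> palette RGB raster."""
    class_map = np.asarray(class_map)
    if class_map.size == 0 or class_map.min() < 1 or class_map.max() > N_CLASSES:
        raise CodecError("class map values must lie in 1..4")
    return _ENCODE_LUT[class_map]


def decode_label(rgb: np.ndarray) -> np.ndarray:
    """Palette RGB raster -> class map; off-palette pixels raise naming the coordinate."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise CodecError(f"expected an H x W x 3 raster, got shape {rgb.shape}")
    packed = (
        (rgb[..., 0].astype(np.int64) << 16)
        | (rgb[..., 1].astype(np.int64) << 8)
        | rgb[..., 2].astype(np.int64)
    )
    out = np.zeros(packed.shape, dtype=np.uint8)
    for key, cid in _DECODE_LUT.items():
        out[packed == key] = cid
    if (out == 0).any():
        y, x = np.argwhere(out == 0)[0]
        raise CodecError(
            f"off-palette pixel {tuple(int(v) for v in rgb[y, x])} at (row={y}, col={x})"
        )
    return out


def encode_label_png(class_map: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(encode_label(class_map), mode="RGB").save(path)


# ------------------------------------------------------------------ cropping

def crop_samples(
    image: np.ndarray,
    label: np.ndarray,
    size: int = 400,
    n: int = 1,
    seed: int = 0,
    min_size: int = MIN_IMAGE_SIZE,
) -> list[Scene]:
    """Cut ``n`` random ``size`` x ``size`` crops with identical image/label windows."""
    image = np.asarray(image)
    label = np.asarray(label)
    if image.shape[:2] != label.shape:
        raise ValueError("image and label must share spatial dimensions")
    h, w = label.shape
    if size < min_size:
        raise ValueError(f"crop size {size} below minimum {min_size}")
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image dims {h}x{w}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        y0 = int(rng.integers(0, h - size + 1))
        x0 = int(rng.integers(0, w - size + 1))
        out.append(
            Scene(
                image=np.ascontiguousarray(image[y0:y0 + size, x0:x0 + size]),
                label=np.ascontiguousarray(label[y0:y0 + size, x0:x0 + size]),
                scene_id=f"crop{i:05d}",
            )
        )
    return out


# ----------------------------------------------------------------- splitting

def split_dataset(ds: Dataset, ratios=(4, 1, 1), seed: int = 0):
    """Disjoint (train, validation, test) cover with sizes proportional to ``ratios``.

    The integer remainder goes to the training split, so 15,000 samples at
    4:1:1 become 10,000 / 2,500 / 2,500.
    """
    n = len(ds)
    total = sum(ratios)
    if n < total:
        raise ValueError(f"dataset of {n} samples too small to split {ratios}")
    n_val = n * ratios[1] // total
    n_test = n * ratios[2] // total
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = order[:n_val]
    test_idx = order[n_val:n_val + n_test]
    train_idx = order[n_val + n_test:]
    pick = lambda idx, role: Dataset([ds.samples[i] for i in sorted(idx)], role=role)
    return pick(train_idx, "train"), pick(val_idx, "validation"), pick(test_idx, "test")


# -------------------------------------------------------------- augmentation

def _affine_params(methods, rng, cfg: AugmentConfig, h: int, w: int) -> dict:
    """Draw the random parameters of the selected geometric methods."""
    p = {}
    if "sym_x" in methods:
        p["sym_x"] = True
    if "sym_y" in methods:
        p["sym_y"] = True
    if "pan" in methods:
        p["pan_y"] = float(rng.uniform(-cfg.pan_range, cfg.pan_range) * h)
        p["pan_x"] = float(rng.uniform(-cfg.pan_range, cfg.pan_range) * w)
    if "scale" in methods:
        p["scale"] = float(rng.uniform(*cfg.scale_range))
    if "rotate" in methods:
        p["angle_deg"] = float(rng.uniform(-cfg.rot_range, cfg.rot_range))
    return p


def _affine_matrix(p: dict, h: int, w: int):
    """Inverse (output -> source) affine about the image centre, row/col order."""
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # forward transform: flip -> scale -> rotate -> pan; invert analytically
    a = math.radians(p.get("angle_deg", 0.0))
    s = p.get("scale", 1.0)
    cos_a, sin_a = math.cos(a), math.sin(a)
    # inverse rotation+scale (rotation in (row, col) plane)
    inv = np.array([[cos_a, sin_a], [-sin_a, cos_a]]) / s
    fy = -1.0 if p.get("sym_x") else 1.0  # x-symmetry: mirror across horizontal axis
    fx = -1.0 if p.get("sym_y") else 1.0
    flip = np.diag([fy, fx])
    m = flip @ inv
    t = np.array([p.get("pan_y", 0.0), p.get("pan_x", 0.0)])
    # source = flip @ inv @ (out - centre - pan) + centre
    offset = -m @ (np.array([cy, cx]) + t) + np.array([cy, cx])
    return m, offset


def apply_transform_label(label: np.ndarray, log: dict) -> np.ndarray:
    """Replay the geometric part of a transform log on a label raster."""
    p = log["affine"]
    if not p:
        return label.copy()
    h, w = label.shape
    m, off = _affine_matrix(p, h, w)
    return warp_nearest(
        np.ascontiguousarray(label), m[0, 0], m[0, 1], m[1, 0], m[1, 1],
        off[0], off[1], NVA_CLASS,
    )


def _apply_variant(scene: Scene, methods, rng, cfg: AugmentConfig):
    h, w = scene.label.shape
    p = _affine_params(methods, rng, cfg, h, w)
    log = {"methods": list(methods), "affine": p}
    image, label = scene.image, scene.label
    if p:
        m, off = _affine_matrix(p, h, w)
        image = warp_bilinear(
            np.ascontiguousarray(image), m[0, 0], m[0, 1], m[1, 0], m[1, 1],
            off[0], off[1], *NVA_FILL,
        )
        label = warp_nearest(
            np.ascontiguousarray(label), m[0, 0], m[0, 1], m[1, 0], m[1, 1],
            off[0], off[1], NVA_CLASS,
        )
    else:
        image = image.copy()
        label = label.copy()
    if "hsv" in methods:
        fh, fs, fv = (float(rng.uniform(*cfg.hsv_range)) for _ in range(3))
        log["hsv"] = [fh, fs, fv]
        image = hsv_scale(image, fh, fs, fv)
    if "noise" in methods:
        # variance interpreted on [0,1]-scaled intensities; applied in uint8 units
        noise = rng.standard_normal(image.shape, dtype=np.float32)
        noise *= math.sqrt(cfg.noise_var) * 255.0
        noise += cfg.noise_mean * 255.0
        out = image.astype(np.float32)
        out += noise
        np.clip(out, 0.0, 255.0, out=out)
        image = (out + 0.5).astype(np.uint8)
        log["noise"] = True
    return Scene(image=image, label=label, params=scene.params, shift=scene.shift), log


def augment_sample(scene: Scene, config: AugmentConfig, rng: np.random.Generator):
    """One source scene -> ``expansion_factor`` scenes (the original plus variants).

    Returns ``(scenes, logs)``; the original carries an empty log. Every
    variant composes 1-3 of the seven methods drawn uniformly without
    replacement.
    """
    scenes = [replace(scene, image=scene.image.copy(), label=scene.label.copy())]
    logs = [{"methods": [], "affine": {}}]
    for _ in range(config.expansion_factor - 1):
        k = int(rng.integers(1, 4))
        methods = tuple(rng.choice(AUGMENT_METHODS, size=k, replace=False))
        variant, log = _apply_variant(scene, methods, rng, config)
        scenes.append(variant)
        logs.append(log)
    return scenes, logs


def _sample_rng(config: AugmentConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


def iter_augmented(samples, config: AugmentConfig):
    """Stream ``(source_index, scene, log)`` over the augmented expansion of ``samples``.

    Memory-light equivalent of :func:`augment_dataset`: per-sample RNG
    streams are derived from ``(config.seed, sample index)`` so the two
    agree exactly.
    """
    for i, scene in enumerate(samples):
        rng = _sample_rng(config, i)
        scenes, logs = augment_sample(scene, config, rng)
        for s, log in zip(scenes, logs):
            yield i, s, log


def augment_dataset(ds: Dataset, config: AugmentConfig) -> Dataset:
    """Materialised augmentation: MA = expansion_factor x M."""
    if not ds.samples:
        raise ValueError("cannot augment an empty dataset")
    out = [scene for _, scene, _ in iter_augmented(ds.samples, config)]
    return Dataset(out, role=ds.role, m_source=len(ds.samples), m_augmented=len(out))


# ------------------------------------------------------------------ manifest

def write_manifest(path, ds: Dataset, logs=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "role": ds.role,
        "M": ds.m_source,
        "MA": ds.m_augmented or len(ds),
        "samples": [s.scene_id or f"sample{i:05d}" for i, s in enumerate(ds.samples)],
    }
    if logs is not None:
        payload["transforms"] = logs
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
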