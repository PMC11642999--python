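"""Corpus engineering: perceptual-hash deduplication, stratified splitting,
and class-balancing augmentation.

When several public image collections are merged into one corpus, the same
photograph frequently appears more than once, sometimes trivially re-encoded
or shifted. Perceptual hashes (difference hash / average hash) fingerprint
the visual content so that near-duplicates land within a small Hamming
distance of each other and can be grouped and dropped before splitting —
otherwise copies of one image leak across the train/test boundary.

Splitting is stratified per class: an outer 80:20 train/test cut followed by
an inner 80:20 train/validation cut, yielding 64/16/20 overall. Class
imbalance is then repaired on the training side only, by synthesizing
affine-perturbed copies (rotation, shift, shear, zoom, horizontal flip —
magnitudes chosen to perturb pose without destroying anatomy) until every
class reaches the target count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidArgumentError
from .synthetic import ImageFixture

HASH_ALGORITHMS = ("dhash", "ahash")

#: Luma weights for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class HashRecord:
    """A 64-bit perceptual hash of one image."""

    image_id: str
    hash: int
    algorithm: str

    def __post_init__(self) -> None:
        if not 0 <= self.hash < (1 << 64):
            raise InvalidArgumentError(f"hash must be a 64-bit value, got {self.hash:#x}")
        if self.algorithm not in HASH_ALGORITHMS:
            raise InvalidArgumentError(
                f"algorithm must be one of {HASH_ALGORITHMS}, got {self.algorithm!r}"
            )


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale (float); 2-D input passes through as float."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[2] == 3:
        return pixels @ _LUMA
    raise InvalidArgumentError(f"expected HxW or HxWx3 pixel grid, got shape {pixels.shape}")


def _overlap_weights(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic matrix averaging n_in cells into n_out equal intervals."""
    w = np.zeros((n_out, n_in))
    step = n_in / n_out
    for i in range(n_out):
        lo, hi = i * step, (i + 1) * step
        for j in range(int(math.floor(lo)), int(math.ceil(hi))):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / step


def area_average(gray: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Exact area-averaged downscale of a 2-D grid to (out_h, out_w)."""
    gray = np.asarray(gray, dtype=float)
    return _overlap_weights(out_h, gray.shape[0]) @ gray @ _overlap_weights(out_w, gray.shape[1]).T


def _pack_bits(bits: np.ndarray) -> int:
    """Row-major bits, most significant bit first, into a 64-bit integer."""
    value = 0
    for b in bits.ravel():
        value = (value << 1) | int(bool(b))
    return value


def perceptual_hash(
    pixels: np.ndarray, algorithm: str = "dhash", image_id: str = ""
) -> HashRecord:
    """64-bit perceptual hash of a pixel grid.

    ``dhash``: grayscale, area-average to an 8-row x 9-column grid, one bit
    per horizontally adjacent pair (left > right). ``ahash``: area-average
    to 8x8, one bit per cell at or above the grid mean. Both emit bits in
    row-major order, most significant bit first. Comparisons treat cells
    within 1e-8 as equal so that float round-off in the averaging cannot
    flip bits of analytically tied cells (e.g. a constant image hashes to 0).
    """
    if algorithm not in HASH_ALGORITHMS:
        raise InvalidArgumentError(
            f"algorithm must be one of {HASH_ALGORITHMS}, got {algorithm!r}"
        )
    gray = to_grayscale(pixels)
    if gray.shape[0] < 9 or gray.shape[1] < 9:
        raise InvalidArgumentError(
            f"image must be at least 9x9 pixels, got {gray.shape[0]}x{gray.shape[1]}"
        )
    if algorithm == "dhash":
        grid = area_average(gray, 8, 9)
        bits = (grid[:, :-1] - grid[:, 1:]) > 1e-8
    else:
        grid = area_average(gray, 8, 8)
        bits = (grid - grid.mean()) >= -1e-8
    return HashRecord(image_id, _pack_bits(bits), algorithm)


def hash_image_file(path: str | Path, algorithm: str = "dhash") -> HashRecord:
    """Hash an image file (PNG/JPEG); undecodable files raise OSError naming the path."""
    from PIL import Image, UnidentifiedImageError

    path = Path(path)
    try:
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("RGB"))
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot decode image file: {path}") from exc
    return perceptual_hash(pixels, algorithm, image_id=path.stem)


def hamming_distance(a: int, b: int) -> int:
    return (a ^ b).bit_count()


def find_duplicates(
    hashes: Sequence[HashRecord], max_hamming: int = 5
) -> list[list[str]]:
    """Group near-duplicate images by transitive closure of small Hamming distance.

    Returns one sorted id list per group of size >= 2 (singletons omitted);
    the lexicographically smallest id in each group — its first element — is
    the keeper. Groups are sorted by keeper id.
    """
    if max_hamming < 0:
        raise InvalidArgumentError(f"max_hamming must be >= 0, got {max_hamming}")
    algorithms = {h.algorithm for h in hashes}
    if len(algorithms) > 1:
        raise InvalidArgumentError(
            f"all hash records must share one algorithm, got {sorted(algorithms)}"
        )
    graph = nx.Graph()
    graph.add_nodes_from(h.image_id for h in hashes)
    for i, hi in enumerate(hashes):
        for hj in hashes[i + 1 :]:
            if hamming_distance(hi.hash, hj.hash) <= max_hamming:
                graph.add_edge(hi.image_id, hj.image_id)
    groups = [sorted(c) for c in nx.connected_components(graph) if len(c) >= 2]
    return sorted(groups, key=lambda g: g[0])


def dedup_report(groups: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Tabular dedup report: one row per grouped image, keepers flagged."""
    rows = [
        (gid, image_id, int(i == 0))
        for gid, group in enumerate(groups)
        for i, image_id in enumerate(group)
    ]
    return pd.DataFrame(rows, columns=["group_id", "image_id", "keeper_flag"])


def drop_duplicates(manifest: pd.DataFrame, groups: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Manifest restricted to keepers (the first id of each group) and singletons."""
    losers = {image_id for group in groups for image_id in group[1:]}
    return manifest[~manifest["image_id"].isin(losers)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

PARTITIONS = ("train", "validation", "test")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    manifest: pd.DataFrame,
    outer_ratio: float = 0.8,
    inner_ratio: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class 80:20 train/test then 80:20 train/validation split.

    Per class the ids are shuffled by a seeded generator; the test count is
    ``round_half_up((1 - outer_ratio) * n)``, the validation count is the
    same rule applied to the remainder, and the rest is training. For class
    sizes divisible by 25 (with the default ratios) the 64/16/20 overall
    fractions are exact. Returns a frame ``image_id, partition``.
    """
    if len(manifest) == 0:
        raise InvalidArgumentError("manifest is empty")
    if not (0 < outer_ratio < 1) or not (0 < inner_ratio < 1):
        raise InvalidArgumentError("split ratios must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for label in sorted(manifest["label"].unique()):
        ids = sorted(manifest.loc[manifest["label"] == label, "image_id"])
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n = len(ids)
        n_test = _round_half_up((1 - outer_ratio) * n)
        remainder = ids[: n - n_test]
        n_val = _round_half_up((1 - inner_ratio) * len(remainder))
        for image_id in remainder[: len(remainder) - n_val]:
            rows.append((image_id, "train"))
        for image_id in remainder[len(remainder) - n_val :]:
            rows.append((image_id, "validation"))
        for image_id in ids[n - n_test :]:
            rows.append((image_id, "test"))
    return pd.DataFrame(rows, columns=["image_id", "partition"])


# ---------------------------------------------------------------------------
# Balancing augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentationParams:
    """Affine-augmentation magnitudes.

    Rotation is in degrees; shifts are fractions of width/height; shear is
    an angle in radians; zoom is a multiplicative range ``[1-z, 1+z]``.
    The defaults perturb pose while preserving anatomical detail.
    """

    rotation_max_deg: float = 20.0
    shift_frac: float = 0.20
    shear_max: float = 0.20
    zoom_frac: float = 0.20
    horizontal_flip: bool = True
    fill_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rotation_max_deg", "shift_frac", "shear_max", "zoom_frac"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not self.zoom_frac < 1:
            raise InvalidArgumentError(f"zoom_frac must be < 1, got {self.zoom_frac}")
        if self.fill_mode != "nearest":
            raise InvalidArgumentError(f"only 'nearest' fill mode is supported")


def plan_balance(counts: Mapping[str, int], target: int) -> dict[str, int]:
    """Per-class deficit to reach ``target``: ``max(0, target - count)``."""
    if target < 1:
        raise InvalidArgumentError(f"target must be >= 1, got {target}")
    return {label: max(0, target - int(count)) for label, count in counts.items()}


def sample_transform(params: AugmentationParams, rng: np.random.Generator) -> dict:
    """Draw one transform. Draw order is fixed (rotation, x shift, y shift,
    shear, zoom, then flip when enabled) so streams are reproducible."""
    draw = {
        "angle_deg": rng.uniform(-params.rotation_max_deg, params.rotation_max_deg),
        "shift_x": rng.uniform(-params.shift_frac, params.shift_frac),
        "shift_y": rng.uniform(-params.shift_frac, params.shift_frac),
        "shear": rng.uniform(-params.shear_max, params.shear_max),
        "zoom": rng.uniform(1 - params.zoom_frac, 1 + params.zoom_frac),
        "flip": bool(params.horizontal_flip and rng.random() < 0.5),
    }
    return draw


def transform_matrix(draw: dict) -> np.ndarray:
    """Forward 2x2 matrix in (row, col) coordinates: Rot @ Shear @ Zoom @ Flip."""
    th = math.radians(draw["angle_deg"])
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    shear = np.array([[1.0, draw["shear"]], [0.0, 1.0]])
    zoom = np.array([[draw["zoom"], 0.0], [0.0, draw["zoom"]]])
    flip = np.array([[1.0, 0.0], [0.0, -1.0 if draw["flip"] else 1.0]])
    return rot @ shear @ zoom @ flip


def apply_transform(image: np.ndarray, draw: dict) -> np.ndarray:
    """Apply one sampled affine transform about the image centre.

    Pixel centres sit at integer coordinates; the transform acts about
    ``((H-1)/2, (W-1)/2)``; resampling is nearest-neighbour and out-of-frame
    samples take the nearest edge value. Shape and dtype are preserved.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([draw["shift_y"] * h, draw["shift_x"] * w])
    minv = np.linalg.inv(transform_matrix(draw))
    offset = center - minv @ (center + shift)

    def warp(channel: np.ndarray) -> np.ndarray:
        return ndimage.affine_transform(
            channel, minv, offset=offset, order=0, mode="nearest", output=channel.dtype
        )

    if image.ndim == 2:
        return warp(image)
    return np.dstack([warp(image[:, :, k]) for k in range(image.shape[2])])


def augment_image(
    image: np.ndarray | ImageFixture, params: AugmentationParams, draw_seed: int
) -> np.ndarray:
    """One randomly perturbed copy of ``image`` (pure in (image, params, draw_seed))."""
    pixels = image.pixels if isinstance(image, ImageFixture) else image
    rng = np.random.default_rng(draw_seed)
    return apply_transform(pixels, sample_transform(params, rng))


def execute_plan(
    images_by_label: Mapping[str, Sequence[np.ndarray]],
    plan: Mapping[str, int],
    params: AugmentationParams,
    seed: int = 0,
) -> dict[str, list[np.ndarray]]:
    """Synthesize each class's deficit by augmenting randomly chosen originals.

    Returns only the newly generated images per class; afterwards
    ``len(original) + len(new) == max(len(original), target)`` for every class.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[np.ndarray]] = {}
    for label in sorted(plan):
        deficit = plan[label]
        sources = images_by_label.get(label, ())
        if deficit > 0 and not len(sources):
            raise InvalidArgumentError(f"class {label!r} has a deficit but no source images")
        new = []
        for _ in range(deficit):
            src = sources[int(rng.integers(len(sources)))]
            new.append(augment_image(src, params, int(rng.integers(2**31))))
        out[label] = new
    return out
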