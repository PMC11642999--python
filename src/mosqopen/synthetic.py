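"""Synthetic fixtures with the statistical structure the open-set pipeline assumes.

Three generators cover the three kinds of input the toolkit consumes:

* :func:`generate_activation_set` — per-class Gaussian clusters of activation
  vectors whose means sit at ``separation * spread`` along scaled one-hot
  directions, mimicking the logit geometry of a well-trained closed-set
  classifier with a single separability knob;
* :func:`generate_ood_activations` — out-of-distribution activations in three
  flavours (a coherent shifted cluster, a uniform box over the known range,
  or low-margin midpoints between class means), standing in for images of
  insects the classifier was never trained on;
* :func:`generate_image_corpus` — an imbalanced toy image corpus rendered
  from deterministic geometric templates, for exercising the dataset
  preparation stages (hashing, splitting, balancing) without asset files.

Every generator is a pure function of its spec and seed: identical inputs
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidSpecError
from .types import UNKNOWN_LABEL, ActivationRecord, ActivationSet

OOD_MODES = ("shifted_cluster", "uniform_box", "low_margin")

#: Per-class image counts shaped like a realistically imbalanced ten-class
#: insect corpus (9–500 images per class, 1749 total).
DEFAULT_IMAGE_COUNTS: dict[str, int] = {
    "class_00": 219,
    "class_01": 500,
    "class_02": 64,
    "class_03": 193,
    "class_04": 36,
    "class_05": 74,
    "class_06": 57,
    "class_07": 97,
    "class_08": 9,
    "class_09": 500,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic activation-cluster generator.

    ``separation`` is measured in units of ``spread``, so the Euclidean
    distance between any two class means is ``separation * spread * sqrt(2)``.
    """

    n_classes: int = 10
    per_class_n: int = 50
    dim: int | None = None  # defaults to n_classes
    separation: float = 6.0
    spread: float = 1.0
    ood_mode: str = "shifted_cluster"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise InvalidSpecError(f"n_classes must be >= 1, got {self.n_classes}")
        if self.per_class_n < 1:
            raise InvalidSpecError(f"per_class_n must be >= 1, got {self.per_class_n}")
        if self.spread <= 0:
            raise InvalidSpecError(f"spread must be > 0, got {self.spread}")
        if self.separation < 0:
            raise InvalidSpecError(f"separation must be >= 0, got {self.separation}")
        if self.resolved_dim < self.n_classes:
            raise InvalidSpecError(
                f"dim ({self.resolved_dim}) must be >= n_classes ({self.n_classes}) "
                "for scaled one-hot class means"
            )
        if self.ood_mode not in OOD_MODES:
            raise InvalidSpecError(
                f"ood_mode must be one of {OOD_MODES}, got {self.ood_mode!r}"
            )

    @property
    def resolved_dim(self) -> int:
        return self.n_classes if self.dim is None else self.dim

    def class_labels(self) -> list[str]:
        w = max(2, len(str(self.n_classes - 1)))
        return [f"class_{i:0{w}d}" for i in range(self.n_classes)]

    def class_means(self) -> np.ndarray:
        """(M, dim) matrix of class means: ``separation * spread`` on axis c."""
        means = np.zeros((self.n_classes, self.resolved_dim))
        means[np.arange(self.n_classes), np.arange(self.n_classes)] = (
            self.separation * self.spread
        )
        return means


def generate_activation_set(spec: SyntheticSpec) -> ActivationSet:
    """Draw ``per_class_n`` isotropic-Gaussian activations around each class mean."""
    rng = np.random.default_rng(spec.seed)
    means = spec.class_means()
    records = []
    for c, label in enumerate(spec.class_labels()):
        draws = means[c] + spec.spread * rng.standard_normal(
            (spec.per_class_n, spec.resolved_dim)
        )
        for i in range(spec.per_class_n):
            records.append(ActivationRecord(f"{label}-{i:04d}", label, draws[i]))
    return ActivationSet(records)


def _shifted_cluster_center(spec: SyntheticSpec, template: int) -> np.ndarray:
    """A point on the all-ones line, equidistant from every class mean.

    Template t sits at distance ``separation * spread * sqrt(2) * (1 + t/2)``
    from each known mean — i.e. at least as far from every class as the
    classes are from each other, as a coherent foreign cluster would be.
    """
    s = spec.separation * spec.spread
    dim = spec.resolved_dim
    f = np.sqrt(2.0) * (1.0 + 0.5 * template)
    # Solve dim*a^2 - 2*s*a + s^2*(1 - f^2) = 0 for the larger root.
    a = s * (1.0 + np.sqrt(1.0 + dim * (f * f - 1.0))) / dim
    return np.full(dim, a)


def generate_ood_activations(
    spec: SyntheticSpec,
    n: int,
    composition: Sequence[int] | None = None,
    known: ActivationSet | None = None,
    unknown_label: str = UNKNOWN_LABEL,
) -> ActivationSet:
    """Draw ``n`` out-of-distribution activations labelled with the unknown marker.

    ``composition`` splits the request into provenance groups (one per OOD
    template, e.g. ``(33, 34, 33)`` for three foreign insect sources); the
    group index is recorded in the sample id (``ood-g<t>-<i>``).
    """
    if n <= 0:
        raise InvalidArgumentError(f"number of OOD samples must be > 0, got {n}")
    if composition is None:
        composition = (n,)
    composition = tuple(int(c) for c in composition)
    if any(c <= 0 for c in composition) or sum(composition) != n:
        raise InvalidArgumentError(
            f"composition {composition} must be positive and sum to n={n}"
        )
    rng = np.random.default_rng([spec.seed, 0x0D])
    dim = spec.resolved_dim
    means = spec.class_means()

    if spec.ood_mode == "uniform_box":
        if known is None:
            known = generate_activation_set(spec)
        km = known.matrix()
        lo, hi = km.min(axis=0), km.max(axis=0)

    records = []
    for t, count in enumerate(composition):
        if spec.ood_mode == "shifted_cluster":
            center = _shifted_cluster_center(spec, t)
            draws = center + spec.spread * rng.standard_normal((count, dim))
        elif spec.ood_mode == "uniform_box":
            draws = rng.uniform(lo, hi, size=(count, dim))
        else:  # low_margin: midpoints between random pairs of class means
            ii = rng.integers(0, spec.n_classes, size=count)
            jj = (ii + 1 + rng.integers(0, spec.n_classes - 1, size=count)) % spec.n_classes
            draws = 0.5 * (means[ii] + means[jj]) + spec.spread * rng.standard_normal(
                (count, dim)
            )
        for i in range(count):
            records.append(
                ActivationRecord(f"ood-g{t}-{i:04d}", unknown_label, draws[i])
            )
    return ActivationSet(records)


# ---------------------------------------------------------------------------
# Toy image corpus
# ---------------------------------------------------------------------------

_BACKGROUND = 30
_FOREGROUND = 220


@dataclass(frozen=True)
class ImageFixture:
    """A rendered toy image: ``pixels`` is an (H, W, 3) uint8 array."""

    image_id: str
    pixels: np.ndarray
    label: str
    template_id: int


def render_template(template_id: int, image_size: tuple[int, int]) -> np.ndarray:
    """Deterministic geometric template for a class: (H, W) uint8 grid.

    Eight base shapes (disc, square, horizontal bar, vertical bar, cross,
    ring, diagonal, frame) cycle with ``template_id``; the shape centre is
    additionally offset by the template id so every class is distinct even
    when shapes repeat.
    """
    h, w = image_size
    if h < 16 or w < 16:
        raise InvalidArgumentError(f"image size must be at least 16x16, got {h}x{w}")
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    off = (template_id % 5) - 2
    cy = (h - 1) / 2.0 + off
    cx = (w - 1) / 2.0 - off
    r = min(h, w) / 4.0
    shape = template_id % 8
    if shape == 0:  # disc
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= r * r
    elif shape == 1:  # square
        mask = (np.abs(rr - cy) <= r) & (np.abs(cc - cx) <= r)
    elif shape == 2:  # horizontal bar
        mask = np.abs(rr - cy) <= r / 2
    elif shape == 3:  # vertical bar
        mask = np.abs(cc - cx) <= r / 2
    elif shape == 4:  # cross
        mask = (np.abs(rr - cy) <= r / 3) | (np.abs(cc - cx) <= r / 3)
    elif shape == 5:  # ring
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        mask = (d2 <= r * r) & (d2 >= (r / 2) ** 2)
    elif shape == 6:  # diagonal stripe
        mask = np.abs((rr - cy) - (cc - cx)) <= r / 2
    else:  # frame
        mask = ((np.abs(rr - cy) <= r) & (np.abs(cc - cx) <= r)) & ~(
            (np.abs(rr - cy) <= r / 2) & (np.abs(cc - cx) <= r / 2)
        )
    grid = np.full((h, w), _BACKGROUND, dtype=np.uint8)
    grid[mask] = _FOREGROUND
    return grid


def generate_image_corpus(
    class_counts: Mapping[str, int],
    image_size: tuple[int, int] = (32, 32),
    noise_sd: float = 8.0,
    seed: int = 0,
) -> tuple[list[ImageFixture], pd.DataFrame]:
    """Render an imbalanced toy corpus plus its manifest table.

    Each class gets a deterministic geometric template (see
    :func:`render_template`) and ``class_counts[label]`` noisy renderings of
    it. The manifest has one row per image: ``image_id, label, path`` (paths
    are relative; actually writing PNG files is the pipeline's concern).
    """
    if not class_counts:
        raise InvalidArgumentError("class_counts must not be empty")
    for label, count in class_counts.items():
        if count < 1:
            raise InvalidArgumentError(
                f"class {label!r} has non-positive count {count}"
            )
    if noise_sd < 0:
        raise InvalidArgumentError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    fixtures: list[ImageFixture] = []
    rows = []
    for t, label in enumerate(sorted(class_counts)):
        base = render_template(t, image_size).astype(float)
        base3 = np.repeat(base[:, :, None], 3, axis=2)
        for i in range(class_counts[label]):
            noisy = base3 + noise_sd * rng.standard_normal(base3.shape)
            pixels = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
            image_id = f"{label}-{i:04d}"
            fixtures.append(ImageFixture(image_id, pixels, label, t))
            rows.append((image_id, label, f"{label}/{image_id}.png"))
    manifest = pd.DataFrame(rows, columns=["image_id", "label", "path"])
    return fixtures, manifest


def toy_extract(
    image: ImageFixture | np.ndarray, templates: Sequence[np.ndarray]
) -> np.ndarray:
    """Template-matching 'logits' for a toy image.

    Component c is the negated mean squared pixel difference to template c,
    divided by 255^2 so the values are O(1) and softmax-friendly. The best
    matching template gets the largest (least negative) component; an exact
    match scores 0.
    """
    pixels = image.pixels if isinstance(image, ImageFixture) else np.asarray(image)
    out = np.empty(len(templates))
    for c, tmpl in enumerate(templates):
        tmpl = np.asarray(tmpl)
        if tmpl.ndim == 2 and pixels.ndim == 3:
            tmpl = np.repeat(tmpl[:, :, None], pixels.shape[2], axis=2)
        if tmpl.shape != pixels.shape:
            raise InvalidArgumentError(
                f"template {c} shape {tmpl.shape} does not match image shape {pixels.shape}"
            )
        diff = pixels.astype(float) - tmpl.astype(float)
        out[c] = -np.mean(diff * diff) / 255.0**2
    return out
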