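"""Pipeline configuration: flat namespaced keys, strict validation.

The on-disk format is a YAML mapping of flat dotted keys
(``synth.n_classes: 10``); unknown keys are rejected before any stage runs
so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .evaluation import DEFAULT_SWEEP_THRESHOLDS
from .synthetic import DEFAULT_IMAGE_COUNTS


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "out"
    table_format: str = "tsv"
    log_level: str = "INFO"

    # synthetic activations
    synth_n_classes: int = 10
    synth_dim: int | None = None
    synth_per_class_n: int = 50
    synth_separation: float = 6.0
    synth_spread: float = 1.0
    synth_ood_mode: str = "shifted_cluster"
    synth_n_ood: int = 100
    synth_ood_composition: tuple[int, ...] = (33, 34, 33)
    synth_test_per_class: int = 10

    # toy image corpus
    image_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_IMAGE_COUNTS)
    )
    image_height: int = 32
    image_width: int = 32
    image_noise_sd: float = 8.0

    # dedup
    dedup_algorithm: str = "dhash"
    dedup_max_hamming: int = 5

    # split / balance
    split_outer_ratio: float = 0.8
    split_inner_ratio: float = 0.8
    balance_target: int = 500
    balance_first: bool = False

    # augmentation
    aug_rotation_max_deg: float = 20.0
    aug_shift_frac: float = 0.20
    aug_shear_max: float = 0.20
    aug_zoom_frac: float = 0.20
    aug_horizontal_flip: bool = True

    # open-set model
    openmax_beta: int | None = None
    openmax_tail_size: int = 20
    openmax_threshold: float = 0.1
    openmax_decision_mode: str = "score_threshold"
    openmax_mav_source: str = "all_samples"
    openmax_location_mode: str = "tail_min"

    # evaluation sweep
    sweep_thresholds: tuple[float, ...] = DEFAULT_SWEEP_THRESHOLDS


_PREFIXES = ("synth", "image", "dedup", "split", "balance", "aug", "openmax", "sweep")


def _field_to_key(name: str) -> str:
    for prefix in _PREFIXES:
        if name.startswith(prefix + "_"):
            return f"{prefix}.{name[len(prefix) + 1 :]}"
    return name


_KEY_TO_FIELD = {_field_to_key(f.name): f.name for f in fields(PipelineConfig)}


def config_to_flat(config: PipelineConfig) -> dict[str, Any]:
    out = {}
    for f in fields(PipelineConfig):
        value = getattr(config, f.name)
        if isinstance(value, tuple):
            value = list(value)
        elif isinstance(value, Mapping):
            value = dict(value)
        out[_field_to_key(f.name)] = value
    return out


def config_from_mapping(mapping: Mapping[str, Any]) -> PipelineConfig:
    """Build a config from flat dotted keys, rejecting anything unknown."""
    kwargs: dict[str, Any] = {}
    for key, value in mapping.items():
        if key not in _KEY_TO_FIELD:
            raise ConfigError(f"unknown configuration key {key!r}")
        name = _KEY_TO_FIELD[key]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigError(f"configuration file {path} must be a mapping of flat keys")
    return config_from_mapping(doc)


def dump_defaults() -> str:
    """YAML text of every key at its default value."""
    return yaml.safe_dump(config_to_flat(PipelineConfig()), sort_keys=True)
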