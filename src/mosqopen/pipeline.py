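"""Stage orchestration: synthetic inputs through model fit, prediction,
evaluation and threshold sweep, with atomic file outputs and a run manifest.

Stages communicate only through files in the output directory, every file is
written atomically (temp file + rename), and a single root seed
deterministically derives a per-stage seed (root plus a CRC of the stage
name) so that adding or removing stages never perturbs another stage's
randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import zlib
from dataclasses import replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import evaluation, openset, prep, synthetic
from .config import PipelineConfig, config_to_flat
from .errors import ConfigError, MosqOpenError
from .types import ActivationSet

log = logging.getLogger("mosqopen")

STAGE_ORDER = ("synth", "dedup", "split", "balance", "fit", "predict", "evaluate", "sweep")

_IMAGE_STAGES = {"dedup", "split", "balance"}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: root plus a hash of the stage name."""
    return (int(root_seed) + zlib.crc32(stage.encode())) % (2**31)


def atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_bytes(path: Path, data: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_table(df: pd.DataFrame, path: Path, table_format: str) -> None:
    sep = "," if table_format == "csv" else "\t"
    atomic_write_text(path, df.to_csv(sep=sep, index=False, float_format="%.9g"))


def sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path) -> Path:
    if not path.exists():
        raise MosqOpenError(f"required input file is missing: {path}")
    return path


class PipelineRun:
    """One execution of an ordered subset of stages against an output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.ext = "csv" if config.table_format == "csv" else "tsv"
        self.artifacts: list[Path] = []

    # --------------------------------------------------------------- helpers

    def _path(self, name: str) -> Path:
        return self.out / name

    def _emit_table(self, df: pd.DataFrame, name: str) -> Path:
        path = self._path(f"{name}.{self.ext}")
        _write_table(df, path, self.config.table_format)
        self.artifacts.append(path)
        return path

    def _emit_text(self, text: str, name: str) -> Path:
        path = self._path(name)
        atomic_write_text(path, text)
        self.artifacts.append(path)
        return path

    def _read_table(self, name: str) -> pd.DataFrame:
        path = _require(self._path(f"{name}.{self.ext}"))
        return pd.read_csv(path, sep="," if self.ext == "csv" else "\t")

    def _synth_spec(self, seed: int) -> synthetic.SyntheticSpec:
        c = self.config
        return synthetic.SyntheticSpec(
            n_classes=c.synth_n_classes,
            per_class_n=c.synth_per_class_n,
            dim=c.synth_dim,
            separation=c.synth_separation,
            spread=c.synth_spread,
            ood_mode=c.synth_ood_mode,
            seed=seed,
        )

    def _openmax_config(self) -> openset.OpenMaxConfig:
        c = self.config
        return openset.OpenMaxConfig(
            beta=c.openmax_beta,
            tail_size=c.openmax_tail_size,
            threshold=c.openmax_threshold,
            decision_mode=c.openmax_decision_mode,
            mav_source=c.openmax_mav_source,
            location_mode=c.openmax_location_mode,
        )

    # ---------------------------------------------------------------- stages

    def stage_synth(self, with_images: bool) -> None:
        c = self.config
        seed = stage_seed(c.seed, "synth")
        log.info("synth: derived seed %d", seed)
        delim = "," if self.ext == "csv" else "\t"

        train = synthetic.generate_activation_set(self._synth_spec(seed))
        test_spec = replace(self._synth_spec(seed), seed=(seed + 1) % (2**31),
                            per_class_n=c.synth_test_per_class)
        test_known = synthetic.generate_activation_set(test_spec)
        ood = synthetic.generate_ood_activations(
            self._synth_spec(seed), c.synth_n_ood, composition=c.synth_ood_composition
        )
        for name, aset in (
            ("train", train),
            ("test_known", test_known),
            ("test_ood", ood),
        ):
            path = self._path(f"{name}.{self.ext}")
            atomic_write_text(path, aset.to_text(delim))
            self.artifacts.append(path)

        if with_images:
            from PIL import Image

            fixtures, manifest = synthetic.generate_image_corpus(
                c.image_counts,
                image_size=(c.image_height, c.image_width),
                noise_sd=c.image_noise_sd,
                seed=seed,
            )
            images_dir = self._path("images")
            for fx in fixtures:
                target = images_dir / f"{fx.label}" / f"{fx.image_id}.png"
                target.parent.mkdir(parents=True, exist_ok=True)
                import io as _io

                buf = _io.BytesIO()
                Image.fromarray(fx.pixels).save(buf, format="PNG")
                atomic_write_bytes(target, buf.getvalue())
            self._emit_table(manifest, "manifest")

    def stage_dedup(self) -> None:
        c = self.config
        manifest = self._read_table("manifest")
        images_dir = self._path("images")
        hashes = [
            prep.HashRecord(
                row.image_id,
                prep.hash_image_file(images_dir / row.path, c.dedup_algorithm).hash,
                c.dedup_algorithm,
            )
            for row in manifest.itertuples(index=False)
        ]
        groups = prep.find_duplicates(hashes, c.dedup_max_hamming)
        log.info("dedup: %d duplicate groups", len(groups))
        self._emit_table(prep.dedup_report(groups), "dedup")

    def stage_split(self) -> None:
        c = self.config
        source = "manifest"
        if c.balance_first and self._path(f"manifest_balanced.{self.ext}").exists():
            source = "manifest_balanced"
        manifest = self._read_table(source)
        dedup_path = self._path(f"dedup.{self.ext}")
        if dedup_path.exists():
            report = pd.read_csv(dedup_path, sep="," if self.ext == "csv" else "\t")
            losers = report.loc[report["keeper_flag"] == 0, "image_id"]
            manifest = manifest[~manifest["image_id"].isin(set(losers))]
        seed = stage_seed(c.seed, "split")
        log.info("split: derived seed %d", seed)
        assignment = prep.stratified_split(
            manifest, c.split_outer_ratio, c.split_inner_ratio, seed
        )
        self._emit_table(assignment, "split")

    def stage_balance(self) -> None:
        c = self.config
        manifest = self._read_table("manifest")
        scope = manifest
        if not c.balance_first:
            split_path = self._path(f"split.{self.ext}")
            if split_path.exists():
                assignment = pd.read_csv(split_path, sep="," if self.ext == "csv" else "\t")
                train_ids = set(assignment.loc[assignment["partition"] == "train", "image_id"])
                scope = manifest[manifest["image_id"].isin(train_ids)]
        counts = scope["label"].value_counts().to_dict()
        plan = prep.plan_balance(counts, c.balance_target)
        self._emit_text(json.dumps(plan, indent=2, sort_keys=True), "plan.json")

        from PIL import Image

        images_dir = self._path("images")
        params = prep.AugmentationParams(
            rotation_max_deg=c.aug_rotation_max_deg,
            shift_frac=c.aug_shift_frac,
            shear_max=c.aug_shear_max,
            zoom_frac=c.aug_zoom_frac,
            horizontal_flip=c.aug_horizontal_flip,
        )
        seed = stage_seed(c.seed, "balance")
        log.info("balance: derived seed %d", seed)
        by_label = {
            label: [
                np.asarray(Image.open(images_dir / p))
                for p in scope.loc[scope["label"] == label, "path"]
            ]
            for label in sorted(scope["label"].unique())
        }
        new_images = prep.execute_plan(by_label, plan, params, seed)
        rows = []
        import io as _io

        for label in sorted(new_images):
            for i, pixels in enumerate(new_images[label]):
                image_id = f"{label}-aug{i:04d}"
                rel = f"{label}/{image_id}.png"
                target = images_dir / rel
                buf = _io.BytesIO()
                Image.fromarray(pixels).save(buf, format="PNG")
                atomic_write_bytes(target, buf.getvalue())
                rows.append((image_id, label, rel))
        augmented = pd.concat(
            [manifest, pd.DataFrame(rows, columns=["image_id", "label", "path"])],
            ignore_index=True,
        )
        self._emit_table(augmented, "manifest_balanced")

    def stage_fit(self) -> None:
        train = ActivationSet.read(_require(self._path(f"train.{self.ext}")))
        model = openset.fit_open_set_model(train, config=self._openmax_config())
        self._emit_text(model.to_json(), "model.json")

    def _load_model(self) -> openset.OpenSetModel:
        return openset.OpenSetModel.load(_require(self._path("model.json")))

    def _load_test(self) -> ActivationSet:
        parts = [ActivationSet.read(_require(self._path(f"test_known.{self.ext}")))]
        ood_path = self._path(f"test_ood.{self.ext}")
        if ood_path.exists():
            parts.append(ActivationSet.read(ood_path))
        return ActivationSet.concat(parts)

    def stage_predict(self) -> None:
        model = self._load_model()
        test = self._load_test()
        preds = openset.predict_set(test, model)
        self._emit_table(openset.predictions_frame(preds), "predictions")

    def stage_evaluate(self) -> None:
        model = self._load_model()
        test = self._load_test()
        preds_df = self._read_table("predictions")
        truth = dict(zip(test.ids(), test.labels()))
        missing = [s for s in preds_df["sample_id"] if s not in truth]
        if missing:
            raise MosqOpenError(f"predictions contain unknown sample ids: {missing[:5]}")
        y_true = [truth[s] for s in preds_df["sample_id"]]
        labels = list(model.vocabulary) + [model.config.unknown_label]
        cm = evaluation.confusion_matrix(y_true, list(preds_df["predicted"]), labels)
        report = evaluation.classification_metrics(cm)

        prob_cols = ["p_unknown"] + [f"p_class_{i}" for i in range(model.n_classes)]
        probs = preds_df[prob_cols].to_numpy()
        curve_labels = [model.config.unknown_label] + list(model.vocabulary)
        curves = evaluation.roc_pr_curves(y_true, probs, curve_labels)

        doc = report.to_dict()
        doc["micro_roc_auc"] = curves.micro_auc
        doc["auprc_macro"] = curves.macro_auprc
        doc["confusion_matrix"] = {
            "labels": labels,
            "counts": cm.counts.tolist(),
        }
        self._emit_text(json.dumps(doc, indent=2, sort_keys=True), "report.json")
        self._emit_table(report.per_class, "per_class")
        self._emit_table(evaluation.curves_frame(curves), "curves")

    def stage_sweep(self) -> None:
        model = self._load_model()
        test = self._load_test()
        sweep = evaluation.threshold_sweep(
            test.labels(), test, model, self.config.sweep_thresholds
        )
        self._emit_table(sweep, "sweep")

    # ------------------------------------------------------------------- run

    def run(self, stages: Sequence[str]) -> None:
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        ordered = [s for s in STAGE_ORDER if s in set(stages)]
        with_images = bool(_IMAGE_STAGES & set(stages))
        if self.config.balance_first:
            # reproduce the balance-then-split corpus arithmetic
            ordered = [s for s in ordered if s != "split"] + (
                ["split"] if "split" in stages else []
            )
        for stage in ordered:
            log.info("running stage %s", stage)
            if stage == "synth":
                self.stage_synth(with_images)
            elif stage == "dedup":
                self.stage_dedup()
            elif stage == "split":
                self.stage_split()
            elif stage == "balance":
                self.stage_balance()
            elif stage == "fit":
                self.stage_fit()
            elif stage == "predict":
                self.stage_predict()
            elif stage == "evaluate":
                self.stage_evaluate()
            elif stage == "sweep":
                self.stage_sweep()
        self._write_manifest(ordered)

    def _write_manifest(self, stages: Sequence[str]) -> None:
        flat = config_to_flat(self.config)
        config_hash = hashlib.sha256(
            json.dumps(flat, sort_keys=True).encode()
        ).hexdigest()
        manifest = {
            "config": flat,
            "config_sha256": config_hash,
            "seed": self.config.seed,
            "stages": list(stages),
            "outputs": {
                str(p.relative_to(self.out)): sha256_file(p)
                for p in self.artifacts
                if p.exists()
            },
            "package_version": _package_version(),
        }
        atomic_write_text(
            self._path("run_manifest.json"), json.dumps(manifest, indent=2, sort_keys=True)
        )


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("mosqopen")
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(config: PipelineConfig, stages: Sequence[str]) -> int:
    """Run the requested stages; returns 0 on success, raising on any error."""
    PipelineRun(config).run(stages)
    return 0
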