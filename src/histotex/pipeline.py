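"""End-to-end experiment orchestration: generate -> extract -> features ->
stats -> segmentation evaluation -> report bundle.

One master seed derives per-stage child seeds through a fixed scheme
(``SeedSequence((master_seed, stage_index))``), so individual stages can
be rerun independently and ``all`` is byte-identical to running the five
subcommands in sequence.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import group_stats, segeval, synthetic, texture
from .segeval import CLASS_NAMES, round2
from .synthetic import SyntheticDatasetSpec

__all__ = ["PipelineConfig", "ReportBundle", "run_experiment",
           "stage_generate", "stage_features", "stage_stats",
           "stage_segeval", "stage_report"]

logger = logging.getLogger(__name__)

_STAGES = ("generate", "features", "stats", "segeval", "report")


def stage_seed(master_seed: int, stage: str) -> int:
    """Fixed, documented child-seed scheme."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence((master_seed, idx))
               .generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Validated, fully serializable configuration of one experiment."""

    dataset: SyntheticDatasetSpec = field(
        default_factory=lambda: SyntheticDatasetSpec.desk_scale())
    alpha: float = 0.05
    glcm_levels: int = 9
    runs: int = 10
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    classifier_window: int = 15
    tile: int = 256
    overlap: int = 32
    patch_size: int = 100
    master_seed: int = 0
    out_dir: str = "histotex_out"

    def validate(self) -> None:
        self.dataset.validate()
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.classifier_window < 3:
            raise ValueError("classifier_window must be >= 3")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.overlap < 0 or self.tile <= self.overlap:
            raise ValueError("need tile > overlap >= 0")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dataset"]["texture_divergence"] = dict(
            self.dataset.texture_divergence)
        d["fractions"] = list(self.fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ds = d.pop("dataset", {})
        spec = SyntheticDatasetSpec(**ds) if ds else \
            SyntheticDatasetSpec.desk_scale()
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(dataset=spec, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class ReportBundle:
    table1_csv: Path
    table2_csv: Path
    table3_csv: Path
    patch_dir: Path
    log_file: Path
    config_snapshot: Path


# ---------------------------------------------------------------------------
# stages (each reads its inputs from the out_dir written by earlier stages)
# ---------------------------------------------------------------------------

def _out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_generate(config: PipelineConfig) -> Path:
    config.validate()
    out = _out(config)
    spec = config.dataset.replace(
        seed=stage_seed(config.master_seed, "generate"))
    images = synthetic.generate_dataset(spec)
    dataset_dir = out / "dataset"
    synthetic.write_dataset(images, dataset_dir)
    logger.info("generate: wrote %d images to %s", len(images), dataset_dir)
    return dataset_dir


def stage_features(config: PipelineConfig) -> Path:
    config.validate()
    out = _out(config)
    images = synthetic.read_dataset(out / "dataset")
    table = texture.build_feature_table(images)
    path = out / "features.csv"
    table.to_csv(path, index=False)
    logger.info("features: %d rows -> %s", len(table), path)
    return path


def stage_stats(config: PipelineConfig) -> Path:
    config.validate()
    out = _out(config)
    table = pd.read_csv(out / "features.csv")
    report = group_stats.significance_report(table, alpha=config.alpha)
    path = out / "table1_analog.csv"
    report.counts_frame().to_csv(path, index=False)
    report.tests_frame().to_csv(out / "tests_long.csv", index=False)
    logger.info("stats: significance counts %s", report.haralick_counts)
    return path


def stage_segeval(config: PipelineConfig) -> Path:
    config.validate()
    out = _out(config)
    images = synthetic.read_dataset(out / "dataset")
    seed = stage_seed(config.master_seed, "segeval")
    report = segeval.run_protocol(
        images, runs=config.runs, fractions=config.fractions,
        window=config.classifier_window, seed=seed)

    report.display_table().to_csv(out / "table2_analog.csv", index=False)
    full = report.mean.copy()
    for m in segeval.METRIC_NAMES:
        full[m + "_sd"] = report.sd[m]
    full.to_csv(out / "table2_full_precision.csv")
    report.per_run.to_csv(out / "per_run_metrics.csv", index=False)

    # best run's classifier applied to the whole dataset (Table-3 analog)
    best = segeval.select_best_run(report)
    best_seed = report.run_seeds[best]
    ids = [im.image_id for im in images]
    by_id = {im.image_id: im for im in images}
    split = segeval.split_dataset(ids, config.fractions, seed=best_seed)
    clf = segeval.fit_baseline_classifier(
        [by_id[i] for i in split.train_ids],
        window=config.classifier_window, seed=best_seed)
    total = np.zeros((8, 8))
    patch_dir = out / "patches"
    patch_dir.mkdir(exist_ok=True)
    n_patches = 0
    for im in images:
        pred = segeval.predict_labels(clf, im.pixels)
        target = segeval.eight_class_labels(im.mask.labels, im.subtype)
        total += segeval.confusion(target, pred).counts
        for pt in segeval.extract_uniform_patches(
                im.pixels, target, pred, size=config.patch_size):
            name = f"{im.image_id}_{pt['class_name']}_r{pt['row']}_c{pt['col']}.png"
            Image.fromarray(pt["pixels"], mode="RGB").save(patch_dir / name)
            n_patches += 1
    cm = segeval.ConfusionMatrix(total)
    norm = cm.to_frame(normalized=True).map(round2)
    norm.to_csv(out / "table3_analog.csv")
    cm.to_frame(normalized=False).to_csv(out / "table3_counts.csv")
    logger.info("segeval: best run %d, %d uniform patches", best, n_patches)
    return out / "table2_analog.csv"


def stage_report(config: PipelineConfig) -> ReportBundle:
    config.validate()
    out = _out(config)
    snapshot = out / "config_snapshot.yml"
    config.to_yaml(snapshot)
    bundle = ReportBundle(
        table1_csv=out / "table1_analog.csv",
        table2_csv=out / "table2_analog.csv",
        table3_csv=out / "table3_analog.csv",
        patch_dir=out / "patches",
        log_file=out / "run.log",
        config_snapshot=snapshot)
    missing = [str(p) for p in (bundle.table1_csv, bundle.table2_csv,
                                bundle.table3_csv, bundle.patch_dir)
               if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            "report stage ran before its inputs exist: " + ", ".join(missing))
    return bundle


def run_experiment(config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order; deterministic per master seed."""
    config.validate()
    out = _out(config)
    log_file = out / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("histotex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        for stage_fn, name in ((stage_generate, "generate"),
                               (stage_features, "features"),
                               (stage_stats, "stats"),
                               (stage_segeval, "segeval")):
            try:
                stage_fn(config)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        return stage_report(config)
    finally:
        root.removeHandler(handler)
        handler.close()
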