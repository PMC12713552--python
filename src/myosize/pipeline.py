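"""End-to-end demo pipeline: simulate → segment → measure → stats → compare.

Chains the package's stages on a synthetic section with fixed seeds and
structured logging, writing every intermediate artifact (image, masks, QC
record, fiber CSVs, statistics, comparison report) into one output
directory. Reruns with the same config are file-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import comparison, dataio, distributions, morphometry, segmentation, synthetic
from .norms import assign_cohort, load_reference_normative_table
from .samples import BiopsySample

log = logging.getLogger("myosize.pipeline")


@dataclass
class PipelineConfig:
    """Configuration for one demo run (plain-YAML serializable)."""

    cohort: str = "2 years"
    sex: str = "pooled"
    n_fibers: int = 200
    age_months: float = 30.0
    pixel_size: float = 0.25
    frame_fraction: float = 0.70
    seed: int = 0
    out_dir: str = "myosize-run"
    disease_mode: str | None = None  # uniform_hypotrophy | variance_inflation
    disease_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.5 <= self.frame_fraction <= 0.75:
            raise ValueError("frame_fraction must lie in [0.5, 0.75]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.error("stage %s: FAILED", name)
                raise RuntimeError(f"pipeline halted at stage {name!r}") from None
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full demo chain; returns a dict of artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = asdict(config)
    cfg.pop("out_dir")  # provenance hash covers analysis settings only
    artifacts: dict[str, str] = {}

    params = synthetic.make_cohort_params(config.cohort, config.sex)

    @_stage("simulate")
    def simulate():
        geo = synthetic.SectionGeometryConfig(
            n_fibers=config.n_fibers, pixel_size=config.pixel_size, seed=config.seed
        )
        image, mask, truth = synthetic.generate_section(params, geo)
        dataio.write_image(image, out / "section.tiff")
        dataio.write_label_mask(mask, out / "truth_mask.tiff")
        dataio.write_fiber_csv(truth.records, out / "ground_truth.csv", config.seed, cfg)
        artifacts["section"] = str(out / "section.tiff")
        return image, mask, truth

    image, truth_mask, truth = simulate()

    @_stage("segment")
    def segment():
        tissue = segmentation.detect_tissue(image)
        mask = segmentation.segment_fibers(image, tissue, config.pixel_size)
        dataio.write_label_mask(mask, out / "segmented_mask.tiff")
        qc = segmentation.qc_record(mask, truth)
        dataio.write_json(qc, out / "segmentation_qc.json", config.seed, cfg)
        artifacts["qc"] = str(out / "segmentation_qc.json")
        return mask, qc

    mask, qc = segment()

    @_stage("measure")
    def measure():
        frame = segmentation.CountingFrame.centered(mask.shape, config.frame_fraction)
        keep = segmentation.apply_counting_frame(mask, frame)
        table = morphometry.measure_mask(mask)
        table = table[table["label_id"].isin(keep)].reset_index(drop=True)
        cohort = config.cohort if config.sex != "pooled" else assign_cohort(config.age_months)
        table = morphometry.apply_filters(table, morphometry.FilterSpec(), cohort)
        dataio.write_fiber_csv(table, out / "fibers.csv", config.seed, cfg)
        artifacts["fibers"] = str(out / "fibers.csv")
        return table

    fibers = measure()

    @_stage("stats")
    def stats():
        s = distributions.summarize(fibers["minferet_um"])
        dataio.write_json(s.as_dict(), out / "summary_stats.json", config.seed, cfg)
        distributions.plot_histogram(fibers["minferet_um"], out / "histogram.png")
        curve = distributions.cumulative_probability(fibers["minferet_um"])
        distributions.plot_cumulative_curves({"query": curve}, out / "cumulative.png")
        artifacts["stats"] = str(out / "summary_stats.json")
        return s

    stats()

    @_stage("compare")
    def compare():
        sex = config.sex if config.sex != "pooled" else "female"
        sample = BiopsySample("pipeline-query", config.age_months, sex, fibers)
        if config.disease_mode:
            sample = synthetic.apply_disease_transform(
                sample, config.disease_mode, config.disease_factor
            )
        report = comparison.compare_to_norms(sample, load_reference_normative_table())
        dataio.write_json(report.to_json_dict(), out / "comparison.json", config.seed, cfg)
        report.levels.to_csv(out / "comparison_levels.csv", index=False)
        artifacts["comparison"] = str(out / "comparison.json")
        return report

    compare()
    log.info("pipeline complete; artifacts in %s", out)
    return artifacts
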