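"""Reproducible pipeline configuration and the end-to-end runner.

A :class:`RunConfig` captures every stage parameter plus input/output paths;
it round-trips losslessly through YAML or JSON and rejects unknown keys, so a
config file is a complete, validated record of an analysis.
:func:`run_pipeline` executes preprocess → classify (one or more algorithms)
→ postprocess → quality/AOI summaries → optional plots and writes a manifest
with parameters and SHA-256 hashes of every output, sufficient to re-run and
verify the analysis.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as gio
from .aoi import aoi_test, load_aois
from .classify import (AdaptiveParams, CLASSIFIERS, I2MCParams, IDTParams,
                       IVTParams)
from .postprocess import drop_fixations, trim_fixations
from .preprocess import PreprocessParams, preprocess_gaze
from .quality import (compare_event_streams, proportion_data_loss,
                      rmsd_precision, summarize_algorithms)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScreenGeometryConfig(_Strict):
    distance_cm: float
    screen_width_cm: float
    screen_height_cm: float
    res_x_px: int
    res_y_px: int

    def build(self) -> gio.ScreenGeometry:
        return gio.ScreenGeometry(**self.model_dump())


class PreprocessConfig(_Strict):
    max_gap_ms: float = 75.0
    margin_ms: float = 10.0
    smooth_window_ms: float = 15.0
    smooth_method: Literal["median", "average"] = "median"

    def build(self) -> PreprocessParams:
        return PreprocessParams(**self.model_dump())


class IVTConfig(_Strict):
    velocity_threshold_dps: float = 30.0
    min_fixation_ms: float = 60.0
    min_saccade_ms: float = 10.0
    missing_samples_threshold: float = 0.5
    merge_dist_deg: float | None = 0.5
    merge_gap_ms: float | None = 75.0

    def build(self) -> IVTParams:
        return IVTParams(**self.model_dump())


class IDTConfig(_Strict):
    dispersion_threshold_deg: float = 1.0
    min_fixation_ms: float = 60.0
    missing_samples_threshold: float = 0.5

    def build(self) -> IDTParams:
        return IDTParams(**self.model_dump())


class AdaptiveConfig(_Strict):
    initial_peak_threshold_dps: float = 200.0
    lam: float = 6.0
    convergence_tol_dps: float = 1.0
    min_fixation_ms: float = 40.0
    min_saccade_ms: float = 12.0
    onset_lambda: float = 3.0
    offset_weight_alpha: float = 0.7
    noise_window_ms: float = 40.0
    missing_samples_threshold: float = 0.5

    def build(self) -> AdaptiveParams:
        return AdaptiveParams(**self.model_dump())


class I2MCConfig(_Strict):
    window_ms: float = 200.0
    step_ms: float = 20.0
    downsample_factors: list[int] = Field(default_factory=lambda: [2, 5, 10])
    weight_cutoff_sd: float = 2.0
    merge_dist_deg: float | None = 0.7
    merge_gap_ms: float | None = 30.0
    min_fixation_ms: float = 40.0
    min_valid_prop_window: float = 0.5
    missing_samples_threshold: float = 0.5

    def build(self) -> I2MCParams:
        d = self.model_dump()
        d["downsample_factors"] = tuple(d["downsample_factors"])
        return I2MCParams(**d)


class PostprocessConfig(_Strict):
    trim_ms: float = 0.0
    min_fixation_ms: float = 0.0
    max_prop_missing: float = 1.0


class ColumnMapConfig(_Strict):
    t: str = "t"
    x: str | list[str] = "x"
    y: str | list[str] = "y"
    valid: str | None = None

    def build(self) -> dict:
        d = {"t": self.t, "x": self.x, "y": self.y}
        if self.valid is not None:
            d["valid"] = self.valid
        return d


class RunConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected."""

    input: str
    output_dir: str = "gazekit_out"
    unit: Literal["px", "deg", "prop"] = "deg"
    time_unit: Literal["ms", "s", "us"] = "ms"
    column_map: ColumnMapConfig = Field(default_factory=ColumnMapConfig)
    geometry: ScreenGeometryConfig | None = None
    algorithms: list[Literal["ivt", "idt", "adaptive", "i2mc"]] = Field(
        default_factory=lambda: ["ivt"])
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    ivt: IVTConfig = Field(default_factory=IVTConfig)
    idt: IDTConfig = Field(default_factory=IDTConfig)
    adaptive: AdaptiveConfig = Field(default_factory=AdaptiveConfig)
    i2mc: I2MCConfig = Field(default_factory=I2MCConfig)
    postprocess: PostprocessConfig = Field(default_factory=PostprocessConfig)
    aois: str | None = None
    compare_margin_ms: float = 15.0
    plots: bool = False
    seed: int = 0
    log_level: Literal["debug", "info", "warning", "error"] = "info"


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file into a validated RunConfig."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    return RunConfig.model_validate(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis end to end; return the manifest."""
    in_path = Path(config.input)
    if not in_path.exists():
        raise gio.InputError(f"input path does not exist: {in_path}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    geometry = config.geometry.build() if config.geometry else None
    stage = "read"
    try:
        rec = gio.read_gaze_table(in_path, config.column_map.build(),
                                  unit=config.unit, geometry=geometry,
                                  time_unit=config.time_unit)
        if rec.unit != "deg":
            rec = gio.to_degrees(rec)
        stage = "preprocess"
        clean = preprocess_gaze(rec, config.preprocess.build())
        gio.write_recording(clean, out_dir / "preprocessed.csv")

        outputs = {"preprocessed": out_dir / "preprocessed.csv"}
        event_sets = {}
        for algo in config.algorithms:
            stage = f"classify:{algo}"
            fn, _ = CLASSIFIERS[algo]
            params = getattr(config, algo).build()
            es = fn(clean, params)
            stage = f"postprocess:{algo}"
            if config.postprocess.trim_ms > 0:
                es = trim_fixations(es, clean, config.postprocess.trim_ms)
            if (config.postprocess.min_fixation_ms > 0
                    or config.postprocess.max_prop_missing < 1.0):
                es = drop_fixations(es, config.postprocess.min_fixation_ms,
                                    config.postprocess.max_prop_missing)
            path = out_dir / f"events_{algo}.csv"
            gio.write_events_table(es, path)
            outputs[f"events_{algo}"] = path
            event_sets[algo] = es

        stage = "quality"
        summary = summarize_algorithms(list(event_sets.values()), clean)
        summary.to_csv(out_dir / "summary.csv", index=False)
        outputs["summary"] = out_dir / "summary.csv"
        quality = {"proportion_data_loss": proportion_data_loss(clean)}
        try:
            quality["rmsd_precision_deg"] = rmsd_precision(clean)
        except gio.InputError:
            quality["rmsd_precision_deg"] = None
        comparisons = {}
        algos = list(event_sets)
        for i in range(len(algos)):
            for j in range(i + 1, len(algos)):
                cs = compare_event_streams(event_sets[algos[i]],
                                           event_sets[algos[j]],
                                           config.compare_margin_ms)
                comparisons[f"{algos[i]}_vs_{algos[j]}"] = cs.__dict__
        if comparisons:
            (out_dir / "comparisons.json").write_text(
                json.dumps(comparisons, indent=2))
            outputs["comparisons"] = out_dir / "comparisons.json"

        if config.aois:
            stage = "aoi"
            aois = load_aois(config.aois)
            for algo, es in event_sets.items():
                df = aoi_test(es, aois)
                path = out_dir / f"aoi_{algo}.csv"
                df.to_csv(path, index=False)
                outputs[f"aoi_{algo}"] = path

        if config.plots:
            stage = "plots"
            from .viz import plot_algorithm_quality, plot_fixations_2d
            outputs["plot_fixations"] = plot_fixations_2d(
                clean, list(event_sets.values()), out_dir / "fixations_2d.png")
            outputs["plot_quality"] = plot_algorithm_quality(
                summary, out_dir / "algorithm_quality.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.model_dump(mode="json"),
        "quality": quality,
        "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                    for k, p in outputs.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
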