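"""End-to-end orchestration: simulate -> preprocess -> detect -> sort -> summarize.

``simulate_and_analyze`` is the workhorse used by the statistics layer, the
examples and the acceptance runs: it renders N slices of a condition preset
and pushes each through the full analysis chain, returning per-slice
summaries.  ``run_pipeline`` wraps the same chain with file outputs and a
reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .detect import ActivityCriterion, detect_segment, frequency_series
from .preprocess import FilterSpec, preprocess_segment
from .simulate import (
    ArrayGeometry,
    ConditionPreset,
    NoiseModel,
    RecordingSegment,
    build_preset,
    render_recording,
)
from .sort import SpcConfig, sort_segment
from .stats import SliceSummary, compare_conditions, summarize_slice

log = logging.getLogger("vhmea")


@dataclass
class PipelineConfig:
    genotype: str = "control"
    drug: str = "basal"
    n_slices: int = 12
    seed: int = 1
    duration: float = 50.0
    fs: float = 20_000.0
    filter: FilterSpec = field(default_factory=FilterSpec)
    multiplier: float = 4.5
    dead_time_ms: float = 1.0
    window: int = 64
    criterion: ActivityCriterion = field(default_factory=ActivityCriterion)
    spc: SpcConfig = field(default_factory=SpcConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    sort_units: bool = False
    output_dir: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spc"]["temperatures"] = list(d["spc"]["temperatures"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d:
            d["filter"] = FilterSpec(**d["filter"])
        if "criterion" in d:
            d["criterion"] = ActivityCriterion(**d["criterion"])
        if "spc" in d:
            spc = dict(d["spc"])
            if "temperatures" in spc:
                spc["temperatures"] = tuple(spc["temperatures"])
            d["spc"] = SpcConfig(**spc)
        if "noise" in d:
            d["noise"] = NoiseModel(**d["noise"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: list[int]
    timings_s: dict[str, float] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)


def _slice_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), index]).generate_state(1)[0] % (2**31))


def analyze_segment(
    segment: RecordingSegment,
    filter_spec: FilterSpec | None = None,
    multiplier: float = 4.5,
    dead_time_ms: float = 1.0,
    window: int = 64,
    criterion: ActivityCriterion | None = None,
    spc: SpcConfig | None = None,
    sort_units: bool = False,
    slice_id: str = "",
):
    """Preprocess, detect and (optionally) sort one segment; return a summary."""
    filtered = preprocess_segment(segment, filter_spec or FilterSpec())
    table, waveforms, active, _thr = detect_segment(
        filtered, multiplier=multiplier, dead_time_ms=dead_time_ms,
        window=window, criterion=criterion,
    )
    # 25-s observation windows on full-length segments; shorter (scaled-down)
    # segments fall back to two windows per segment
    freq_window = min(25.0, segment.duration / 2.0)
    freqs = frequency_series(table, window_s=freq_window,
                             electrodes=[int(e) for e in np.flatnonzero(active)])
    assignments = None
    if sort_units:
        assignments = sort_segment(waveforms, active, spc or SpcConfig())
    summary = summarize_slice(
        table, active, freqs, assignments,
        slice_id=slice_id or segment.slice_id,
        genotype=segment.genotype, drug=segment.drug,
    )
    return summary, table, waveforms, active, assignments


def simulate_and_analyze(
    genotype: str,
    drug: str,
    n_slices: int,
    seed: int,
    sort_units: bool = False,
    duration: float = 50.0,
    fs: float = 20_000.0,
    geometry: ArrayGeometry | None = None,
    preset: ConditionPreset | None = None,
    noise: NoiseModel | None = None,
    filter_spec: FilterSpec | None = None,
    criterion: ActivityCriterion | None = None,
    spc: SpcConfig | None = None,
    multiplier: float = 4.5,
    progress: bool = False,
) -> list[SliceSummary]:
    """Render ``n_slices`` of one condition and run the full analysis on each."""
    geometry = geometry or ArrayGeometry.default()
    preset = preset or build_preset(genotype, drug)
    noise = noise or NoiseModel()
    summaries = []
    for i in range(n_slices):
        s = _slice_seed(seed, i)
        segment, _truth = render_recording(
            geometry, preset, noise, seed=s, fs=fs, duration=duration,
            slice_id=f"{genotype}-{drug}-{i:02d}",
        )
        spc_i = None
        if sort_units:
            base = spc or SpcConfig()
            spc_i = dataclasses.replace(base, seed=_slice_seed(seed, 10_000 + i))
        summary, *_ = analyze_segment(
            segment, filter_spec=filter_spec, multiplier=multiplier,
            criterion=criterion, spc=spc_i, sort_units=sort_units,
            slice_id=segment.slice_id,
        )
        summaries.append(summary)
        if progress:
            log.info("slice %s: n_active=%d mean_freq=%.2f Hz",
                     summary.slice_id, summary.n_active, summary.mean_frequency_hz)
    return summaries


def run_pipeline(config: PipelineConfig):
    """Full file-producing run: summaries + condition report + manifest."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    seeds = [_slice_seed(config.seed, i) for i in range(config.n_slices)]
    summaries = simulate_and_analyze(
        config.genotype, config.drug, config.n_slices, config.seed,
        sort_units=config.sort_units, duration=config.duration, fs=config.fs,
        filter_spec=config.filter, criterion=config.criterion, spc=config.spc,
        multiplier=config.multiplier,
    )
    timings["analyze"] = time.perf_counter() - t0

    report = {
        "condition": f"{config.genotype}:{config.drug}",
        "n_slices": config.n_slices,
        "slices": [
            {
                "slice_id": s.slice_id,
                "n_active": s.n_active,
                "mean_frequency_hz": s.mean_frequency_hz,
                "total_spikes_per_minute": s.total_spikes_per_minute,
                "units_per_electrode": s.units_per_electrode,
            }
            for s in summaries
        ],
        "mean_n_active": float(np.mean([s.n_active for s in summaries])),
        "mean_frequency_hz": float(np.nanmean([s.mean_frequency_hz for s in summaries])),
        "mean_spikes_per_minute": float(np.mean([s.total_spikes_per_minute for s in summaries])),
    }
    units = [s.units_per_electrode for s in summaries if s.units_per_electrode is not None]
    if units:
        report["mean_units_per_electrode"] = float(np.mean(units))

    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=_package_version(),
        seeds=seeds,
        timings_s=timings,
    )
    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (outdir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True)
        )
    return summaries, report, manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("vhmea")
    except PackageNotFoundError:
        return "0.0.0+local"
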