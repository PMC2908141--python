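"""HDF5/CSV/YAML input-output for recordings, events and configuration.

Recording container schema (versioned):
  /voltages            float32 (n_electrodes, n_samples) in microvolts
  root attrs           schema_version, fs, duration, genotype, drug,
                       slice_id, segment_id, meta (JSON blob of the same)
  /geometry            attrs n_rows, n_cols, spacing_um; dataset mask
  /truth/...           optional planted ground truth (spike times per unit,
                       templates, rates, per-electrode active flags)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import (
    ArrayGeometry,
    GroundTruth,
    RecordingSegment,
    SpikeTemplate,
)

SCHEMA_VERSION = 1


class FormatError(ValueError):
    pass


def write_recording(path: str | Path, segment: RecordingSegment,
                    truth: GroundTruth | None = None) -> None:
    meta = {
        "schema_version": SCHEMA_VERSION,
        "fs": segment.fs,
        "duration": segment.duration,
        "genotype": segment.genotype,
        "drug": segment.drug,
        "slice_id": segment.slice_id,
        "segment_id": segment.segment_id,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("voltages", data=segment.samples.astype(np.float32),
                         compression="gzip", compression_opts=1)
        for k, v in meta.items():
            f.attrs[k] = v
        f.attrs["meta"] = json.dumps(meta)
        g = f.create_group("geometry")
        g.attrs["n_rows"] = segment.geometry.n_rows
        g.attrs["n_cols"] = segment.geometry.n_cols
        g.attrs["spacing_um"] = segment.geometry.spacing_um
        g.create_dataset("mask", data=np.asarray(segment.geometry.ventral_horn_mask))
        if truth is not None:
            tg = f.create_group("truth")
            tg.create_dataset("active", data=truth.active)
            st = tg.create_group("spike_times")
            tp = tg.create_group("templates")
            for (e, u), times in truth.spike_times.items():
                name = f"e{e}_u{u}"
                st.create_dataset(name, data=times)
                tpl = truth.templates[(e, u)]
                d = tp.create_dataset(name, data=tpl.waveform)
                d.attrs["peak_amplitude_uv"] = tpl.peak_amplitude_uv
                d.attrs["width_ms"] = tpl.width_ms
                d.attrs["polarity"] = tpl.polarity
                d.attrs["rate_hz"] = truth.rates.get((e, u), float("nan"))


def _require_attr(f: h5py.File, name: str):
    if name not in f.attrs:
        raise FormatError(f"missing required attribute {name!r}")
    return f.attrs[name]


def read_recording(path: str | Path) -> tuple[RecordingSegment, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        if "voltages" not in f:
            raise FormatError("missing dataset 'voltages'")
        version = int(_require_attr(f, "schema_version"))
        if version > SCHEMA_VERSION:
            raise FormatError(f"unsupported schema version {version}")
        fs = float(_require_attr(f, "fs"))
        duration = float(_require_attr(f, "duration"))
        if fs <= 0 or duration <= 0:
            raise FormatError("fs and duration must be positive")
        if "geometry" not in f:
            raise FormatError("missing group 'geometry'")
        g = f["geometry"]
        geometry = ArrayGeometry(
            n_rows=int(g.attrs["n_rows"]),
            n_cols=int(g.attrs["n_cols"]),
            spacing_um=float(g.attrs["spacing_um"]),
            ventral_horn_mask=tuple(int(i) for i in g["mask"][()]),
        )
        segment = RecordingSegment(
            samples=f["voltages"][()],
            fs=fs,
            duration=duration,
            geometry=geometry,
            genotype=str(f.attrs.get("genotype", "")),
            drug=str(f.attrs.get("drug", "")),
            slice_id=str(f.attrs.get("slice_id", "")),
            segment_id=str(f.attrs.get("segment_id", "")),
        )
        truth = None
        if "truth" in f:
            tg = f["truth"]
            truth = GroundTruth(active=tg["active"][()].astype(bool))
            for name, ds in tg["spike_times"].items():
                e, u = (int(s[1:]) for s in name.split("_"))
                truth.spike_times[(e, u)] = ds[()]
                tpl_ds = tg["templates"][name]
                truth.templates[(e, u)] = SpikeTemplate(
                    waveform=tpl_ds[()],
                    peak_amplitude_uv=float(tpl_ds.attrs["peak_amplitude_uv"]),
                    width_ms=float(tpl_ds.attrs["width_ms"]),
                    polarity=str(tpl_ds.attrs["polarity"]),
                )
                truth.rates[(e, u)] = float(tpl_ds.attrs["rate_hz"])
    return segment, truth


def write_waveforms(path: str | Path, waveforms, mode: str = "a") -> None:
    """Append the detector's waveform matrix to a recording container."""
    with h5py.File(path, mode) as f:
        if "waveforms" in f:
            del f["waveforms"]
        g = f.create_group("waveforms")
        g.attrs["window"] = waveforms.window
        for e, snips in waveforms.snippets.items():
            g.create_dataset(f"e{e}", data=snips.astype(np.float32))


def write_unit_manifest(path: str | Path, truth: GroundTruth) -> None:
    rows = [
        {
            "electrode": e,
            "unit_id": u,
            "rate_hz": truth.rates.get((e, u), float("nan")),
            "n_spikes": len(times),
        }
        for (e, u), times in sorted(truth.spike_times.items())
    ]
    pd.DataFrame(rows, columns=["electrode", "unit_id", "rate_hz", "n_spikes"]).to_csv(
        path, index=False
    )


def write_events_csv(path: str | Path, table) -> None:
    table.to_dataframe().to_csv(path, index=False)


def write_assignments_csv(path: str | Path, assignments) -> None:
    rows = []
    for e in sorted(assignments):
        a = assignments[e]
        for i, lbl in enumerate(a.labels):
            rows.append({"electrode": e, "spike_idx": i, "unit": int(lbl),
                         "temperature": a.temperature})
    pd.DataFrame(rows, columns=["electrode", "spike_idx", "unit", "temperature"]).to_csv(
        path, index=False
    )


def save_config(path: str | Path, config) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path):
    from .pipeline import PipelineConfig

    data = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.from_dict(data)
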