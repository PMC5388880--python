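"""Reading and writing of the package's on-disk formats.

Bolus cohorts travel as a CSV manifest plus per-trace two-column CSVs or a
single HDF5 container; LFPs as HDF5 (samples dataset + sampling-rate
attribute) or two-column CSV; masks as single-channel TIFF with a JSON
sidecar holding the physical pixel size; configurations as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
import tifffile

from .bolus import BolusTrace
from .morphometry import LabeledMask
from .pac import LFPRecording

__all__ = [
    "write_bolus_cohort_csv", "read_bolus_cohort_csv",
    "write_bolus_cohort_hdf5", "read_bolus_cohort_hdf5",
    "write_lfp_hdf5", "read_lfp_hdf5",
    "write_mask_tiff", "read_mask_tiff",
    "write_config_json",
]


def write_bolus_cohort_csv(
    pairs: Iterable[tuple[BolusTrace, BolusTrace]],
    outdir: str | Path,
    truth: pd.DataFrame | None = None,
) -> Path:
    """Write per-trace CSVs plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in pairs:
        for trace in pair:
            fname = f"{trace.vessel_id}_{trace.condition}.csv"
            pd.DataFrame({"time_s": trace.time, "fluorescence": trace.fluorescence}
                         ).to_csv(outdir / fname, index=False)
            rows.append({"vessel_id": trace.vessel_id, "vessel_type": trace.vessel_type,
                         "condition": trace.condition, "trace_file": fname})
    manifest = pd.DataFrame(rows)
    if truth is not None:
        manifest = manifest.merge(truth, on="vessel_id", how="left",
                                  suffixes=("", "_truth"))
    path = outdir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


def read_bolus_cohort_csv(manifest_path: str | Path) -> list[BolusTrace]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    traces = []
    for _, row in df.iterrows():
        tr = pd.read_csv(manifest_path.parent / row["trace_file"])
        traces.append(BolusTrace(
            vessel_id=str(row["vessel_id"]), vessel_type=row["vessel_type"],
            condition=row["condition"], time=tr["time_s"].to_numpy(),
            fluorescence=tr["fluorescence"].to_numpy(),
        ))
    return traces


def write_bolus_cohort_hdf5(
    pairs: Iterable[tuple[BolusTrace, BolusTrace]],
    path: str | Path,
) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for pair in pairs:
            for trace in pair:
                g = f.create_group(f"{trace.vessel_id}/{trace.condition}")
                g.create_dataset("time_s", data=trace.time)
                g.create_dataset("fluorescence", data=trace.fluorescence)
                g.attrs["vessel_type"] = trace.vessel_type
    return path


def read_bolus_cohort_hdf5(path: str | Path) -> list[BolusTrace]:
    traces = []
    with h5py.File(path, "r") as f:
        for vid in f:
            for cond in f[vid]:
                g = f[vid][cond]
                traces.append(BolusTrace(
                    vessel_id=vid, vessel_type=g.attrs["vessel_type"],
                    condition=cond, time=g["time_s"][:],
                    fluorescence=g["fluorescence"][:],
                ))
    return traces


def write_lfp_hdf5(rec: LFPRecording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=rec.samples)
        d.attrs["sampling_rate"] = rec.sampling_rate
        d.attrs["channel_id"] = rec.channel_id
        d.attrs["animal_id"] = rec.animal_id
        d.attrs["genotype"] = rec.genotype
    return path


def read_lfp_hdf5(path: str | Path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        d = f["samples"]
        return LFPRecording(
            samples=d[:], sampling_rate=float(d.attrs["sampling_rate"]),
            channel_id=str(d.attrs.get("channel_id", "")),
            animal_id=str(d.attrs.get("animal_id", "")),
            genotype=str(d.attrs.get("genotype", "")),
        )


def write_mask_tiff(mask: LabeledMask, path: str | Path) -> Path:
    """Single-channel TIFF plus a JSON sidecar with the pixel size (um)."""
    path = Path(path)
    tifffile.imwrite(path, mask.pixels.astype(np.int32))
    sidecar = {"pixel_size_um": mask.pixel_size, "stain_label": mask.stain_label}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_mask_tiff(path: str | Path) -> LabeledMask:
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    pixel_size, stain = 1.0, ""
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        pixel_size = float(meta.get("pixel_size_um", 1.0))
        stain = str(meta.get("stain_label", ""))
    return LabeledMask(np.asarray(pixels), pixel_size, stain)


def write_config_json(cfg: object, path: str | Path) -> Path:
    path = Path(path)
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)
    path.write_text(json.dumps(cfg, indent=2, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")
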