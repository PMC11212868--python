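"""File formats: trace CSV, multi-page TIFF images, cohort CSV, JSON.

Traces are long-format CSV with one row per frame per cell
(``time_s, sarcomere_length_um, nuclear_length_um, nuclear_width_um,
cell_id, genotype``).  Images are multi-page TIFF in channel order
chromatin/tubulin/foci/lamina with the voxel size in the resolution tags,
plus a sidecar JSON carrying the per-image ground truth.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .images import CHANNEL_ORDER, GroundTruth
from .traces import ContractionTrace

TRACE_COLUMNS = ["time_s", "sarcomere_length_um", "nuclear_length_um",
                 "nuclear_width_um", "cell_id", "genotype"]


def traces_to_frame(traces) -> pd.DataFrame:
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "time_s": t.time,
            "sarcomere_length_um": t.sarcomere_length,
            "nuclear_length_um": t.nuclear_length,
            "nuclear_width_um": t.nuclear_width,
            "cell_id": t.cell_id,
            "genotype": t.genotype_label,
        }))
    return pd.concat(frames, ignore_index=True)


def write_traces_csv(traces, path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.9g")


def read_traces_csv(path) -> list[ContractionTrace]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("time_s")
        t = g["time_s"].to_numpy()
        dt = np.diff(t)
        pacing = 1.0
        if len(dt) > 1:
            # recover pacing frequency from the trace span assuming whole cycles
            span = t[-1] - t[0] + np.median(dt)
            pacing = max(1, round(span)) / span if span > 0 else 1.0
            pacing = 1.0 / (span / max(1, round(span)))
        traces.append(ContractionTrace(
            time=t,
            sarcomere_length=g["sarcomere_length_um"].to_numpy(),
            nuclear_length=g["nuclear_length_um"].to_numpy(),
            nuclear_width=g["nuclear_width_um"].to_numpy(),
            cell_id=str(cell_id),
            genotype_label=str(g["genotype"].iloc[0]),
            pacing_frequency=float(pacing),
        ))
    return traces


def write_image_tiff(channels: dict, path, voxel_size: float,
                     truth: GroundTruth | None = None) -> None:
    """Multi-page TIFF (chromatin/tubulin/foci/lamina) + ground-truth JSON."""
    stack = np.stack([channels[c] for c in CHANNEL_ORDER]).astype(np.float32)
    px_per_um = 1.0 / voxel_size
    tifffile.imwrite(path, stack, resolution=(px_per_um, px_per_um),
                     photometric="minisblack",
                     metadata={"axes": "CYX", "channels": list(CHANNEL_ORDER),
                               "voxel_size_um": voxel_size})
    if truth is not None:
        Path(str(path) + ".truth.json").write_text(
            json.dumps(truth.to_dict(), indent=1))


def read_image_tiff(path):
    """Returns (channels dict, voxel_size, truth dict or None)."""
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        voxel = None
        meta = tf.shaped_metadata or tf.imagej_metadata
        if isinstance(meta, (list, tuple)) and meta:
            meta = meta[0]
        if isinstance(meta, dict):
            voxel = meta.get("voxel_size_um")
        if voxel is None:
            res = tf.pages[0].tags.get("XResolution")
            if res is not None:
                num, den = res.value
                voxel = den / num
    channels = {c: stack[i] for i, c in enumerate(CHANNEL_ORDER)}
    truth_path = Path(str(path) + ".truth.json")
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return channels, float(voxel), truth


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
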