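"""Readers and writers: flat-binary/HDF5 LFP, CSV annotations, JSON results.

The flat-binary LFP format is 16-bit little-endian interleaved samples plus
a JSON sidecar declaring the sampling rate, channel names and gain
(physical units = stored integer x gain).  The HDF5 container stores the
float samples losslessly.  Annotations are CSV tables of half-open labeled
intervals.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .recording import LFPRecording, SessionAnnotation

logger = logging.getLogger("thetanest")

__all__ = [
    "write_lfp_binary",
    "read_lfp",
    "write_lfp_hdf5",
    "read_lfp_hdf5",
    "write_annotation",
    "read_annotation",
    "write_ground_truth",
]


def write_lfp_binary(rec: LFPRecording, path: str | Path,
                     sidecar: str | Path | None = None) -> Path:
    """Write interleaved little-endian int16 samples plus a JSON sidecar.

    The gain is chosen so the full int16 range covers the data; stored
    values quantize the input (read back as ``int16 * gain``).
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    peak = float(np.max(np.abs(rec.samples))) or 1.0
    gain = peak / 32000.0
    ints = np.round(rec.samples / gain).astype("<i2")
    ints.T.reshape(-1).tofile(path)  # interleaved: sample-major
    meta = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_labels),
        "gain": gain,
        "dtype": "int16-le",
        "n_samples": rec.n_samples,
        "t0": rec.t0,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_lfp(path: str | Path, sidecar: str | Path | None = None) -> LFPRecording:
    """Read a flat int16 LFP file with its JSON sidecar.

    The sidecar must declare ``fs``, ``channel_names`` and ``gain``; sample
    counts are validated against the file length.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar} does not declare a sampling rate 'fs'")
    channels = meta.get("channel_names")
    if not channels:
        raise ValueError(f"sidecar {sidecar} does not declare 'channel_names'")
    gain = float(meta.get("gain", 1.0))
    raw = np.fromfile(path, dtype="<i2")
    n_ch = len(channels)
    if raw.size % n_ch != 0:
        raise ValueError(
            f"{path}: {raw.size} samples not divisible by {n_ch} channels"
        )
    if "n_samples" in meta and raw.size != meta["n_samples"] * n_ch:
        raise ValueError(
            f"{path}: expected {meta['n_samples'] * n_ch} values "
            f"({meta['n_samples']} samples x {n_ch} channels), found {raw.size}"
        )
    samples = raw.reshape(-1, n_ch).T.astype(float) * gain
    return LFPRecording(samples, float(meta["fs"]), channels,
                        float(meta.get("t0", 0.0)))


def write_lfp_hdf5(rec: LFPRecording, path: str | Path) -> Path:
    """Lossless HDF5 container (float64 samples)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        # track_times=False keeps repeated runs byte-identical
        ds = f.create_dataset("samples", data=rec.samples, track_times=False)
        ds.attrs["fs"] = rec.fs
        ds.attrs["t0"] = rec.t0
        ds.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
    return path


def read_lfp_hdf5(path: str | Path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        ds = f["samples"]
        return LFPRecording(
            ds[...],
            float(ds.attrs["fs"]),
            [str(c) for c in ds.attrs["channel_labels"]],
            float(ds.attrs.get("t0", 0.0)),
        )


def write_annotation(annotation: SessionAnnotation, path: str | Path) -> Path:
    path = Path(path)
    annotation.to_frame().to_csv(path, index=False)
    return path


def read_annotation(path: str | Path) -> SessionAnnotation:
    """Read and validate a CSV annotation (onset_s, offset_s, label_type, label).

    An empty file yields an empty annotation with a logged warning;
    overlapping intervals within a label type are rejected with the
    offending rows named.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("annotation file %s is empty", path)
        return SessionAnnotation([])
    if frame.empty:
        logger.warning("annotation file %s has no intervals", path)
        return SessionAnnotation([])
    return SessionAnnotation.from_frame(frame)


def write_ground_truth(truth, path: str | Path) -> Path:
    """Serialize generator ground truth to JSON (arrays as lists)."""
    path = Path(path)
    payload = {
        "true_direction": truth.true_direction,
        "true_lag_ms": truth.true_lag_ms,
        "burst_events": [
            {"time_s": t, "family": k, "theta_phase": ph}
            for t, k, ph in truth.burst_events
        ],
        "template_freqs": truth.template_freqs.tolist(),
        "family_templates": truth.family_templates.tolist(),
        "context_weights": {k: v.tolist() for k, v in truth.context_weights.items()},
        "component_variances": truth.component_variances,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path
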