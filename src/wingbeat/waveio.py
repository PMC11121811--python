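"""Waveform file I/O: float sample arrays with a JSON metadata sidecar.

A waveform on disk is a pair ``<name>.npy`` (float64 samples) or
``<name>.csv`` (one voltage per line) plus ``<name>.json`` holding
``sampling_rate``, optional ``t0`` (ISO-8601) and optional ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .sigproc import DEFAULT_SAMPLING_RATE, TransitSignal

__all__ = ["read_waveform", "write_waveform", "iter_waveforms"]


def write_waveform(path_stem, signal: TransitSignal, fmt: str = "npy") -> Path:
    """Write samples + sidecar; returns the sidecar path."""
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "npy":
        np.save(stem.with_suffix(".npy"), signal.samples)
        data_file = stem.with_suffix(".npy").name
    elif fmt == "csv":
        np.savetxt(stem.with_suffix(".csv"), signal.samples, fmt="%.9g")
        data_file = stem.with_suffix(".csv").name
    else:
        raise ValueError(f"unknown waveform format {fmt!r}")
    meta = {
        "sampling_rate": signal.sampling_rate,
        "t0": None if signal.t0 is None else str(signal.t0),
        "samples_file": data_file,
        "truth": signal.truth,
    }
    sidecar = stem.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2)
    return sidecar


def read_waveform(sidecar_path) -> TransitSignal:
    sidecar = Path(sidecar_path)
    with open(sidecar) as fh:
        meta = json.load(fh)
    data = sidecar.parent / meta["samples_file"]
    if data.suffix == ".npy":
        samples = np.load(data)
    else:
        samples = np.loadtxt(data)
    t0 = meta.get("t0")
    return TransitSignal(
        samples,
        sampling_rate=float(meta.get("sampling_rate", DEFAULT_SAMPLING_RATE)),
        t0=None if t0 is None else np.datetime64(t0),
        truth=meta.get("truth"),
    )


def iter_waveforms(directory):
    """Yield TransitSignal objects for every sidecar JSON in a directory."""
    for sidecar in sorted(Path(directory).glob("*.json")):
        yield read_waveform(sidecar)
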