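"""Sampled single-channel current traces and their on-disk format.

A recording is stored as a two-column TSV (``time_s``, ``current_pA``) next to
a JSON sidecar holding acquisition metadata; the pair round-trips to full
float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TraceRecording", "TraceFormatError", "write_trace", "read_trace"]

_SIDECAR_REQUIRED = ("v_applied_mV", "sampling_rate_kHz")


class TraceFormatError(ValueError):
    """A trace file or its sidecar does not match the expected schema."""


@dataclass(frozen=True)
class TraceRecording:
    """Current time series at a fixed holding potential.

    ``currents`` are in pA (open-pore current is negative at negative holding
    potentials); ``sampling_rate`` in kHz; ``metadata`` carries provenance
    (condition label, seed, model hash, ...).
    """

    currents: np.ndarray
    sampling_rate: float  # kHz
    v_applied: float  # mV
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "currents", arr)
        if arr.ndim != 1:
            raise ValueError("currents must be one-dimensional")
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("currents must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.currents.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / (self.sampling_rate * 1e3)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / (self.sampling_rate * 1e3)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(rec: TraceRecording, path) -> Path:
    """Write TSV + JSON sidecar; returns the TSV path."""
    path = Path(path)
    times = rec.times_s
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("time_s\tcurrent_pA\n")
        for t, i in zip(times, rec.currents):
            handle.write(f"{float(t)!r}\t{float(i)!r}\n")
    sidecar = {
        "v_applied_mV": rec.v_applied,
        "sampling_rate_kHz": rec.sampling_rate,
        "n_samples": rec.n_samples,
        **rec.metadata,
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as handle:
        json.dump(sidecar, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return path


def read_trace(path) -> TraceRecording:
    """Read a TSV + sidecar pair written by :func:`write_trace`."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise TraceFormatError(f"missing sidecar {sidecar_path}")
    try:
        with open(sidecar_path, encoding="utf-8") as handle:
            sidecar = json.load(handle)
    except json.JSONDecodeError as exc:
        raise TraceFormatError(f"sidecar {sidecar_path} is not valid JSON") from exc
    missing = [k for k in _SIDECAR_REQUIRED if k not in sidecar]
    if missing:
        raise TraceFormatError(f"sidecar missing required keys: {missing}")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.shape[1] != 2:
        raise TraceFormatError("trace TSV must have exactly two columns")
    metadata = {
        k: v for k, v in sidecar.items()
        if k not in (*_SIDECAR_REQUIRED, "n_samples")
    }
    return TraceRecording(
        currents=data[:, 1],
        sampling_rate=float(sidecar["sampling_rate_kHz"]),
        v_applied=float(sidecar["v_applied_mV"]),
        metadata=metadata,
    )
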