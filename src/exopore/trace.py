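"""Trace container and file I/O.

A :class:`Trace` is a uniformly sampled current (pA) or membrane-capacitance
(fF) signal.  Two on-disk dialects are supported:

* a columnar text format — CSV with ``#``-prefixed metadata header lines
  (``rate_hz``, ``units``, ``kind``, ``filter_hz``, ``t0_s`` and
  ``annotation:<name>=<time_s>`` entries) followed by ``time_s,value`` rows;
* an HDF5 container with the samples under ``/trace/samples`` and the same
  metadata stored as attributes.

Times are seconds at the I/O boundary; the analysis code works in ms.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

AMPEROMETRY = "amperometry"
CAPACITANCE = "capacitance"

_KIND_DEFAULTS = {
    AMPEROMETRY: {"sampling_rate": 25000.0, "filter_cutoff": 2000.0, "units": "pA"},
    CAPACITANCE: {"sampling_rate": 2000.0, "filter_cutoff": None, "units": "fF"},
}


@dataclass
class Trace:
    """Uniformly sampled signal with units and acquisition metadata.

    Parameters
    ----------
    samples : array-like
        Signal values (pA for amperometry, fF for capacitance).
    sampling_rate : float, optional
        Hz.  Defaults to 25 kHz for amperometry traces.
    kind : str
        ``"amperometry"`` or ``"capacitance"``.
    t0 : float
        Time of the first sample, seconds.
    filter_cutoff : float or None
        -3 dB cutoff (Hz) of the analog filter already applied, if any.
        Defaults to 2 kHz for amperometry.
    annotations : dict
        Marker name -> time in seconds (e.g. ``{"flash": 0.5}``).
    """

    samples: np.ndarray
    sampling_rate: float | None = None
    kind: str = AMPEROMETRY
    t0: float = 0.0
    filter_cutoff: float | None = None
    units: str | None = None
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KIND_DEFAULTS:
            raise ValueError(f"unknown trace kind {self.kind!r}")
        defaults = _KIND_DEFAULTS[self.kind]
        if self.sampling_rate is None:
            self.sampling_rate = defaults["sampling_rate"]
        if self.filter_cutoff is None and self.kind == AMPEROMETRY:
            self.filter_cutoff = defaults["filter_cutoff"]
        if self.units is None:
            self.units = defaults["units"]
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    # -- derived geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return self.n * self.dt_ms

    def times_ms(self) -> np.ndarray:
        """Sample times in ms, relative to t0."""
        return np.arange(self.n) * self.dt_ms

    def index_at_ms(self, t_ms: float) -> float:
        """Fractional sample index of a time given in ms relative to t0."""
        return t_ms / self.dt_ms

    def with_samples(self, samples: np.ndarray, **changes) -> "Trace":
        return replace(self, samples=np.asarray(samples, dtype=float), **changes)


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

_REQUIRED_HEADER = ("rate_hz", "units")


def _write_text(trace: Trace, path: str) -> None:
    lines = [
        f"# rate_hz={float(trace.sampling_rate)!r}",
        f"# units={trace.units}",
        f"# kind={trace.kind}",
        f"# t0_s={float(trace.t0)!r}",
    ]
    if trace.filter_cutoff is not None:
        lines.append(f"# filter_hz={float(trace.filter_cutoff)!r}")
    for name, t in trace.annotations.items():
        lines.append(f"# annotation:{name}={float(t)!r}")
    lines.append("time_s,value")
    t = trace.t0 + np.arange(trace.n) / trace.sampling_rate
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for ti, vi in zip(t.tolist(), trace.samples.tolist()):
            fh.write(f"{ti!r},{vi!r}\n")


def _read_text(path: str) -> Trace:
    meta: dict[str, str] = {}
    annotations: dict[str, float] = {}
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    continue
                key, _, val = body.partition("=")
                key = key.strip()
                if key.startswith("annotation:"):
                    annotations[key[len("annotation:"):]] = float(val)
                else:
                    meta[key] = val.strip()
            elif line[0].isalpha():
                continue  # column header row
            else:
                a, _, b = line.partition(",")
                times.append(float(a))
                values.append(float(b))
    for key in _REQUIRED_HEADER:
        if key not in meta:
            raise ValueError(f"trace header field {key!r} missing in {path}")
    rate = float(meta["rate_hz"])
    t = np.asarray(times)
    if t.size >= 2:
        dt = np.diff(t)
        nominal = 1.0 / rate
        if np.max(np.abs(dt - nominal)) > 1e-6 * max(nominal, abs(t[-1])):
            raise ValueError(f"non-uniform time column in {path}")
    fcut = float(meta["filter_hz"]) if "filter_hz" in meta else None
    return Trace(
        samples=np.asarray(values),
        sampling_rate=rate,
        kind=meta.get("kind", AMPEROMETRY),
        t0=float(meta.get("t0_s", t[0] if t.size else 0.0)),
        filter_cutoff=fcut,
        units=meta["units"],
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# HDF5 dialect
# ---------------------------------------------------------------------------


def _write_hdf5(trace: Trace, path: str) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("trace")
        ds = grp.create_dataset("samples", data=trace.samples)
        ds.attrs["rate_hz"] = trace.sampling_rate
        ds.attrs["units"] = trace.units
        ds.attrs["kind"] = trace.kind
        ds.attrs["t0_s"] = trace.t0
        if trace.filter_cutoff is not None:
            ds.attrs["filter_hz"] = trace.filter_cutoff
        ds.attrs["annotations"] = json.dumps(trace.annotations)


def _read_hdf5(path: str) -> Trace:
    with h5py.File(path, "r") as fh:
        ds = fh["trace/samples"]
        attrs = dict(ds.attrs)
        for key in _REQUIRED_HEADER:
            if key not in attrs:
                raise ValueError(f"trace attribute {key!r} missing in {path}")
        return Trace(
            samples=ds[()],
            sampling_rate=float(attrs["rate_hz"]),
            kind=str(attrs.get("kind", AMPEROMETRY)),
            t0=float(attrs.get("t0_s", 0.0)),
            filter_cutoff=float(attrs["filter_hz"]) if "filter_hz" in attrs else None,
            units=str(attrs["units"]),
            annotations=json.loads(attrs.get("annotations", "{}")),
        )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_HDF5_EXT = {".h5", ".hdf5", ".hdf"}


def _dialect(path: str, format_hint: str | None) -> str:
    if format_hint in ("text", "hdf5"):
        return format_hint
    ext = os.path.splitext(path)[1].lower()
    return "hdf5" if ext in _HDF5_EXT else "text"


def read_trace(path: str, format_hint: str | None = None) -> Trace:
    """Read a trace file (text or HDF5 dialect, chosen by extension or hint)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _dialect(path, format_hint) == "hdf5":
        return _read_hdf5(path)
    return _read_text(path)


def write_trace(trace: Trace, path: str, format_hint: str | None = None) -> str:
    """Write a trace losslessly; the dialect round-trips with :func:`read_trace`."""
    if _dialect(path, format_hint) == "hdf5":
        _write_hdf5(trace, path)
    else:
        _write_text(trace, path)
    return path
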