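"""Plain-text I/O for TCSPC histograms and IRF curves.

Format: two whitespace/tab-delimited columns (time in ns, counts), header
lines starting with ``#``. A header line ``# fwhm_ns: <value>`` carries the
IRF width metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .decay_model import IRFCurve, TCSPCHistogram, TimeGrid

__all__ = ["read_histogram", "write_histogram", "read_irf", "write_irf"]


def _read_two_columns(path) -> tuple[TimeGrid, np.ndarray, dict]:
    meta: dict[str, str] = {}
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
    if len(times) < 2:
        raise ValueError(f"{path}: need at least two data rows")
    t = np.asarray(times)
    steps = np.diff(t)
    width = float(np.median(steps))
    if width <= 0 or np.any(np.abs(steps - width) > 1e-6 * max(width, 1.0)):
        raise ValueError(f"{path}: time axis is not uniformly spaced")
    grid = TimeGrid(bin_width=width, n_bins=len(t), origin=float(t[0]))
    return grid, np.asarray(values), meta


def read_histogram(path) -> TCSPCHistogram:
    """Read a TCSPC histogram from two-column delimited text."""
    grid, counts, _ = _read_two_columns(path)
    return TCSPCHistogram(grid=grid, counts=counts)


def read_irf(path) -> IRFCurve:
    """Read an IRF curve; picks up ``fwhm_ns`` metadata when present."""
    grid, values, meta = _read_two_columns(path)
    fwhm = float(meta["fwhm_ns"]) if "fwhm_ns" in meta else None
    return IRFCurve(grid=grid, values=values, fwhm=fwhm)


def _write_two_columns(path, grid: TimeGrid, values: np.ndarray, header: list[str]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("# time_ns\tcounts\n")
        for t, v in zip(grid.times, values):
            fh.write(f"{t:.6f}\t{v:.10g}\n")


def write_histogram(path, hist: TCSPCHistogram, header: list[str] | None = None) -> None:
    _write_two_columns(path, hist.grid, hist.counts, header or [])


def write_irf(path, irf: IRFCurve, header: list[str] | None = None) -> None:
    lines = list(header or [])
    if irf.fwhm is not None:
        lines.append(f"fwhm_ns: {irf.fwhm}")
    _write_two_columns(path, irf.grid, irf.values, lines)
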