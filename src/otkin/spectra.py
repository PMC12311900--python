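"""Spectrum data model and preprocessing.

A 1-D NMR spectrum is treated as a discrete measure: nonnegative mass
sitting at chemical-shift (ppm) grid points.  All downstream optimal-
transport machinery operates on (position, mass) atom lists, so spectra
on different grids never need resampling onto a common axis.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "Manifest",
    "load_spectrum",
    "write_spectrum",
    "load_manifest",
    "write_manifest",
    "preprocess",
    "normalize",
    "pool",
]

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class Spectrum:
    """Discrete measure over an ascending ppm axis.

    Attributes
    ----------
    axis : ndarray
        Chemical-shift positions in ppm, strictly increasing, finite.
    intensity : ndarray
        Mass at each grid point; same length as ``axis``.
    meta : dict
        Free-form provenance (source path, time index, ...).
    """

    axis: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if axis.ndim != 1 or intensity.ndim != 1:
            raise ValueError("axis and intensity must be one-dimensional")
        if axis.size != intensity.size:
            raise ValueError(
                f"axis has {axis.size} points but intensity has {intensity.size}"
            )
        if axis.size < 1:
            raise ValueError("spectrum needs at least one grid point")
        if not np.all(np.isfinite(axis)) or not np.all(np.isfinite(intensity)):
            raise ValueError("axis and intensity must be finite")
        if axis.size > 1 and not np.all(np.diff(axis) > 0):
            raise ValueError("axis must be strictly increasing")

    @property
    def total_mass(self) -> float:
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return int(self.axis.size)

    def with_meta(self, **kv: Any) -> "Spectrum":
        return replace(self, meta={**self.meta, **kv})


@dataclass(frozen=True)
class Manifest:
    """Ordered (time, path) entries of a measured series."""

    times: tuple[float, ...]
    paths: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.paths):
            raise ValueError("times and paths differ in length")
        if len(self.times) == 0:
            raise ValueError("manifest is empty")
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("manifest times must be strictly increasing")
        if len(set(self.paths)) != len(self.paths):
            raise ValueError("manifest paths must be unique")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(zip(self.times, self.paths))


_DELIMS = (",", "\t", ";", None)  # None = any whitespace


def _split_line(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.split()
    return [c.strip() for c in line.split(delim)]


def _sniff_delim(line: str) -> str | None:
    for d in (",", "\t", ";"):
        if d in line:
            return d
    return None


def load_spectrum(path: str | Path, *, delimiter: str | None = "auto") -> Spectrum:
    """Read a two-column (ppm, intensity) delimited-text spectrum file.

    The delimiter is auto-detected (comma / tab / semicolon / whitespace)
    unless given.  A single header line is skipped if its cells are not
    numeric.  Descending-ppm files (the usual NMR display convention) are
    reordered to ascending.
    """
    path = Path(path)
    raw = path.read_text()
    return _parse_spectrum(raw, delimiter=delimiter, source=str(path))


def loads_spectrum(text: str, *, delimiter: str | None = "auto") -> Spectrum:
    """Parse spectrum text (see :func:`load_spectrum`)."""
    return _parse_spectrum(text, delimiter=delimiter, source="<string>")


def _parse_spectrum(raw: str, *, delimiter, source: str) -> Spectrum:
    lines = [ln for ln in raw.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{source}: no data rows")
    delim = _sniff_delim(lines[0]) if delimiter == "auto" else delimiter

    start = 0
    first = _split_line(lines[0], delim)
    try:
        [float(c) for c in first[:2]]
    except ValueError:
        start = 1  # header row
    if start >= len(lines):
        raise ValueError(f"{source}: no numeric data rows")

    ppm, inten = [], []
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        cells = _split_line(ln, delim)
        if len(cells) < 2:
            raise ValueError(f"{source}:{lineno}: expected two columns, got {ln!r}")
        try:
            x, y = float(cells[0]), float(cells[1])
        except ValueError:
            raise ValueError(f"{source}:{lineno}: non-numeric cell in {ln!r}") from None
        ppm.append(x)
        inten.append(y)

    ppm_arr = np.asarray(ppm)
    inten_arr = np.asarray(inten)
    order = np.argsort(ppm_arr, kind="stable")
    ppm_arr, inten_arr = ppm_arr[order], inten_arr[order]
    if ppm_arr.size > 1 and np.any(np.diff(ppm_arr) == 0):
        dup = ppm_arr[np.flatnonzero(np.diff(ppm_arr) == 0)[0]]
        raise ValueError(f"{source}: duplicate ppm value {dup!r}")
    return Spectrum(ppm_arr, inten_arr, meta={"source": source})


def write_spectrum(s: Spectrum, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a spectrum as two-column delimited text with a header line.

    Uses repr-roundtrip float formatting so load→write→load is
    bit-identical on the numeric values.
    """
    buf = io.StringIO()
    buf.write(f"ppm{delimiter}intensity\n")
    for x, y in zip(s.axis, s.intensity):
        buf.write(f"{float(x)!r}{delimiter}{float(y)!r}\n")
    Path(path).write_text(buf.getvalue())


def load_manifest(path: str | Path) -> Manifest:
    """Read a delimited-text manifest with columns time, path.

    Relative spectrum paths are resolved against the manifest's directory.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty manifest")
    delim = _sniff_delim(lines[0])
    start = 0
    try:
        float(_split_line(lines[0], delim)[0])
    except ValueError:
        start = 1
    times, paths = [], []
    for ln in lines[start:]:
        cells = _split_line(ln, delim)
        if len(cells) < 2:
            raise ValueError(f"{path}: bad manifest row {ln!r}")
        times.append(float(cells[0]))
        p = Path(cells[1])
        if not p.is_absolute():
            p = path.parent / p
        paths.append(str(p))
    return Manifest(tuple(times), tuple(paths))


def write_manifest(m: Manifest, path: str | Path, *, relative_to: str | Path | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time,path\n")
        for t, p in m:
            pp = Path(p)
            if relative_to is not None:
                try:
                    pp = pp.relative_to(relative_to)
                except ValueError:
                    pass
            fh.write(f"{float(t)!r},{pp}\n")


def preprocess(s: Spectrum, *, clip_negative: bool = True) -> Spectrum:
    """Clip negative intensities (residual baseline noise) to zero.

    Spectra are assumed phased and baseline-corrected upstream; clipping
    is the only correction applied.  With ``clip_negative=False`` the
    spectrum passes through unchanged (diagnostic use).
    """
    if not clip_negative:
        return s
    clipped = np.maximum(s.intensity, 0.0)
    if clipped.sum() <= 0.0:
        raise ValueError("no signal after clipping")
    return replace(s, intensity=clipped)


def normalize(s: Spectrum) -> Spectrum:
    """Scale intensities to unit total mass."""
    total = s.intensity.sum()
    if total <= 0.0:
        raise ValueError("cannot normalize: total intensity is not positive")
    return replace(s, intensity=s.intensity / total)


def pool(s: Spectrum, max_bins: int) -> Spectrum:
    """Sum-pool consecutive grid points into at most ``max_bins`` bins.

    Pooling conserves total mass exactly: each output bin carries the sum
    of its members' masses and sits at their mass-weighted mean ppm
    (arithmetic mean for zero-mass bins).  Linear-interpolation resampling
    is deliberately avoided — it does not conserve mass.
    """
    if max_bins < 1:
        raise ValueError("max_bins must be >= 1")
    n = len(s)
    if max_bins >= n:
        return s
    # Even split of indices into max_bins consecutive groups.
    edges = np.linspace(0, n, max_bins + 1).round().astype(int)
    edges = np.unique(edges)
    masses = np.add.reduceat(s.intensity, edges[:-1])
    weighted = np.add.reduceat(s.intensity * s.axis, edges[:-1])
    counts = np.diff(edges)
    plain = np.add.reduceat(s.axis, edges[:-1]) / counts
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = np.where(masses > 0, weighted / np.where(masses > 0, masses, 1.0), plain)
    # Weighted means of consecutive disjoint groups are nondecreasing but
    # can tie; nudge ties apart is unnecessary because groups of a strictly
    # increasing axis have strictly increasing means when nonempty.
    return Spectrum(pos, masses, meta={**s.meta, "pooled_from": n})
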