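"""Reagent library construction by cutting chemical-shift regions.

A library is a set of reference sub-spectra, one per reagent, obtained by
cutting ppm intervals out of chosen spectra of the series (typically the
substrates from the first spectrum and the products from the last) or out
of separately measured reagent spectra.  The cut fragments, normalized to
unit mass, are the components the transport regression mixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .spectra import Manifest, Spectrum, load_spectrum, normalize, preprocess

__all__ = [
    "RegionSet",
    "ComponentLibrary",
    "cut_regions",
    "build_library",
    "cut_mixture",
    "load_region_config",
]


def _normalize_intervals(intervals: Sequence[Sequence[float]]) -> tuple[tuple[float, float], ...]:
    """Sort each interval to lo < hi, then sort intervals by lo."""
    out = []
    for iv in intervals:
        lo, hi = float(iv[0]), float(iv[1])
        if lo > hi:
            lo, hi = hi, lo
        if lo == hi:
            raise ValueError(f"degenerate interval [{lo}, {hi})")
        out.append((lo, hi))
    return tuple(sorted(out))


@dataclass(frozen=True)
class RegionSet:
    """Named reagent with its ppm intervals and source spectrum.

    Intervals are half-open ``[lo, hi)`` so adjacent regions never double
    count a grid point; they are accepted in either order and normalized
    to lo < hi.  ``source`` identifies the spectrum the region is cut
    from: an int is a time index into the manifest (negative allowed,
    Python-style), a string is a file path.
    """

    name: str
    intervals: tuple[tuple[float, float], ...]
    source: int | str | None = None

    def __post_init__(self) -> None:
        ivs = _normalize_intervals(self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise ValueError(f"region set {self.name!r} has no intervals")
        for (lo1, hi1), (lo2, hi2) in zip(ivs, ivs[1:]):
            if lo2 < hi1:
                raise ValueError(
                    f"region set {self.name!r}: intervals [{lo1},{hi1}) and "
                    f"[{lo2},{hi2}) overlap"
                )


@dataclass(frozen=True)
class ComponentLibrary:
    """Ordered named reagent sub-spectra, each normalized to unit mass."""

    components: tuple[tuple[str, Spectrum], ...]
    regions: tuple[RegionSet, ...] = ()

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("library needs at least one component")
        names = [n for n, _ in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reagent names in library")
        for name, spec in self.components:
            if abs(spec.total_mass - 1.0) > 1e-9:
                raise ValueError(f"component {name!r} is not normalized")

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.components)

    @property
    def spectra(self) -> tuple[Spectrum, ...]:
        return tuple(s for _, s in self.components)

    def all_intervals(self) -> tuple[tuple[float, float], ...]:
        """Union of every region interval in the library (unmerged)."""
        out: list[tuple[float, float]] = []
        for rs in self.regions:
            out.extend(rs.intervals)
        return tuple(sorted(out))


def _in_intervals(axis: np.ndarray, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(axis.shape, dtype=bool)
    for lo, hi in intervals:
        mask |= (axis >= lo) & (axis < hi)
    return mask


def cut_regions(s: Spectrum, intervals: Sequence[Sequence[float]]) -> Spectrum:
    """Restrict a spectrum to grid points inside the half-open intervals.

    Points outside every interval are dropped (not zeroed): the result is
    a smaller discrete measure, which is what the transport problem wants.
    """
    ivs = _normalize_intervals(intervals)
    mask = _in_intervals(s.axis, ivs)
    if not mask.any():
        raise ValueError(f"empty region: no grid point falls in {list(ivs)}")
    return Spectrum(s.axis[mask], s.intensity[mask], meta=dict(s.meta))


def build_library(
    sources: Mapping[str, tuple[Spectrum, Sequence[Sequence[float]]]],
    *,
    region_sources: Mapping[str, int | str] | None = None,
) -> ComponentLibrary:
    """Cut, clip and normalize one component per reagent.

    Parameters
    ----------
    sources : mapping
        reagent name -> (source spectrum, list of [lo, hi] ppm intervals).
    region_sources : mapping, optional
        reagent name -> provenance tag recorded on the RegionSet.

    Intervals of *different* reagents may overlap — the transport
    regression, not the cutter, resolves overlap — but a warning is
    emitted so accidental overlap is visible.
    """
    if not sources:
        raise ValueError("no reagents given")
    region_sources = region_sources or {}
    comps: list[tuple[str, Spectrum]] = []
    regions: list[RegionSet] = []
    for name, (spec, intervals) in sources.items():
        rs = RegionSet(name=name, intervals=tuple(tuple(iv) for iv in intervals),
                       source=region_sources.get(name))
        regions.append(rs)
        cut = cut_regions(spec, rs.intervals)
        comps.append((name, normalize(preprocess(cut)).with_meta(component=name)))
    # pairwise overlap check between different reagents (warning only)
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            for lo1, hi1 in a.intervals:
                for lo2, hi2 in b.intervals:
                    if max(lo1, lo2) < min(hi1, hi2):
                        warnings.warn(
                            f"regions of {a.name!r} and {b.name!r} overlap in "
                            f"[{max(lo1, lo2)}, {min(hi1, hi2)}) ppm; the transport "
                            "regression will resolve the shared signal",
                            stacklevel=2,
                        )
    return ComponentLibrary(tuple(comps), tuple(regions))


def cut_mixture(s: Spectrum, lib: ComponentLibrary, *, widen: float = 0.0) -> Spectrum:
    """Restrict a mixture spectrum to the union of all library intervals.

    ``widen`` pads every interval symmetrically by that many ppm (default
    0: exactly the library intervals).  The result is clipped and
    normalized, ready for estimation.
    """
    intervals = lib.all_intervals()
    if not intervals:
        raise ValueError("library has no recorded regions to cut the mixture with")
    if widen:
        intervals = tuple((lo - widen, hi + widen) for lo, hi in intervals)
    mask = _in_intervals(s.axis, intervals)
    if not mask.any():
        raise ValueError("empty union: no mixture grid point falls in any library region")
    cut = Spectrum(s.axis[mask], s.intensity[mask], meta=dict(s.meta))
    return normalize(preprocess(cut))


def load_region_config(path: str | Path) -> dict[str, dict]:
    """Read a YAML region config.

    Format::

        components:
          substrate:
            source: 0          # time index into the manifest, or a file path
            intervals: [[1.0, 1.4], [2.0, 2.2]]
          product:
            source: -1
            intervals: [[3.0, 3.5]]

    Returns reagent name -> {"source": ..., "intervals": [...]}.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "components" not in data:
        raise ValueError(f"{path}: region config must have a top-level 'components' map")
    out: dict[str, dict] = {}
    for name, entry in data["components"].items():
        if "intervals" not in entry:
            raise ValueError(f"{path}: component {name!r} has no intervals")
        out[str(name)] = {
            "source": entry.get("source", 0),
            "intervals": [list(map(float, iv)) for iv in entry["intervals"]],
        }
    return out


def library_from_config(
    config: Mapping[str, dict],
    manifest: Manifest,
    *,
    spectra_cache: dict | None = None,
) -> ComponentLibrary:
    """Build a library from a region config plus the measured series.

    Integer sources index the manifest's time axis (0 = first spectrum,
    -1 = last); string sources are read as standalone spectrum files
    (separately measured reagents).
    """
    cache: dict = {} if spectra_cache is None else spectra_cache
    sources: dict[str, tuple[Spectrum, list]] = {}
    tags: dict[str, int | str] = {}
    for name, entry in config.items():
        src = entry["source"]
        if isinstance(src, int):
            path = manifest.paths[src]
        else:
            path = str(src)
        if path not in cache:
            cache[path] = load_spectrum(path)
        sources[name] = (cache[path], entry["intervals"])
        tags[name] = src
    return build_library(sources, region_sources=tags)
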