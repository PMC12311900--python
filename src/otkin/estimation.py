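"""Per-time-point proportion estimation and the warm-started series sweep.

Each measured mixture spectrum is analyzed independently: cut to the
library regions, clipped, normalized, pooled to a tractable grid and
regressed against the library by the transport LP.  Across a time series
the solves are warm-started from the previous time point's active arcs,
since consecutive spectra are similar; the contract is that warm and cold
sweeps reach identical objectives, never that warm is faster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library import ComponentLibrary, cut_mixture
from .spectra import Manifest, Spectrum, load_spectrum, normalize, pool, preprocess
from .transport import TransportSolution, build_problem, solve

__all__ = [
    "ProportionEstimate",
    "KineticTrace",
    "estimate_one",
    "estimate_series",
    "reconstruct_missing",
]

log = logging.getLogger(__name__)

DEFAULT_MAX_BINS = 2000


@dataclass
class ProportionEstimate:
    """Estimated reagent proportions at one time point."""

    time: float
    p: dict[str, float]
    p0: float
    objective: float
    status: str
    iterations: int
    warm_started: bool
    solution: TransportSolution | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class KineticTrace:
    """Time-ordered proportion estimates with a constant component set."""

    estimates: list[ProportionEstimate]
    names: tuple[str, ...]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [e.time for e in self.estimates]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("estimate times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.estimates)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.estimates])

    def proportions(self, name: str) -> np.ndarray:
        """Time series of one reagent's proportion (NaN where failed)."""
        return np.array([e.p.get(name, np.nan) if e.ok else np.nan
                         for e in self.estimates])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            row = {"time": e.time, "p0": e.p0 if e.ok else np.nan}
            for name in self.names:
                row[f"p_{name}"] = e.p.get(name, np.nan) if e.ok else np.nan
            row.update(objective=e.objective if e.ok else np.nan,
                       status=e.status, iterations=e.iterations,
                       warm_started=e.warm_started)
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, path: str | Path, *, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def estimate_one(
    mixture: Spectrum,
    lib: ComponentLibrary,
    kappa_mixture: float = 0.5,
    kappa_components: float = 0.5,
    *,
    cut: bool = True,
    max_bins: int = DEFAULT_MAX_BINS,
    warm: Sequence[tuple[int, int]] | None = None,
    time: float = 0.0,
    keep_solution: bool = False,
) -> ProportionEstimate:
    """Estimate reagent proportions in one mixture spectrum.

    Pipeline: optional cut to library regions -> clip negatives ->
    normalize -> pool to ``max_bins`` -> build transport LP -> solve.
    With ``cut=False`` the full spectrum is regressed against the
    (possibly partial) library; small penalties are then advisable since
    much of the signal is redundant relative to the cut-down references.
    """
    if cut:
        prepared = cut_mixture(mixture, lib)
    else:
        prepared = normalize(preprocess(mixture))
    prepared = pool(prepared, max_bins)
    prepared = normalize(prepared)  # pooling conserves mass; re-normalize for safety
    problem = build_problem(prepared, lib, kappa_mixture, kappa_components)
    sol = solve(problem, warm=warm)
    return ProportionEstimate(
        time=time,
        p={name: float(v) for name, v in zip(lib.names, sol.p)},
        p0=sol.p0,
        objective=sol.objective,
        status=sol.status,
        iterations=sol.iterations,
        warm_started=sol.warm_started,
        solution=sol if keep_solution else None,
    )


def estimate_series(
    manifest: Manifest,
    lib: ComponentLibrary,
    kappa_mixture: float = 0.5,
    kappa_components: float = 0.5,
    *,
    cut: bool = True,
    max_bins: int = DEFAULT_MAX_BINS,
    warm_start: bool = True,
    config: dict | None = None,
) -> KineticTrace:
    """Sweep the whole measured series in time order.

    A failed solve at one time point is recorded with its error status
    and missing proportions; it does not abort the sweep.  When
    ``warm_start`` is on, each solve is seeded with the previous time
    point's active arcs (silently degrading to a cold start when the
    problem dimensions change between spectra).
    """
    estimates: list[ProportionEstimate] = []
    warm_basis = None
    for t, path in manifest:
        try:
            mixture = load_spectrum(path)
            est = estimate_one(
                mixture, lib, kappa_mixture, kappa_components,
                cut=cut, max_bins=max_bins,
                warm=warm_basis if warm_start else None,
                time=t, keep_solution=True,
            )
            warm_basis = est.solution.basis if warm_start else None
            est.solution = None
            log.info("t=%g status=%s objective=%.6g iterations=%d",
                     t, est.status, est.objective, est.iterations)
        except Exception as exc:  # noqa: BLE001 — per-t failures are recorded
            log.warning("t=%g failed: %s", t, exc)
            est = ProportionEstimate(
                time=t, p={}, p0=np.nan, objective=np.nan,
                status=f"error: {exc}", iterations=0, warm_started=False,
            )
            warm_basis = None
        estimates.append(est)
    return KineticTrace(estimates, lib.names, config or {
        "kappa_mixture": kappa_mixture,
        "kappa_components": kappa_components,
        "cut": cut,
        "max_bins": max_bins,
        "warm_start": warm_start,
    })


def reconstruct_missing(trace: KineticTrace) -> pd.DataFrame:
    """Extract the contamination proportion p0 as a first-class trace.

    When a reagent is absent from the library but spectrally separated
    from it, its signal is written off as contamination, so p0 against
    time traces the missing reagent's true proportion.
    """
    return pd.DataFrame({
        "time": [e.time for e in trace.estimates],
        "p0": [e.p0 if e.ok else np.nan for e in trace.estimates],
    })
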