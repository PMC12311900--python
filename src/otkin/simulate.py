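"""Synthetic distorted reaction-spectrum series with exact ground truth.

The forward model emulates the pathologies of on-the-fly reaction
monitoring by 1-D NMR: sums of Lorentzian/Gaussian peaks whose areas
follow a kinetic model, shim-like asymmetric lineshape smearing, random
per-spectrum peak drift along the ppm axis (no field lock), additive
baseline noise, and optional attenuation of the first few spectra
(insufficient spin polarization right after mixing).

Distortion and drift are mass-preserving per reagent, so the configured
kinetic proportions remain the exact ground truth of every rendered
spectrum (up to the additive noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .library import ComponentLibrary, library_from_config, load_region_config
from .spectra import Manifest, Spectrum, write_manifest, write_spectrum

__all__ = [
    "PeakSpec",
    "Kinetics",
    "ReactionSimConfig",
    "SimulatedDataset",
    "eval_kinetics",
    "render_spectrum",
    "simulate",
]

_SQRT2LN2 = np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PeakSpec:
    """One spectral peak of a reagent.

    ``width`` is the half-width at half-maximum (HWHM) in ppm for both
    shapes; ``relative_area`` weights the peak within its reagent (proton
    multiplicity).
    """

    position: float
    width: float
    shape: Literal["lorentzian", "gaussian"] = "lorentzian"
    relative_area: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.relative_area <= 0:
            raise ValueError("relative_area must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def density(self, delta: np.ndarray, offset: float = 0.0) -> np.ndarray:
        """Unit-area continuous lineshape evaluated at ``delta`` (ppm)."""
        x = delta - (self.position + offset)
        w = self.width
        if self.shape == "lorentzian":
            return (w / np.pi) / (x * x + w * w)
        sigma = w / _SQRT2LN2
        return np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class Kinetics:
    """Kinetic model driving the true proportions.

    Models (closed forms, unit initial total):

    * ``first_order`` A -> B, rate ``k``:   [A] = exp(-k t), [B] = 1 - [A]
    * ``consecutive`` A -> B -> C, rates ``k1``, ``k2`` (two-exponential
      intermediate; equal-rate limit handled analytically)
    * ``logistic``    substrate/product pair with product proportion
      1 / (1 + exp(-r (t - t_half)))  (autocatalytic sigmoid)
    """

    model: Literal["first_order", "consecutive", "logistic"]
    k: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    r: float = 1.0
    t_half: float = 0.0

    def n_species(self) -> int:
        return {"first_order": 2, "consecutive": 3, "logistic": 2}[self.model]

    def proportions(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        if self.model == "first_order":
            if self.k <= 0:
                raise ValueError("rate k must be > 0")
            a = np.exp(-self.k * t)
            return np.column_stack([a, 1.0 - a])
        if self.model == "consecutive":
            if self.k1 <= 0 or self.k2 <= 0:
                raise ValueError("rates k1, k2 must be > 0")
            a = np.exp(-self.k1 * t)
            if abs(self.k1 - self.k2) < 1e-12:
                b = self.k1 * t * np.exp(-self.k1 * t)
            else:
                b = self.k1 / (self.k2 - self.k1) * (
                    np.exp(-self.k1 * t) - np.exp(-self.k2 * t)
                )
            c = 1.0 - a - b
            return np.column_stack([a, b, c])
        if self.model == "logistic":
            if self.r <= 0:
                raise ValueError("rate r must be > 0")
            b = 1.0 / (1.0 + np.exp(-self.r * (t - self.t_half)))
            return np.column_stack([1.0 - b, b])
        raise ValueError(f"unknown kinetic model {self.model!r}")


@dataclass(frozen=True)
class ReactionSimConfig:
    """Full configuration of a simulated monitored reaction.

    ``noise_sd`` is the standard deviation of additive Gaussian baseline
    noise, expressed as a fraction of the maximum intensity of the
    noiseless first spectrum.  ``drift_sd`` is the per-spectrum step (in
    ppm) of each peak's random-walk position drift; the walk reflects at
    ``+-drift_max`` because unlocked-field drift is bounded by the
    magnet's intrinsic stability — a free Brownian walk would displace
    peaks without bound over a long series, which no spectrometer
    exhibits.  ``distortion_width``
    and ``distortion_skew`` parameterize the mass-preserving skewed
    smearing kernel (two offset half-Gaussians) emulating shim
    distortion.  ``early_attenuation`` multiplies the first few spectra
    by the given factors.
    """

    reagents: dict[str, tuple[PeakSpec, ...]]
    kinetics: Kinetics
    times: tuple[float, ...]
    axis_range: tuple[float, float] = (0.0, 10.0)
    axis_points: int = 2000
    distortion_width: float = 0.0
    distortion_skew: float = 0.0
    drift_sd: float = 0.0
    drift_max: float = 0.3
    noise_sd: float = 0.0
    early_attenuation: tuple[float, ...] = ()
    region_margin: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.times) < 1:
            raise ValueError("need at least one time point")
        t = np.asarray(self.times)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.drift_sd < 0 or self.noise_sd < 0 or self.distortion_width < 0:
            raise ValueError("drift_sd, noise_sd, distortion_width must be >= 0")
        if self.drift_sd > 0 and self.drift_max <= 0:
            raise ValueError("drift_max must be > 0 when drift is enabled")
        if not -1.0 < self.distortion_skew < 1.0:
            raise ValueError("distortion_skew must be in (-1, 1)")
        if len(self.reagents) != self.kinetics.n_species():
            raise ValueError(
                f"kinetic model {self.kinetics.model!r} drives "
                f"{self.kinetics.n_species()} species but "
                f"{len(self.reagents)} reagents were configured"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.reagents)

    def axis(self) -> np.ndarray:
        return np.linspace(*self.axis_range, self.axis_points)


def eval_kinetics(config: ReactionSimConfig) -> pd.DataFrame:
    """Ground-truth proportion table p*_{j,t}; rows sum to 1 exactly."""
    p = config.kinetics.proportions(np.asarray(config.times))
    df = pd.DataFrame(p, columns=[f"p_{n}" for n in config.names])
    df.insert(0, "time", np.asarray(config.times, dtype=float))
    return df


def _skew_kernel(width: float, skew: float, dx: float) -> np.ndarray:
    """Normalized asymmetric smearing kernel on the grid spacing ``dx``.

    Two half-Gaussians with sigma width*(1 -/+ skew) on the left/right of
    the center; width in ppm.  Zero width gives the identity kernel.
    """
    if width <= 0:
        return np.ones(1)
    sig_l = width * (1.0 - skew)
    sig_r = width * (1.0 + skew)
    half = max(1, int(np.ceil(4.0 * max(sig_l, sig_r) / dx)))
    x = np.arange(-half, half + 1) * dx
    kern = np.where(
        x < 0,
        np.exp(-0.5 * (x / max(sig_l, 1e-30)) ** 2),
        np.exp(-0.5 * (x / max(sig_r, 1e-30)) ** 2),
    )
    return kern / kern.sum()


def _convolve_fold(y: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Convolve and fold out-of-range tails into the edge bins.

    Folding (rather than truncating) the overhang conserves total mass
    exactly for any normalized kernel.
    """
    if kern.size == 1:
        return y * kern[0]
    c = kern.size // 2
    full = np.convolve(y, kern, mode="full")
    core = full[c:c + y.size].copy()
    core[0] += full[:c].sum()
    core[-1] += full[c + y.size:].sum()
    return core


def _reagent_shape(
    config: ReactionSimConfig,
    name: str,
    axis: np.ndarray,
    offsets: np.ndarray,
    kern: np.ndarray,
) -> np.ndarray:
    """Unit-mass discrete shape of one reagent with drift and distortion."""
    dx = axis[1] - axis[0] if axis.size > 1 else 1.0
    peaks = config.reagents[name]
    total_area = sum(pk.relative_area for pk in peaks)
    y = np.zeros(axis.size)
    for pk, off in zip(peaks, offsets):
        dens = pk.density(axis, offset=float(off)) * dx
        captured = dens.sum()
        # Lorentzian tails are heavy: a HWHM-0.05 peak 1 ppm from the axis
        # edge already loses ~3% of its mass; warn only on gross truncation.
        if captured < 0.95:
            warnings.warn(
                f"peak of {name!r} at {pk.position + off:.3f} ppm is truncated "
                f"by the axis range ({1 - captured:.1%} of its mass lost)",
                stacklevel=3,
            )
        # renormalize the discretized peak so reagent mass shares stay exact
        dens = dens / captured if captured > 0 else dens
        y += (pk.relative_area / total_area) * dens
    y = _convolve_fold(y, kern)
    return y / y.sum()


def render_spectrum(
    config: ReactionSimConfig,
    t_index: int,
    *,
    drift: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Render the mixture spectrum at one time point of the series.

    ``drift`` is a (n_reagents, max_peaks) array of ppm offsets for this
    time point (default zero).  Noise requires an ``rng``; without one
    the noiseless spectrum is returned.
    """
    axis = config.axis()
    p_true = config.kinetics.proportions(np.asarray([config.times[t_index]]))[0]
    kern = _skew_kernel(config.distortion_width, config.distortion_skew,
                        axis[1] - axis[0] if axis.size > 1 else 1.0)
    if drift is None:
        drift = np.zeros((len(config.reagents), max(len(p) for p in config.reagents.values())))
    y = np.zeros(axis.size)
    for j, name in enumerate(config.names):
        y += p_true[j] * _reagent_shape(config, name, axis, drift[j], kern)
    if config.noise_sd > 0 and rng is not None:
        y = y + rng.normal(0.0, config.noise_sd * y.max(), size=y.size)
    if t_index < len(config.early_attenuation):
        y = y * config.early_attenuation[t_index]
    return Spectrum(axis, y, meta={"time": float(config.times[t_index])})


@dataclass
class SimulatedDataset:
    """Everything a simulate -> estimate -> compare run needs."""

    dir: Path
    manifest: Manifest
    truth: pd.DataFrame
    regions: dict[str, dict]
    config: ReactionSimConfig

    @property
    def manifest_path(self) -> Path:
        return self.dir / "manifest.csv"

    @property
    def regions_path(self) -> Path:
        return self.dir / "regions.yaml"

    @property
    def truth_path(self) -> Path:
        return self.dir / "truth.csv"

    def build_library(self) -> ComponentLibrary:
        return library_from_config(self.regions, self.manifest)


def _merge_intervals(ivs: list[tuple[float, float]]) -> list[list[float]]:
    ivs = sorted(ivs)
    out: list[list[float]] = []
    for lo, hi in ivs:
        if out and lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return out


def _reflect(x: np.ndarray, m: float) -> np.ndarray:
    """Fold a free walk into [-m, m] by reflection at the boundaries."""
    if m <= 0 or not np.isfinite(m):
        return x
    y = np.mod(x + m, 4.0 * m) - m
    return np.where(y > m, 2.0 * m - y, y)


def auto_regions(config: ReactionSimConfig, truth: pd.DataFrame) -> dict[str, dict]:
    """Derive a region config from the true (undrifted) peak locations.

    Each reagent gets intervals of ``region_margin`` ppm around its
    peaks (merged when overlapping), cut from the spectrum at the time
    its true proportion is largest — substrates from the start of the
    series, products from the end, mirroring manual library practice.
    """
    regions: dict[str, dict] = {}
    for name in config.names:
        ivs = [(pk.position - config.region_margin, pk.position + config.region_margin)
               for pk in config.reagents[name]]
        source = int(np.argmax(truth[f"p_{name}"].to_numpy()))
        regions[name] = {"source": source, "intervals": _merge_intervals(ivs)}
    return regions


def simulate(config: ReactionSimConfig, out_dir: str | Path) -> SimulatedDataset:
    """Simulate the series and write it in the formats the estimator reads.

    Writes per-time spectrum files, a manifest (time, path), an
    auto-derived region config and the ground-truth proportion table
    (column-compatible with the estimator's trace export).  Deterministic
    given ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = eval_kinetics(config)

    n_t = len(config.times)
    n_r = len(config.reagents)
    max_peaks = max(len(p) for p in config.reagents.values())
    # per-reagent, per-peak random-walk drift (cumulative over time)
    steps = rng.normal(0.0, config.drift_sd, size=(n_t, n_r, max_peaks)) \
        if config.drift_sd > 0 else np.zeros((n_t, n_r, max_peaks))
    drift = _reflect(np.cumsum(steps, axis=0), config.drift_max)

    paths = []
    for ti in range(n_t):
        spec = render_spectrum(config, ti, drift=drift[ti], rng=rng)
        path = out / f"spectrum_{ti:04d}.csv"
        write_spectrum(spec, path)
        paths.append(str(path))

    manifest = Manifest(tuple(float(t) for t in config.times), tuple(paths))
    write_manifest(manifest, out / "manifest.csv", relative_to=out)
    regions = auto_regions(config, truth)
    (out / "regions.yaml").write_text(
        yaml.safe_dump({"components": regions}, sort_keys=True))
    truth.to_csv(out / "truth.csv", index=False)
    return SimulatedDataset(out, manifest, truth, regions, config)
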