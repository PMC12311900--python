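import numpy as np
import pytest

from otkin.library import ComponentLibrary
from otkin.spectra import Spectrum, normalize


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_measure(rng, n_atoms, lo=0.0, hi=5.0):
    """Random unit-mass discrete measure on [lo, hi]."""
    pos = np.sort(rng.uniform(lo, hi, n_atoms))
    while np.any(np.diff(pos) == 0):
        pos = np.sort(rng.uniform(lo, hi, n_atoms))
    mass = rng.uniform(0.1, 1.0, n_atoms)
    return Spectrum(pos, mass / mass.sum())


def delta(x, mass=1.0):
    return Spectrum(np.array([float(x)]), np.array([float(mass)]))


def disjoint_library(rng, k, atoms_per_comp=5, window=1.0, gap=1.0):
    """k components with disjoint supports in consecutive ppm windows."""
    comps = []
    for j in range(k):
        lo = j * (window + gap)
        comps.append((f"C{j}", random_measure(rng, atoms_per_comp, lo, lo + window)))
    return ComponentLibrary(tuple(comps))


def mix_of(lib, p):
    """Exact convex combination of library components (shared atom list)."""
    pos = np.concatenate([s.axis for s in lib.spectra])
    mass = np.concatenate([pj * s.intensity for pj, s in zip(p, lib.spectra)])
    order = np.argsort(pos)
    return normalize(Spectrum(pos[order], mass[order]))
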