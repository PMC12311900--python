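"""Noise-penalized optimal-transport regression of a mixture spectrum.

The mixture spectrum (a unit-mass discrete measure mu on the ppm axis) is
explained as a sub-mixture of k reagent reference measures nu_1..nu_k plus
discarded "noise" mass on both sides.  The estimate solves the joint
linear program over transport plan gamma, mixture noise s, component
noise u and proportions p:

    minimize    sum_arcs c * gamma  +  kappa_m * sum_i s_i
                                    +  kappa_c * sum_jm u_jm
    subject to  sum_m gamma_{i,jm} + s_i        = a_i        (each mixture atom i)
                sum_i gamma_{i,jm} + u_jm       = p_j * b_jm (each component atom jm)
                sum_j p_j <= 1,   all variables >= 0

with arc cost c = |x_i - y_jm| in ppm.  The contamination proportion is
p_0 = 1 - sum_j p_j: mixture mass that is cheaper to discard (at kappa_m
per unit) than to attribute to any reagent.  kappa_m and kappa_c are in
ppm — a peak displaced by less than roughly kappa_m + kappa_c is
transported (tolerated), one further away is written off as noise.

Arcs with cost above kappa_m + kappa_c can never be used by an optimal
plan (discarding both endpoints is at least as cheap), so they are pruned
up front and the LP stays sparse.

The LP is solved with HiGHS via :func:`scipy.optimize.linprog`.  Warm
starting across a time series reuses the previous solve's active arcs as
the initial column set and restores optimality by dual-feasibility column
generation, so a warm solve provably reaches the same optimum as a cold
one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .library import ComponentLibrary
from .spectra import Spectrum

__all__ = [
    "TransportProblem",
    "TransportSolution",
    "w1_closed_form",
    "build_problem",
    "solve",
]

_NORM_TOL = 1e-8
_DUAL_TOL = 1e-9


def w1_closed_form(
    pos_a: np.ndarray,
    mass_a: np.ndarray,
    pos_b: np.ndarray,
    mass_b: np.ndarray,
) -> float:
    """Exact 1-D Wasserstein-1 distance between two unit-mass measures.

    Uses the closed form W1 = integral |F_a - F_b| over the merged
    support, where F are the cumulative distribution functions.  Serves
    as the independent oracle for the transport LP (single component,
    large penalties).
    """
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    mass_a = np.asarray(mass_a, dtype=float)
    mass_b = np.asarray(mass_b, dtype=float)
    if abs(mass_a.sum() - 1.0) > _NORM_TOL or abs(mass_b.sum() - 1.0) > _NORM_TOL:
        raise ValueError("w1_closed_form requires unit-mass inputs")
    z = np.concatenate([pos_a, pos_b])
    order = np.argsort(z, kind="stable")
    z = z[order]
    dmass = np.concatenate([mass_a, -mass_b])[order]
    cdf_diff = np.cumsum(dmass)[:-1]  # F_a - F_b on [z_i, z_{i+1})
    return float(np.sum(np.abs(cdf_diff) * np.diff(z)))


@dataclass(frozen=True)
class TransportProblem:
    """Sparse joint transport/regression LP data.

    Component atoms are flattened across reagents; ``comp_of_atom`` maps
    each flat atom index to its reagent index j, ``comp_mass`` holds
    b_jm.  Arcs are (mixture atom, flat component atom) pairs with cost
    ``arc_cost`` = |x_i - y_jm| ppm.
    """

    mix_pos: np.ndarray          # (n,)
    mix_mass: np.ndarray         # (n,)
    comp_pos: np.ndarray         # (M,)
    comp_mass: np.ndarray        # (M,)
    comp_of_atom: np.ndarray     # (M,) reagent index of each flat atom
    k: int
    names: tuple[str, ...]
    kappa_mixture: float
    kappa_components: float
    arc_mix: np.ndarray          # (A,)
    arc_comp: np.ndarray         # (A,)
    arc_cost: np.ndarray         # (A,)
    pruned: bool = True

    @property
    def n(self) -> int:
        return int(self.mix_pos.size)

    @property
    def n_comp_atoms(self) -> int:
        return int(self.comp_pos.size)

    @property
    def n_arcs(self) -> int:
        return int(self.arc_cost.size)


@dataclass
class TransportSolution:
    """Optimal proportions, plan and noise allocations of one solve."""

    p: np.ndarray                # (k,)
    p0: float
    names: tuple[str, ...]
    plan: np.ndarray             # (A,) transported mass per arc
    mixture_noise: np.ndarray    # (n,) discarded mixture mass s_i
    component_noise: np.ndarray  # (M,) discarded scaled component mass u_jm
    objective: float             # ppm * mass
    status: str
    iterations: int
    warm_started: bool = False
    basis: tuple = field(default=(), repr=False)  # active (i, f) arc pairs

    def to_dict(self) -> dict:
        return {
            "p": {name: float(v) for name, v in zip(self.names, self.p)},
            "p0": float(self.p0),
            "objective": float(self.objective),
            "status": self.status,
            "iterations": int(self.iterations),
            "warm_started": bool(self.warm_started),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def build_problem(
    mixture: Spectrum,
    lib: ComponentLibrary,
    kappa_mixture: float = 0.5,
    kappa_components: float = 0.5,
    *,
    prune: bool = True,
) -> TransportProblem:
    """Enumerate admissible transport arcs between mixture and library.

    With ``prune`` (default) arcs costing more than
    kappa_mixture + kappa_components are dropped; discarding both
    endpoints is never worse than using such an arc, so the optimum is
    unchanged.
    """
    if kappa_mixture <= 0:
        raise ValueError("kappa_mixture must be > 0")
    if kappa_components < 0:
        raise ValueError("kappa_components must be >= 0")
    if len(mixture) == 0:
        raise ValueError("empty mixture")
    a = np.asarray(mixture.intensity, dtype=float)
    if abs(a.sum() - 1.0) > _NORM_TOL:
        raise ValueError("mixture must be normalized to unit mass")

    comp_pos_list, comp_mass_list, comp_idx_list = [], [], []
    for j, spec in enumerate(lib.spectra):
        comp_pos_list.append(spec.axis)
        comp_mass_list.append(spec.intensity)
        comp_idx_list.append(np.full(len(spec), j, dtype=np.int64))
    comp_pos = np.concatenate(comp_pos_list)
    comp_mass = np.concatenate(comp_mass_list)
    comp_of_atom = np.concatenate(comp_idx_list)

    x = mixture.axis
    threshold = kappa_mixture + kappa_components if prune else np.inf

    # Enumerate arcs per component (each component axis is sorted) using
    # a searchsorted window around every mixture atom.
    arc_mix_parts, arc_comp_parts = [], []
    offset = 0
    for j, spec in enumerate(lib.spectra):
        y = spec.axis
        if np.isfinite(threshold):
            lo = np.searchsorted(y, x - threshold, side="left")
            hi = np.searchsorted(y, x + threshold, side="right")
        else:
            lo = np.zeros(x.size, dtype=np.int64)
            hi = np.full(x.size, y.size, dtype=np.int64)
        counts = hi - lo
        if counts.sum() > 0:
            mix_idx = np.repeat(np.arange(x.size), counts)
            within = np.concatenate(
                [np.arange(l, h) for l, h in zip(lo, hi) if h > l]
            ) if counts.sum() else np.empty(0, dtype=np.int64)
            arc_mix_parts.append(mix_idx)
            arc_comp_parts.append(within + offset)
        offset += y.size

    if arc_mix_parts:
        arc_mix = np.concatenate(arc_mix_parts)
        arc_comp = np.concatenate(arc_comp_parts)
    else:
        arc_mix = np.empty(0, dtype=np.int64)
        arc_comp = np.empty(0, dtype=np.int64)
    arc_cost = np.abs(x[arc_mix] - comp_pos[arc_comp])
    if np.isfinite(threshold):
        keep = arc_cost <= threshold
        arc_mix, arc_comp, arc_cost = arc_mix[keep], arc_comp[keep], arc_cost[keep]

    return TransportProblem(
        mix_pos=x,
        mix_mass=a,
        comp_pos=comp_pos,
        comp_mass=comp_mass,
        comp_of_atom=comp_of_atom,
        k=lib.k,
        names=lib.names,
        kappa_mixture=float(kappa_mixture),
        kappa_components=float(kappa_components),
        arc_mix=arc_mix,
        arc_comp=arc_comp,
        arc_cost=arc_cost,
        pruned=prune,
    )


def _solve_lp(problem: TransportProblem, arc_subset: np.ndarray | None):
    """Solve the joint LP restricted to ``arc_subset`` (None = all arcs).

    Returns (res, arc_subset_used).  Variable order: gamma over the
    subset, then s (n), u (M), p (k).
    """
    n, M, k = problem.n, problem.n_comp_atoms, problem.k
    if arc_subset is None:
        arc_subset = np.arange(problem.n_arcs)
    am = problem.arc_mix[arc_subset]
    ac = problem.arc_comp[arc_subset]
    cost = problem.arc_cost[arc_subset]
    A = arc_subset.size
    nvar = A + n + M + k

    c = np.concatenate([
        cost,
        np.full(n, problem.kappa_mixture),
        np.full(M, problem.kappa_components),
        np.zeros(k),
    ])

    rows = np.concatenate([
        am,                       # gamma in mixture balance
        np.arange(n),             # s_i
        n + ac,                   # gamma in component balance
        n + np.arange(M),         # u_jm
        n + np.arange(M),         # -b_jm * p_j
    ])
    cols = np.concatenate([
        np.arange(A),
        A + np.arange(n),
        np.arange(A),
        A + n + np.arange(M),
        A + n + M + problem.comp_of_atom,
    ])
    vals = np.concatenate([
        np.ones(A),
        np.ones(n),
        np.ones(A),
        np.ones(M),
        -problem.comp_mass,
    ])
    A_eq = sparse.coo_matrix((vals, (rows, cols)), shape=(n + M, nvar)).tocsr()
    b_eq = np.concatenate([problem.mix_mass, np.zeros(M)])

    A_ub = sparse.coo_matrix(
        (np.ones(k), (np.zeros(k, dtype=int), A + n + M + np.arange(k))),
        shape=(1, nvar),
    ).tocsr()
    b_ub = np.ones(1)

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    return res, arc_subset


def _extract(problem: TransportProblem, res, arc_subset: np.ndarray,
             warm_started: bool, cg_iters: int) -> TransportSolution:
    n, M, k = problem.n, problem.n_comp_atoms, problem.k
    A = arc_subset.size
    x = res.x
    plan = np.zeros(problem.n_arcs)
    plan[arc_subset] = x[:A]
    s = x[A:A + n]
    u = x[A + n:A + n + M]
    p = x[A + n + M:]
    p0 = max(0.0, min(1.0, 1.0 - float(p.sum())))
    support = plan > 1e-12
    basis = tuple(zip(problem.arc_mix[support].tolist(),
                      problem.arc_comp[support].tolist()))
    nit = int(getattr(res, "nit", 0)) + cg_iters
    return TransportSolution(
        p=p.copy(),
        p0=p0,
        names=problem.names,
        plan=plan,
        mixture_noise=s.copy(),
        component_noise=u.copy(),
        objective=float(res.fun),
        status="optimal",
        iterations=nit,
        warm_started=warm_started,
        basis=basis,
    )


def _reduced_costs(problem: TransportProblem, res, n: int) -> np.ndarray:
    """Reduced cost of every arc given the restricted solve's duals."""
    y = res.eqlin.marginals  # duals of [mixture balance (n); component balance (M)]
    alpha = y[:n]
    beta = y[n:]
    return problem.arc_cost - alpha[problem.arc_mix] - beta[problem.arc_comp]


def solve(
    problem: TransportProblem,
    warm: Sequence[tuple[int, int]] | None = None,
    *,
    max_cg_rounds: int = 30,
) -> TransportSolution:
    """Solve the joint transport LP to optimality.

    ``warm`` is the previous time point's active-arc list (``basis`` of a
    TransportSolution).  The restricted LP over those arcs plus all noise
    and proportion columns is always feasible (full discard); column
    generation then adds any arc with negative reduced cost until the
    restricted optimum is provably globally optimal.  If the arc pairs do
    not apply to this problem's dimensions, the solve silently falls back
    to a cold start.
    """
    n = problem.n

    def fail(res):
        raise RuntimeError(f"LP solver failed: status={res.status}, {res.message}")

    if warm is not None and problem.n_arcs > 0:
        pairs = np.asarray(list(warm), dtype=np.int64).reshape(-1, 2)
        valid = (
            (pairs[:, 0] >= 0) & (pairs[:, 0] < n)
            & (pairs[:, 1] >= 0) & (pairs[:, 1] < problem.n_comp_atoms)
        ) if pairs.size else np.empty(0, dtype=bool)
        pairs = pairs[valid] if pairs.size else pairs
        # locate warm pairs among this problem's arcs via a packed key
        stride = problem.n_comp_atoms + 1
        arc_key = problem.arc_mix * stride + problem.arc_comp
        want = pairs[:, 0] * stride + pairs[:, 1] if pairs.size else np.empty(0, dtype=np.int64)
        active = np.flatnonzero(np.isin(arc_key, want))
        cg_rounds = 0
        while cg_rounds < max_cg_rounds:
            res, used = _solve_lp(problem, active)
            if res.status != 0:
                break
            rc = _reduced_costs(problem, res, n)
            rc[used] = 0.0
            violated = np.flatnonzero(rc < -_DUAL_TOL)
            if violated.size == 0:
                return _extract(problem, res, used, True, cg_rounds)
            active = np.union1d(active, violated)
            cg_rounds += 1
        # fall through to cold start (guarantees the contract)

    res, used = _solve_lp(problem, None)
    if res.status != 0:
        fail(res)
    return _extract(problem, res, used, warm is not None, 0)
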