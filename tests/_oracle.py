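"""Independent brute-force oracle for the joint transport regression.

For a fixed proportion vector p, the remaining problem is an unbalanced
1-D transport between the mixture and the p-scaled component atoms, with
per-unit discard penalties on both sides.  The oracle evaluates that
fixed-p cost with its own small LP over (gamma, s, u) only — a different
formulation from the joint LP under test, which optimizes p as an LP
variable — and minimizes over p by grid search on the simplex.

The fixed-p cost is a partial minimization of a linear program, hence
convex piecewise-linear in p, so the base grid (step 1e-3) is refined
around its argmin by successive shrinking grids down to step 1e-8; with
O(1) ppm geometry this pins the minimum value far below the 1e-6
comparison tolerance.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import sparse
from scipy.optimize import linprog


class FixedPCost:
    """Exact unbalanced-OT cost between mixture and p-scaled components."""

    def __init__(self, mix_pos, mix_mass, comp_specs, kappa_m, kappa_c):
        # comp_specs: list of (positions, masses) per reagent, unit mass each
        self.a = np.asarray(mix_mass, float)
        x = np.asarray(mix_pos, float)
        self.k = len(comp_specs)
        pos = np.concatenate([np.asarray(p, float) for p, _ in comp_specs])
        self.b = np.concatenate([np.asarray(m, float) for _, m in comp_specs])
        self.comp_of = np.concatenate(
            [np.full(len(p), j) for j, (p, _) in enumerate(comp_specs)]
        )
        n, M = x.size, pos.size
        self.n, self.M = n, M
        cost = np.abs(x[:, None] - pos[None, :]).ravel()  # all arcs, no pruning
        self.c = np.concatenate([cost, np.full(n, kappa_m), np.full(M, kappa_c)])
        A = n * M
        gi = np.repeat(np.arange(n), M)
        gf = np.tile(np.arange(M), n)
        rows = np.concatenate([gi, np.arange(n), n + gf, n + np.arange(M)])
        cols = np.concatenate([np.arange(A), A + np.arange(n),
                               np.arange(A), A + n + np.arange(M)])
        vals = np.ones(rows.size)
        self.A_eq = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(n + M, A + n + M)).tocsr()

    def __call__(self, p) -> float:
        p = np.asarray(p, float)
        b_eq = np.concatenate([self.a, p[self.comp_of] * self.b])
        res = linprog(self.c, A_eq=self.A_eq, b_eq=b_eq,
                      bounds=(0, None), method="highs",
                      options={"presolve": False})
        assert res.status == 0, res.message
        return float(res.fun)


def _simplex_grid(k: int, step: float, center=None, halfwidth=None):
    """Grid over {p >= 0, sum p <= 1}, optionally windowed around center."""
    if center is None:
        axes = [np.arange(0.0, 1.0 + step / 2, step)] * k
    else:
        axes = []
        for c in center:
            lo = max(0.0, c - halfwidth)
            hi = min(1.0, c + halfwidth)
            axes.append(np.arange(lo, hi + step / 2, step))
    for p in itertools.product(*axes):
        if sum(p) <= 1.0 + 1e-12:
            yield np.asarray(p)


def brute_force_optimum(cost: FixedPCost) -> tuple[float, np.ndarray]:
    """Grid-search minimum of the fixed-p cost over the simplex."""
    k = cost.k
    base_step = 1e-3 if k == 1 else 2e-2
    best_val, best_p = np.inf, None
    for p in _simplex_grid(k, base_step):
        v = cost(p)
        if v < best_val:
            best_val, best_p = v, p
    step = base_step
    while step > 1e-7:
        new_step = step / 5.0
        # re-center until the window argmin is interior: a minimizer on the
        # window edge means the descent direction leaves the window
        for _ in range(10):
            center = best_p
            moved = False
            for p in _simplex_grid(k, new_step, center=center,
                                   halfwidth=1.5 * step):
                v = cost(p)
                if v < best_val - 1e-15:
                    best_val, best_p = v, p
                    moved = True
            on_edge = np.any(np.abs(best_p - center) >= 1.5 * step - new_step / 2)
            if not (moved and on_edge):
                break
        step = new_step
    return best_val, best_p
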