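# Methods

## Model

A 1-D NMR spectrum is modeled as a discrete measure: nonnegative mass
a_i at chemical-shift positions x_i (ppm).  Working with measures rather
than interpolated densities is what makes optimal transport applicable,
and it removes any need for a common grid: mixture and library spectra
may be sampled on entirely different axes, since all costs are computed
from actual ppm positions.

Reagent proportions at one time point are estimated by the joint linear
program given in the README: transport plan γ over admissible
(mixture atom, component atom) arcs with cost |x_i − y_jm|, noise
channels s (mixture side) and u (component side) priced at κ_mixture and
κ_components per unit mass, proportions p on the sub-simplex Σp_j ≤ 1,
and contamination p₀ = 1 − Σp_j.  The formulation has these provable
behaviors, all covered by tests:

- **Exactness.** If μ = Σ p*_j ν_j exactly, the optimum is p = p*,
  objective 0.
- **Shift tolerance.** A substrate peak displaced by d is transported
  (estimate unchanged) when d < κ_mixture, and discarded beyond that —
  the penalty is literally the user's tolerance for peak displacement.
  The two delta-spectrum cases (d = 0.2: transport, p₁ = 1, objective
  0.2; d = 0.8 with κ = 0.5: discard, p₁ = 0, objective 0.5) are asserted
  exactly.
- **Oracle agreement.** For one component and penalties above the axis
  diameter, discarding never pays and the LP objective equals the
  closed-form 1-D Wasserstein distance ∫|F_μ − F_ν|.
- **Contamination accounting.** Signal unexplained by any library
  component is bought by the noise channel and appears in p₀; with a
  missing, spectrally separated reagent of true share q, p₀ ≈ q.

### Numerical choices

- Solver: HiGHS through `scipy.optimize.linprog`, sparse constraint
  matrices.  Mass balances hold at 1e-9; solver failures raise with the
  backend status.
- Arc pruning: arcs costing more than κ_mixture + κ_components are
  dropped before solving — discarding both endpoints is never worse than
  using such an arc, so the optimum is untouched while the LP stays
  sparse (verified against unpruned solves).
- Degenerate inputs are defined, not errors: a mixture atom with no
  admissible arc is discarded at κ_mixture (a fully disjoint mixture
  yields p = 0, p₀ = 1, objective κ_mixture).
- Ties among optimal plans are accepted as solver-given; only p, p₀ and
  the objective are treated as contractual, and p only where the optimum
  is provably unique (e.g. disjoint supports).
- Pooling onto ≤ `max_bins` grid points (default 2000) sum-pools
  consecutive points and places each bin at its mass-weighted mean ppm
  (arithmetic mean for empty bins); total mass is conserved exactly.
  Linear-interpolation resampling is never used because it does not
  conserve mass.
- Negative intensities (residual baseline noise in phased, baselined
  spectra — the only preprocessing this package assumes upstream) are
  clipped to zero by default.

### Warm start

`scipy`'s HiGHS interface exposes neither a starting basis nor an initial
point, so sequential solves are warm-started by *column generation*: the
restricted LP over the previous time point's active arcs (plus all noise
and proportion columns, which keep it feasible — full discard is always
feasible) is solved, the reduced cost c_a − α_i − β_jm of every excluded
arc is computed from the returned duals, and violated arcs are added
until dual feasibility certifies global optimality.  The contract is
objective equality with a cold solve (enforced at 1e-9 in tests), never
speed.  If the problem dimensions change between spectra (different
grids) or column generation stalls, the solve silently falls back to a
cold start, preserving the contract.

## Parameters that matter

| parameter | units | default | role |
|---|---|---|---|
| κ_mixture | ppm | 0.5 | price of discarding mixture signal; the shift tolerance for substrate-side peaks |
| κ_components | ppm | 0.5 | price of discarding (scaled) library signal |
| max_bins | — | 2000 | LP size control; pooling resolution |
| cut | — | on | restrict mixtures to the union of library regions before estimation |
| widen | ppm | 0 | optional symmetric padding of the cut intervals |

With mixtures cut to the library regions the estimates are insensitive to
the penalties across a wide grid (tested: every p_{j,t} moves ≤ 0.02
across κ ∈ {0.1, 0.25, 0.5, 1.0}²).  With full-spectrum input and a
partial library the penalties matter: small values let the redundant
signal drain into p₀ cheaply and the kinetic shape survives; large values
force redundant signal onto the nearest component and flatten its curve.
In that regime the results should be read qualitatively.

## Synthetic data generator

The generator emulates the pathologies of monitoring a live reaction
without shimming or locking, with exact ground truth:

- **Peaks**: sums of Lorentzian or Gaussian lines (HWHM parameterization,
  per-peak relative areas for multiplicity) per reagent.
- **Kinetics**: first-order A→B (closed form e^(−kt)), consecutive
  A→B→C (two-exponential, equal-rate limit handled analytically), and
  logistic (autocatalytic sigmoid).  Ground-truth proportion rows sum to
  1 exactly.
- **Shim distortion**: convolution with a normalized skewed kernel (two
  offset half-Gaussians, parameterized by width and skew).  Out-of-range
  convolution tails are folded into the edge bins so mass is conserved
  exactly.
- **Peak drift**: a seeded per-reagent, per-peak random walk along the
  ppm axis, reflected at ±`drift_max` (default 0.3 ppm).  The reflection
  models the physical boundedness of unlocked-field drift — magnet
  stability caps the excursion — where a free Brownian walk would
  displace peaks arbitrarily far over a long series and eventually carry
  them past any finite shift tolerance, which no spectrometer exhibits.
- **Baseline noise**: additive Gaussian, sd expressed as a fraction of
  the first spectrum's maximum intensity.
- **Early attenuation**: scalar factors on the first few spectra,
  mimicking insufficient spin polarization right after mixing (harmless
  to proportion estimates, which are scale-invariant).

Each rendered reagent shape is renormalized after discretization and
distortion, so the configured kinetic proportions are the *exact* mass
shares of every spectrum (up to additive noise) and remain valid ground
truth under drift and distortion.  Region configurations are auto-derived
from the undrifted peak positions ± a margin, cut from the spectrum where
each reagent's true share peaks (substrates early, products late).

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: FID-domain effects (truncation, apodization),
phase and baseline errors (spectra are assumed phased and baselined),
J-coupling fine structure, relaxation/saturation beyond scalar
attenuation, temperature-dependent shift changes, and solvent
suppression artifacts.

## Validation problem sizes

The shipped validation uses desk-scale problems chosen to exercise every
claim: 200 random instances (≤ 50 atoms/side) for the Wasserstein oracle;
50 tiny instances (≤ 6 atoms) against a brute-force grid search over p
(base step 1e-3, convexity-justified local refinement — the fixed-p cost
is a partial minimization of an LP and therefore convex piecewise-linear
in p) with an independent fixed-p transport LP per candidate; 50-spectrum
simulated series for the warm-start and parameter-recovery checks
(axis 2000 points, pooled to 300–600 bins); 16-setting penalty grids on
12-spectrum series.  Real series of 1000+ spectra run the same code path;
only the per-solve LP size (controlled by `max_bins` and region widths)
matters for runtime.

## Known limitations

- κ is a single global tolerance; a spectrum whose drift exceeds
  κ_mixture for a reagent with no other signal loses that reagent to p₀.
- The comparator implements normalized region-sum integration only; it
  intentionally reproduces the overlap bias of classical workflows.
- p₀ conflates contamination, missing reagents and model mismatch; its
  interpretation as a missing reagent's kinetics requires that reagent's
  peaks to be spectrally separated from the library regions by more than
  κ_mixture + κ_components.
- No smoothing across time is applied (estimates are raw per-t), and no
  kinetic model is fitted to the resulting trace.
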