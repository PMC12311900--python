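# otkin — NMR reaction monitoring by optimal-transport regression

`otkin` estimates the time course of a chemical reaction from a series of
1-D ¹H NMR spectra measured while the reaction runs.  Its users are
chemists monitoring kinetics under realistic acquisition conditions —
no time for shimming, no deuterated solvent for a field lock — where
lineshapes are distorted, peaks drift along the chemical-shift axis, and
signals of different reagents overlap.  Classical quantification (summing
intensity over fixed ppm regions) breaks down exactly there: overlapping
regions double-count shared signal, and in the limit of full overlap the
measured kinetic curve degenerates to a constant.

## The method

Each measured mixture spectrum is treated as a unit-mass discrete measure
μ_t on the ppm axis.  The user cuts chemical-shift regions out of chosen
spectra of the series (substrates from an early spectrum, products from a
late one) to build a *library* of reference measures ν₁ … ν_k, one per
reagent.  The proportion vector p_t is then estimated by a noise-penalized
Wasserstein regression — a single linear program per time point:

```
minimize    Σ_arcs c·γ  +  κ_mixture · Σ_i s_i  +  κ_components · Σ_jm u_jm
subject to  Σ_m γ_ijm + s_i   =  a_i            (each mixture atom i)
            Σ_i γ_ijm + u_jm  =  p_j · b_jm     (each component atom jm)
            Σ_j p_j ≤ 1,  γ, s, u, p ≥ 0
```

where the arc cost c = |x_i − y_jm| is the ppm distance mass is moved,
s and u are signal discarded to a noise channel at per-unit prices
κ_mixture and κ_components (both in ppm, default 0.5), and
p₀ = 1 − Σ_j p_j is the estimated contamination proportion.  Because cost
grows with *distance moved* rather than point-wise mismatch, the estimate
tolerates lineshape distortion and peak drift up to roughly the κ scale,
and resolves peak overlap by letting intensity flow between regions in one
global optimization.  If a reagent is missing from the library, its signal
is priced into p₀, whose time trace then reconstructs the missing
reagent's kinetics.

Across a time series, consecutive solves are warm-started: the previous
time point's active transport arcs seed a restricted LP whose optimality
is then certified (and repaired if needed) through reduced-cost column
generation, so warm and cold sweeps provably reach identical objectives.

## Worked example

Simulate a first-order A → B reaction (8 spectra, 1% baseline noise,
0.02 ppm/step peak drift, 0.03 ppm shim distortion), then run both the
transport regression and the classical region-sum comparator:

```sh
otkin simulate --out-dir demo --model first_order --rate 1.0 --n-times 8 \
      --noise-sd 0.01 --drift-sd 0.02 --distortion-width 0.03 --seed 11
otkin compare --manifest demo/manifest.csv --regions demo/regions.yaml \
      --out-dir demo_out --max-bins 400 --truth demo/truth.csv
```

which prints

```
reagent  max_abs_method_diff  rms_method_diff  max_abs_ot_vs_truth  max_abs_regionsum_vs_truth  rms_ot_vs_truth  rms_regionsum_vs_truth
      A             0.002038         0.000748             0.023151                    0.023151         0.009160                0.009361
      B             0.001060         0.000454             0.023151                    0.023151         0.009456                0.009361
```

With well-separated peaks the two methods agree (max deviation 0.002) and
both track the true exponential within ~0.02 — the deviation from truth
here is dominated by the small library contamination at the series ends.
The per-time-point estimates land in `demo_out/trace.csv`:

```
time,p0,p_A,p_B,objective,status,iterations,warm_started
0.0,0.0,0.976848864768593,0.023151135231407115,0.002815482386748232,optimal,951,False
0.42857142857142855,0.0004905530456181806,0.6537697941378888,0.345739652816493,0.016353396437896326,optimal,1774,True
...
```

`p_A` follows e^(−kt), `p0` stays near zero (complete library), and the
objective — the residual transport-plus-noise cost in ppm·mass — stays
small.  Under peak overlap the two methods separate sharply: the
region-sum curve flattens while the transport estimate keeps tracking the
truth (`otkin compare` on an overlapping simulation shows this directly;
see `docs/methods.md`).

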