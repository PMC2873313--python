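# Methods

## Model

The package models the classic auxin-transport assay as a closed
one-dimensional chain of 2N+3 well-mixed compartments: a source agar block
`S`, alternating apoplasts `a_0..a_N` and cytoplasms `c_1..c_N`, and a
collecting block `F`. Concentrations are per unit area (the model is
two-dimensional); a compartment of length `d` and width `w` holds
`count = conc · d · w` molecules. All `C` molecules start in the source
block and none enter or leave afterwards.

Six one-way elementary processes define the dynamics, each an exchange
velocity (m/s) acting across a shared interface of width `w`:

| process | velocity | where |
|---|---|---|
| agar ↔ terminal apoplast | `q = 2D/L_s` | both ends, both directions |
| PIN efflux (pump) | `P_PIN g(φ) f_cA` | cytoplasm → downstream apoplast |
| GHK backflux | `P_PIN g(φ) e^−φ f_aA` | apoplast → upstream cytoplasm |
| passive uptake | `P_diff f_aH` | apoplast → either neighbour cytoplasm |
| passive efflux | `P_diff f_cH` | cytoplasm → either neighbour apoplast |

with `g(φ) = φ/(1−e^−φ)` and the Henderson–Hasselbalch fractions
`f_H = 1/(1+10^(pH−pK))`, `f_A = 1−f_H` evaluated at the compartment's pH.
`q = 2D/L_s` treats each agar block as well mixed, with the diffusive
resistance of the mean path from the block interior to its face; this
choice is what ties the long-time kinetics to the block length, and it
reproduces the closed-form half-time to four significant figures against
the full numerical solution.

Dividing each velocity by the donating compartment's length gives the
per-molecule stochastic reaction constants `k1..k8` (rules R1–R8); dividing
each interfacial flux by the receiving compartment's length gives the ODE
system. The two descriptions are mean-field equivalent term by term, and
`tests/test_rules.py` asserts the matrix identity exactly.

Two of the processes are optional switches because they are tiny for the
reference physiology and the rule table omits them at execution time:

* **GHK backflux** (`include_pin_backflux`): ~0.7% of the pump. The
  stochastic solver zeroes it by default (the executed rule system's
  "small parameter"); the deterministic solver keeps it, which is what
  delays the numerical sink half-time relative to the source by the front
  traversal time.
* **passive cytoplasmic efflux** (`include_passive_efflux`): the smallest
  rate in the system (`P_diff f_cH` ≈ 2×10⁻⁹ m/s). The ODE keeps it by
  default so that the full two-way passive flux law holds (a uniform state
  with no pump and no pH gradient is then an exact equilibrium); the
  stochastic rule set omits it by default. Its effect on every reported
  quantity is below 0.05%.

## Parameters

Reference values (SI): `l = 100 µm`, `w = 10 µm`, `λ = 0.5 µm`,
`L_s = 2 mm`, `N = 20` (so `L = 2.0105 mm`), `P_diff = 5.6×10⁻⁷ m/s`,
`P_PIN = 3.3×10⁻⁶ m/s`, `D = 6.7×10⁻¹⁰ m²/s`, `pH_c = 7.2`, `pH_a = 5.3`,
`pK = 4.8`, `V = −120 mV`, `T = 295.15 K`. The default initial load is
`C = 12,044` molecules, which is 0.1 nM in the block volume `L_s·w·w`
(the out-of-plane depth is taken equal to the cell width; this is the only
place a third dimension enters). `N = 20` is the integer cell count
consistent with the printed tissue and cell lengths; `L` is always
recomputed from `N`, `l`, `λ` rather than rounded to 2 mm.

## Asymptotic solution

With `ε = (l+λ)/L ≈ 0.05`, the membrane ratios `P_diff f_aH / P_PIN` and
`g(φ) e^−φ f_aA` are themselves O(ε) and are rescaled to O(1) groups. At
leading order the apoplasts are in quasi-steady balance and two regimes
emerge:

* **transport scale** (`L/P_PIN` ≈ 10 min): the source holds at `S0` and a
  sharp front crosses the file at
  `v_eff = uptake·pump/(2·uptake + backflux)` ≈ 2.017 cm/h (front
  traversal `L/v_eff` ≈ 359 s). Behind the front the collecting block
  fills linearly: `F^n(t) = C·k·(t − L/v_eff)`.
* **diffusive scale** (`1/k` ≈ 5 h): `S(t) = S0 e^{−kt}`,
  `F(t) = S0(1−e^{−kt})` with `k = (q·uptake/(q+uptake))/L_s`; both
  half-times equal `ln2/k` ≈ 206.2 min exactly.

The leading-order velocity neglects apoplast storage (`λ·a/(l·c)` ≈ 0.2 for
the reference geometry, formally O(λ̄/ε)); the conservation-corrected bulk
speed is therefore ~17% slower than `v_eff`, which is visible as the gap
between `L/v_eff` (359 s) and the numerical sink-source half-time lag
(~424 s). The composite profile evaluator treats this regime faithfully
only when `λ̄ = O(ε²)`, the scaling under which the convergence test
refines the geometry.

## Numerics

* **ODE**: Dormand–Prince (scipy `RK45`), `rtol = 10⁻⁸`,
  `atol = 10⁻¹² × S0`; LSODA available behind a flag. Solutions are
  sampled on a fixed 4000-point grid and interpolated linearly; the
  interpolation error on half-times is below 0.01 s, far under the 0.01 min
  reporting precision (the solver's dense interpolant is not stored to keep
  long integrations at constant memory). Mass conservation is checked to
  10⁻⁶ relative; the analytic fixed point (everything in the collecting
  block except a small recirculating `c_N`, `a_N` level) is available in
  closed form.
* **SSA**: direct method over the flattened rule union, propensity refresh
  limited to the two compartments touched per firing, numba-compiled
  (~5×10⁶ events/s on one core). Snapshots are taken on a uniform grid;
  the first arrival into the collecting block is recorded at its exact jump
  time, so first-passage statistics are not grid-quantised. A 64-bit base
  seed spawns independent per-run streams through `SeedSequence`; identical
  seeds give byte-identical results.
* **Half-times**: the steady level is the mean over the last 10% of the
  record, accepted only if the last two 5% windows agree within 0.2% of the
  excursion (windowed means make the estimator robust to counting noise;
  records are integrated to ~12 half-lives, 150,000 s). The half level is
  the midpoint of the initial and steady values — for the sink this is half
  the steady level; for the source, whose steady level is ~0, it is half
  the initial value. Crossings are linearly interpolated.
* **Confidence intervals**: normal approximation, mean ± 1.96·SE across
  runs; significance of stochastic-deterministic differences uses the
  two-standard-error rule with SE = SD/√runs, masked where SE = 0.
* **GHK factor**: the removable singularity at φ = 0 is replaced by its
  limit below |φ| < 10⁻¹².

## Study sizes

Reported stochastic quantities use reduced, seeded ensembles chosen so the
Monte-Carlo error of each mean is well below 1%: 200 runs for half-time and
sink-count means (SE ≈ 0.2 min and ≈ 1 molecule), 500 early-stopped runs
for first-arrival statistics (SE ≈ 1 s), and 150 runs per load for the
noise-scaling comparison. The variability summary is the across-run SD of
the per-run *type-averaged* molecule count relative to `C`, time-averaged
over the record; averaging the many small stem compartments before taking
the run-to-run spread is what makes cytoplasm and apoplast entries roughly
thirty-fold quieter than the agar blocks, and a tenfold load reduces every
entry by ≈ 1 − 10^(−1/2) ≈ 68%.

## What the generator does and does not emulate

The model is a single cell file with uniform compartments, fixed pH,
voltage and permeabilities, no auxin metabolism, no influx carriers, and
closed boundaries. Passing tests therefore demonstrate internal consistency
of the three frameworks and correct reproduction of this idealised assay —
not fidelity to real stem tissue, where multiple files, tissue-specific
carrier distributions, metabolism and detection thresholds all intervene.
First-arrival speeds in particular are detector-idealised (single-molecule
sensitivity) and exceed bulk-front speeds by construction.

## Known limitations

* The asymptotic module is leading-order only; no uniformly valid composite
  across the two time scales is attempted (the two regime evaluators plus
  the crossover markers `L/v_eff` vs `1/k` are exposed instead).
* The continuum limit requires inter-cell transport to be fast relative to
  the tissue scale; for thick apoplasts (`λ̄` not small) the leading-order
  front speed overestimates the bulk speed, as quantified above.
* The plateau estimator requires records reaching ~10 half-lives; shorter
  records raise a diagnostic rather than guessing.
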