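# tisdesign

Rare-event kinetics and dynamics-guided redesign for enzyme-like model
systems: transition interface sampling (TIS) rate constants, umbrella
sampling + WHAM free-energy profiles, machine-learned identification of
reactive-like conformations, and a multistate sequence-design objective with
screening statistics.

## The problem

In an enzyme whose chemical step is slow, most barrier approaches fail: the
substrate reaches part-way along the reaction coordinate and is turned back.
If the conformations that *will* react differ, measurably and ahead of time,
from those that will not, then mutations that stabilize the reactive-like
conformations should accelerate turnover.  Testing that idea computationally
needs several pieces working together:

* **Path sampling.**  With a scalar progress coordinate
  λ = d(breaking bond) − d(forming bond), reactant well A (λ < −0.8 Å) and
  product well B (λ > 0.8 Å), TIS collects reactive (A→B) and nonreactive
  (A→A, reaching at least λ = −0.4 Å) turnover attempts by shooting-move
  Monte Carlo, and assembles the rate constant as

      k = Φ_A · P(λ_B | λ_A),
      P(λ_B | λ_A) = P(λ_B | λ_n) · Π_i P(λ_{i+1} | λ_i),

  the effective positive flux through the reactant boundary times a product
  of conditional interface-crossing probabilities.  The incremental curve
  P(λ + 0.05 Å | λ) locates the *bottleneck* — the progress at which
  attempts are most likely to fail.
* **Free-energy profiling.**  Umbrella sampling along λ with harmonic
  restraints (k_f = 200 kcal/mol/Å², no ½ factor) and WHAM, in a fast
  screening mode (5 ps/window) and an accurate detailed mode
  (100 ps/window, 50 ps discarded), yields ΔG‡.
* **Learning.**  Logistic regression (with LASSO subset selection) and a
  70-unit single-hidden-layer network are trained to predict, from geometric
  features in sliding 30-fs prereaction windows (t = 0 at the last
  compression of the breaking bond), whether an attempt will succeed.
* **Design.**  Representative reactive/nonreactive structures selected by
  the models define the objective f(s) = Σ E_R,i(s) − Σ E_NR,i(s); designs
  within 20 kcal/mol of the optimum that keep the reactive structures within
  5 kcal/mol of the reference stability are screened by equilibrium
  reactive-like populations, screening ΔG‡, and finally replicate TIS rates
  with one-sided Mann–Whitney tests under Benjamini–Hochberg control.

The package implements this whole pipeline over a system-agnostic interface
(potential, gradient, λ) and ships desk-scale surrogate systems with planted
ground truth — a bistable double well with closed-form references, a 3D
group-transfer "migration mimic" whose gate particle modulates the barrier,
and a toy sequence space — so every stage can be validated against
brute-force oracles.  See `docs/methods.md` for the models and conventions.

## Worked example

Compare a TIS rate constant with direct transition counting on the bundled
double well (4 kcal/mol barrier, 300 K):

```python
from tisdesign import pipeline, rates
from tisdesign.systems import make_double_well

dw = make_double_well(barrier_height=4.0, well_centers=(-1.0, 1.0), n_env=1)
grid = rates.default_interface_grid(9)          # 9 interfaces, -0.8 .. 0 A
tis = pipeline.tis_rate_estimate(dw, seed=7, grid=grid,
                                 n_moves=1200, n_equil=200)
bf = pipeline.brute_force_rate(dw, total_ps=1000.0, seed=3, min_events=200)
print(f"TIS:   k = {tis['k']:.3e} 1/s "
      f"(flux {tis['flux']:.3e} 1/s, P = {tis['total_probability']:.3e})")
print(f"brute: k = {bf['k']:.3e} 1/s ({bf['n_events']} events)")
```

```
TIS:   k = 1.548e+10 1/s (flux 8.360e+12 1/s, P = 1.851e-03)
brute: k = 1.576e+10 1/s (335 events)
```

The flux says excursions from the reactant well attempt the barrier about
every 0.1 ps; only ~2 in a thousand attempts that cross the first interface
carry through to the product well, giving a ~10¹⁰ s⁻¹ rate that agrees with
the history-based transition count within replicate confidence intervals.

The full redesign study on the migration-mimic variant family runs as

```python
from tisdesign.pipeline import StudyConfig, run_design_study
res = run_design_study(StudyConfig(seed=3))
print(res["top_sequence"], res["top_tier"], f"{res['rate_ratio']:.1f}x",
      res["mw_p"])
```

which samples pathway ensembles, trains both classifiers, selects
structures, searches the sequence space, screens candidates, and rate-tests
the top one — recovering the planted gate-opening mutation as tier 1 with a
several-fold, Mann–Whitney-significant rate increase.

A `tisdesign` command-line interface wraps the main stages
(`tisdesign simulate`, `tisdesign tis rate`, `tisdesign pmf run`,
`tisdesign stats compare|fdr`, `tisdesign run-pipeline`).

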