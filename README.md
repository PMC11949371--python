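# respondsim

A dynamic, cohort-based, state-transition model of an opioid use disorder
(OUD) population, together with the empirical calibration pipeline used to
fit it: Latin hypercube search of the calibrated-parameter space with
sequential acceptance against target uncertainty windows, plus validation
and identifiability diagnostics.

The package is aimed at health-policy modellers and biostatisticians who
need a reproducible, testable implementation of rejection-style empirical
calibration for a structurally complex compartmental simulator.

## The model

The cohort occupies 9 health states — no-treatment `N`, four treatment
states `T` (buprenorphine, naltrexone, methadone, detox) and four paired
post-treatment states `P` — crossed with 4 substance-use states (active /
non-active × injection / non-injection: ANI, NANI, AI, NAI), stratified by
age band and sex. The model advances expected counts on a weekly cycle:

* arrivals `α_jk(t) = A(t)·p_jk(t)` enter no-treatment;
* other-cause mortality at SMR-adjusted life-table rates `β`;
* overdoses in active states at rates `ν_N = ο(t)·m_N`,
  `ν_T = ν_N·m_T`, `ν_P = ν_N·m_P` (none in detox, none in non-active
  states); a yearly fatal proportion `f(t)` of the pooled overdoses is
  fatal;
* health-state transitions `N→T` (`λ_NT`; detox scaled by `η(t)`),
  `T→P` (`λ_TP`), `P→N` (`λ_PN = −ln(1−0.25) ≈ 0.29`), with treatment
  initiation effects `γ` moving active entrants out of active use;
* within-state 4×4 weekly substance-use transitions (edges a–h).

All rates convert to probabilities as `p = 1 − e^{−rt}` (Poisson
assumption). Deaths are the only exits, so yearly **total OUD count =
alive at year end + that year's fatal overdoses + other-cause deaths**.

## Calibration

Calibrated parameters (arrivals `A(t)`, detox multipliers `η(t)`,
overdose multipliers `m_N, m_T, m_P`, fatal proportions `f(t)`,
post-treatment initiation effects `γ_P`, and age-stratified no-/post-
treatment transition probabilities `ρ_N, ρ_P`) get prior marginals
(published uniform bounds; Beta elsewhere). `N` Latin hypercube candidates
are simulated in vectorized batches and filtered sequentially:

1. 2015 total OUD count inside its published 95% CI (272 707, 277 402);
2. detox admissions 2013–15 inside ±10% of the observed counts;
3. fatal overdoses 2013–15 inside ±10%;
4. strictly increasing total OUD counts 2013 → 2015.

Diagnostics: per-stage attrition, boundary concentration of accepted
marginals (suggests range shifts), accepted-subset stability, a backward
target-exclusion heuristic, and a validation battery (other-death /
fatal-overdose ratio against the literature range 2.4–4.1, overdose
under-reporting direction, active-use percentage face validity).

The real fixed inputs come from non-public linked administrative data;
`respondsim.fixtures` generates a structurally faithful synthetic bundle
(correct stratification, plausible magnitudes, labelled provenance) so the
entire pipeline runs with no download.

## Worked example

```python
import respondsim as rs

bundle = rs.build_default_bundle(seed=0)
result = rs.run_calibration(bundle.space, bundle.fixed, bundle.targets,
                            n=20_000, seed=1)
print(result.stage_names, result.counts_passing)
out = result.accepted_outputs
print(result.n_accepted, out.year_col("total_oud", 2015).mean())
```

prints (numbers from this exact run):

```
['total_oud', 'detox', 'fatal', 'trend'] [1911, 53, 12, 9]
9 275157.94855345204
```

i.e. of 20 000 sampled parameter sets, 1 911 hit the 2015 total-OUD
window, 53 also hit all detox windows, 12 also hit all fatal windows and 9
survived the trend constraint (acceptance rate 4.5×10⁻⁴); the accepted
sets' mean simulated 2015 total OUD count is ≈275 158 persons, inside the
target CI by construction. The `examples/` directory walks through
simulation, calibration, validation and the exclusion diagnostic.

There is also a thin CLI:

```bash
respondsim fixtures --out bundle/
respondsim calibrate --bundle bundle/ --n-samples 20000 --seed 1 --out cal/
respondsim validate --bundle bundle/ --accepted cal/accepted_sets.csv --out val/
```

## Layout

- `src/respondsim/core.py` — weekly-cycle cohort engine (batched)
- `src/respondsim/space.py` — prior marginals, LHS designs
- `src/respondsim/calibration.py` — sequential filter + diagnostics
- `src/respondsim/validation.py` — validation battery, exclusion heuristic
- `src/respondsim/fixtures.py` — synthetic default inputs, targets, priors
- `src/respondsim/io_utils.py`, `cli.py` — persistence and CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
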