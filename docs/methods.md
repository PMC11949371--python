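# Methods

## Model structure and assumptions

The simulator is a deterministic, expected-value cohort model: occupancy
is a nonnegative real tensor indexed by health state (9), substance-use
state (4), age band and sex, advanced on a weekly cycle. Determinism makes
the rejection calibration well-posed — a candidate parameter set maps to
exactly one output trajectory — and the expected counts coincide with the
mean of the equivalent individual-level stochastic process, which is how
the engine is cross-checked (see *Verification* below).

Within a week, events apply in a fixed order:

1. **Arrivals.** `A(t)` people per week enter no-treatment, distributed
   over demography by the yearly proportions `p_jk(t)` and over use states
   by a fixed split (all arrivals are active users; 30% injection by
   default). The model is open only through arrivals; the sole exits are
   the two mortality streams.
2. **Other-cause mortality** at weekly probabilities `1 − e^{−β}`, with
   SMR-adjusted rates `β` by group (no-treatment, treatment,
   post-treatment) and stratum.
3. **Overdoses.** Only active states carry risk; active injection carries
   `inj_od_ratio` (default 2.0) times the active-non-injection rate. Rates
   are `ν_N = ο(t)·m_N` in no-treatment, `ν_T = ν_N·m_T` per medication,
   zero in detox, `ν_P = ν_N·m_P` post-treatment. The yearly fatal
   proportion `f(t)` applies to the *pooled* overdose count, and fatal
   removals are allocated proportionally to each state's contribution —
   algebraically, every state's overdose count is scaled by `f(t)`.
   Overdose is treated as an instantaneous event: survivors stay in place
   (no overdose dwell state).
4. **Health-state transitions** along the parameterized edges only:
   `N→{T_bup, T_ntx, T_met, T_detox}`, `T→` its paired `P`, `P→N`. There
   is no direct `P→T` edge. Competing exits from `N` are renormalized
   multinomially, `p_i = (r_i/R)(1 − e^{−R})`, preserving both the Poisson
   interpretation and a proper distribution. Entrants to a treatment keep
   their active state with probability `γ_T` (by route), otherwise drop to
   the matching non-active state; detox entry forces everyone non-active;
   entrants to post-treatment use `γ_P`; returning to no-treatment has no
   initiation effect.
5. **Substance-use transitions** via 4×4 weekly matrices assembled from
   the eight edge probabilities a–h (a: ANI→NANI, b: ANI→AI, c: NANI→ANI,
   d: NANI→NAI, e: AI→NAI, f: AI→ANI, g: NAI→AI, h: NAI→NANI; the mapping
   is config-overridable). Diagonals absorb the remainder. The detox
   matrix forces all mass to the matching non-active state, so detox
   occupancy is non-active at all times.

Conservation (end population = start + arrivals − deaths) is checked every
cycle at 1e-9 relative tolerance, and negative occupancy raises an
integrity error.

**Event-order choice.** The weekly order above (arrivals → other deaths →
overdoses → health transitions → use transitions) is a modelling decision;
at weekly step sizes the order sensitivity is small, and fixing it makes
the engine deterministic and testable.

**Annual accounting.** Total OUD count for year *y* is alive at year end
plus that year's fatal overdoses and other-cause deaths (deaths of year
*y* only, not cumulative). Detox admissions are the summed weekly entries
into the detox state. "Year-end" active-use percentages are final-week
occupancies (not annual averages).

## Stratification

Default strata: 2 sexes × 4 age bands (edges 15, 25, 35, 55, 100),
configurable. With these strata the calibrated space has 80 scalars:
3 arrivals + 3 detox multipliers + 2 post-treatment initiation effects +
1 `m_N` + 3 `m_T` + 1 `m_P` + 3 fatal proportions + 2×(8 edges × 4 age
bands) transition probabilities. The dimensionality is logged in the run
manifest rather than hard-coded anywhere.

## Parameter space and sampling

Each calibrated scalar has a declarative marginal: uniform with the
published bounds for arrivals, `η(t)`, `γ_P`, `m_N` and `m_P`; Beta for
the probability-valued parameters. Latin hypercube sampling (via
`scipy.stats.qmc.LatinHypercube`) guarantees exactly one draw per
equal-probability bin per dimension with independently permuted columns;
within-bin placement is uniform jitter by default, with a midpoint mode
for deterministic tests. A fixed seed makes the design bit-identical.

**Stand-in Beta shapes.** The published analysis derives its Beta priors
from supplementary data we do not ship, so the fixture shapes are
documented stand-ins chosen to mirror the *reported behaviour* of those
priors — they were informative, data-derived, and essentially unchanged
by calibration:

* `f(t)`: means 0.070 / 0.100 / 0.115 with the precision of a binomial
  proportion estimated from ~13 000 observed overdoses per year (the
  stated derivation route for these priors). Relative SD ≈ 3%.
* `ρ_N, ρ_P`: means around weekly exit-from-active probabilities of
  0.013 (no-treatment) and 0.020 (post-treatment) and relapse
  probabilities of 0.041 and 0.50 respectively — post-treatment relapse
  is fast, reflecting rapid relapse after treatment dropout — with a mild
  negative age gradient and prior effective sample size 2000
  (literature-pooled precision).
* `m_T`: weakly informative stand-ins (Beta(8,16), Beta(12,12),
  Beta(6,18) for buprenorphine, naltrexone, methadone).

Had the transition and fatal-proportion priors been made weakly
informative instead, the sequential filter's acceptance probability would
collapse orders of magnitude below the observed full-scale rate, and the
face-validity quantities would not be identified — both at odds with the
reported behaviour the fixtures are meant to emulate.

## Synthetic fixture magnitudes

The real fixed inputs (initial cohort, entry rates, baseline overdose and
death rates, demographic proportions) come from non-public linked
administrative data. The fixture bundle is a labelled synthetic stand-in
with the right structure and plausible magnitudes. Its scale constants —
initial population 223 460, baseline overdose rate ≈ 8–9 × 10⁻⁴ per week,
baseline detox entry rate 2.15 × 10⁻³ per week, other-cause death rate
≈ 4 × 10⁻⁴ per week — were fixed *once* by matching the midpoint-of-prior
simulation to the published target table (and an other/fatal death ratio
of 3.2), then frozen; they are recorded in the bundle manifest. Without
this centering the published priors could not reach the target windows at
all and the calibration demo would be vacuous. A self-check asserts that
the midpoint 2015 total OUD count stays within a factor 2 of the target.

What the fixtures do **not** emulate: real demographic gradients, secular
trends within years, correlation between entry rates and overdose risk,
or any statistical property of the Massachusetts data beyond the printed
targets. Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the *pipeline*, not epidemiological fidelity of
the synthetic inputs.

## Calibration protocol

Candidates are filtered in the published stage order — 2015 total OUD,
then detox admissions (all three years jointly), then fatal overdoses
(all three years jointly), then the trend constraint — with short-circuit
semantics and per-stage attrition counts. Design choices:

* "Increasing trend" is strict inequality (2013 < 2014 < 2015),
  configurable to weak.
* An optional secondary filter requiring larger 2014 than 2013 arrivals
  exists but is off by default (it is mentioned only in the full-scale
  results narrative, not the protocol definition).
* The growing-N protocol is exposed as `iterate_calibration`, which runs
  independent LHS batches under a deterministic seed sequence so random
  streams are never reused.
* Boundary diagnostic: a parameter is flagged when >30% of accepted mass
  sits in the outer 10% of its prior range; a shifted/expanded range is
  suggested.
* Stability: random accepted subsets are re-simulated and compared to the
  full accepted set by KS distance per output; the distance shrinking
  with subset size indicates the accepted sample is large enough.

At the scaled-down size used throughout (1e5 LHS candidates; the
full-scale analysis used 5×10⁶), the fixture acceptance rate is ≈4×10⁻⁴,
giving tens of accepted sets. Problem sizes in the tests (6 000-candidate
wide-window runs for diagnostics needing hundreds of accepted sets,
30 000 for the exclusion experiment, 1e5 for the headline run) were chosen
as the smallest sizes at which the respective statistics are stable.

## Validation battery

* **Other-death ratio:** other-cause deaths / fatal overdoses per year;
  the literature places it at 2.4–4.1.
* **Under-reporting direction:** simulated all-overdose counts vs an
  observed series (a labelled synthetic stand-in here); observed counts
  are under-reported, so simulated counts are expected above them. The
  fixture series is set so the direction holds for 2013 and fails for
  2014–15, mirroring the qualitative full-scale finding.
* **Active-percentage face validity:** year-end active share overall and
  by group, with the expected ordering treatments < no-treatment <
  post-treatment.
* **Backward target exclusion:** calibration is re-run with target
  families removed cumulatively from the last stage backwards, reusing
  the same seed (hence the same LHS design) so newly accepted candidates
  are exactly those the fuller protocol rejected; per-parameter histogram
  overlap, central-interval overlap and KS distances expose parameters a
  target family was pinning. "Non-overlapping" is operationalized as
  histogram overlap < 0.05 (the source describes the finding only
  visually; a threshold makes it assertable).

## Verification

An independent agent-based Monte-Carlo implementation (tests only)
simulates every person with Bernoulli/categorical draws under the same
event order on a one-stratum toy with ≥1e5 agents; cohort aggregates must
match the oracle within 3 standard errors. Property tests cover
conservation, detox non-activity, LHS stratification at every sampled
dimension, filter attrition monotonicity, acceptance idempotence
(re-simulated accepted sets land inside every window), and invariance of
the filter to batch partitioning.

## Numerical notes and degenerate inputs

* `p = 1 − e^{−rt}` is computed with `expm1`; the competing-risk
  renormalization uses the `R → 0` limit `p_i = r_i` safely.
* A ±10% window around a zero-valued target is degenerate `[0, 0]` and
  triggers a warning.
* Zero accepted sets is a valid calibration outcome: the result carries a
  per-stage failure histogram to guide range revision, and the CLI exits
  0 with an explicit warning.
* Tiny negative occupancies from float cancellation (< 1e-6 absolute) are
  clipped to zero; anything larger raises an integrity error.

## Known limitations

* Parameters vary yearly, not weekly; projections beyond the calibration
  horizon are out of scope.
* No likelihood-based or ABC-SMC acceptance; the filter is a hard window
  pass/fail, which over-rejects near window edges and cannot shift prior
  ranges on its own (the boundary diagnostic only suggests revisions).
* Post-treatment parameters are weakly identified — there are no
  post-treatment-specific targets — so their accepted marginals stay
  close to their priors; this mirrors the full-scale analysis.
* In-treatment transition probabilities, capture-recapture population
  estimation and cost/QALY accounting are consumed as fixed inputs or
  targets, never estimated here.
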