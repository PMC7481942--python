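# Methods

## The scheduling problem

An outpatient specialty clinic (the motivating case is a psychiatric
department with one doctor per patient list) runs a weekly grid of
`|I| = 5` days × `|T| = 72` five-minute slots.  Each patient `k` on the
waiting list needs a contiguous block of `t_k ∈ {4, 5, 6}` slots, is either a
first visit (`Z_k = 1`, revenue `w1 = 70 €`) or a follow-up (`w0 = 50 €`),
and — the crux — attends an appointment placed at day `i`, slot `t` only with
probability `P_itk`.  No-shows waste booked clinic time and revenue.

The scheduler solves, each week, the binary program

```
max  Σ_{i,t,k}  x_itk · P_itk · (Z_k w1 + (1 − Z_k) w0)
```

subject to

1. **one patient per slot** — for every grid cell, the starts that would
   cover it sum to at most one;
2. **assignment** — each buffered patient is scheduled exactly once or
   explicitly deferred (`x_k^T = 1`);
3. **first-visit quota** — assigned first-visit slots
   `≥ b4 = min(Σ_{Z_k=1} t_k, ⌈q·|I|·|T|⌉)` with `q = 0.3`;
4. **priority quota** — assigned high-priority slots
   `≥ b5 = min(Σ_{d_k=0} t_k, |I|·|T| − b4)`;
5. **contiguity** — each day's occupied cells form a prefix (no holes);
6. **daily load** — an active day's occupied slots lie in
   `[|T| − h1, |T| + h2]` with `h1 = 3`, `h2 = 0`.

`P_itk` is evaluated at the appointment's **start** slot only, the most
literal reading of the objective (the start-cell binaries are what the
objective sums).

### Sign of the daily lower bound

Printed as an inequality `Σ x·t_k ≥ |T| + h1`, the daily minimum-load
constraint is infeasible under its own parameter values (75 required slots in
a 72-slot day with no overtime).  `h1` is described as a *slack* on the
minimum number of slots, and lengths of 4–6 slots can leave a sub-4-slot
tail, so this package implements the bound as `≥ |T| − h1` (at least 69
occupied slots in an active day).  The slack is configurable
(`day_min_slack`).

### Day activation

An unconditional daily lower bound makes every week with a small buffer
infeasible (the first quiet week would need 69 booked slots it cannot fill).
A binary `y_i` per day gates the bound — `L·y_i ≤ load_i ≤ U·y_i`, with
`y_i ≥ y_{i+1}` so days open in order — preserving the no-under-filled-days
intent while letting quiet weeks run short.  If a weekly instance is still
infeasible (degenerate buffers), a relaxation ladder drops first the daily
lower bound, then the quotas, and tags the returned schedule with what was
relaxed; in the shipped experiments no week needed either relaxation.

### Formulation used by the solver

The feasible set above is implemented with explicit per-cell occupancy
binaries `occ[i,c]` linked by equality to the cover sums.  This is exactly
equivalent (the linking rows force `occ` to the cover value) but turns the
one-per-slot, contiguity and daily-load families into rows with one or two
nonzeros, which HiGHS solves roughly eight times faster than the literal
cover-sum formulation on weekly instances.  HiGHS presolve is left off: on
these packing models its root heuristics are several times faster on the
unpresolved matrix.  The MILP backend is `scipy.optimize.milp`; models export
to LP and MPS text for inspection by other solvers.

Numerical conventions: relative MIP gap `1e-9` for correctness tests and
`1e-4` for simulation runs; wall-clock limits are never used in simulations
(termination by gap keeps runs bit-reproducible).  Co-optimal schedules are
resolved by a second solve that fixes the revenue objective (within
`1e-9·|V|`) and minimizes a canonical start-cell score `Σ (i·|T| + t + 1)`,
preferring early starts and, when revenue is degenerate, the all-deferred
schedule; the tie-break solution is only accepted if its recomputed revenue
does not fall below the first solve's.  The brute-force oracle applies the
identical score.  Expected revenue sums patients in sorted-id order so
equal schedules give bit-identical totals; revenues are integers and
probabilities float64.

## Weekly buffer with dynamic priorities

The scheduler never sees the whole waiting list.  Each week a buffer is
built: (2a) everyone tied at the maximum sojourn enters with high priority;
(2b) patients are added in decreasing sojourn order until buffered follow-up
workload reaches `⌈(1 − q)|I||T|⌉ = 252` slots (the single patient whose
addition meets the floor is tagged low priority, everyone before high);
(2c) first visits are topped up, low priority, to `⌈q|I||T|⌉ = 108` slots.
Interpretations this package fixes (the process description leaves them
open): "the patients with the longest waiting time" means *all* patients
tied at the maximum sojourn; the 2b floor counts follow-up workload only
(`threshold_scope="total"` switches to counting every addition); ties beyond
sojourn break by arrival order.  Deferred patients re-enter with their
sojourn intact; every patient still waiting ages one week at week's end.

## Show-probability generator

The case study estimated `P_itk` by L1-penalized logistic regression on a
licensed hospital EHR (76,658 appointments, 97 predictors, 14.05% mean
no-show).  Neither the data nor the fitted coefficients are available, so
this package generates probabilities with the same covariate axes:

```
logit P(show) = b0 + u_k + day_i + s_t·t + s_lead·sojourn + month_m
```

| parameter | default | meaning |
| --- | --- | --- |
| `u_k` | Normal(0, 0.8) | per-patient propensity (log-odds) |
| `day_i` | (0.15, 0.05, 0, −0.05, −0.15) | day-of-week offsets |
| `s_t` | −0.004 / slot | later in the day, lower show |
| `s_lead` | −0.03 / week | longer waits, lower show |
| `month_m` | 0.2·sin(2πm/12) | mild seasonality (4-week months) |
| `b0` | calibrated | fixes the population mean |

The defaults are **synthetic**: effect sizes were never published.  They are
chosen once so per-patient mean show probabilities span roughly 0.6–0.99 —
enough heterogeneity that selecting on probabilities matters — and are not
tuned to any downstream result.  The intercept is root-found (`brentq`) so
the Monte-Carlo population mean no-show over a uniform appointment grid and
sojourns 0–8 equals 14.05%; with all effects zero this reduces to the closed
form `b0 = logit(0.8595)`.

What the generator deliberately does not emulate: the EHR model's
demographic/clinical predictors, within-patient attendance history
(draws are independent across weeks given the surface), and any correlation
between appointment length and show propensity.  Tests passing under this
generator therefore demonstrate the *mechanics* of probability-aware
scheduling (selection, quotas, capacity), not the clinical effect sizes of
the original study — which is why the simulation acceptance checks assert
orderings between policies, never the published table's cell values.

`fit_noshow_model` fits the same model class to tabular records
(cross-validated Lasso via scikit-learn's saga solver; covariates
standardized, intercept unpenalized, folds seeded).  When the penalty zeroes
every coefficient the intercept is set to its closed-form MLE `logit(ȳ)` —
saga's stopping rule under-optimizes the intercept in that degenerate
regime.

## Simulation design

48 weeks.  The initial list is 8 cohorts (sojourns 8 down to 1) of
`Uniform{62..66}` patients each — the cohort-size choice mirrors the weekly
arrival process, since the original initial-list size is unstated.  Each
week: arrivals (`Uniform{62..66}`, sojourn 1, 30% first visits) → buffer →
schedule → attendance draws at the assigned cell → shows pay and leave,
no-shows rebook with `p_r = 0.3` at sojourn 0 or abandon → deferred return
→ everyone waiting ages +1.  A rebooking no-show keeps its first-visit flag
(the visit never happened).

Metric interpretations (both alternatives are computed in the weekly frame):
"patients in the queue" is the waiting-list size after all week-end updates;
"average sojourn" is the mean sojourn, at scheduling time, of that week's
scheduled patients; averages cover all 48 weeks (no burn-in discard).  Idle
time counts no-show bookings in full plus, for constant-interval bookings,
the overhang `(6 − t_k)` slots of attended appointments; unbooked end-of-day
tails are not idle time (the doctor is not on the clock).

Randomness is split into independent numpy streams (initial list, arrivals,
attendance) and attendance draws are keyed by `(seed, week, patient)`, so
policies compared on a seed face identical arrival histories and identical
attendance luck for any patient-week both happen to schedule.  The generator
intercept is calibrated with a fixed internal seed so all runs share one
probability model.

### Scale of the shipped experiments

The policy-ordering experiments (test suite and acceptance script) run a
half-size clinic: 36 slots/day, arrivals `Uniform{31..33}`, preserving the
full-size ratios (constant-interval capacity 30/week below mean demand 32;
variable capacity 30–45 above it).  A half-scale week solves in ~1–3 s;
full-scale weekly instances (~34k binaries) solve too, but multiply across
4 policies × 5 seeds × 48 weeks into hours of compute for the same
qualitative comparison.  Full scale remains available by passing the default
`ClinicParams()` to the simulator.

## Comparison policies

* `fifo_constant` — the legacy desk: strict FIFO, every booking 30 minutes.
* `fifo_variable` — strict FIFO with patient-specific lengths.  Strict means
  a patient who does not fit the current day's remainder starts the next
  day; no searching past them.
* `time_constant` — the probabilistic predecessor model: same assignment
  program, every booking forced to 6 slots, quotas on booked slots.
* `time_variable` — the full model above.

All four see the same weekly buffer, so differences are pure policy effects.
FIFO policies ignore quotas and probabilities (they model the incumbent
system, which had neither).

## Known limitations

Single doctor; deterministic service times (idle time comes only from
no-shows and booking overhang); no overbooking, walk-ins, cancellations or
punctuality effects; attendance independent across weeks for a given
patient.  With synthetic effect sizes, absolute simulated revenues and
queue lengths are not forecasts for any real clinic; only the relative
behavior of the policies is meaningful.
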