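# clinsched

Probabilistic outpatient appointment scheduling with **variable-length
slots**, for health-operations researchers and clinic planners studying
no-show mitigation.

Outpatient clinics lose revenue and stretch waiting lists when booked
patients fail to attend.  If individual show probabilities can be estimated
(e.g. from electronic health records), the weekly timetable itself can hedge
against no-shows.  `clinsched` implements a weekly scheduler that does this
while also booking each patient for the time they actually need, plus the
machinery to evaluate it: a dynamic-priority waiting-list process, three
comparison policies, a heterogeneous no-show generator, and a closed-loop
clinic simulator.

## The model

Each week a buffer `K` of candidates is assigned to a grid of `|I| = 5` days
× `|T| = 72` five-minute slots.  Patient `k` needs `t_k ∈ {4,5,6}`
contiguous slots, pays `w1 = 70 €` (first visit, `Z_k = 1`) or `w0 = 50 €`
(follow-up) **if they attend**, which happens with probability `P_itk` at
day `i`, slot `t`.  The scheduler solves the binary program

```
max  Σ_{i,t,k}  x_itk · P_itk · (Z_k w1 + (1 − Z_k) w0)

s.t. each grid cell covered at most once          (one patient at a time)
     Σ_{i,t} x_itk + x_k^T = 1        ∀k          (schedule once or defer)
     Σ x_itk · t_k · Z_k        ≥ b4              (first-visit slot quota)
     Σ x_itk · t_k · (1 − d_k)  ≥ b5              (high-priority slot quota)
     occupied cells form a prefix of each day     (no holes)
     per-day occupancy in [|T| − h1, |T| + h2]    (active days run full)
     x binary
```

with quotas `b4 = min(Σ_{Z_k=1} t_k, ⌈q|I||T|⌉)`,
`b5 = min(Σ_{d_k=0} t_k, |I||T| − b4)`, first-visit share `q = 0.3`, and
priorities `d_k` set by the waiting-list process (longest waiters first).
Solved with HiGHS through `scipy.optimize.milp`; every model exports to LP
and MPS text.  A brute-force enumerator provides exact optima on small
instances for verification.  See `docs/methods.md` for formulation notes
(occupancy encoding, day activation, tie-breaking) and the no-show
generator's design.

## Worked example

Three patients compete for one 8-slot day (no quotas, lower bound relaxed):
a first visit A (4 slots, show probability 0.9) and follow-ups B (4 slots,
0.8) and C (4 slots, 0.95).  Only two fit.

```python
import numpy as np
from clinsched import ClinicParams, Patient, make_instance, solve_schedule

params = ClinicParams(days_per_week=1, slots_per_day=8, first_visit_quota=0.0,
                      day_min_slack=8)
def patient(pid, first, prob):
    p = Patient(id=pid, is_first_visit=first, required_slots=4, priority=0,
                arrival_index=ord(pid))
    p.show_prob = np.full((1, 8), prob)
    return p

buffer = [patient("A", True, 0.9), patient("B", False, 0.8),
          patient("C", False, 0.95)]
s = solve_schedule(make_instance(buffer, params, quotas=(0, 0), day_lower=0))
print(s.objective_value, s.assignments, s.deferred)
```

```
110.5 {'A': (0, 0), 'C': (0, 4)} {'B'}
```

The scheduler books A then C back-to-back and defers B: expected revenue
`0.9·70 + 0.95·50 = 110.5 €`, which beats any pair containing B.  The same
instance run through `brute_force_schedule` returns the identical objective.

At simulation scale, `run_simulation` wires the weekly loop together.  On a
half-size clinic (36 slots/day, 31–33 weekly arrivals — same
capacity-to-demand ratios as the full grid), 48 weeks, seed 1:

```python
from clinsched import ClinicParams, NoShowGenParams, run_simulation
res = run_simulation(ClinicParams().half_scale(), NoShowGenParams(),
                     scheduler="time_variable", weeks=48, rng_seed=1)
print(res.summary())
```

```
{'mean_queue_length': 210.10416666666666,
 'mean_sojourn_scheduled': 7.096640784692255,
 'mean_weekly_profit': 1727.9166666666667,
 'mean_weekly_idle_minutes': 121.66666666666667,
 'noshow_rate': 0.13396004700352526,
 'mean_weekly_scheduled': 35.458333333333336}
```

The same seed under the legacy policies: FIFO-constant averages a queue of
342 patients, 1390 €/week and 275 idle minutes; the constant-slot
probabilistic model 334 patients and 1438 €/week.  The variable-slot model
serves more patients per week (35.5 vs 30), keeps the realized no-show rate
below FIFO's (0.134 vs 0.147) and shortens the queue — the orderings the
package's acceptance checks assert across shared seeds.

The CLI mirrors the library:

```bash
clinsched schedule --patients patients.csv --config clinic.yaml --out schedule.csv
clinsched simulate --scheduler time_variable --weeks 48 --seed 7 --out runs/
clinsched compare  --policies fifo_constant,time_variable --seeds 0,1,2 --out table.csv
```

## Layout

```
src/clinsched/
  core.py                clinic parameters, patients, schedules, validation
  milp_scheduler.py      the assignment program + brute-force oracle
  linmodel.py            binary-LP container, HiGHS solve, LP/MPS export
  buffer_builder.py      dynamic-priority weekly buffer
  baseline_schedulers.py FIFO policies and the constant-slot model
  noshow_model.py        probability generator, calibration, Lasso fitting
  clinic_simulator.py    48-week closed loop and metrics
  reference.py           case-study reference averages (comparison fixture)
  cli_io.py, cli.py      config/CSV I/O, comparison report, CLI
docs/methods.md          model, assumptions, design choices, limitations
```
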