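"""The probabilistic variable-slot assignment program.

A weekly buffer of patients is assigned to start cells of a (days x slots)
grid to maximize expected revenue

    max  sum_{i,t,k} x_itk * P_k[i,t] * (Z_k*w1 + (1-Z_k)*w0)

subject to: one patient per slot; every patient is scheduled once or deferred;
first-visit and high-priority slot quotas (b4, b5); each day's occupied slots
form a contiguous prefix; and active-day occupancy within
``[slots_per_day - h1, slots_per_day + h2]``.

The implementation materializes per-cell occupancy binaries ``occ[i,c]`` equal
to the slot-cover sums, which makes the one-per-slot, contiguity and
daily-load constraints single-variable or two-variable rows and solves an
order of magnitude faster than writing the cover sums out in every row, with
an identical feasible set.  An unconditional daily lower bound would be
infeasible whenever the buffer is small, so per-day activation binaries
``y_i`` (days open in order) gate it; see docs/methods.md.

``brute_force_schedule`` exhaustively enumerates feasible schedules on tiny
instances and serves as the independent optimality oracle in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ClinicParams,
    MissingProbabilityError,
    Patient,
    Schedule,
    expected_revenue,
)
from .linmodel import LinearModel

__all__ = [
    "MilpInstance",
    "InfeasibleScheduleError",
    "compute_quotas",
    "make_instance",
    "build_milp",
    "solve_schedule",
    "brute_force_schedule",
    "enumerate_feasible_schedules",
    "secondary_score",
]


class InfeasibleScheduleError(RuntimeError):
    """No feasible schedule exists, even after the relaxation ladder."""


def compute_quotas(
    buffer: list[Patient],
    params: ClinicParams,
    booked: dict[str, int] | None = None,
) -> tuple[int, int]:
    """Quota right-hand sides.

    b4 = min(first-visit workload, ceil(q |I||T|)) — slots that must go to
    first visits; b5 = min(high-priority workload, |I||T| - b4) — slots that
    must go to high-priority patients.  Workloads are measured in booked
    slots.  Requires every buffered patient to carry a priority tag.
    """
    booked = booked or {}

    def slots(p: Patient) -> int:
        return booked.get(p.id, p.required_slots)

    for p in buffer:
        if p.priority is None:
            raise ValueError(f"patient {p.id} has no priority tag; build the buffer first")
    first_workload = sum(slots(p) for p in buffer if p.is_first_visit)
    high_workload = sum(slots(p) for p in buffer if p.priority == 0)
    b4 = min(first_workload, params.first_visit_slot_floor)
    b5 = min(high_workload, params.slots_per_week - b4)
    return int(b4), int(b5)


@dataclass
class MilpInstance:
    """One weekly scheduling problem: buffer, parameters, quotas, day bounds."""

    buffer: list[Patient]
    params: ClinicParams
    b4: int
    b5: int
    day_lower: int
    day_upper: int
    booked: dict[str, int] = field(default_factory=dict)

    def booked_slots(self, p: Patient) -> int:
        return self.booked.get(p.id, p.required_slots)

    def start_domain(self, p: Patient) -> range:
        """Valid 0-based start slots: the appointment must fit in the day."""
        return range(0, self.params.slots_per_day - self.booked_slots(p) + 1)


def make_instance(
    buffer: list[Patient],
    params: ClinicParams,
    booked: dict[str, int] | None = None,
    quotas: tuple[int, int] | None = None,
    day_lower: int | None = None,
) -> MilpInstance:
    booked = booked or {}
    if quotas is None:
        quotas = compute_quotas(buffer, params, booked)
    return MilpInstance(
        buffer=list(buffer),
        params=params,
        b4=quotas[0],
        b5=quotas[1],
        day_lower=params.day_lower_bound if day_lower is None else day_lower,
        day_upper=params.day_upper_bound,
        booked=dict(booked),
    )


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def _check_quota_feasibility(instance: MilpInstance) -> None:
    p = instance.params
    cap = p.days_per_week * instance.day_upper
    first_workload = sum(
        instance.booked_slots(q) for q in instance.buffer if q.is_first_visit
    )
    high_workload = sum(
        instance.booked_slots(q) for q in instance.buffer if q.priority == 0
    )
    if instance.b4 > min(first_workload, cap):
        raise InfeasibleScheduleError(
            f"quota b4={instance.b4} exceeds achievable first-visit workload "
            f"min({first_workload}, {cap})"
        )
    if instance.b5 > min(high_workload, cap):
        raise InfeasibleScheduleError(
            f"quota b5={instance.b5} exceeds achievable high-priority workload "
            f"min({high_workload}, {cap})"
        )


def build_milp(
    instance: MilpInstance, day_activation: bool = True
) -> tuple[LinearModel, dict]:
    """Build the assignment program as a :class:`LinearModel`.

    Returns the model and a variable map with keys ``x`` (patient-index, day,
    start) -> column, ``defer`` patient-index -> column, ``occ`` and ``y``.
    Variable names use 1-based day/slot indices for the LP/MPS export.
    """
    _check_quota_feasibility(instance)
    p = instance.params
    days, T = p.days_per_week, p.slots_per_day
    m = LinearModel(name="weekly_schedule")
    x: dict[tuple[int, int, int], int] = {}
    defer: dict[int, int] = {}
    occ: dict[tuple[int, int], int] = {}
    y: dict[int, int] = {}

    for k, patient in enumerate(instance.buffer):
        if patient.show_prob is None:
            raise MissingProbabilityError(
                f"patient {patient.id}: no show-probability surface; cannot "
                "price assignments"
            )
        surface = np.asarray(patient.show_prob)
        w = patient.revenue_for(p)
        for i in range(days):
            for t in instance.start_domain(patient):
                x[(k, i, t)] = m.add_var(
                    f"x_{patient.id}_{i + 1}_{t + 1}", obj=float(surface[i, t]) * w
                )
    for k, patient in enumerate(instance.buffer):
        defer[k] = m.add_var(f"xT_{patient.id}")
    for i in range(days):
        for c in range(T):
            occ[(i, c)] = m.add_var(f"occ_{i + 1}_{c + 1}")
    use_y = day_activation and instance.day_lower > 0
    if use_y:
        for i in range(days):
            y[i] = m.add_var(f"y_{i + 1}")

    # occupancy linking (constraint family 2: one patient per slot) and
    # contiguity (family 6: occupied cells form a prefix of the day)
    cover_cols: dict[tuple[int, int], list[int]] = {
        (i, c): [] for i in range(days) for c in range(T)
    }
    for (k, i, t), col in x.items():
        for c in range(t, t + instance.booked_slots(instance.buffer[k])):
            cover_cols[(i, c)].append(col)
    for i in range(days):
        for c in range(T):
            m.add_constr(
                f"occ_{i + 1}_{c + 1}",
                cover_cols[(i, c)] + [occ[(i, c)]],
                [1.0] * len(cover_cols[(i, c)]) + [-1.0],
                lb=0.0,
                ub=0.0,
            )
        for c in range(T - 1):
            m.add_constr(
                f"contig_{i + 1}_{c + 1}",
                [occ[(i, c)], occ[(i, c + 1)]],
                [1.0, -1.0],
                lb=0.0,
            )

    # each patient scheduled exactly once or deferred (family 3)
    for k, patient in enumerate(instance.buffer):
        cols = [x[(k, i, t)] for i in range(days) for t in instance.start_domain(patient)]
        m.add_constr(
            f"assign_{patient.id}", cols + [defer[k]], [1.0] * len(cols) + [1.0],
            lb=1.0, ub=1.0,
        )

    # quotas (families 4 and 5), weighted by booked slots
    if instance.b4 > 0:
        cols, vals = [], []
        for (k, i, t), col in x.items():
            patient = instance.buffer[k]
            if patient.is_first_visit:
                cols.append(col)
                vals.append(float(instance.booked_slots(patient)))
        m.add_constr("quota_first", cols, vals, lb=float(instance.b4))
    if instance.b5 > 0:
        cols, vals = [], []
        for (k, i, t), col in x.items():
            patient = instance.buffer[k]
            if patient.priority == 0:
                cols.append(col)
                vals.append(float(instance.booked_slots(patient)))
        m.add_constr("quota_high", cols, vals, lb=float(instance.b5))

    # daily workload bounds (families 7 and 8) via occupancy sums
    for i in range(days):
        cols = [occ[(i, c)] for c in range(T)]
        if use_y:
            m.add_constr(
                f"day_lower_{i + 1}", cols + [y[i]],
                [1.0] * T + [-float(instance.day_lower)], lb=0.0,
            )
            m.add_constr(
                f"day_upper_{i + 1}", cols + [y[i]],
                [1.0] * T + [-float(instance.day_upper)], ub=0.0,
            )
        else:
            m.add_constr(
                f"day_load_{i + 1}", cols, [1.0] * T, lb=0.0,
                ub=float(instance.day_upper),
            )
    if use_y:
        for i in range(days - 1):
            m.add_constr(f"day_order_{i + 1}", [y[i], y[i + 1]], [1.0, -1.0], lb=0.0)

    return m, {"x": x, "defer": defer, "occ": occ, "y": y}


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def secondary_score(schedule: Schedule, params: ClinicParams) -> int:
    """Canonical tie-breaking score: sum over assignments of
    ``day*|T| + start + 1``.  Lower is preferred, so co-optimal schedules
    resolve to early starts and, when revenue is degenerate (all-zero
    probabilities), to the all-deferred schedule."""
    return sum(
        day * params.slots_per_day + start + 1
        for day, start in schedule.assignments.values()
    )


def _extract(instance: MilpInstance, varmap: dict, xvec: np.ndarray,
             relaxations: tuple[str, ...], mip_gap: float | None) -> Schedule:
    assignments: dict[str, tuple[int, int]] = {}
    deferred: set[str] = set()
    for (k, i, t), col in varmap["x"].items():
        if xvec[col] > 0.5:
            assignments[instance.buffer[k].id] = (i, t)
    for k, col in varmap["defer"].items():
        if xvec[col] > 0.5:
            deferred.add(instance.buffer[k].id)
    schedule = Schedule(
        patients=list(instance.buffer),
        assignments=assignments,
        deferred=deferred,
        booked={
            p.id: instance.booked[p.id]
            for p in instance.buffer
            if p.id in instance.booked
        },
        relaxations=relaxations,
        mip_gap=mip_gap,
    )
    schedule.objective_value = expected_revenue(schedule, instance.params)
    return schedule


def solve_schedule(
    instance: MilpInstance,
    gap: float = 1e-9,
    time_limit: float | None = None,
    tie_break: bool = True,
    relax: bool = True,
) -> Schedule:
    """Solve the weekly assignment program.

    Tries the full model first; if it is infeasible (small buffers cannot
    fill a day to its lower bound while meeting quotas) and ``relax`` is set,
    retries without the daily lower bound, then additionally without quotas,
    tagging the returned schedule with the relaxations applied.

    With ``tie_break``, a second solve over the near-optimal face minimizes
    the canonical start-cell score so co-optimal schedules resolve
    identically across solvers and runs; the tie-break solution is kept only
    if its recomputed expected revenue is not below the first solve's.
    """
    ladders: list[tuple[tuple[str, ...], MilpInstance]] = [((), instance)]
    if relax:
        ladders.append(
            (("day_lower_relaxed",), replace(instance, day_lower=0))
        )
        ladders.append(
            (
                ("day_lower_relaxed", "quotas_relaxed"),
                replace(instance, day_lower=0, b4=0, b5=0),
            )
        )
    last_error: Exception | None = None
    for tags, inst in ladders:
        try:
            model, varmap = build_milp(inst)
        except InfeasibleScheduleError as exc:
            last_error = exc
            continue
        res = model.solve(gap=gap, time_limit=time_limit)
        if res.feasible:
            schedule = _extract(inst, varmap, res.x, tags, res.mip_gap)
            if tie_break and res.optimal:
                schedule = _tie_break(inst, model, varmap, schedule)
            return schedule
        last_error = InfeasibleScheduleError(
            "weekly model infeasible"
            + (f" under relaxations {tags}" if tags else "")
            + " (daily-bound/quota structure)"
        )
    raise last_error if last_error is not None else InfeasibleScheduleError("infeasible")


def _tie_break(
    instance: MilpInstance, model: LinearModel, varmap: dict, first: Schedule
) -> Schedule:
    primary = sum(
        model.obj[col] * 1.0
        for (k, i, t), col in varmap["x"].items()
        if instance.buffer[k].id in first.assignments
        and first.assignments[instance.buffer[k].id] == (i, t)
    )
    eps = 1e-9 * max(1.0, abs(primary))
    cols = [col for col in varmap["x"].values()]
    vals = [model.obj[col] for col in cols]
    model.add_constr("tie_primary", cols, vals, lb=primary - eps)
    saved_obj = list(model.obj)
    T = instance.params.slots_per_day
    for col in range(model.n_vars):
        model.obj[col] = 0.0
    for (k, i, t), col in varmap["x"].items():
        model.obj[col] = -float(i * T + t + 1)  # maximize negative score
    res = model.solve(gap=1e-9)
    model.obj = saved_obj
    if res.feasible:
        second = _extract(instance, varmap, res.x, first.relaxations, first.mip_gap)
        if second.objective_value >= first.objective_value:
            return second
    return first


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

_ENUM_MAX_BUFFER = 8
_ENUM_MAX_COMBOS = 500_000


def enumerate_feasible_schedules(
    instance: MilpInstance, day_activation: bool = True
):
    """Yield every feasible schedule of a tiny instance.

    Feasibility mirrors the MILP exactly: contiguous prefix packing per day
    (so a day's schedule is an ordered sequence of patients starting at slot
    0), daily loads of nonempty days within ``[day_lower, day_upper]``,
    nonempty days forming a prefix of the week when ``day_activation`` and a
    positive lower bound apply, and both quotas.
    """
    n = len(instance.buffer)
    days = instance.params.days_per_week
    if n > _ENUM_MAX_BUFFER or (days + 1) ** n > _ENUM_MAX_COMBOS:
        raise ValueError(
            f"instance too large for exhaustive enumeration "
            f"(buffer {n}, days {days})"
        )
    lengths = [instance.booked_slots(p) for p in instance.buffer]
    prefix_rule = day_activation and instance.day_lower > 0

    for day_of in itertools.product(range(days + 1), repeat=n):
        # day index `days` means deferred
        per_day: list[list[int]] = [[] for _ in range(days)]
        for k, d in enumerate(day_of):
            if d < days:
                per_day[d].append(k)
        loads = [sum(lengths[k] for k in members) for members in per_day]
        if any(load > instance.day_upper for load in loads):
            continue
        nonempty = [i for i, members in enumerate(per_day) if members]
        if any(0 < loads[i] < instance.day_lower for i in nonempty):
            continue
        if prefix_rule and nonempty != list(range(len(nonempty))):
            continue
        # quotas on the assigned set (order-independent)
        first_slots = sum(
            lengths[k] for k, d in enumerate(day_of)
            if d < days and instance.buffer[k].is_first_visit
        )
        high_slots = sum(
            lengths[k] for k, d in enumerate(day_of)
            if d < days and instance.buffer[k].priority == 0
        )
        if first_slots < instance.b4 or high_slots < instance.b5:
            continue
        deferred = {
            instance.buffer[k].id for k, d in enumerate(day_of) if d == days
        }
        for orders in itertools.product(
            *(itertools.permutations(members) for members in per_day)
        ):
            assignments: dict[str, tuple[int, int]] = {}
            for i, order in enumerate(orders):
                start = 0
                for k in order:
                    assignments[instance.buffer[k].id] = (i, start)
                    start += lengths[k]
            yield Schedule(
                patients=list(instance.buffer),
                assignments=assignments,
                deferred=set(deferred),
                booked={
                    p.id: instance.booked[p.id]
                    for p in instance.buffer
                    if p.id in instance.booked
                },
            )


def brute_force_schedule(
    instance: MilpInstance, relax: bool = True
) -> Schedule:
    """Exhaustive-enumeration optimum with the same tie-breaking convention
    as :func:`solve_schedule`; the independent oracle for small instances."""
    ladders: list[tuple[tuple[str, ...], MilpInstance]] = [((), instance)]
    if relax:
        ladders.append((("day_lower_relaxed",), replace(instance, day_lower=0)))
        ladders.append(
            (
                ("day_lower_relaxed", "quotas_relaxed"),
                replace(instance, day_lower=0, b4=0, b5=0),
            )
        )
    for tags, inst in ladders:
        best: Schedule | None = None
        best_key: tuple | None = None
        for candidate in enumerate_feasible_schedules(inst):
            obj = expected_revenue(candidate, inst.params)
            key = (
                -obj,
                secondary_score(candidate, inst.params),
                tuple(sorted((pid, c) for pid, c in candidate.assignments.items())),
            )
            if best_key is None or key < best_key:
                candidate.objective_value = obj
                candidate.relaxations = tags
                best, best_key = candidate, key
        if best is not None:
            return best
    raise InfeasibleScheduleError("no feasible schedule in enumeration")
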