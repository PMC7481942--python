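"""Comparison policies: FIFO queue disciplines and the probabilistic
constant-interval model.

``fifo_schedule`` reproduces the legacy booking desk: patients are taken in
waiting-list order and placed at the earliest free cell, either with the
historical fixed 30-minute booking (``constant``) or with their own required
length (``variable``).  It is a pure queue discipline — no probabilities, no
quotas.  ``time_constant_schedule`` is the probabilistic assignment model
with every booking forced to the constant length, i.e. the predecessor system
this package's variable-slot model extends.
"""

from __future__ import annotations

from .core import ClinicParams, Patient, Schedule, expected_revenue
from .milp_scheduler import make_instance, solve_schedule

__all__ = ["fifo_schedule", "time_constant_schedule"]


def fifo_schedule(
    buffer: list[Patient] | "object",
    params: ClinicParams,
    mode: str = "variable",
) -> Schedule:
    """Greedy first-come-first-served placement.

    Strict FIFO: a patient who does not fit in the current day's remaining
    slots starts the next day, leaving the tail unbooked; nobody is searched
    forward past a patient who could not be placed.  Patients left when the
    grid is exhausted are deferred.
    """
    if mode not in ("constant", "variable"):
        raise ValueError(f"unknown FIFO mode {mode!r}")
    patients = list(buffer)
    days, T = params.days_per_week, params.slots_per_day
    assignments: dict[str, tuple[int, int]] = {}
    deferred: set[str] = set()
    booked: dict[str, int] = {}
    day, cursor = 0, 0
    for p in patients:
        length = params.constant_slots if mode == "constant" else p.required_slots
        if day < days and cursor + length > T:
            day += 1
            cursor = 0
        if day >= days:
            deferred.add(p.id)
            continue
        assignments[p.id] = (day, cursor)
        if mode == "constant":
            booked[p.id] = length
        cursor += length
    schedule = Schedule(
        patients=patients,
        assignments=assignments,
        deferred=deferred,
        booked=booked,
    )
    if all(p.show_prob is not None for p in patients if p.id in assignments):
        schedule.objective_value = expected_revenue(schedule, params)
    return schedule


def time_constant_schedule(
    buffer: list[Patient] | "object",
    params: ClinicParams,
    gap: float = 1e-9,
    tie_break: bool = True,
) -> Schedule:
    """Probabilistic assignment with constant-length bookings.

    Every patient is booked for ``params.constant_slots`` slots regardless of
    their required length; quotas are recomputed on the constant bookings and
    the same assignment program is solved.  With all required lengths equal
    to the constant length this coincides exactly with the variable model.
    """
    patients = list(buffer)
    booked = {p.id: params.constant_slots for p in patients}
    instance = make_instance(patients, params, booked=booked)
    return solve_schedule(instance, gap=gap, tie_break=tie_break)
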