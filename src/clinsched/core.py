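"""Domain types shared by every scheduler: clinic configuration, patients,
schedules, the expected-revenue objective and schedule validation.

The clinic operates a single doctor on a weekly grid of ``days_per_week`` days
times ``slots_per_day`` five-minute slots.  Each patient ``k`` needs a
contiguous block of ``t_k`` slots, is either a first visit (revenue ``w1``) or
a follow-up (revenue ``w0``), and attends an appointment placed at day ``i``,
slot ``t`` with probability ``P_k[i, t]``.  A weekly schedule assigns a subset
of a candidate buffer to start cells and defers the rest back to the waiting
list; its value is the expected revenue of the assigned appointments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClinicParams",
    "Patient",
    "Schedule",
    "Violation",
    "MissingProbabilityError",
    "expected_revenue",
    "validate_schedule",
]


class MissingProbabilityError(ValueError):
    """Raised when a schedule references a show probability that is absent."""


@dataclass(frozen=True)
class ClinicParams:
    """Scheduling-policy and simulation constants of the clinic.

    Defaults reproduce the operating parameters of the Spanish outpatient
    psychiatry clinic the model was designed for: a 5-day week of 72
    five-minute slots (six hours a day), a 30% first-visit quota, revenues of
    70/50 EUR for first/follow-up visits, appointment lengths of 4-6 slots and
    62-66 weekly appointment requests.

    ``day_min_slack`` (h1) and ``day_max_slack`` (h2) bound the occupied slots
    of an active day to ``[slots_per_day - h1, slots_per_day + h2]``.
    """

    days_per_week: int = 5
    slots_per_day: int = 72
    slot_minutes: int = 5
    first_visit_quota: float = 0.3
    revenue_first: int = 70
    revenue_followup: int = 50
    day_min_slack: int = 3
    day_max_slack: int = 0
    reschedule_prob: float = 0.3
    appt_slots_min: int = 4
    appt_slots_max: int = 6
    arrivals_min: int = 62
    arrivals_max: int = 66
    first_visit_arrival_fraction: float = 0.3
    weeks: int = 48
    constant_booking_minutes: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.first_visit_quota <= 1.0:
            raise ValueError(
                f"first_visit_quota must lie in [0, 1], got {self.first_visit_quota}"
            )
        if not 0.0 <= self.reschedule_prob <= 1.0:
            raise ValueError(
                f"reschedule_prob must lie in [0, 1], got {self.reschedule_prob}"
            )
        if not 0.0 <= self.first_visit_arrival_fraction <= 1.0:
            raise ValueError(
                "first_visit_arrival_fraction must lie in [0, 1], got "
                f"{self.first_visit_arrival_fraction}"
            )
        if not (self.slots_per_day >= self.appt_slots_max >= self.appt_slots_min >= 1):
            raise ValueError(
                "need slots_per_day >= appt_slots_max >= appt_slots_min >= 1, got "
                f"{self.slots_per_day} / {self.appt_slots_max} / {self.appt_slots_min}"
            )
        if self.day_max_slack < 0:
            raise ValueError(f"day_max_slack must be >= 0, got {self.day_max_slack}")
        if not 0 <= self.day_min_slack <= self.slots_per_day:
            raise ValueError(
                f"day_min_slack must lie in [0, slots_per_day], got {self.day_min_slack}"
            )
        if self.arrivals_min > self.arrivals_max:
            raise ValueError(
                f"arrivals_min ({self.arrivals_min}) > arrivals_max ({self.arrivals_max})"
            )
        for name in ("days_per_week", "slot_minutes", "weeks"):
            if getattr(self, name) < (1 if name != "weeks" else 0):
                raise ValueError(f"{name} out of range: {getattr(self, name)}")

    # --- derived quantities -------------------------------------------------

    @property
    def slots_per_week(self) -> int:
        return self.days_per_week * self.slots_per_day

    @property
    def day_lower_bound(self) -> int:
        """Minimum occupied slots of an active day (|T| - h1)."""
        return max(0, self.slots_per_day - self.day_min_slack)

    @property
    def day_upper_bound(self) -> int:
        """Maximum occupied slots of a day (|T| + h2)."""
        return self.slots_per_day + self.day_max_slack

    @property
    def constant_slots(self) -> int:
        """Booking length of the legacy constant-interval system, in slots."""
        return math.ceil(self.constant_booking_minutes / self.slot_minutes)

    @property
    def first_visit_slot_floor(self) -> int:
        """Minimum weekly slots reserved for first visits: ceil(q |I||T|)."""
        return math.ceil(self.first_visit_quota * self.slots_per_week)

    @property
    def followup_slot_floor(self) -> int:
        """Minimum weekly slots reserved for follow-ups: ceil((1-q)|I||T|)."""
        return math.ceil((1.0 - self.first_visit_quota) * self.slots_per_week)

    def half_scale(self) -> "ClinicParams":
        """A half-size clinic (36 slots/day, 31-33 weekly arrivals) that keeps
        the full-scale ratios of capacity to demand.  Used for experiments
        where weekly full-scale solves would be needlessly slow."""
        return replace(self, slots_per_day=36, arrivals_min=31, arrivals_max=33)


@dataclass
class Patient:
    """One patient on the waiting list.

    ``show_prob`` is the (days x slots) show-probability surface for the
    *current* week; it is rebuilt each week because lead time (sojourn) and
    calendar month shift the probabilities.  ``priority`` is unset until the
    weekly buffer is built (0 = high, 1 = low).
    """

    id: str
    is_first_visit: bool
    required_slots: int
    sojourn: int = 1
    priority: int | None = None
    arrival_index: int = 0
    patient_effect: float = 0.0
    show_prob: np.ndarray | None = None
    provenance: str | None = None

    def check(self, params: ClinicParams) -> None:
        if not (
            params.appt_slots_min <= self.required_slots <= params.appt_slots_max
        ):
            raise ValueError(
                f"patient {self.id}: required_slots={self.required_slots} outside "
                f"[{params.appt_slots_min}, {params.appt_slots_max}]"
            )
        if self.sojourn < 0:
            raise ValueError(f"patient {self.id}: negative sojourn {self.sojourn}")
        if self.show_prob is not None:
            p = np.asarray(self.show_prob)
            if p.min() < 0.0 or p.max() > 1.0:
                raise ValueError(f"patient {self.id}: probabilities outside [0, 1]")

    def revenue_for(self, params: ClinicParams) -> int:
        return params.revenue_first if self.is_first_visit else params.revenue_followup


@dataclass
class Schedule:
    """Result of scheduling one weekly buffer.

    ``assignments`` maps patient id to a 0-based ``(day, start_slot)`` cell;
    an appointment occupies the half-open slot range
    ``[start, start + booked)``.  ``deferred`` holds the ids sent back to the
    waiting list.  ``booked`` holds booking lengths that differ from the
    patient's ``required_slots`` (constant-interval policies book 6 slots for
    everyone); absent ids are booked at ``required_slots``.
    """

    patients: list[Patient]
    assignments: dict[str, tuple[int, int]] = field(default_factory=dict)
    deferred: set[str] = field(default_factory=set)
    booked: dict[str, int] = field(default_factory=dict)
    objective_value: float | None = None
    relaxations: tuple[str, ...] = ()
    mip_gap: float | None = None

    def patient_map(self) -> dict[str, Patient]:
        return {p.id: p for p in self.patients}

    def booked_slots(self, pid: str) -> int:
        if pid in self.booked:
            return self.booked[pid]
        return self.patient_map()[pid].required_slots


@dataclass(frozen=True)
class Violation:
    """One broken schedule invariant; ``family`` names the constraint family
    (partition / fit / overlap / contiguity / daily_bound / quota)."""

    family: str
    day: int | None
    patients: tuple[str, ...]
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"[{self.family}] {self.message}"


def expected_revenue(schedule: Schedule, params: ClinicParams) -> float:
    """Expected weekly revenue of a schedule.

    Sums, over assigned patients, the show probability at the appointment's
    *start* cell times the visit revenue; deferred patients contribute zero.
    Patients are summed in sorted-id order so that mathematically equal
    schedules always produce bit-identical totals.
    """
    by_id = schedule.patient_map()
    total = 0.0
    for pid in sorted(schedule.assignments):
        day, start = schedule.assignments[pid]
        patient = by_id[pid]
        if patient.show_prob is None:
            raise MissingProbabilityError(
                f"patient {pid}: no show-probability surface for cell "
                f"(day {day}, slot {start})"
            )
        surface = np.asarray(patient.show_prob)
        if not (0 <= day < surface.shape[0] and 0 <= start < surface.shape[1]):
            raise MissingProbabilityError(
                f"patient {pid}: probability undefined at cell "
                f"(day {day}, slot {start}); surface shape {surface.shape}"
            )
        total += float(surface[day, start]) * patient.revenue_for(params)
    return total


def validate_schedule(
    schedule: Schedule,
    params: ClinicParams,
    quotas: tuple[int, int] | None = None,
) -> list[Violation]:
    """Check every structural schedule invariant; returns violations as data.

    Checks: the buffer is partitioned between assignments and deferrals, each
    appointment fits inside its day, no grid cell is covered twice, each day's
    occupied cells form a contiguous prefix, daily occupancy respects the
    upper bound, and (when ``quotas=(b4, b5)`` is given) the first-visit and
    high-priority slot quotas are met.
    """
    violations: list[Violation] = []
    by_id = schedule.patient_map()

    assigned_ids = set(schedule.assignments)
    for pid in sorted(assigned_ids & schedule.deferred):
        violations.append(
            Violation("partition", None, (pid,), f"patient {pid} both assigned and deferred")
        )
    for pid in sorted(set(by_id) - assigned_ids - schedule.deferred):
        violations.append(
            Violation("partition", None, (pid,), f"patient {pid} neither assigned nor deferred")
        )
    for pid in sorted((assigned_ids | schedule.deferred) - set(by_id)):
        violations.append(
            Violation("partition", None, (pid,), f"patient {pid} not in the buffer")
        )

    days = params.days_per_week
    cover: dict[tuple[int, int], list[str]] = {}
    for pid in sorted(assigned_ids & set(by_id)):
        day, start = schedule.assignments[pid]
        length = schedule.booked_slots(pid)
        if not (0 <= day < days) or start < 0 or start + length > params.slots_per_day:
            violations.append(
                Violation(
                    "fit",
                    day,
                    (pid,),
                    f"patient {pid} at (day {day}, slot {start}) x {length} slots "
                    f"does not fit in a {params.slots_per_day}-slot day",
                )
            )
            continue
        for cell in range(start, start + length):
            cover.setdefault((day, cell), []).append(pid)

    for (day, cell), pids in sorted(cover.items()):
        if len(pids) > 1:
            violations.append(
                Violation(
                    "overlap",
                    day,
                    tuple(pids),
                    f"slot (day {day}, cell {cell}) covered by {len(pids)} patients",
                )
            )

    for day in range(days):
        occupied = sorted(cell for (d, cell) in cover if d == day)
        if occupied and occupied != list(range(len(occupied))):
            violations.append(
                Violation(
                    "contiguity",
                    day,
                    tuple(sorted({p for (d, c), ps in cover.items() if d == day for p in ps})),
                    f"day {day}: occupied cells {occupied} are not a prefix of the day",
                )
            )
        if len(occupied) > params.day_upper_bound:
            violations.append(
                Violation(
                    "daily_bound",
                    day,
                    (),
                    f"day {day}: {len(occupied)} occupied slots exceed the "
                    f"bound {params.day_upper_bound}",
                )
            )

    if quotas is not None:
        b4, b5 = quotas
        first_slots = sum(
            schedule.booked_slots(pid)
            for pid in assigned_ids & set(by_id)
            if by_id[pid].is_first_visit
        )
        high_slots = sum(
            schedule.booked_slots(pid)
            for pid in assigned_ids & set(by_id)
            if by_id[pid].priority == 0
        )
        if first_slots < b4:
            violations.append(
                Violation(
                    "quota", None, (), f"first-visit slots {first_slots} < quota b4={b4}"
                )
            )
        if high_slots < b5:
            violations.append(
                Violation(
                    "quota", None, (), f"high-priority slots {high_slots} < quota b5={b5}"
                )
            )
    return violations
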