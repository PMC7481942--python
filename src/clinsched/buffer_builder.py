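"""Weekly buffer construction with dynamic priorities.

Each week the clinic does not schedule the whole waiting list but a candidate
subset (the *buffer*) built in three steps:

1. every patient tied at the maximum sojourn enters with high priority;
2. patients are added in decreasing sojourn order until the buffered
   follow-up workload reaches the follow-up slot floor ``ceil((1-q)|I||T|)``
   (or the list empties) — all of these are high priority except the single
   patient whose addition meets the floor, who is tagged low priority;
3. first visits are added in decreasing sojourn order, with low priority,
   until the buffered first-visit workload reaches ``ceil(q |I||T|)`` or no
   first visits remain.

Buffered patients leave the waiting list for the week; whoever the scheduler
defers re-enters with their sojourn preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ClinicParams, Patient

__all__ = ["WaitingList", "Buffer", "build_buffer"]


def _order_key(p: Patient) -> tuple[int, int]:
    # longest waiting first; FIFO within a sojourn class
    return (-p.sojourn, p.arrival_index)


@dataclass
class WaitingList:
    """The clinic's waiting list; kept sorted by (sojourn desc, arrival asc)."""

    patients: list[Patient] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient ids on the waiting list")
        self.patients.sort(key=_order_key)

    def __len__(self) -> int:
        return len(self.patients)

    def add(self, newcomers: list[Patient]) -> None:
        known = {p.id for p in self.patients}
        for p in newcomers:
            if p.id in known:
                raise ValueError(f"patient {p.id} already on the waiting list")
            known.add(p.id)
        self.patients.extend(newcomers)
        self.patients.sort(key=_order_key)

    def increment_sojourns(self) -> None:
        """End-of-week aging: every patient still waiting gains one week."""
        for p in self.patients:
            p.sojourn += 1


@dataclass
class Buffer:
    """Ordered weekly candidate list; every patient carries a priority tag
    (0 high / 1 low) and a provenance tag naming the build step (2a/2b/2c)."""

    patients: list[Patient] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def build_buffer(
    waiting_list: WaitingList,
    params: ClinicParams,
    threshold_scope: str = "followup",
) -> Buffer:
    """Build the weekly buffer and remove its members from the waiting list.

    ``threshold_scope`` controls which workload step 2 counts against the
    follow-up floor: ``"followup"`` (default; the floor is phrased as slots
    dedicated to follow-up patients) or ``"total"`` (count every addition).
    """
    if threshold_scope not in ("followup", "total"):
        raise ValueError(f"unknown threshold_scope {threshold_scope!r}")
    ordered = sorted(waiting_list.patients, key=_order_key)
    if not ordered:
        return Buffer([])

    chosen: list[Patient] = []

    # step 2a: everyone tied at the maximum sojourn, high priority
    max_sojourn = ordered[0].sojourn
    idx = 0
    while idx < len(ordered) and ordered[idx].sojourn == max_sojourn:
        p = ordered[idx]
        p.priority = 0
        p.provenance = "2a"
        chosen.append(p)
        idx += 1

    def followup_workload() -> int:
        if threshold_scope == "total":
            return sum(p.required_slots for p in chosen)
        return sum(p.required_slots for p in chosen if not p.is_first_visit)

    # step 2b: fill the follow-up slot floor in decreasing sojourn order
    floor_fu = params.followup_slot_floor
    added_2b: list[Patient] = []
    while followup_workload() < floor_fu and idx < len(ordered):
        p = ordered[idx]
        p.priority = 0
        p.provenance = "2b"
        chosen.append(p)
        added_2b.append(p)
        idx += 1
    if added_2b and followup_workload() >= floor_fu:
        added_2b[-1].priority = 1  # the addition that met the floor

    # step 2c: top up first visits to the first-visit slot floor, low priority
    floor_fv = params.first_visit_slot_floor
    first_workload = sum(p.required_slots for p in chosen if p.is_first_visit)
    remaining = ordered[idx:]
    pos = 0
    while first_workload < floor_fv and pos < len(remaining):
        p = remaining[pos]
        pos += 1
        if not p.is_first_visit:
            continue
        p.priority = 1
        p.provenance = "2c"
        chosen.append(p)
        first_workload += p.required_slots

    chosen_ids = {p.id for p in chosen}
    waiting_list.patients = [p for p in waiting_list.patients if p.id not in chosen_ids]
    return Buffer(chosen)
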