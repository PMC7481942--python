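"""The variable-slot assignment program and its exhaustive oracle."""

import numpy as np
import pytest

from clinsched import (
    ClinicParams,
    Patient,
    brute_force_schedule,
    build_milp,
    compute_quotas,
    expected_revenue,
    make_instance,
    solve_schedule,
    validate_schedule,
)
from clinsched.milp_scheduler import InfeasibleScheduleError

from conftest import random_instance


class TestQuotas:
    def test_quota_capped_by_weekly_share(self, table_params, make_patient):
        # 125 first visits of 4 slots: workload 500 > ceil(0.3*360) = 108
        buffer = [
            make_patient(f"f{j}", first=True, slots=4, priority=0) for j in range(125)
        ]
        b4, _ = compute_quotas(buffer, table_params)
        assert b4 == 108

    def test_quota_capped_by_workload(self, table_params, make_patient):
        buffer = [
            make_patient(f"f{j}", first=True, slots=4, priority=0) for j in range(5)
        ]
        b4, _ = compute_quotas(buffer, table_params)
        assert b4 == 20

    def test_empty_buffer(self, table_params):
        assert compute_quotas([], table_params) == (0, 0)

    def test_requires_priorities(self, table_params, make_patient):
        p = make_patient("x", priority=None)
        with pytest.raises(ValueError, match="priority"):
            compute_quotas([p], table_params)

    def test_high_priority_quota_capped_by_remaining_grid(self, table_params, make_patient):
        # every slot is high priority: b5 is capped at |I||T| - b4
        buffer = [
            make_patient(f"g{j}", first=(j < 60), slots=6, priority=0)
            for j in range(120)
        ]
        b4, b5 = compute_quotas(buffer, table_params)
        assert b4 == 108
        assert b5 == table_params.slots_per_week - b4


class TestModelStructure:
    def test_start_domain_respects_in_day_fit(self, relaxed_one_day, make_patient):
        params = relaxed_one_day(T=8)
        p = make_patient("a", slots=4)
        inst = make_instance([p], params, quotas=(0, 0), day_lower=0)
        assert list(inst.start_domain(p)) == [0, 1, 2, 3, 4]

    def test_variable_count_matches_independent_enumeration(self, make_patient):
        """Model size cross-checked against a direct count: per patient one
        binary per (day, valid start) plus a deferral; plus one occupancy
        binary per grid cell (no day-activation binaries when the lower
        bound is relaxed)."""
        params = ClinicParams(
            days_per_week=3, slots_per_day=12, day_min_slack=12,
            appt_slots_min=2, appt_slots_max=6,
        )
        rng = np.random.default_rng(0)
        buffer = [
            make_patient(
                f"v{j}", slots=int(rng.integers(4, 7)), days=3, slots_per_day=12
            )
            for j in range(7)
        ]
        inst = make_instance(buffer, params, quotas=(0, 0), day_lower=0)
        model, varmap = build_milp(inst)
        expected_x = sum(
            params.days_per_week * (params.slots_per_day - p.required_slots + 1)
            for p in buffer
        )
        assert len(varmap["x"]) == expected_x
        assert model.n_vars == expected_x + len(buffer) + params.slots_per_week

    def test_lp_and_mps_roundtrip_counts(self, relaxed_one_day, make_patient):
        """Re-parse both text exports with independent mini-parsers and
        compare variable/constraint counts with the model's own."""
        params = relaxed_one_day(T=6)
        buffer = [make_patient("a", slots=2, slots_per_day=6),
                  make_patient("b", slots=3, slots_per_day=6)]
        inst = make_instance(buffer, params, quotas=(0, 0), day_lower=0)
        model, _ = build_milp(inst)

        lp = model.to_lp()
        in_constraints = False
        lp_rows = 0
        lp_binaries = 0
        for line in lp.splitlines():
            if line.startswith("Subject To"):
                in_constraints = True
                continue
            if line.startswith("Binary"):
                in_constraints = False
                section = "bin"
                continue
            if line.startswith("End"):
                break
            if in_constraints and ":" in line:
                lp_rows += 1
            elif line.startswith(" ") and ":" not in line and not line.startswith(" obj"):
                lp_binaries += 1
        assert lp_rows == model.export_row_count()
        assert lp_binaries == model.n_vars

        mps = model.to_mps()
        lines = mps.splitlines()
        rows_section = lines[lines.index("ROWS") + 1 : lines.index("COLUMNS")]
        mps_rows = sum(1 for ln in rows_section if ln.split()[0] in "ELG")
        cols = set()
        for ln in lines[lines.index("COLUMNS") + 1 : lines.index("RHS")]:
            parts = ln.split()
            if parts and parts[0] != "MARKER":
                cols.add(parts[0])
        assert mps_rows == model.export_row_count()
        assert cols == set(model.var_names)

    def test_structurally_impossible_quota_diagnosed_before_solve(
        self, relaxed_one_day, make_patient
    ):
        params = relaxed_one_day(T=6)
        p = make_patient("a", first=True, slots=4, slots_per_day=6)
        inst = make_instance([p], params, quotas=(40, 0), day_lower=0)
        with pytest.raises(InfeasibleScheduleError, match="b4"):
            build_milp(inst)


class TestSolve:
    def test_single_profitable_patient_is_scheduled(self, relaxed_one_day, make_patient):
        params = relaxed_one_day(T=8)
        p = make_patient("solo", first=False, prob=0.6, slots=4)
        inst = make_instance([p], params, quotas=(0, 0), day_lower=0)
        s = solve_schedule(inst)
        assert s.assignments == {"solo": (0, 0)}
        assert s.objective_value == pytest.approx(30.0, abs=1e-9)

    def test_three_way_selection_matches_enumeration(self, relaxed_one_day, make_patient):
        """Two of three 4-slot patients fit one 8-slot day; the optimal pair
        (by expected revenue) is chosen and matches the brute-force optimum
        exactly."""
        params = relaxed_one_day(T=8)
        a = make_patient("A", first=True, slots=4, prob=0.9)
        b = make_patient("B", first=False, slots=4, prob=0.8)
        c = make_patient("C", first=False, slots=4, prob=0.95)
        inst = make_instance([a, b, c], params, quotas=(0, 0), day_lower=0)
        s = solve_schedule(inst)
        assert set(s.assignments) == {"A", "C"}
        assert s.deferred == {"B"}
        assert s.objective_value == pytest.approx(0.9 * 70 + 0.95 * 50, abs=1e-9)
        assert s.objective_value == brute_force_schedule(inst).objective_value

    def test_zero_probability_degenerates_to_deferral(self, relaxed_one_day, make_patient):
        params = relaxed_one_day(T=8)
        pts = [make_patient(f"z{j}", prob=0.0, slots=2) for j in range(3)]
        inst = make_instance(pts, params, quotas=(0, 0), day_lower=0)
        s = solve_schedule(inst, tie_break=True)
        assert s.assignments == {}
        assert s.deferred == {"z0", "z1", "z2"}
        assert s.objective_value == 0.0

    def test_oversized_pair_schedules_higher_revenue_patient(
        self, relaxed_one_day, make_patient
    ):
        params = relaxed_one_day(T=6)
        a = make_patient("a", first=False, slots=4, prob=0.5, slots_per_day=6)
        b = make_patient("b", first=False, slots=4, prob=0.9, slots_per_day=6)
        inst = make_instance([a, b], params, quotas=(0, 0), day_lower=0)
        s = solve_schedule(inst)
        assert set(s.assignments) == {"b"}
        assert s.objective_value == brute_force_schedule(inst).objective_value

    def test_empty_buffer_brute_force(self, relaxed_one_day):
        params = relaxed_one_day(T=6)
        inst = make_instance([], params, quotas=(0, 0), day_lower=0)
        s = brute_force_schedule(inst)
        assert s.assignments == {} and s.objective_value == 0.0

    def test_brute_force_refuses_large_instances(self, table_params, make_patient):
        buffer = [
            make_patient(f"r{j}", days=5, slots_per_day=72, priority=0)
            for j in range(9)
        ]
        inst = make_instance(buffer, table_params)
        with pytest.raises(ValueError, match="enumeration"):
            brute_force_schedule(inst)

    @pytest.mark.parametrize("seed", range(15))
    def test_solver_matches_oracle(self, seed, relaxed_one_day):
        inst = random_instance(seed + 1000, relaxed_one_day)
        s = solve_schedule(inst)
        b = brute_force_schedule(inst)
        assert s.objective_value == b.objective_value
        assert validate_schedule(s, inst.params) == []

    def test_appending_a_patient_never_hurts(self, relaxed_one_day, make_patient):
        rng = np.random.default_rng(7)
        params = relaxed_one_day(T=10)
        for trial in range(8):
            pts = [
                make_patient(
                    f"m{j}", slots=int(rng.integers(2, 5)),
                    prob=float(rng.random()), slots_per_day=10,
                )
                for j in range(int(rng.integers(1, 4)))
            ]
            base = solve_schedule(
                make_instance(pts, params, quotas=(0, 0), day_lower=0)
            )
            extra = make_patient(
                "extra", slots=int(rng.integers(2, 5)),
                prob=float(rng.random()), slots_per_day=10,
            )
            grown = solve_schedule(
                make_instance(pts + [extra], params, quotas=(0, 0), day_lower=0)
            )
            assert grown.objective_value >= base.objective_value - 1e-12

    def test_quota_and_contiguity_hold_on_solved_schedules(self, make_patient):
        """Quota-constrained instances: the solved schedule meets b4/b5 and
        every structural invariant."""
        params = ClinicParams(
            days_per_week=2, slots_per_day=10, day_min_slack=10,
            first_visit_quota=0.3, appt_slots_min=2, appt_slots_max=4,
        )
        rng = np.random.default_rng(11)
        for trial in range(5):
            pts = []
            for j in range(6):
                p = Patient(
                    id=f"s{j}",
                    is_first_visit=bool(j % 2),
                    required_slots=int(rng.integers(2, 5)),
                    priority=int(j >= 3),
                    arrival_index=j,
                )
                p.show_prob = rng.random((2, 10))
                pts.append(p)
            inst = make_instance(pts, params, day_lower=0)
            s = solve_schedule(inst)
            assert validate_schedule(s, params, quotas=(inst.b4, inst.b5)) == []

    def test_day_activation_fills_days_in_order(self, make_patient):
        """With a binding daily lower bound, a small buffer concentrates on
        the earliest days instead of going infeasible."""
        params = ClinicParams(
            days_per_week=3, slots_per_day=8, day_min_slack=2,
            appt_slots_min=2, appt_slots_max=4, first_visit_quota=0.0,
        )
        pts = [
            make_patient(f"d{j}", slots=3, prob=0.9, days=3, slots_per_day=8)
            for j in range(4)
        ]
        inst = make_instance(pts, params, quotas=(0, 0))
        s = solve_schedule(inst)
        used_days = {day for day, _ in s.assignments.values()}
        assert validate_schedule(s, params) == []
        # 12 slots of demand fit two days of >= 6 occupied slots each
        assert s.relaxations == ()
        assert used_days <= {0, 1}

    def test_objective_recomputation_matches_solver(self, relaxed_one_day):
        inst = random_instance(4321, relaxed_one_day)
        s = solve_schedule(inst)
        assert s.objective_value == pytest.approx(
            expected_revenue(s, inst.params), rel=1e-9
        )
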