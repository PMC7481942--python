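"""A minimal solver-agnostic container for binary linear programs.

Stores variables, ranged linear constraints and a max-sense objective; solves
through :func:`scipy.optimize.milp` (HiGHS) and exports to the standard LP and
MPS text formats.  Double-bounded rows are split into ``_lo`` / ``_up`` pairs
on export so both writers stay within the simplest dialect of each format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["LinearModel", "SolveResult", "SolverError"]

INF = math.inf


class SolverError(RuntimeError):
    pass


@dataclass
class SolveResult:
    status: int  # scipy milp status: 0 optimal, 1 limit w/ incumbent, 2 infeasible
    x: np.ndarray | None
    objective: float | None
    mip_gap: float | None

    @property
    def optimal(self) -> bool:
        return self.status == 0

    @property
    def feasible(self) -> bool:
        return self.x is not None


@dataclass
class LinearModel:
    """Binary linear program with a maximization objective."""

    name: str = "model"
    var_names: list[str] = field(default_factory=list)
    obj: list[float] = field(default_factory=list)
    # constraints as parallel arrays of sparse rows
    row_names: list[str] = field(default_factory=list)
    row_cols: list[list[int]] = field(default_factory=list)
    row_vals: list[list[float]] = field(default_factory=list)
    row_lb: list[float] = field(default_factory=list)
    row_ub: list[float] = field(default_factory=list)

    # --- building -----------------------------------------------------------

    def add_var(self, name: str, obj: float = 0.0) -> int:
        self.var_names.append(name)
        self.obj.append(float(obj))
        return len(self.var_names) - 1

    def add_constr(
        self,
        name: str,
        cols: list[int],
        vals: list[float],
        lb: float = -INF,
        ub: float = INF,
    ) -> int:
        if len(cols) != len(vals):
            raise ValueError("cols and vals length mismatch")
        self.row_names.append(name)
        self.row_cols.append(list(cols))
        self.row_vals.append([float(v) for v in vals])
        self.row_lb.append(float(lb))
        self.row_ub.append(float(ub))
        return len(self.row_names) - 1

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    @property
    def n_rows(self) -> int:
        return len(self.row_names)

    def matrix(self) -> sp.csc_array:
        data: list[float] = []
        rows: list[int] = []
        cols: list[int] = []
        for r, (cc, vv) in enumerate(zip(self.row_cols, self.row_vals)):
            rows.extend([r] * len(cc))
            cols.extend(cc)
            data.extend(vv)
        return sp.csc_array(
            (data, (rows, cols)), shape=(self.n_rows, self.n_vars)
        )

    # --- solving ------------------------------------------------------------

    def solve(
        self,
        gap: float = 1e-9,
        time_limit: float | None = None,
        node_limit: int | None = None,
        presolve: bool = False,
    ) -> SolveResult:
        """Maximize over binary variables with HiGHS.

        ``time_limit`` makes termination wall-clock dependent and therefore
        non-deterministic; leave it unset when reproducibility matters.
        Presolve is off by default: on these packing models HiGHS's root
        heuristics run several times faster on the unpresolved matrix.
        """
        options: dict = {"mip_rel_gap": float(gap), "disp": False, "presolve": presolve}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        if node_limit is not None:
            options["node_limit"] = int(node_limit)
        c = -np.asarray(self.obj, dtype=float)  # scipy minimizes
        res = milp(
            c=c,
            constraints=LinearConstraint(
                self.matrix(),
                np.asarray(self.row_lb, dtype=float),
                np.asarray(self.row_ub, dtype=float),
            ),
            integrality=np.ones(self.n_vars),
            bounds=Bounds(0.0, 1.0),
            options=options,
        )
        if res.status in (0, 1) and res.x is not None:
            return SolveResult(
                status=int(res.status),
                x=np.asarray(res.x),
                objective=-float(res.fun),
                mip_gap=float(res.mip_gap) if res.mip_gap is not None else None,
            )
        return SolveResult(status=int(res.status), x=None, objective=None, mip_gap=None)

    # --- export -------------------------------------------------------------

    def _split_rows(self):
        """Yield (name, cols, vals, sense, rhs) with ranged rows split."""
        for name, cols, vals, lb, ub in zip(
            self.row_names, self.row_cols, self.row_vals, self.row_lb, self.row_ub
        ):
            if lb == ub:
                yield name, cols, vals, "E", lb
            elif lb == -INF and ub < INF:
                yield name, cols, vals, "L", ub
            elif ub == INF and lb > -INF:
                yield name, cols, vals, "G", lb
            elif lb == -INF and ub == INF:
                continue  # free row; never produced by the schedulers
            else:
                yield f"{name}_lo", cols, vals, "G", lb
                yield f"{name}_up", cols, vals, "L", ub

    def export_row_count(self) -> int:
        """Number of constraint rows the text writers emit (ranged rows split)."""
        return sum(1 for _ in self._split_rows())

    def to_lp(self) -> str:
        """CPLEX-style LP text."""
        out = [f"\\ {self.name}", "Maximize", " obj:"]
        terms = []
        for j, coef in enumerate(self.obj):
            if coef != 0.0:
                terms.append(f" {'+' if coef >= 0 else '-'} {abs(coef):.12g} {self.var_names[j]}")
        out[-1] += "".join(terms) if terms else " 0 " + self.var_names[0]
        out.append("Subject To")
        sense_txt = {"E": "=", "L": "<=", "G": ">="}
        for name, cols, vals, sense, rhs in self._split_rows():
            expr = "".join(
                f" {'+' if v >= 0 else '-'} {abs(v):.12g} {self.var_names[j]}"
                for j, v in zip(cols, vals)
            )
            out.append(f" {name}:{expr} {sense_txt[sense]} {rhs:.12g}")
        out.append("Binary")
        for name in self.var_names:
            out.append(f" {name}")
        out.append("End")
        return "\n".join(out) + "\n"

    def to_mps(self) -> str:
        """Fixed-ish MPS text (free-format field spacing)."""
        lines = [f"NAME          {self.name}", "ROWS", " N  COST"]
        split = list(self._split_rows())
        for name, _, _, sense, _ in split:
            lines.append(f" {sense}  {name}")
        # column-major entries
        col_entries: dict[int, list[tuple[str, float]]] = {}
        for j, coef in enumerate(self.obj):
            if coef != 0.0:
                # MPS has no sense line; encode max as negated-min objective
                col_entries.setdefault(j, []).append(("COST", -coef))
        for name, cols, vals, _, _ in split:
            for j, v in zip(cols, vals):
                col_entries.setdefault(j, []).append((name, v))
        lines.append("COLUMNS")
        lines.append("    MARKER                 'MARKER'                 'INTORG'")
        for j in range(self.n_vars):
            for row, v in col_entries.get(j, []):
                lines.append(f"    {self.var_names[j]:<12}{row:<12}{v:.12g}")
        lines.append("    MARKER                 'MARKER'                 'INTEND'")
        lines.append("RHS")
        for name, _, _, sense, rhs in split:
            if rhs != 0.0:
                lines.append(f"    RHS         {name:<12}{rhs:.12g}")
        lines.append("BOUNDS")
        for name in self.var_names:
            lines.append(f" BV BND         {name}")
        lines.append("ENDATA")
        return "\n".join(lines) + "\n"
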