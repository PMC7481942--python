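import numpy as np
import pytest

from clinsched import ClinicParams, Patient


@pytest.fixture(scope="session")
def table_params() -> ClinicParams:
    """The clinic's published operating parameters (all defaults)."""
    return ClinicParams()


@pytest.fixture(scope="session")
def half_params(table_params) -> ClinicParams:
    return table_params.half_scale()


@pytest.fixture
def make_patient():
    """Factory for patients with a constant or given probability surface."""

    def _make(
        pid: str,
        first: bool = False,
        slots: int = 4,
        prob=0.9,
        days: int = 1,
        slots_per_day: int = 8,
        sojourn: int = 1,
        priority: int | None = 0,
        arrival_index: int | None = None,
    ) -> Patient:
        p = Patient(
            id=pid,
            is_first_visit=first,
            required_slots=slots,
            sojourn=sojourn,
            priority=priority,
            arrival_index=arrival_index if arrival_index is not None else ord(pid[-1]),
        )
        surface = np.asarray(prob, dtype=float)
        if surface.ndim == 0:
            surface = np.full((days, slots_per_day), float(surface))
        p.show_prob = surface
        return p

    return _make


@pytest.fixture
def relaxed_one_day():
    """One-day clinic with no daily lower bound or quota pressure."""

    def _make(T: int = 8, **kw) -> ClinicParams:
        kw.setdefault("appt_slots_min", 2)
        kw.setdefault("appt_slots_max", min(6, T))
        return ClinicParams(
            days_per_week=1,
            slots_per_day=T,
            first_visit_quota=0.0,
            day_min_slack=T,
            arrivals_min=1,
            arrivals_max=1,
            **kw,
        )

    return _make


def random_instance(seed: int, params_factory, n_max: int = 5):
    """A random tiny scheduling instance for oracle comparisons."""
    import clinsched as cs

    rng = np.random.default_rng(seed)
    T = int(rng.integers(6, 11))
    n = int(rng.integers(1, n_max + 1))
    params = params_factory(T=T)
    patients = []
    for j in range(n):
        p = Patient(
            id=f"q{j}",
            is_first_visit=bool(rng.random() < 0.4),
            required_slots=int(rng.integers(2, 5)),
            priority=int(rng.random() < 0.5),
            arrival_index=j,
        )
        p.show_prob = rng.random((1, T))
        patients.append(p)
    return cs.make_instance(patients, params, quotas=(0, 0), day_lower=0)
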