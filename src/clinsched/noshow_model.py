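"""Heterogeneous show-probability generation and no-show model fitting.

The real probabilities behind the case study came from an L1-penalized
logistic regression on a licensed hospital EHR (76,658 appointments, 97
predictors, 14.05% mean no-show) and are not available.  This module
generates probabilities with the same *structure* — a logistic model over
patient, day of week, time of day, calendar month and lead time —

    logit P(show) = b0 + u_k + day[i] + slope_t * t + slope_lead * sojourn
                    + month[m]

with a Normal random intercept ``u_k`` per patient, calibrated so the
population mean no-show matches the published 14.05%.  Effect sizes are
synthetic defaults (the source model's coefficients were never published);
they are chosen so per-patient mean show probabilities span roughly
[0.6, 0.99], enough heterogeneity for probabilistic scheduling to matter.

``fit_noshow_model`` fits the same kind of cross-validated Lasso logistic
model to tabular appointment records, for users who do have data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .core import ClinicParams, Patient

__all__ = [
    "NoShowGenParams",
    "show_probability",
    "probability_surface",
    "probability_surfaces",
    "month_of_week",
    "calibrate_intercept",
    "calibrated",
    "generate_population",
    "NoShowFit",
    "fit_noshow_model",
]

_DEF_MONTH = tuple(0.2 * math.sin(2.0 * math.pi * m / 12.0) for m in range(12))


@dataclass(frozen=True)
class NoShowGenParams:
    """Log-odds structure of the show-probability generator.

    ``intercept=None`` means "not yet calibrated"; :func:`calibrated` fixes
    it so the population mean no-show hits ``target_mean_noshow``.  Units:
    everything is on the log-odds scale; ``time_of_day_slope`` is per
    five-minute slot, ``leadtime_slope`` per week of sojourn.
    """

    intercept: float | None = None
    patient_effect_sd: float = 0.8
    day_effects: tuple[float, ...] = (0.15, 0.05, 0.0, -0.05, -0.15)
    time_of_day_slope: float = -0.004
    leadtime_slope: float = -0.03
    month_effects: tuple[float, ...] = _DEF_MONTH
    target_mean_noshow: float = 0.1405

    def __post_init__(self) -> None:
        if not 0.0 < self.target_mean_noshow < 1.0:
            raise ValueError("target_mean_noshow must lie in (0, 1)")
        if self.patient_effect_sd < 0.0:
            raise ValueError("patient_effect_sd must be >= 0")
        if len(self.month_effects) != 12:
            raise ValueError("month_effects must have 12 entries")


def month_of_week(week: int) -> int:
    """Map a 1-based simulation week to a 1-based month of 4 weeks
    (week 1-4 -> month 1, ..., week 45-48 -> month 12, then wrapping)."""
    if week < 1:
        raise ValueError(f"week must be >= 1, got {week}")
    return (math.ceil(week / 4) - 1) % 12 + 1


def show_probability(
    patient_effect: float,
    day: int,
    slot: int,
    sojourn: int,
    month: int,
    params: NoShowGenParams,
) -> float:
    """Show probability at one (day, slot) cell; ``day``/``slot`` 0-based,
    ``month`` 1-based."""
    if params.intercept is None:
        raise ValueError("generator not calibrated: intercept is None")
    if not 0 <= day < len(params.day_effects):
        raise IndexError(f"day {day} outside 0..{len(params.day_effects) - 1}")
    if not 1 <= month <= 12:
        raise IndexError(f"month {month} outside 1..12")
    if slot < 0:
        raise IndexError(f"negative slot {slot}")
    eta = (
        params.intercept
        + patient_effect
        + params.day_effects[day]
        + params.time_of_day_slope * slot
        + params.leadtime_slope * sojourn
        + params.month_effects[month - 1]
    )
    return float(expit(eta))


def _surface_eta(
    effects: np.ndarray, sojourns: np.ndarray, month: int,
    gen: NoShowGenParams, clinic: ClinicParams,
) -> np.ndarray:
    if gen.intercept is None:
        raise ValueError("generator not calibrated: intercept is None")
    if len(gen.day_effects) < clinic.days_per_week:
        raise ValueError(
            f"day_effects has {len(gen.day_effects)} entries for a "
            f"{clinic.days_per_week}-day week"
        )
    days = np.asarray(gen.day_effects[: clinic.days_per_week])
    slots = gen.time_of_day_slope * np.arange(clinic.slots_per_day)
    base = (
        gen.intercept
        + effects
        + gen.leadtime_slope * sojourns
        + gen.month_effects[month - 1]
    )
    return base[:, None, None] + days[None, :, None] + slots[None, None, :]


def probability_surface(
    patient: Patient, week: int, gen: NoShowGenParams, clinic: ClinicParams
) -> np.ndarray:
    """(days x slots) show-probability surface for one patient this week."""
    return probability_surfaces([patient], week, gen, clinic)[0]


def probability_surfaces(
    patients: Sequence[Patient], week: int, gen: NoShowGenParams,
    clinic: ClinicParams,
) -> np.ndarray:
    """Stacked (n x days x slots) surfaces; vectorized over the buffer."""
    effects = np.array([p.patient_effect for p in patients], dtype=float)
    sojourns = np.array([p.sojourn for p in patients], dtype=float)
    return expit(_surface_eta(effects, sojourns, month_of_week(week), gen, clinic))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibrate_intercept(
    gen: NoShowGenParams,
    clinic: ClinicParams | None = None,
    n: int = 5000,
    rng_seed: int = 0,
    sojourns: Iterable[int] = range(0, 9),
    months: Iterable[int] = range(1, 13),
) -> float:
    """Root-find the intercept so the Monte-Carlo population mean no-show
    matches ``gen.target_mean_noshow``.

    The population is ``n`` patient effects ~ Normal(0, sd) with sojourns
    drawn uniformly from ``sojourns``; appointments are averaged over the
    full (day, slot) grid and the given months.  Deterministic given
    ``rng_seed``.
    """
    clinic = clinic or ClinicParams()
    target_show = 1.0 - gen.target_mean_noshow
    effects_zero = (
        gen.patient_effect_sd == 0.0
        and not any(gen.day_effects[: clinic.days_per_week])
        and gen.time_of_day_slope == 0.0
        and gen.leadtime_slope == 0.0
        and not any(gen.month_effects)
    )
    if effects_zero:
        return float(logit(target_show))

    rng = np.random.default_rng(rng_seed)
    effects = rng.normal(0.0, gen.patient_effect_sd, size=n)
    soj_choices = np.asarray(list(sojourns), dtype=float)
    soj = rng.choice(soj_choices, size=n)
    month_list = list(months)
    days = np.asarray(gen.day_effects[: clinic.days_per_week])
    slots = gen.time_of_day_slope * np.arange(clinic.slots_per_day)
    cell = (days[:, None] + slots[None, :]).ravel()  # (days*slots,)
    month_eff = np.asarray([gen.month_effects[m - 1] for m in month_list])
    base = effects + gen.leadtime_slope * soj  # (n,)

    def mean_show(b0: float) -> float:
        # mean over patients x months x grid cells
        eta = (
            b0
            + base[:, None, None]
            + month_eff[None, :, None]
            + cell[None, None, :]
        )
        return float(expit(eta).mean())

    lo, hi = -15.0, 15.0
    f = lambda b0: mean_show(b0) - target_show
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("calibration target not bracketed by intercept in [-15, 15]")
    return float(brentq(f, lo, hi, xtol=1e-10))


def calibrated(
    gen: NoShowGenParams,
    clinic: ClinicParams | None = None,
    n: int = 5000,
    rng_seed: int = 0,
) -> NoShowGenParams:
    """Copy of ``gen`` with the intercept calibrated (no-op if already set)."""
    if gen.intercept is not None:
        return gen
    return replace(
        gen, intercept=calibrate_intercept(gen, clinic, n=n, rng_seed=rng_seed)
    )


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------


def generate_population(
    n: int,
    gen: NoShowGenParams,
    clinic: ClinicParams,
    rng: np.random.Generator | int,
    start_index: int = 0,
    sojourn: int = 1,
) -> list[Patient]:
    """Draw ``n`` patients: required slots uniform on the configured range,
    first-visit flags Bernoulli, patient effects Normal(0, sd).  Probability
    surfaces are materialized later, per week, because they depend on sojourn
    and month."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if n < 0:
        raise ValueError("n must be >= 0")
    lengths = rng.integers(clinic.appt_slots_min, clinic.appt_slots_max + 1, size=n)
    first = rng.random(n) < clinic.first_visit_arrival_fraction
    effects = rng.normal(0.0, gen.patient_effect_sd, size=n)
    return [
        Patient(
            id=f"p{start_index + j:06d}",
            is_first_visit=bool(first[j]),
            required_slots=int(lengths[j]),
            sojourn=sojourn,
            arrival_index=start_index + j,
            patient_effect=float(effects[j]),
        )
        for j in range(n)
    ]


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class NoShowFit:
    """Cross-validated L1 logistic fit: coefficients on standardized
    covariates, the selected inverse-penalty C, and the excluded (zeroed)
    covariates."""

    covariates: list[str]
    intercept: float
    coefficients: pd.Series
    selected_C: float
    excluded: list[str]
    _scaler_mean: np.ndarray
    _scaler_scale: np.ndarray

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        X = (records[self.covariates].to_numpy(float) - self._scaler_mean) / (
            self._scaler_scale
        )
        return expit(self.intercept + X @ self.coefficients.to_numpy())


def fit_noshow_model(
    records: pd.DataFrame,
    penalty_grid: Sequence[float] | None = None,
    covariates: Sequence[str] | None = None,
    outcome: str = "show",
    cv: int = 5,
    fold_seed: int = 0,
    max_iter: int = 5000,
) -> NoShowFit:
    """Fit an L1-penalized logistic model of attendance to appointment
    records, selecting the penalty by cross-validated deviance.

    ``records`` needs a binary ``outcome`` column (1 = attended) and numeric
    covariate columns; ``penalty_grid`` is a grid of inverse penalties C
    (larger C = weaker penalty).  Covariates are standardized before
    penalization, the intercept is unpenalized, and folds are seeded for
    reproducibility.
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    if outcome not in records.columns:
        raise ValueError(f"records lack an outcome column {outcome!r}")
    y = records[outcome].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: only one class present")
    if covariates is None:
        covariates = [
            c
            for c in records.columns
            if c != outcome and pd.api.types.is_numeric_dtype(records[c])
        ]
    covariates = list(covariates)
    X = records[covariates].to_numpy(float)
    mean, scale = X.mean(axis=0), X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Xs = (X - mean) / scale
    Cs = list(penalty_grid) if penalty_grid is not None else list(np.logspace(-3, 2, 10))
    model = LogisticRegressionCV(
        Cs=Cs,
        penalty="elasticnet",
        l1_ratios=[1.0],  # pure lasso
        solver="saga",
        scoring="neg_log_loss",
        cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=fold_seed),
        max_iter=max_iter,
        tol=1e-5,
        random_state=fold_seed,
    )
    model.fit(Xs, y)
    coefs = pd.Series(model.coef_[0], index=covariates)
    excluded = [name for name, c in coefs.items() if c == 0.0]
    intercept = float(model.intercept_[0])
    if (coefs == 0.0).all():
        # saga's stopping rule under-optimizes the (unpenalized) intercept
        # once the penalty freezes every coefficient; the intercept-only MLE
        # is available in closed form
        from scipy.special import logit as _logit

        intercept = float(_logit(y.mean()))
    return NoShowFit(
        covariates=covariates,
        intercept=intercept,
        coefficients=coefs,
        selected_C=float(model.C_[0]),
        excluded=excluded,
        _scaler_mean=mean,
        _scaler_scale=scale,
    )
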