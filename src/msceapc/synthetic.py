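"""SEER-like synthetic incidence tables with known ground truth.

Emulates the shape of SEER*Stat tabulations: single-year age x calendar
year strata over a diagnosis window, smooth person-year schedules varying
by cohort, and Poisson case counts with mean ``h(t) x PYs`` under known
MSCE-APC parameters. The default preset mirrors the SEER9 analysis window
(diagnosis 1975-2016, ages 0-84, cohorts <= 1960, four population labels);
person-year magnitudes are order-of-magnitude stand-ins for a nine-registry
male or female race stratum, not population projections.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .incidence import IncidenceTable, PoissonLikelihood
from .params import BiologicalParams, TrendParams, get_preset

__all__ = [
    "make_py_schedule",
    "generate_incidence_table",
    "seer9_like_schedule",
    "DEFAULT_DIAGNOSIS_YEARS",
    "DEFAULT_AGES",
]

DEFAULT_DIAGNOSIS_YEARS = range(1975, 2017)
DEFAULT_AGES = range(0, 85)

#: Per-stratum person-years giving totals of order 1e7-1e8 over the full
#: window, the magnitude of a single SEER9 sex-by-race stratum.
DEFAULT_BASE_PY = 2e4


def _default_age_shape(age: np.ndarray) -> np.ndarray:
    """Smooth population-pyramid-like weight: flat through midlife, then
    declining beyond ~70 (smaller surviving population at old ages)."""
    return 0.05 + 1.0 / (1.0 + np.exp((age - 72.0) / 6.0))


def make_py_schedule(
    diagnosis_years: Iterable[int] = DEFAULT_DIAGNOSIS_YEARS,
    ages: Iterable[int] = DEFAULT_AGES,
    base_py: float = DEFAULT_BASE_PY,
    cohort_shape: Callable | None = None,
    age_shape: Callable | None = None,
) -> pd.DataFrame:
    """Person-years per (age, year) stratum: smooth, positive, cohort-scalable.

    ``py = base_py * age_shape(age) * cohort_shape(year - age)``; both shape
    callables default to constants (a mild age decline for ``age_shape``).
    """
    years = np.asarray(list(diagnosis_years), dtype=int)
    ages_ = np.asarray(list(ages), dtype=int)
    if years.size == 0 or ages_.size == 0:
        raise ValueError("diagnosis_years and ages must be non-empty")
    yy, aa = np.meshgrid(years, ages_, indexing="ij")
    yy = yy.ravel()
    aa = aa.ravel()
    shape_a = (age_shape or _default_age_shape)(aa.astype(float))
    shape_c = cohort_shape((yy - aa).astype(float)) if cohort_shape else 1.0
    py = base_py * np.asarray(shape_a, dtype=float) * np.asarray(shape_c, dtype=float)
    py = np.broadcast_to(py, aa.shape)
    if np.any(py <= 0):
        raise ValueError("person-year schedule must be positive")
    return pd.DataFrame({"age": aa, "year": yy, "py": py})


def seer9_like_schedule(base_py: float = DEFAULT_BASE_PY) -> pd.DataFrame:
    """The default SEER9-like person-year schedule (1975-2016, ages 0-84)."""
    return make_py_schedule(base_py=base_py)


def generate_incidence_table(
    bp: BiologicalParams,
    tp: TrendParams,
    py_schedule: pd.DataFrame | None = None,
    model: str = "fd",
    seed: int | None = None,
    max_cohort: int | None = 1960,
    population: str = "synthetic",
    step: float = 0.25,
    n_stem: float = 1e6,
) -> IncidenceTable:
    """Draw an incidence table with ``cases_i ~ Poisson(h_i x PY_i)``.

    The hazard is evaluated with the same grid evaluator the likelihood
    uses, so generated tables are exactly on-model for round-trip tests.
    Reproducible given ``seed``.
    """
    if py_schedule is None:
        py_schedule = seer9_like_schedule()
    df = py_schedule.copy()
    df["cases"] = 0
    skeleton = IncidenceTable.from_dataframe(
        df[["age", "year", "cases", "py"]],
        population=population, max_cohort=max_cohort,
    )
    lik = PoissonLikelihood(skeleton, model=model, step=step, n_stem=n_stem)
    lam = lik.expected(bp, tp)
    rng = np.random.default_rng(seed)
    out = skeleton.data.copy()
    out["cases"] = rng.poisson(lam)
    return IncidenceTable.from_dataframe(
        out[["age", "year", "cases", "py"]],
        population=population, max_cohort=max_cohort,
    )


def preset_table(
    population: str,
    base_py: float = DEFAULT_BASE_PY,
    seed: int | None = None,
    model: str = "fd",
) -> IncidenceTable:
    """Synthetic table at the published posterior medians for a population."""
    bp, tp = get_preset(population)
    return generate_incidence_table(
        bp, tp, seer9_like_schedule(base_py), model=model,
        seed=seed, population=population,
    )
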