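"""Incidence tables and the Poisson likelihood of the MSCE-APC model.

Registry-style incidence data come as strata of (age at diagnosis,
calendar year, case count, person-years), one table per population.
Case counts in a stratum are modeled as Poisson with mean
``lambda = h(t) x PYs`` where ``h`` is the clinical hazard evaluated at
the stratum midpoint (age + 0.5, for the row's birth cohort
``B = year - age``).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .hazard import cohort_hazard_grid
from .params import BiologicalParams, ParameterDomainError, TrendParams

logger = logging.getLogger(__name__)

__all__ = [
    "IncidenceTable",
    "FitResult",
    "PoissonLikelihood",
    "read_incidence_table",
    "predict_expected_counts",
    "poisson_loglik",
    "saturated_loglik",
    "deviance",
    "lr_test",
]

REQUIRED_COLUMNS = ("age", "year", "cases", "py")


@dataclass
class IncidenceTable:
    """Strata of (age, year, cases, person-years) with derived birth cohort.

    Rows with birth cohort ``year - age`` beyond ``max_cohort`` are
    excluded on construction (cohorts after 1960 carry too few cases in
    the emulated registry window); zero person-year rows are dropped with
    a warning.
    """

    data: pd.DataFrame
    population: str = ""
    max_cohort: int | None = 1960
    n_excluded_cohort: int = field(default=0, repr=False)
    n_dropped_zero_py: int = field(default=0, repr=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        population: str = "",
        max_cohort: int | None = 1960,
        min_age: int | None = None,
        max_age: int | None = None,
    ) -> "IncidenceTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"incidence table missing columns {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["age"] = df["age"].astype(int)
        df["year"] = df["year"].astype(int)
        df["cases"] = df["cases"].astype(int)
        df["py"] = df["py"].astype(float)
        if (df["cases"] < 0).any():
            raise ValueError("negative case counts")
        if (df["py"] < 0).any():
            raise ValueError("negative person-years")
        if df.duplicated(["age", "year"]).any():
            raise ValueError("duplicate (age, year) strata")
        if ((df["py"] == 0) & (df["cases"] > 0)).any():
            raise ValueError("rows with cases > 0 but zero person-years")

        if min_age is not None:
            df = df[df["age"] >= min_age]
        if max_age is not None:
            df = df[df["age"] <= max_age]

        zero = df["py"] == 0
        n_zero = int(zero.sum())
        if n_zero:
            logger.warning("dropping %d zero person-year strata", n_zero)
            df = df[~zero]

        df["cohort"] = df["year"] - df["age"]
        n_exc = 0
        if max_cohort is not None:
            keep = df["cohort"] <= max_cohort
            n_exc = int((~keep).sum())
            if n_exc:
                logger.info(
                    "excluding %d strata with birth cohort > %d", n_exc, max_cohort
                )
            df = df[keep]
        df = df.sort_values(["year", "age"]).reset_index(drop=True)
        return cls(
            data=df,
            population=population,
            max_cohort=max_cohort,
            n_excluded_cohort=n_exc,
            n_dropped_zero_py=n_zero,
        )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def cases(self) -> np.ndarray:
        return self.data["cases"].to_numpy()

    @property
    def py(self) -> np.ndarray:
        return self.data["py"].to_numpy()

    def write(self, path) -> None:
        self.data[list(REQUIRED_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_incidence_table(
    path,
    population: str = "",
    max_cohort: int | None = 1960,
    min_age: int | None = None,
    max_age: int | None = None,
) -> IncidenceTable:
    """Load a delimited-text table with header columns (age, year, cases, py)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if population == "":
        population = Path(str(path)).stem
    return IncidenceTable.from_dataframe(
        df, population=population, max_cohort=max_cohort,
        min_age=min_age, max_age=max_age,
    )


@dataclass
class FitResult:
    """Outcome of a likelihood fit: estimates, fit quality, diagnostics."""

    params: dict
    bp: BiologicalParams
    tp: TrendParams
    loglik: float
    deviance: float
    df: int
    n_free: int
    converged: bool
    message: str = ""
    n_restarts: int = 1

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "loglik": self.loglik,
            "deviance": self.deviance,
            "df": self.df,
            "n_free": self.n_free,
            "converged": self.converged,
            "message": self.message,
            "n_restarts": self.n_restarts,
        }


class PoissonLikelihood:
    """Poisson likelihood of an incidence table under the MSCE-APC model.

    Precomputes the cohort/grid index structure once so that repeated
    evaluations (optimization, MCMC) only pay for the hazard grids.
    """

    def __init__(
        self,
        table: IncidenceTable,
        model: str = "fd",
        step: float = 0.25,
        n_stem: float = 1e6,
    ):
        if model not in ("fd", "two_hit"):
            raise ValueError(f"model must be 'fd' or 'two_hit', got {model!r}")
        self.table = table
        self.model = model
        self.step = step
        self.n_stem = n_stem

        df = table.data
        self.cases = df["cases"].to_numpy(dtype=float)
        self.py = df["py"].to_numpy(dtype=float)
        self.cohorts, self._row_cohort = np.unique(
            df["cohort"].to_numpy(dtype=float), return_inverse=True
        )
        # stratum midpoint ages; hazard argument is t = age + 0.5 - lag
        self.mid_age = df["age"].to_numpy(dtype=float) + 0.5
        self.max_age = float(self.mid_age.max()) + step
        self._log_fact = gammaln(self.cases + 1.0)

    def with_cases(self, cases: np.ndarray) -> "PoissonLikelihood":
        """Shallow copy with replaced case counts (same strata/PY layout).

        Useful for repeated-simulation studies where only the Poisson draws
        change between replicates.
        """
        import copy

        cases = np.asarray(cases, dtype=float)
        if cases.shape != self.cases.shape or np.any(cases < 0):
            raise ValueError("cases must be a non-negative array matching the table")
        new = copy.copy(self)
        new.cases = cases
        new._log_fact = gammaln(cases + 1.0)
        return new

    def _row_hazard(self, bp: BiologicalParams, tp: TrendParams) -> np.ndarray:
        t, H, _ = cohort_hazard_grid(
            self.cohorts, bp, tp, max_age=self.max_age,
            step=self.step, model=self.model, n_stem=self.n_stem,
        )
        tt = self.mid_age - bp.lag
        idx = np.rint(tt / self.step).astype(int)
        on_grid = np.abs(idx * self.step - tt) < 1e-9
        idx = np.clip(idx, 0, H.shape[1] - 1)
        h = H[self._row_cohort, idx]
        if not np.all(on_grid):
            # general path: linear interpolation for off-grid midpoints
            off = ~on_grid & (tt > 0)
            for i in np.nonzero(off)[0]:
                h[i] = np.interp(tt[i], t, H[self._row_cohort[i]])
        h[tt <= 0.0] = 0.0
        return h

    def expected(self, bp: BiologicalParams, tp: TrendParams) -> np.ndarray:
        """Per-stratum expected counts lambda_i = h(age_i + 0.5; B_i) * PY_i."""
        return self._row_hazard(bp, tp) * self.py

    def loglik(self, bp: BiologicalParams, tp: TrendParams) -> float:
        """Sum_i [cases_i log lambda_i - lambda_i - log(cases_i!)].

        Returns -inf when any stratum has lambda = 0 with observed cases,
        or when the parameters leave the model domain (beta <= 0,
        overflowing trends).
        """
        try:
            lam = self.expected(bp, tp)
        except ParameterDomainError:
            return -math.inf
        return self.loglik_from_lambda(lam)

    def loglik_from_lambda(self, lam: np.ndarray) -> float:
        if not np.all(np.isfinite(lam)):
            return -math.inf
        c = self.cases
        zero = lam == 0.0
        if np.any(zero & (c > 0)):
            return -math.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(zero, 0.0, c * np.log(np.where(zero, 1.0, lam)))
        return float(np.sum(term - lam - self._log_fact))

    def saturated_loglik(self) -> float:
        """Log-likelihood with lambda_i = cases_i (0 log 0 := 0)."""
        c = self.cases
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(c > 0, c * np.log(np.where(c > 0, c, 1.0)), 0.0)
        return float(np.sum(term - c - self._log_fact))

    def deviance(
        self, bp: BiologicalParams, tp: TrendParams, n_free: int = 0
    ) -> tuple[float, int]:
        """Poisson deviance vs the saturated model and residual df.

        ``D = 2 sum_i [cases_i log(cases_i/lambda_i) - (cases_i - lambda_i)]``
        with the cases = 0 contribution equal to ``2 lambda_i``.
        """
        lam = self.expected(bp, tp)
        return self.deviance_from_lambda(lam, n_free)

    def deviance_from_lambda(self, lam, n_free: int = 0) -> tuple[float, int]:
        c = self.cases
        pos = c > 0
        if np.any((lam == 0.0) & pos):
            return math.inf, len(c) - n_free
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pos, c / np.where(lam > 0, lam, 1.0), 1.0)
            d = np.where(pos, c * np.log(ratio) - (c - lam), lam)
        return float(2.0 * np.sum(d)), len(c) - n_free


def predict_expected_counts(
    table: IncidenceTable,
    bp: BiologicalParams,
    tp: TrendParams,
    model: str = "fd",
    step: float = 0.25,
    n_stem: float = 1e6,
) -> np.ndarray:
    """Expected Poisson counts per stratum (see :class:`PoissonLikelihood`)."""
    return PoissonLikelihood(table, model=model, step=step, n_stem=n_stem).expected(bp, tp)


def poisson_loglik(
    table: IncidenceTable,
    bp: BiologicalParams,
    tp: TrendParams,
    model: str = "fd",
    step: float = 0.25,
    n_stem: float = 1e6,
) -> float:
    """Poisson log-likelihood of the table under the model."""
    return PoissonLikelihood(table, model=model, step=step, n_stem=n_stem).loglik(bp, tp)


def saturated_loglik(table: IncidenceTable) -> float:
    """Log-likelihood of the saturated model (one free mean per stratum)."""
    return PoissonLikelihood(table).saturated_loglik()


def deviance(
    table: IncidenceTable,
    bp: BiologicalParams,
    tp: TrendParams,
    model: str = "fd",
    n_free: int = 0,
    step: float = 0.25,
    n_stem: float = 1e6,
) -> tuple[float, int]:
    """Poisson deviance vs the saturated model, and residual df."""
    return PoissonLikelihood(table, model=model, step=step, n_stem=n_stem).deviance(
        bp, tp, n_free=n_free
    )


def lr_test(dev_null: float, dev_alt: float, df_diff: int) -> float:
    """Upper-tail chi-square p-value for nested-model deviance difference."""
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    diff = dev_null - dev_alt
    if diff < -1e-8:
        raise ValueError(
            f"dev_alt ({dev_alt}) exceeds dev_null ({dev_null}): nesting violated"
        )
    return float(stats.chi2.sf(max(diff, 0.0), df_diff))
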