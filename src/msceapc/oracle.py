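"""Individual-level forward simulation of the full MSCE process.

This module exists to validate the analytic hazard: it realizes the model
directly — field-defect onset as the first event of a nonhomogeneous
Poisson process with rate ``nu_FD(s; B)`` (sampled by thinning), clone
initiations at rate ``mu1`` after onset, exact birth-death clonal dynamics
with per-cell transformation, and the fixed clinical lag — and derives an
empirical hazard with Monte-Carlo confidence bands to compare against the
convolution formula.

Run it at desk-scale inflated rates (and, if needed, reduced ``alpha``) so
that event counts are large without astronomically large clones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._clone import clone_outcomes, first_transform_times
from .params import BiologicalParams, TrendParams
from .trends import fd_rate, promotion_g

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedCohort",
    "EmpiricalHazard",
    "simulate_cohort",
    "simulate_subject",
    "simulate_clone_outcomes",
    "empirical_hazard",
]

#: clone-size cap; regimes that reach it should inflate mu2 or deflate alpha
DEFAULT_CLONE_CAP = 10_000_000


@dataclass
class SimulatedCohort:
    """Per-subject event times from the stochastic oracle.

    ``fd_age`` / ``cancer_age`` are NaN when the event did not occur before
    the censoring age. ``cancer_age`` includes the clinical lag, so it is
    always at least ``fd_age + lag`` when both are present.
    """

    birth_year: float
    fd_age: np.ndarray
    cancer_age: np.ndarray
    censor_age: float
    seed: int
    bp: BiologicalParams
    tp: TrendParams
    n_cap_events: int = 0

    def __len__(self) -> int:
        return len(self.fd_age)

    @property
    def n_events(self) -> int:
        return int(np.isfinite(self.cancer_age).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fd_age": self.fd_age,
                "cancer_age": self.cancer_age,
                "birth_year": self.birth_year,
                "censor_age": self.censor_age,
            }
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class EmpiricalHazard:
    """Interval-censored event counts / person-time with exact Poisson CIs."""

    age_lo: np.ndarray
    age_hi: np.ndarray
    events: np.ndarray
    person_time: np.ndarray
    hazard: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    @property
    def age_mid(self) -> np.ndarray:
        return 0.5 * (self.age_lo + self.age_hi)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_lo": self.age_lo,
                "age_hi": self.age_hi,
                "events": self.events,
                "person_time": self.person_time,
                "hazard": self.hazard,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _fd_envelope(nu_fn, max_age: float, refine: int = 32) -> np.ndarray:
    """Piecewise-constant majorant of nu on 1-year bins (x 1.05 safety)."""
    n_bins = int(np.ceil(max_age))
    env = np.empty(n_bins)
    for j in range(n_bins):
        s = np.linspace(j, min(j + 1.0, max_age), refine)
        env[j] = 1.05 * float(np.max(nu_fn(s)))
    return env


def _sample_fd_ages(nu_fn, max_age: float, n: int, rng: np.random.Generator):
    """First-event times of the nonhomogeneous Poisson process by thinning.

    Candidate points arrive at the bin majorant rate and are accepted with
    probability ``nu(t) / majorant``; all subjects advance in vectorized
    rounds. Returns ages with inf where no event occurred before max_age.
    """
    env = _fd_envelope(nu_fn, max_age)
    t = np.zeros(n)
    out = np.full(n, np.inf)
    active = np.ones(n, dtype=bool)
    while np.any(active):
        idx = np.nonzero(active)[0]
        ti = t[idx]
        j = np.minimum(ti.astype(int), len(env) - 1)
        M = env[j]
        bin_end = np.minimum(j + 1.0, max_age)
        # zero-rate bins: skip to the bin boundary
        dead = M <= 0.0
        gap = np.empty(len(idx))
        gap[dead] = np.inf
        gap[~dead] = rng.exponential(1.0 / M[~dead])
        tn = ti + gap
        crossed = tn >= bin_end
        ti = np.where(crossed, bin_end, tn)
        propose = ~crossed
        if np.any(propose):
            cand = tn[propose]
            acc = rng.random(cand.shape) * M[propose] < np.asarray(
                nu_fn(cand), dtype=float
            )
            hit = idx[propose][acc]
            out[hit] = cand[acc]
            active[hit] = False
        t[idx] = ti
        done = idx[ti >= max_age]
        active[done] = False
    return out


def simulate_cohort(
    bp: BiologicalParams,
    tp: TrendParams,
    B: float,
    n_subjects: int,
    max_age: float,
    seed: int,
    clone_cap: int = DEFAULT_CLONE_CAP,
) -> SimulatedCohort:
    """Simulate ``n_subjects`` independent life histories for cohort ``B``.

    Censoring at ``max_age`` applies to the clinical cancer age (first
    transformation + lag).
    """
    if max_age > 120:
        raise ValueError("max_age must be <= 120")
    g = float(promotion_g(B, bp.g0, tp))
    beta = bp.beta(g)

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, abs(int(B))])
    fd_ss, clone_ss = ss.spawn(2)
    rng = np.random.default_rng(fd_ss)
    nu_fn = lambda s: fd_rate(s, B, bp.nu0, tp)

    fd = _sample_fd_ages(nu_fn, max_age, n_subjects, rng)
    # transformation must occur before max_age - lag to be observed
    t_horizon = max(max_age - bp.lag, 0.0)

    seeds = clone_ss.generate_state(n_subjects).astype(np.int64)
    times, n_capped = first_transform_times(
        fd, seeds, bp.mu1, bp.alpha, beta, bp.mu2, t_horizon, clone_cap
    )
    if n_capped:
        warnings.warn(
            f"{n_capped} clones hit the population cap ({clone_cap}) and were "
            "abandoned without transformation; inflate mu2 or deflate alpha "
            "for oracle regimes",
            RuntimeWarning,
        )
    cancer = times + bp.lag
    cancer[~np.isfinite(cancer)] = np.nan
    cancer[cancer >= max_age] = np.nan
    fd_out = np.where(np.isfinite(fd), fd, np.nan)
    return SimulatedCohort(
        birth_year=B,
        fd_age=fd_out,
        cancer_age=cancer,
        censor_age=max_age,
        seed=seed,
        bp=bp,
        tp=tp,
        n_cap_events=int(n_capped),
    )


def simulate_subject(
    bp: BiologicalParams,
    tp: TrendParams,
    B: float,
    max_age: float,
    seed: int,
) -> dict:
    """One subject record (fd_age / cancer_age, NaN when absent)."""
    c = simulate_cohort(bp, tp, B, 1, max_age, seed)
    return {
        "birth_year": B,
        "fd_age": float(c.fd_age[0]),
        "cancer_age": float(c.cancer_age[0]),
        "censor_age": max_age,
    }


def simulate_clone_outcomes(
    alpha: float,
    beta: float,
    mu2: float,
    n_clones: int,
    horizon: float,
    seed: int,
    clone_cap: int = DEFAULT_CLONE_CAP,
):
    """First-transform times and alive-at-horizon flags for independent
    clones started from a single cell (engine validation helper)."""
    return clone_outcomes(n_clones, seed & 0xFFFFFFFF, alpha, beta, mu2,
                          horizon, clone_cap)


def analytic_bin_hazard(
    bp: BiologicalParams,
    tp: TrendParams,
    B: float,
    edges,
    step: float = 0.05,
) -> np.ndarray:
    """Survival-weighted mean of the analytic hazard over each age bin.

    This is the quantity the occurrence/exposure rate of
    :func:`empirical_hazard` estimates: events per person-time at risk in
    the bin, i.e. ``int_b h S da / int_b S da`` — not the midpoint hazard,
    which differs noticeably in wide bins where the hazard is curved.
    """
    from .hazard import hazard_curve

    edges = np.asarray(edges, dtype=float)
    out = np.empty(len(edges) - 1)
    for k in range(len(out)):
        a = np.arange(edges[k], edges[k + 1] + step / 2, step)
        crv = hazard_curve(a, bp, tp, B, step=step)
        w = np.trapezoid(crv.survival, a)
        out[k] = np.trapezoid(crv.hazard * crv.survival, a) / w if w > 0 else 0.0
    return out


def empirical_hazard(cohort: SimulatedCohort, age_grid) -> EmpiricalHazard:
    """Event counts / person-time at risk per age bin with exact Poisson CIs.

    Subjects are at risk from birth until cancer or censoring. Bins with
    no person-time are omitted with a warning.
    """
    edges = np.asarray(age_grid, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("age_grid must be an increasing array of bin edges")
    if cohort.n_events < 100:
        logger.info(
            "only %d events; Monte-Carlo bands will be wide", cohort.n_events
        )
    end = np.where(
        np.isfinite(cohort.cancer_age), cohort.cancer_age, cohort.censor_age
    )
    events_age = cohort.cancer_age[np.isfinite(cohort.cancer_age)]

    lo, hi = edges[:-1], edges[1:]
    pt = np.empty(len(lo))
    ev = np.empty(len(lo), dtype=int)
    for k in range(len(lo)):
        pt[k] = np.sum(np.clip(end, lo[k], hi[k]) - lo[k])
        ev[k] = int(np.sum((events_age >= lo[k]) & (events_age < hi[k])))
    keep = pt > 0
    if not np.all(keep):
        warnings.warn(
            f"omitting {int((~keep).sum())} empty-risk-set age bins",
            RuntimeWarning,
        )
    lo, hi, pt, ev = lo[keep], hi[keep], pt[keep], ev[keep]

    haz = ev / pt
    # exact Poisson (Garwood) interval for the count, scaled by person-time
    ci_lo = np.where(ev > 0, stats.chi2.ppf(0.025, 2 * ev) / 2.0, 0.0) / pt
    ci_hi = stats.chi2.ppf(0.975, 2 * (ev + 1)) / 2.0 / pt
    return EmpiricalHazard(
        age_lo=lo, age_hi=hi, events=ev, person_time=pt,
        hazard=haz, ci_low=ci_lo, ci_high=ci_hi,
    )
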