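"""Regularized age-period-cohort modulation of the field-defect rate.

Period effects act continuously along historical time on the rate
``nu_FD`` at which an ESCC-predisposing field-defect arises, rather than
multiplying the hazard by diagnosis-year constants as in traditional APC
models. All trend factors are regularized to equal exactly 1 on the
right of their reference year, so ``nu_FD`` settles smoothly onto the
background rate ``nu0`` for recent calendar years and cohorts.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from .params import BiologicalParams, ParameterDomainError, TrendParams

__all__ = [
    "period_factor",
    "cohort_factor",
    "fd_rate",
    "fd_prevalence",
    "promotion_g",
]


def _period_exponent(y, tp: TrendParams):
    """log of the period factor; 0 for y >= y0."""
    x = np.asarray(y, dtype=float) - tp.y0
    return np.where(x < 0.0, tp.w1 * x * x * (1.0 + tp.w2 * x), 0.0)


def _cohort_exponent(B, tp: TrendParams):
    """log of the cohort factor; 0 for B >= B0."""
    x = np.asarray(B, dtype=float) - tp.B0
    return np.where(x < 0.0, tp.b1 * x * x * (1.0 + tp.b2 * x), 0.0)


def period_factor(y, tp: TrendParams):
    """Multiplier exp[w1 (y-y0)^2 (1 + w2 (y-y0))] for y < y0, exactly 1 after.

    The quadratic leading term gives a smooth approach (value 1, zero slope)
    to the background rate at the reference year ``y0``.
    """
    with np.errstate(over="ignore"):
        out = np.exp(_period_exponent(y, tp))
    return out if out.ndim else float(out)


def cohort_factor(B, tp: TrendParams):
    """Multiplier exp[b1 (B-B0)^2 (1 + b2 (B-B0))] for B < B0, exactly 1 after."""
    with np.errstate(over="ignore"):
        out = np.exp(_cohort_exponent(B, tp))
    return out if out.ndim else float(out)


def _attenuation(s, tp: TrendParams):
    """Early-life attenuation A(s) = max(0, log(s/s0)); optionally capped at 1."""
    s = np.asarray(s, dtype=float)
    if not tp.use_log_attenuation:
        return np.ones_like(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.log(np.where(s > 0.0, s, np.nan) / tp.s0)
    a = np.where(s > tp.s0, a, 0.0)
    if tp.cap_attenuation:
        a = np.minimum(a, 1.0)
    return a


def fd_rate(s, B, nu0: float, tp: TrendParams):
    """Field-defect onset rate nu_FD(s; B), per year.

    ``s`` is age, ``B`` birth year; the calendar year is ``y = B + s``
    (continuous years). Once both ``y`` and ``B`` exceed the reference
    year ``y0`` the rate is the background ``nu0`` exactly (no
    attenuation); otherwise the period, cohort and attenuation factors
    multiply ``nu0``. The exponents are summed before exponentiating so
    that an enormous period factor times a vanishing cohort factor stays
    finite.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0.0):
        raise ParameterDomainError("age s must be >= 0")
    B = np.asarray(B, dtype=float)
    expo = _period_exponent(B + s, tp) + _cohort_exponent(B, tp)
    # overflowing exponents yield inf (or inf*0 = nan) and are rejected
    # downstream as out-of-domain; silence the arithmetic warnings here
    with np.errstate(over="ignore", invalid="ignore"):
        rate = nu0 * np.exp(expo) * _attenuation(s, tp)
    rate = np.where(B >= tp.y0, nu0, rate)
    if rate.ndim == 0:
        return float(rate)
    return rate


def fd_prevalence(a: float, B: float, nu0: float, tp: TrendParams) -> float:
    """Probability of having acquired the field-defect by age ``a``.

    ``1 - exp(-int_0^a nu_FD(s; B) ds)`` by adaptive quadrature, splitting
    the range at the attenuation onset ``s0`` and at the calendar crossing
    ``y0 - B`` where the period factor switches off.
    """
    if a < 0:
        raise ParameterDomainError("age a must be >= 0")
    if a == 0:
        return 0.0
    pts = [p for p in (tp.s0, tp.y0 - B) if 0.0 < p < a]
    total, _ = integrate.quad(
        lambda s: fd_rate(s, B, nu0, tp),
        0.0, a, points=sorted(pts) or None, limit=200,
    )
    return float(-np.expm1(-total))


def promotion_g(B, g0: float, tp: TrendParams):
    """Cohort-adjusted net cell proliferation g(B) = g0 exp[g1 X (1 + g2 X)].

    ``X = B - 1800``. With ``g1 = g2 = 0`` (null trend) the promotion rate
    is cohort-independent. Validity of the derived death rate
    ``beta = alpha - g - mu2 > 0`` is checked downstream where alpha and
    mu2 are known.
    """
    x = np.asarray(B, dtype=float) - 1800.0
    with np.errstate(over="ignore"):
        out = g0 * np.exp(tp.g1 * x * (1.0 + tp.g2 * x))
    return out if out.ndim else float(out)


def check_promotion_domain(bp: BiologicalParams, tp: TrendParams, cohorts) -> None:
    """Raise ParameterDomainError if beta <= 0 for any cohort in ``cohorts``."""
    g = np.asarray(promotion_g(cohorts, bp.g0, tp))
    beta = bp.alpha - g - bp.mu2
    if not np.all(beta > 0.0):
        bad = np.asarray(cohorts)[beta <= 0.0]
        raise ParameterDomainError(
            f"beta = alpha - g(B) - mu2 <= 0 for cohorts {bad[:5]!r}..."
        )
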