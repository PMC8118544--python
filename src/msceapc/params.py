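"""Parameter containers for the MSCE-APC incidence model.

Two parameter groups describe one population:

* :class:`BiologicalParams` — cell-level rates of the multistage clonal
  expansion (MSCE) process: the background field-defect onset rate ``nu0``,
  the per-field initiation rate ``mu1`` of dysplastic clones, the per-cell
  malignant transformation rate ``mu2``, the premalignant cell division
  rate ``alpha`` (fixed at 17.4/yr, the esophageal stem-cell division rate,
  because it is not identifiable from incidence data), the baseline net
  clonal proliferation ``g0 = alpha - beta - mu2``, and a fixed clinical
  ``lag`` (5 years) between the first malignant cell and diagnosis.
* :class:`TrendParams` — the regularized period/cohort modulation of the
  field-defect rate and the birth-cohort adjustment of promotion.

The cell death rate ``beta`` is always derived, never stored:
``beta = alpha - g - mu2`` where ``g`` is the (possibly cohort-adjusted)
net proliferation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping


class ParameterDomainError(ValueError):
    """A parameter combination outside the model's biological domain."""


@dataclass(frozen=True)
class BiologicalParams:
    """Cell-level rates defining the MSCE process for one population.

    All rates are per year. ``beta`` is derived as ``alpha - g - mu2`` and
    must remain positive over the cohort-adjusted range of ``g``.
    """

    nu0: float
    mu1: float
    mu2: float
    g0: float
    alpha: float = 17.4
    lag: float = 5.0

    def __post_init__(self) -> None:
        for name in ("nu0", "mu1", "mu2", "g0", "alpha", "lag"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ParameterDomainError(f"{name} must be >= 0, got {v!r}")
        if not self.alpha > self.g0:
            raise ParameterDomainError(
                f"alpha ({self.alpha}) must exceed g0 ({self.g0}) so that "
                "beta = alpha - g - mu2 stays positive"
            )

    def beta(self, g: float | None = None) -> float:
        """Cell death rate for net proliferation ``g`` (default ``g0``)."""
        g = self.g0 if g is None else g
        b = self.alpha - g - self.mu2
        if b <= 0.0:
            raise ParameterDomainError(
                f"derived beta = alpha - g - mu2 = {b} <= 0 (g={g})"
            )
        return b

    def replace(self, **kw) -> "BiologicalParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TrendParams:
    """Regularized age-period-cohort modulation parameters.

    The field-defect rate for a subject of birth year ``B`` at age ``s``
    (calendar year ``y = B + s``) is

    ``nu_FD(s; B) = nu0 * P(y) * C(B) * A(s)``

    with the period factor ``P(y) = exp[w1 (y-y0)^2 (1 + w2 (y-y0))]`` for
    ``y < y0`` (1 otherwise), the cohort factor
    ``C(B) = exp[b1 (B-B0)^2 (1 + b2 (B-B0))]`` for ``B < B0`` (1 otherwise),
    and the early-life attenuation ``A(s) = max(0, log(s/s0))`` when
    ``use_log_attenuation`` is set (1 otherwise). The reference birth year
    is tied to the reference period, ``B0 = y0``, and ``nu_FD = nu0``
    exactly once both ``y`` and ``B`` exceed ``y0``.

    Promotion is cohort-adjusted as
    ``g(B) = g0 * exp[g1 (B-1800) (1 + g2 (B-1800))]``.
    """

    w1: float = 0.0
    w2: float = 0.0
    y0: float = 1960.0
    s0: float = 0.5
    b1: float = 0.0
    b2: float = 0.0
    g1: float = 0.0
    g2: float = 0.0
    use_log_attenuation: bool = True
    cap_attenuation: bool = False

    def __post_init__(self) -> None:
        if not self.s0 > 0.0:
            raise ParameterDomainError(f"s0 must be > 0, got {self.s0}")
        if not (1850.0 <= self.y0 <= 2020.0):
            raise ParameterDomainError(
                f"y0 must lie in a plausible calendar range [1850, 2020], got {self.y0}"
            )

    @property
    def B0(self) -> float:
        """Reference birth year; constrained equal to the period reference y0."""
        return self.y0

    @classmethod
    def from_linquad(cls, gl: float, gq: float, **kw) -> "TrendParams":
        """Build from the regular (linear, quadratic) log-promotion coefficients.

        The promotion exponent ``g1 X (1 + g2 X)`` equals ``gl X + gq X^2``
        with ``gl = g1`` and ``gq = g1 g2``. This parameterization stays
        regular at the no-trend origin (the ``g2`` direction is
        unidentified when ``g1 = 0``), which matters for likelihood-ratio
        calibration.
        """
        if gl == 0.0:
            if gq != 0.0:
                raise ParameterDomainError(
                    "gq != 0 with gl == 0 is not representable as g1*(1+g2*X)"
                )
            return cls(g1=0.0, g2=0.0, **kw)
        return cls(g1=gl, g2=gq / gl, **kw)

    def replace(self, **kw) -> "TrendParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def _preset(nu0, mu1, mu2, g0, g1, g2, b1, b2, w1, w2, y0, s0):
    bp = BiologicalParams(nu0=nu0, mu1=mu1, mu2=mu2, g0=g0)
    tp = TrendParams(w1=w1, w2=w2, y0=y0, s0=s0, b1=b1, b2=b2, g1=g1, g2=g2)
    return bp, tp


#: Posterior-median parameter estimates for the four SEER9 ESCC populations
#: (diagnosis years 1975-2016, birth cohorts <= 1960). These are the fitted
#: values of the published MSCE-APC analysis of US esophageal squamous cell
#: carcinoma and serve as realistic defaults for synthetic-data generation
#: and worked examples.
POSTERIOR_MEDIANS: Mapping[str, tuple[BiologicalParams, TrendParams]] = {
    "black_males": _preset(
        nu0=9.54e-5, mu1=39.4632, mu2=0.0345e-7, g0=0.0249,
        g1=0.0268, g2=-0.0029, b1=0.0106, b2=0.0440,
        w1=0.0002, w2=-0.7856, y0=1967.1696, s0=0.4954,
    ),
    "black_females": _preset(
        nu0=5.52e-5, mu1=15.7833, mu2=0.4878e-7, g0=0.0632,
        g1=0.0096, g2=-0.0011, b1=0.0139, b2=0.0610,
        w1=0.0011, w2=-0.2582, y0=1961.0, s0=0.3586,
    ),
    "white_males": _preset(
        nu0=5.52e-5, mu1=4.3755, mu2=1.3273e-7, g0=0.1836,
        g1=0.0001, g2=0.0688, b1=0.0038, b2=0.0305,
        w1=0.0006, w2=-0.0928, y0=1963.0811, s0=1.8121,
    ),
    "white_females": _preset(
        nu0=6.51e-5, mu1=1.2988, mu2=0.3392e-7, g0=0.2032,
        g1=0.0, g2=14.5845, b1=0.0042, b2=0.0289,
        w1=-0.0002, w2=0.2786, y0=1961.0, s0=0.6246,
    ),
}


def get_preset(population: str) -> tuple[BiologicalParams, TrendParams]:
    """Return (BiologicalParams, TrendParams) for a named population preset."""
    try:
        return POSTERIOR_MEDIANS[population]
    except KeyError:
        raise KeyError(
            f"unknown population {population!r}; "
            f"choose from {sorted(POSTERIOR_MEDIANS)}"
        ) from None
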