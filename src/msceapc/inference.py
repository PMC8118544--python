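"""Maximum-likelihood fitting and Metropolis-Hastings MCMC.

The free parameter vector is a configurable subset of the biological
rates (``nu0, mu1, mu2, g0``) and trend parameters
(``g1, g2, b1, b2, w1, w2, y0, s0``) — twelve parameters in the full
model, matching the published parameterization (``alpha`` and the
clinical lag are fixed constants, and the cohort reference ``B0`` is tied
to ``y0``).

Strictly positive rates are sampled and optimized on the log scale; prior
boxes are uniform on the sampling (transformed) scale, i.e. log-uniform
on the natural scale for rates, whose plausible ranges span many decades.
The sampler is an adaptive random-walk Metropolis-Hastings: the proposal
covariance is learned from the chain history during burn-in and then
frozen, preserving detailed balance for the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .incidence import FitResult, IncidenceTable, PoissonLikelihood
from .params import BiologicalParams, ParameterDomainError, TrendParams

__all__ = [
    "PriorSpec",
    "ParamSpace",
    "PosteriorSamples",
    "default_priors",
    "fit_mle",
    "run_mcmc",
    "posterior_summary",
]

_BP_FIELDS = {"nu0", "mu1", "mu2", "g0"}
_TP_FIELDS = {"g1", "g2", "b1", "b2", "w1", "w2", "y0", "s0"}
# regular (linear, quadratic) log-promotion coefficients; alternative to g1/g2
_LINQUAD = {"gl", "gq"}
_LOG_DEFAULT = {"nu0", "mu1", "mu2", "g0"}


@dataclass(frozen=True)
class PriorSpec:
    """Bounds and treatment of one parameter.

    ``lower``/``upper`` are on the natural scale; ``transform`` selects the
    optimization/sampling scale ('identity' or 'log').
    """

    name: str
    lower: float
    upper: float
    fixed: bool = False
    transform: str = "identity"

    def __post_init__(self):
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not self.fixed and not self.lower < self.upper:
            raise ValueError(f"{self.name}: need lower < upper for free parameters")
        if self.transform == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log transform needs positive bounds")

    def _t(self, x: float) -> float:
        return math.log(x) if self.transform == "log" else x

    def to_internal(self, x: float) -> float:
        """Map a natural value into the unit-box coordinate [0, 1].

        Internal coordinates are box-normalized on the transformed scale,
        so every free parameter is O(1) for the optimizer and sampler
        regardless of its natural units.
        """
        lo, hi = self._t(self.lower), self._t(self.upper)
        return (self._t(x) - lo) / (hi - lo)

    def from_internal(self, z: float) -> float:
        lo, hi = self._t(self.lower), self._t(self.upper)
        v = lo + z * (hi - lo)
        return math.exp(v) if self.transform == "log" else v


def default_priors(
    bp: BiologicalParams,
    tp: TrendParams,
    free: Sequence[str],
) -> list[PriorSpec]:
    """Wide prior boxes around the current values for the named free
    parameters: two decades either side for rates (log scale), +/- 50 years
    for ``y0``, generous symmetric boxes for trend coefficients."""
    ref = {**bp.to_dict(), **tp.to_dict(), "gl": tp.g1, "gq": tp.g1 * tp.g2}
    priors = []
    for name in free:
        v = float(ref[name])
        if name in _LOG_DEFAULT:
            priors.append(PriorSpec(name, v / 100.0, v * 100.0, transform="log"))
        elif name == "y0":
            priors.append(PriorSpec(name, max(v - 50.0, 1851.0), min(v + 50.0, 2019.0)))
        elif name == "s0":
            priors.append(PriorSpec(name, max(v / 10.0, 1e-3), max(v * 10.0, 5.0)))
        else:
            span = max(10.0 * abs(v), 0.05)
            priors.append(PriorSpec(name, v - span, v + span))
    return priors


class ParamSpace:
    """Maps a free-parameter vector (internal scale) to model parameters.

    ``base_bp``/``base_tp`` supply every fixed value; free parameters are
    named by :class:`PriorSpec` entries. The synthetic names ``gl``/``gq``
    select the regular linear-quadratic log-promotion parameterization
    (mutually exclusive with ``g1``/``g2``).
    """

    def __init__(
        self,
        base_bp: BiologicalParams,
        base_tp: TrendParams,
        priors: Sequence[PriorSpec],
    ):
        self.base_bp = base_bp
        self.base_tp = base_tp
        self.priors = [p for p in priors if not p.fixed]
        names = [p.name for p in self.priors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate free parameter names")
        if _LINQUAD & set(names) and {"g1", "g2"} & set(names):
            raise ValueError("gl/gq and g1/g2 parameterizations are exclusive")
        unknown = set(names) - _BP_FIELDS - _TP_FIELDS - _LINQUAD
        if unknown:
            raise ValueError(f"unknown free parameters {sorted(unknown)}")
        self.names = names

    @property
    def n_free(self) -> int:
        return len(self.priors)

    def initial_vector(self, overrides: dict | None = None) -> np.ndarray:
        ref = {
            **self.base_bp.to_dict(),
            **self.base_tp.to_dict(),
            "gl": self.base_tp.g1,
            "gq": self.base_tp.g1 * self.base_tp.g2,
        }
        if overrides:
            ref.update(overrides)
        z = np.empty(self.n_free)
        for i, p in enumerate(self.priors):
            v = float(np.clip(ref[p.name], p.lower, p.upper))
            z[i] = p.to_internal(v)
        return z

    def bounds_internal(self) -> list[tuple[float, float]]:
        return [(0.0, 1.0)] * self.n_free

    def natural(self, z: np.ndarray) -> dict:
        return {
            p.name: p.from_internal(float(z[i])) for i, p in enumerate(self.priors)
        }

    def build(self, z: np.ndarray) -> tuple[BiologicalParams, TrendParams]:
        vals = self.natural(z)
        bp_kw = {k: v for k, v in vals.items() if k in _BP_FIELDS}
        tp_kw = {k: v for k, v in vals.items() if k in _TP_FIELDS}
        bp = self.base_bp.replace(**bp_kw) if bp_kw else self.base_bp
        if "gl" in vals or "gq" in vals:
            gl = vals.get("gl", self.base_tp.g1)
            gq = vals.get("gq", self.base_tp.g1 * self.base_tp.g2)
            if gl == 0.0:
                tp_kw.update(g1=0.0, g2=0.0 if gq == 0.0 else math.nan)
                if gq != 0.0:
                    raise ParameterDomainError("gq != 0 with gl == 0")
            else:
                tp_kw.update(g1=gl, g2=gq / gl)
        tp = self.base_tp.replace(**tp_kw) if tp_kw else self.base_tp
        return bp, tp

    def in_box(self, z: np.ndarray) -> bool:
        for zi, (lo, hi) in zip(z, self.bounds_internal()):
            if not (lo <= zi <= hi):
                return False
        return True


def _neg_loglik_factory(lik: PoissonLikelihood, space: ParamSpace) -> Callable:
    big = 1e12

    def nll(z: np.ndarray) -> float:
        try:
            bp, tp = space.build(z)
        except (ParameterDomainError, ValueError):
            return big
        ll = lik.loglik(bp, tp)
        return -ll if math.isfinite(ll) else big

    return nll


def fit_mle(
    table: IncidenceTable | PoissonLikelihood,
    init: dict | None = None,
    priors: Sequence[PriorSpec] | None = None,
    model: str = "fd",
    base: tuple[BiologicalParams, TrendParams] | None = None,
    n_restarts: int = 1,
    seed: int | None = None,
    step: float = 0.25,
) -> FitResult:
    """Maximum-likelihood fit by bounded quasi-Newton (L-BFGS-B, central
    finite-difference gradients with relative step 1e-6 on the box-normalized
    transformed scale).

    ``base`` supplies the fixed parameter values (required unless ``table``
    already is a :class:`PoissonLikelihood` and ``base`` given separately).
    ``init`` optionally overrides starting values for free parameters.
    With ``n_restarts > 1`` additional starts are jittered uniformly within
    20% of the prior box (deterministic given ``seed``) and the best
    optimum is kept. Non-convergence is flagged, never silent.
    """
    if base is None:
        raise ValueError("base=(BiologicalParams, TrendParams) is required")
    bp0, tp0 = base
    lik = (
        table
        if isinstance(table, PoissonLikelihood)
        else PoissonLikelihood(table, model=model, step=step)
    )
    if priors is None:
        raise ValueError("priors (list of PriorSpec) are required")
    space = ParamSpace(bp0, tp0, priors)
    nll = _neg_loglik_factory(lik, space)
    bounds = space.bounds_internal()
    z0 = space.initial_vector(init)

    rng = np.random.default_rng(seed)
    starts = [z0]
    for _ in range(max(n_restarts - 1, 0)):
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        jitter = (hi - lo) * 0.2 * (rng.random(space.n_free) - 0.5)
        starts.append(np.clip(z0 + jitter, lo, hi))

    best = None
    for s in starts:
        res = optimize.minimize(
            nll, s, method="L-BFGS-B", bounds=bounds,
            jac="3-point", options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8,
                                    "finite_diff_rel_step": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res

    bp_hat, tp_hat = space.build(best.x)
    ll = -best.fun
    dev, df = lik.deviance(bp_hat, tp_hat, n_free=space.n_free)
    return FitResult(
        params=space.natural(best.x),
        bp=bp_hat,
        tp=tp_hat,
        loglik=ll,
        deviance=dev,
        df=df,
        n_free=space.n_free,
        converged=bool(best.success),
        message=str(best.message),
        n_restarts=len(starts),
    )


def laplace_covariance(
    table: IncidenceTable | PoissonLikelihood,
    params: dict,
    priors: Sequence[PriorSpec],
    base: tuple[BiologicalParams, TrendParams],
    model: str = "fd",
    step: float = 0.25,
    h: float = 1e-4,
) -> np.ndarray:
    """Inverse observed-information covariance at a parameter point.

    The Hessian of the negative log-likelihood is formed by central finite
    differences on the internal (box-normalized) scale and pseudo-inverted
    with an eigenvalue floor. Useful as an informed Metropolis proposal
    covariance when starting a chain at the MLE.
    """
    bp0, tp0 = base
    lik = (
        table
        if isinstance(table, PoissonLikelihood)
        else PoissonLikelihood(table, model=model, step=step)
    )
    space = ParamSpace(bp0, tp0, priors)
    nll = _neg_loglik_factory(lik, space)
    z = space.initial_vector(params)
    n = len(z)
    H = np.empty((n, n))
    e = np.eye(n)
    for i in range(n):
        for j in range(i, n):
            fpp = nll(z + h * e[i] + h * e[j])
            fpm = nll(z + h * e[i] - h * e[j])
            fmp = nll(z - h * e[i] + h * e[j])
            fmm = nll(z - h * e[i] - h * e[j])
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    floor = max(np.max(np.abs(vals)) * 1e-10, 1e-8)
    vals = np.maximum(vals, floor)
    return (vecs / vals) @ vecs.T


@dataclass
class PosteriorSamples:
    """MCMC draws over the free parameters (natural scale) with diagnostics."""

    draws: pd.DataFrame
    internal: np.ndarray = field(repr=False)
    acceptance_rate: float = 0.0
    n_burn: int = 0
    seed: int | None = None
    names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.draws)

    def write_chain(self, path) -> None:
        self.draws.to_csv(path, sep="\t", index=False)


def run_mcmc(
    table: IncidenceTable | PoissonLikelihood | Callable,
    priors: Sequence[PriorSpec],
    n_samples: int,
    seed: int,
    model: str = "fd",
    base: tuple[BiologicalParams, TrendParams] | None = None,
    init: dict | None = None,
    n_burn: int | None = None,
    step: float = 0.25,
    proposal_cov: np.ndarray | None = None,
) -> PosteriorSamples:
    """Adaptive random-walk multivariate Metropolis-Hastings.

    Targets likelihood x uniform prior on the sampling scale. The proposal
    covariance starts diagonal (5% of each box width), is re-estimated
    from the chain history every 200 iterations during burn-in (scaled by
    the standard 2.38^2/d factor with a small regularizing ridge), and is
    frozen afterwards. ``proposal_cov`` (internal scale, e.g. from
    :func:`laplace_covariance` at the MLE) seeds the proposal instead of
    the diagonal default. Burn-in defaults to 25% of ``n_samples`` (at
    least 1000). Reproducible given ``seed``; raises if the frozen chain
    accepts nothing.

    ``table`` may also be a callable ``z_natural_dict -> loglik`` for
    validation against closed-form targets.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if base is None and not callable(table):
        raise ValueError("base=(BiologicalParams, TrendParams) is required")

    if callable(table) and not isinstance(table, (IncidenceTable, PoissonLikelihood)):
        bp0, tp0 = base if base is not None else (
            BiologicalParams(nu0=1e-4, mu1=1.0, mu2=1e-7, g0=0.1),
            TrendParams(),
        )
        space = ParamSpace(bp0, tp0, priors)

        def logpost(z):
            return table(space.natural(z))

    else:
        bp0, tp0 = base
        lik = (
            table
            if isinstance(table, PoissonLikelihood)
            else PoissonLikelihood(table, model=model, step=step)
        )
        space = ParamSpace(bp0, tp0, priors)

        def logpost(z):
            try:
                bp, tp = space.build(z)
            except (ParameterDomainError, ValueError):
                return -math.inf
            return lik.loglik(bp, tp)

    d = space.n_free
    bounds = np.array(space.bounds_internal())
    lo, hi = bounds[:, 0], bounds[:, 1]
    widths = hi - lo
    if n_burn is None:
        n_burn = max(1000, n_samples // 4)
    total = n_burn + n_samples

    rng = np.random.default_rng(seed)
    z = space.initial_vector(init)
    lp = logpost(z)
    if not math.isfinite(lp):
        raise ValueError("initial point has zero posterior density")

    if proposal_cov is not None:
        base_cov = np.asarray(proposal_cov, dtype=float)
    else:
        base_cov = np.diag((0.05 * widths) ** 2) * (d / 2.38 ** 2)
    scale = 2.38 ** 2 / d
    chol = np.linalg.cholesky(scale * base_cov)
    history = np.empty((total, d))
    accepted_post = 0
    proposed_post = 0
    batch_acc = 0

    for it in range(total):
        prop = z + chol @ rng.standard_normal(d)
        accepted = False
        if np.all((prop >= lo) & (prop <= hi)):
            lp_prop = logpost(prop)
            if math.log(rng.random()) < lp_prop - lp:
                z, lp = prop, lp_prop
                accepted = True
        if it >= n_burn:
            proposed_post += 1
            accepted_post += accepted
        else:
            batch_acc += accepted
        history[it] = z
        if it < n_burn and (it + 1) % 200 == 0:
            # global scale toward the 0.234 random-walk optimum, and the
            # proposal shape from the recent chain history
            rate = batch_acc / 200.0
            batch_acc = 0
            scale *= math.exp(0.6 * (rate - 0.234))
            if it >= 400:
                emp = np.atleast_2d(np.cov(history[max(0, it - 4000): it + 1].T))
                base_cov = emp + 1e-12 * np.diag(widths ** 2)
            try:
                chol = np.linalg.cholesky(scale * base_cov)
            except np.linalg.LinAlgError:
                chol = np.diag(np.sqrt(np.maximum(np.diag(scale * base_cov), 1e-16)))

    if accepted_post == 0:
        raise RuntimeError(
            "MCMC accepted no proposals after burn-in; "
            "check the prior box and starting point"
        )
    kept = history[n_burn:]
    nat = np.column_stack(
        [
            [p.from_internal(v) for v in kept[:, i]]
            for i, p in enumerate(space.priors)
        ]
    )
    draws = pd.DataFrame(nat, columns=space.names)
    return PosteriorSamples(
        draws=draws,
        internal=kept,
        acceptance_rate=accepted_post / proposed_post,
        n_burn=n_burn,
        seed=seed,
        names=list(space.names),
    )


def run_ensemble_mcmc(
    table: IncidenceTable | PoissonLikelihood,
    priors: Sequence[PriorSpec],
    n_steps: int,
    seed: int,
    base: tuple[BiologicalParams, TrendParams],
    model: str = "fd",
    init: dict | None = None,
    n_burn_steps: int | None = None,
    n_walkers: int = 32,
    init_cov: np.ndarray | None = None,
    init_scale: float = 1.5,
    step: float = 0.25,
) -> PosteriorSamples:
    """Affine-invariant ensemble sampling (emcee) of the same posterior.

    The random-walk sampler of :func:`run_mcmc` mixes slowly through the
    curved ridges this model's trend parameters produce (e.g. the
    period-trend pair w1/w2); the stretch-move ensemble handles that
    geometry far better at equal likelihood-evaluation budgets. Walkers
    start from an overdispersed Gaussian around ``init`` — shaped by
    ``init_cov`` (internal scale, e.g. :func:`laplace_covariance` at the
    MLE) times ``init_scale``, or a small diagonal ball otherwise — and
    the first ``n_burn_steps`` (default ``n_steps // 2``) are discarded.
    Retained draws are flattened across walkers.
    """
    bp0, tp0 = base
    lik = (
        table
        if isinstance(table, PoissonLikelihood)
        else PoissonLikelihood(table, model=model, step=step)
    )
    space = ParamSpace(bp0, tp0, priors)
    d = space.n_free

    def logpost(z):
        if np.any(z < 0.0) or np.any(z > 1.0):
            return -math.inf
        try:
            bp, tp = space.build(z)
        except (ParameterDomainError, ValueError):
            return -math.inf
        return lik.loglik(bp, tp)

    import emcee

    if n_burn_steps is None:
        n_burn_steps = max(n_steps // 2, 100)
    rng = np.random.default_rng(seed)
    z0 = space.initial_vector(init)
    if init_cov is not None:
        L = np.linalg.cholesky(
            np.asarray(init_cov, dtype=float) + 1e-12 * np.eye(d)
        )
    else:
        L = 0.01 * np.eye(d)
    starts = []
    tries = 0
    while len(starts) < n_walkers:
        cand = np.clip(
            z0 + init_scale * (L @ rng.standard_normal(d)), 1e-4, 1.0 - 1e-4
        )
        if math.isfinite(logpost(cand)):
            starts.append(cand)
        tries += 1
        if tries > 100 * n_walkers:
            raise RuntimeError("could not find valid walker starting points")
    p0 = np.asarray(starts)

    sampler = emcee.EnsembleSampler(n_walkers, d, logpost)
    sampler.random_state = np.random.RandomState(seed & 0xFFFFFFFF).get_state()
    state = sampler.run_mcmc(p0, n_burn_steps, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_steps - n_burn_steps, progress=False)
    kept = sampler.get_chain(flat=True)
    nat = np.column_stack(
        [
            [p.from_internal(v) for v in kept[:, i]]
            for i, p in enumerate(space.priors)
        ]
    )
    return PosteriorSamples(
        draws=pd.DataFrame(nat, columns=space.names),
        internal=kept,
        acceptance_rate=float(np.mean(sampler.acceptance_fraction)),
        n_burn=n_burn_steps * n_walkers,
        seed=seed,
        names=list(space.names),
    )


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Marginal posterior medians with central 95% credible intervals."""
    if len(samples) < 100:
        raise ValueError("need >= 100 post-burn-in draws for summaries")
    q = samples.draws.quantile([0.5, 0.025, 0.975]).T
    q.columns = ["median", "lower", "upper"]
    return q[["median", "lower", "upper"]]
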