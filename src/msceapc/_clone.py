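"""Numba kernels for the individual-level MSCE forward simulation.

Each premalignant clone is simulated as an exact event-driven (Gillespie)
linear birth-death process with per-cell rates: division ``alpha``, death
``beta``, malignant transformation ``mu2``. A transformation produces one
malignant daughter and one dysplastic daughter, so the dysplastic count is
unchanged by the event; the first transformation time is all that matters
downstream, so the clone stops there.

Per-subject reproducibility: every subject consumes its own RNG stream
seeded from a counter-derived 32-bit seed, so results are identical for
identical root seeds regardless of execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _clone_first_transform(t0, alpha, beta, mu2, horizon, cap):
    """First transformation time of a clone started at t0 with one cell.

    Returns (time, capped) with time = inf when the clone goes extinct or
    reaches the horizon first; capped = True when the population hit the
    cap (the clone is then abandoned without transforming).
    """
    n = 1
    t = t0
    total_per_cell = alpha + beta + mu2
    while n > 0:
        t += np.random.exponential(1.0 / (n * total_per_cell))
        if t >= horizon:
            return np.inf, False
        u = np.random.random() * total_per_cell
        if u < mu2:
            return t, False
        elif u < mu2 + alpha:
            n += 1
            if n >= cap:
                return np.inf, True
        else:
            n -= 1
    return np.inf, False


@njit(cache=True)
def first_transform_times(fd_ages, seeds, mu1, alpha, beta, mu2, max_age, cap):
    """First malignant-transformation age per subject, given FD onset ages.

    Clone initiations arrive at rate ``mu1`` after the FD onset; clones
    initiated after the current earliest transformation cannot matter and
    are pruned. Subjects with no transformation before ``max_age`` get inf.
    Returns (times, n_cap_events).
    """
    n = fd_ages.shape[0]
    out = np.full(n, np.inf)
    n_capped = 0
    if mu1 <= 0.0:
        return out, n_capped
    for i in range(n):
        if not np.isfinite(fd_ages[i]):
            continue
        np.random.seed(seeds[i])
        best = np.inf
        t = fd_ages[i]
        while True:
            t += np.random.exponential(1.0 / mu1)
            horizon = best if best < max_age else max_age
            if t >= horizon:
                break
            ft, capped = _clone_first_transform(t, alpha, beta, mu2, horizon, cap)
            if capped:
                n_capped += 1
            if ft < best:
                best = ft
        out[i] = best
    return out, n_capped


@njit(cache=True)
def clone_outcomes(n_clones, seed, alpha, beta, mu2, horizon, cap):
    """Simulate independent clones from t=0; returns first-transform times
    (inf = extinct or alive without transformation by the horizon) and a
    flag for clones still alive at the horizon. Used for engine checks
    (e.g. extinction probability beta/alpha when mu2 ~ 0)."""
    np.random.seed(seed)
    times = np.empty(n_clones)
    alive = np.zeros(n_clones, dtype=np.bool_)
    for i in range(n_clones):
        n = 1
        t = 0.0
        total_per_cell = alpha + beta + mu2
        ft = np.inf
        while n > 0:
            t += np.random.exponential(1.0 / (n * total_per_cell))
            if t >= horizon:
                alive[i] = True
                break
            u = np.random.random() * total_per_cell
            if u < mu2:
                ft = t
                break
            elif u < mu2 + alpha:
                n += 1
                if n >= cap:
                    alive[i] = True
                    break
            else:
                n -= 1
        times[i] = ft
    return times, alive
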