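"""Two-boundary drift-diffusion model for Go/NoGo decisions.

The decision on each trial is modelled as a Wiener process with unit noise
scale starting at ``z * a`` between an upper boundary ``a`` (overt response,
"respond") and a lower boundary 0 ("withhold"). Go trials accumulate with a
positive drift ``v_go``; NoGo trials with a negative drift ``v_nogo``, so
that the correct outcome on each trial type corresponds to a different
boundary. Observed reaction time is the first-passage time plus a
non-decision time ``t_nd`` (stimulus encoding + motor execution). A trial
with no upper-boundary crossing before the response deadline — whether the
process was absorbed at the lower boundary, still diffusing, or crossed too
late — is recorded as a withhold with no RT, matching how a Go/NoGo task
scores the absence of a button press.

The drift bias ``v_bias = |v_go| - |v_nogo|`` summarizes the net tilt of
evidence accumulation toward responding.

Fitting is non-hierarchical maximum likelihood per condition: upper-boundary
crossings contribute the first-passage density at their RT, withheld trials
the complementary probability mass of an upper crossing before the deadline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DDMParams",
    "DecisionOutcome",
    "DDMFit",
    "simulate_ddm_trial",
    "simulate_ddm_trials",
    "prob_upper",
    "wfpt_density",
    "upper_cdf",
    "fit_ddm",
]


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion parameters for one condition.

    v_go : drift rate on Go trials (1/s, positive toward "respond")
    v_nogo : drift rate on NoGo trials (1/s, negative)
    a : boundary separation (evidence units)
    z : relative start point in (0, 1), fraction of ``a``
    t_nd : non-decision time (s)
    """

    v_go: float
    v_nogo: float
    a: float
    z: float
    t_nd: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0 < self.z < 1:
            raise ValueError("relative start point z must be in (0, 1)")
        if self.t_nd < 0:
            raise ValueError("non-decision time must be >= 0")

    @property
    def v_bias(self) -> float:
        """Drift bias: |v_go| - |v_nogo| (derived, never stored)."""
        return abs(self.v_go) - abs(self.v_nogo)

    def drift(self, trial_type: str) -> float:
        if trial_type == "go":
            return self.v_go
        if trial_type == "nogo":
            return self.v_nogo
        raise ValueError(f"trial_type must be 'go' or 'nogo', got {trial_type!r}")


@dataclass(frozen=True)
class DecisionOutcome:
    boundary: str            # "respond" | "withhold"
    rt_s: float | None       # None when no response was emitted
    trial_type: str


@dataclass
class DDMFit:
    params: DDMParams
    loglik: float
    converged: bool
    n_trials: int


# ---------------------------------------------------------------------------
# closed-form choice probability
# ---------------------------------------------------------------------------

def prob_upper(v: float, a: float, z: float) -> float:
    """P(upper-boundary absorption) for drift v, separation a, start z·a.

    Classic gambler's-ruin limit of the Wiener process with unit noise:
    (1 - exp(-2 v a z)) / (1 - exp(-2 v a)); equals z when v = 0.
    """
    if a <= 0 or not 0 < z < 1:
        raise ValueError("require a > 0 and 0 < z < 1")
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return z
    return float(np.expm1(-x * z) / np.expm1(-x))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_ddm_trials(
    params: DDMParams,
    trial_type: str,
    n: int,
    deadline_s: float | np.ndarray,
    dt: float = 5e-4,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` trials by Euler–Maruyama; vectorized.

    Returns
    -------
    responded : bool array (n,)
        True where the upper boundary was hit and the response fell before
        the deadline.
    rt : float array (n,)
        Reaction time in seconds (first passage + t_nd); NaN for withholds.
    """
    if dt > 1e-3:
        raise ValueError("dt must be <= 1 ms for acceptable discretization bias")
    rng = np.random.default_rng(rng)
    deadline = np.broadcast_to(np.asarray(deadline_s, dtype=float), (n,))
    if np.any(deadline <= params.t_nd):
        raise ValueError("deadline must exceed the non-decision time")
    v = params.drift(trial_type)

    x = np.full(n, params.z * params.a)
    alive = np.ones(n, dtype=bool)
    fpt = np.full(n, np.nan)
    hit_upper = np.zeros(n, dtype=bool)
    max_decision = deadline - params.t_nd
    n_steps = int(np.ceil(max_decision.max() / dt))
    sqdt = np.sqrt(dt)

    a = params.a
    for step in range(1, n_steps + 1):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        x_old = x[idx]
        x_new = x_old + v * dt + sqdt * rng.standard_normal(idx.size)
        x[idx] = x_new
        t_now = step * dt
        up = x_new >= a
        down = x_new <= 0.0
        # Brownian-bridge correction: probability of an unobserved boundary
        # excursion between grid points; removes the O(sqrt(dt)) bias of
        # naive Euler first-passage detection.
        interior = ~(up | down)
        if interior.any():
            xo, xn = x_old[interior], x_new[interior]
            p_up = np.exp(-2.0 * (a - xo) * (a - xn) / dt)
            p_dn = np.exp(-2.0 * xo * xn / dt)
            r = rng.random(xo.size)
            bridge_up = r < p_up
            bridge_dn = (~bridge_up) & (r < p_up + p_dn)
            ii = np.nonzero(interior)[0]
            up[ii[bridge_up]] = True
            down[ii[bridge_dn]] = True
        done = up | down
        if done.any():
            j = idx[done]
            fpt[j] = t_now
            hit_upper[j] = up[done]
            alive[j] = False
        # trials whose decision window has elapsed are censored
        expired = alive & (t_now >= max_decision)
        alive[expired] = False

    rt = fpt + params.t_nd
    responded = hit_upper & (rt <= deadline)
    rt = np.where(responded, rt, np.nan)
    return responded, rt


def simulate_ddm_trial(
    params: DDMParams,
    trial_type: str,
    deadline_s: float,
    dt: float = 5e-4,
    seed: np.random.Generator | int | None = None,
) -> DecisionOutcome:
    """Simulate a single Go/NoGo trial."""
    responded, rt = simulate_ddm_trials(params, trial_type, 1, deadline_s, dt, seed)
    if responded[0]:
        return DecisionOutcome("respond", float(rt[0]), trial_type)
    return DecisionOutcome("withhold", None, trial_type)


# ---------------------------------------------------------------------------
# first-passage density (standard small-time / large-time series)
# ---------------------------------------------------------------------------

def _f_lower_normalized(tt: np.ndarray, w: float, err: float = 1e-10) -> np.ndarray:
    """Lower-boundary first-passage density for v=0, a=1, start w, at
    normalized times ``tt``; series representation with automatic choice
    between the small-time and large-time expansions per element."""
    tt = np.asarray(tt, dtype=float)
    out = np.zeros_like(tt)
    pos = tt > 0
    t = tt[pos]
    if t.size == 0:
        return out

    # number of terms each expansion needs for error < err
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(2.0 * err * np.sqrt(2.0 * np.pi * t)), 0.0))
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * t) * err < 1.0,
                      np.maximum(ks, np.sqrt(t) + 1.0), 2.0)
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * t * err), 0.0) / (np.pi**2 * t))
        kl = np.where(np.pi * t * err < 1.0,
                      np.maximum(kl, 1.0 / (np.pi * np.sqrt(t))),
                      1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    dens = np.empty_like(t)

    if use_small.any():
        ts = t[use_small]
        K = int(np.ceil(ks[use_small].max()))
        k = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 1)
        arg = w + 2.0 * k[None, :]
        dens_s = (arg * np.exp(-(arg**2) / (2.0 * ts[:, None]))).sum(axis=1)
        dens[use_small] = dens_s / np.sqrt(2.0 * np.pi * ts**3)
    if (~use_small).any():
        tl = t[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        k = np.arange(1, K + 1)
        dens_l = (k[None, :] * np.exp(-(k[None, :]**2) * np.pi**2 * tl[:, None] / 2.0)
                  * np.sin(k[None, :] * np.pi * w)).sum(axis=1)
        dens[~use_small] = np.pi * dens_l

    out[pos] = np.maximum(dens, 0.0)
    return out


def wfpt_density(
    t: float | np.ndarray,
    params: DDMParams,
    trial_type: str = "go",
    boundary: str = "respond",
) -> np.ndarray:
    """First-passage time density at the given boundary, in 1/s.

    ``t`` is measured from stimulus onset; density is zero for
    ``t <= t_nd``. The densities of the two boundaries jointly integrate
    to one over (t_nd, ∞).
    """
    if boundary not in ("respond", "withhold"):
        raise ValueError("boundary must be 'respond' or 'withhold'")
    v = params.drift(trial_type)
    a, w, t_nd = params.a, params.z, params.t_nd
    if boundary == "respond":      # upper boundary == lower boundary of mirrored process
        v, w = -v, 1.0 - w
    t = np.atleast_1d(np.asarray(t, dtype=float))
    td = t - t_nd
    out = np.zeros_like(td)
    ok = td > 0
    if ok.any():
        tt = td[ok] / a**2
        base = _f_lower_normalized(tt, w)
        out[ok] = base / a**2 * np.exp(-v * a * w - v**2 * td[ok] / 2.0)
    return out


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)


def upper_cdf(T: float, params: DDMParams, trial_type: str = "go") -> float:
    """P(upper-boundary crossing with RT <= T); Gauss–Legendre quadrature."""
    if T <= params.t_nd:
        return 0.0
    lo, hi = params.t_nd, T
    x = 0.5 * (hi - lo) * _GL_NODES + 0.5 * (hi + lo)
    fx = wfpt_density(x, params, trial_type, "respond")
    return float(0.5 * (hi - lo) * (_GL_WEIGHTS * fx).sum())


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

_BOUNDS = [(0.05, 8.0),      # v_go
           (-8.0, -0.05),    # v_nogo
           (0.3, 4.0),       # a
           (0.05, 0.95),     # z
           (0.01, 0.8)]      # t_nd


def _neg_loglik(theta: np.ndarray, data: Mapping) -> float:
    try:
        p = DDMParams(*theta)
    except ValueError:
        return 1e12
    nll = 0.0
    for tt in ("go", "nogo"):
        rts = data[f"rt_{tt}"]
        if rts.size:
            if p.t_nd >= rts.min():
                return 1e12
            dens = wfpt_density(rts, p, tt, "respond")
            nll -= np.log(np.maximum(dens, 1e-12)).sum()
        for deadline, count in data[f"withheld_{tt}"]:
            if deadline <= p.t_nd:
                continue  # withhold certain: zero contribution
            mass = 1.0 - upper_cdf(deadline, p, tt)
            nll -= count * np.log(max(mass, 1e-12))
    return float(nll)


def _prepare(trials: pd.DataFrame) -> dict:
    data: dict = {}
    for tt in ("go", "nogo"):
        sub = trials[trials["trial_type"] == tt]
        resp = sub[sub["responded"].astype(bool)]
        data[f"rt_{tt}"] = resp["rt_s"].to_numpy(dtype=float)
        wh = sub[~sub["responded"].astype(bool)]
        if len(wh):
            # withheld trials grouped by deadline (5 ms grid) so the
            # censoring integral is evaluated once per group
            dl = np.round(wh["deadline_s"].to_numpy(dtype=float) / 0.005) * 0.005
            uniq, counts = np.unique(dl, return_counts=True)
            data[f"withheld_{tt}"] = list(zip(uniq, counts))
        else:
            data[f"withheld_{tt}"] = []
    return data


def fit_ddm(
    trials: pd.DataFrame,
    condition: str | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> dict[str, DDMFit] | DDMFit:
    """Fit DDM parameters by maximum likelihood.

    Parameters
    ----------
    trials : DataFrame
        Columns ``trial_type`` ('go'/'nogo'), ``responded`` (bool),
        ``rt_s`` (s, NaN for withholds), ``deadline_s`` (s).
    condition : str, optional
        Column name; when given, one independent fit per level is returned
        as a dict keyed by level.
    n_restarts : int
        Bounded quasi-Newton restarts from random interior points; the best
        log-likelihood wins.

    Notes
    -----
    Both trial types must be present — v_go and v_nogo are only identified
    by their own trials.
    """
    if condition is not None:
        return {lev: fit_ddm(sub, None, n_restarts, seed)
                for lev, sub in trials.groupby(condition, sort=True)}

    if not trials["responded"].any():
        raise ValueError("cannot fit: no responses at all")
    for tt in ("go", "nogo"):
        if not (trials["trial_type"] == tt).any():
            raise ValueError(f"cannot fit: no {tt} trials")

    data = _prepare(trials)
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in _BOUNDS])
    hi = np.array([b[1] for b in _BOUNDS])
    starts = [np.array([2.0, -2.0, 1.5, 0.5, 0.25])]
    min_rt = min((data["rt_go"].min() if data["rt_go"].size else np.inf),
                 (data["rt_nogo"].min() if data["rt_nogo"].size else np.inf))
    for _ in range(n_restarts - 1):
        s = lo + (hi - lo) * rng.uniform(0.1, 0.9, size=5)
        s[4] = min(s[4], 0.8 * min_rt)
        starts.append(s)

    best = None
    for s in starts:
        res = optimize.minimize(_neg_loglik, s, args=(data,), method="L-BFGS-B",
                                bounds=_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
    params = DDMParams(*best.x)
    return DDMFit(params=params, loglik=-float(best.fun),
                  converged=bool(best.success), n_trials=len(trials))
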