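"""Freidlin-Wentzell minimum action paths for noise-induced ER switching.

On the chemical-Langevin (diffusion) approximation of the slow ER dynamics,
the probability of a fluctuation path phi(tau) scales as exp(-Y * A[phi]) with

    A[phi] = 1/2 int (phid - b)^T D^{-1} (phid - b) dtau,

where b(x) = sum_k nu_k w_k(x) is the macroscopic drift and
D(x) = sum_k nu_k nu_k^T w_k(x) the diffusion matrix assembled from the
intensive channel rates w_k.  The minimum S of A over paths joining two
stable fixed points (and over the transit time) sets the exponential scale of
the mean switching time, tau_s = C * exp(Y * S); the prefactor C is estimated
separately by direct simulation at small system sizes.

The ER action is minimised in the two independent slow coordinates (m, a)
with enzymes eliminated by the Briggs-Haldane quasi-steady state, over
interior knots of a midpoint-discretised path, with an outer golden-section
search over the total transit time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .er_model import ERParams
from .ssa import estimate_transition_times, spawn_seeds

__all__ = [
    "DriftDiffusion",
    "MAPResult",
    "SwitchingEstimate",
    "cle_drift_diffusion",
    "er_drift_diffusion",
    "er_params_at_size",
    "fw_action",
    "fw_action_gradient",
    "minimize_action",
    "estimate_prefactor",
]


@dataclass(frozen=True)
class DriftDiffusion:
    """Drift field b(x) and diagonal diffusion field D(x) on a box domain.

    ``b`` and ``D`` must be vectorised over leading axes; ``D`` returns the
    diagonal entries (the ER slow channels perturb m and a independently, so
    the diffusion matrix is diagonal; cross-terms would need a full-matrix
    variant).
    """

    b: Callable[[np.ndarray], np.ndarray]
    D: Callable[[np.ndarray], np.ndarray]
    dim: int
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None


def cle_drift_diffusion(x: np.ndarray, rates: Callable, stoich: np.ndarray):
    """Generic chemical-Langevin assembly: b = nu^T w, D = nu^T diag(w) nu.

    ``rates(x)`` returns the channel rates w_k (vectorised over leading axes),
    ``stoich`` is (n_channels, dim).  Returns (b, D_full).
    """
    w = np.asarray(rates(x))
    b = w @ stoich
    D = np.einsum("...k,kd,ke->...de", w, stoich, stoich)
    return b, D


def _er_channel_rates(params: ERParams):
    """Intensive rates of the four slow ER channels at fractions (m, a).

    Channels: methylation (+m), enzymatic demethylation (-m), acetylation
    (+a), enzymatic deacetylation (-a); enzymes at Briggs-Haldane QSSA.
    """
    c = params.c
    Y = params.n_sites

    def rates(x):
        x = np.asarray(x, dtype=float)
        m = x[..., 0]
        a = x[..., 1]
        u = np.maximum(1.0 - m - a, 1e-12)
        g = (c[0] + c[3] * a * Y) * m * Y
        r = c[1] + c[2] + c[4] + c[5]
        y5 = params.e_hdm * g / np.maximum(g + r, 1e-300)
        h = (c[8] + c[11] * m * Y) * a * Y
        s = c[9] + c[10] + c[12] + c[13]
        y7 = params.e_hdac * h / np.maximum(h + s, 1e-300)
        w = np.empty(x.shape[:-1] + (4,))
        w[..., 0] = (c[6] + c[7] * m * Y) * u
        w[..., 1] = (c[2] + c[5]) * y5 / Y
        w[..., 2] = (c[14] + c[15] * a * Y) * u
        w[..., 3] = (c[10] + c[13]) * y7 / Y
        return w

    return rates


_ER_STOICH = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])


def er_drift_diffusion(params: ERParams) -> DriftDiffusion:
    """CLE drift/diffusion of the reduced (m, a) ER dynamics."""
    rates = _er_channel_rates(params)

    def b(x):
        w = rates(x)
        return w @ _ER_STOICH

    def D(x):
        w = rates(x)
        return np.stack([w[..., 0] + w[..., 1], w[..., 2] + w[..., 3]], axis=-1)

    eps = 1e-9
    return DriftDiffusion(
        b=b, D=D, dim=2,
        lower=np.array([eps, eps]), upper=np.array([1.0 - eps, 1.0 - eps]),
    )


def er_params_at_size(params: ERParams, n_sites: int) -> ERParams:
    """Rescale an ER system to a different site count Y at fixed macroscopic law.

    The standard system-size family: rates bimolecular in site counts
    (channels 4, 8, 12, 16 and the unrecruited enzyme bindings 1, 9) scale
    with the inverse powers of Y that keep the intensive channel rates fixed,
    and enzyme totals scale proportionally to Y.  Switching times along this
    family follow tau_s = C * exp(Y * S).
    """
    Y0 = params.n_sites
    Y = int(n_sites)
    f = Y0 / Y
    c = params.c.copy()
    c[[0, 8]] *= f          # c1, c9: enzyme x substrate
    c[[7, 15]] *= f         # c8, c16: substrate x substrate
    c[[3, 11]] *= f * f     # c4, c12: enzyme x substrate x modifier
    return replace(
        params,
        c=c,
        n_sites=Y,
        e_hdm=max(1, round(params.e_hdm / f)),
        e_hdac=max(1, round(params.e_hdac / f)),
    )


# ---------------------------------------------------------------------------
# action functional
# ---------------------------------------------------------------------------

def _segment_quantities(path: np.ndarray, times: np.ndarray, dd: DriftDiffusion, reg: float):
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("knot times must be strictly increasing")
    mid = 0.5 * (path[:-1] + path[1:])
    v = (path[1:] - path[:-1]) / dt[:, None]
    b = dd.b(mid)
    D = np.maximum(dd.D(mid), reg)
    return dt, mid, v, b, D


def fw_action(path: np.ndarray, times: np.ndarray, dd: DriftDiffusion, reg: float = 1e-10) -> float:
    """Midpoint-discretised Freidlin-Wentzell action of a path.

    Zero (to discretisation error) on any forward deterministic trajectory;
    non-finite integrands raise with the offending segment index.
    """
    dt, _, v, b, D = _segment_quantities(np.asarray(path, float), np.asarray(times, float), dd, reg)
    integrand = 0.5 * np.sum((v - b) ** 2 / D, axis=-1)
    if not np.all(np.isfinite(integrand)):
        bad = int(np.nonzero(~np.isfinite(integrand))[0][0])
        raise FloatingPointError(f"non-finite action integrand at segment {bad}")
    return float(np.sum(integrand * dt))


def _field_jacobians(mid: np.ndarray, dd: DriftDiffusion, h: float = 1e-7):
    """Central-difference Jacobians of b and D at the segment midpoints."""
    d = dd.dim
    Jb = np.empty(mid.shape[:-1] + (d, d))   # Jb[..., i, j] = db_i/dx_j
    JD = np.empty(mid.shape[:-1] + (d, d))   # JD[..., i, j] = dD_i/dx_j
    for j in range(d):
        dp = np.zeros(d)
        dp[j] = h
        Jb[..., j] = (dd.b(mid + dp) - dd.b(mid - dp)) / (2 * h)
        JD[..., j] = (dd.D(mid + dp) - dd.D(mid - dp)) / (2 * h)
    return Jb, JD


def fw_action_gradient(path: np.ndarray, times: np.ndarray, dd: DriftDiffusion, reg: float = 1e-10):
    """(action, d action / d path) with field derivatives by central differences."""
    path = np.asarray(path, float)
    times = np.asarray(times, float)
    dt, mid, v, b, D = _segment_quantities(path, times, dd, reg)
    r = v - b
    integrand = 0.5 * np.sum(r**2 / D, axis=-1)
    action = float(np.sum(integrand * dt))

    Jb, JD = _field_jacobians(mid, dd)
    p = r / D * dt[:, None]                       # dA/dv_i per segment
    # dA/dmid = -Jb^T p - 0.5 * (r^2 / D^2)^T JD * dt
    gmid = -np.einsum("sij,si->sj", Jb, p) - 0.5 * np.einsum(
        "si,sij->sj", (r**2 / D**2) * dt[:, None], JD
    )
    grad = np.zeros_like(path)
    dv = p / dt[:, None]                          # dA/dx via v: -dv at left, +dv at right
    grad[:-1] -= dv
    grad[1:] += dv
    grad[:-1] += 0.5 * gmid
    grad[1:] += 0.5 * gmid
    return action, grad


# ---------------------------------------------------------------------------
# minimisation
# ---------------------------------------------------------------------------

@dataclass
class MAPResult:
    """Optimal switching path and its action."""

    path: np.ndarray
    times: np.ndarray
    action: float
    converged: bool
    total_time: float
    diagnostics: dict

    def __post_init__(self):
        if self.action < -1e-12:
            raise ValueError("action must be non-negative")


def _minimize_fixed_T(dd, start, end, T, n_points, x_init, reg, maxiter):
    times = np.linspace(0.0, T, n_points)
    d = dd.dim

    def pack(path):
        return path[1:-1].ravel()

    def unpack(z):
        path = np.empty((n_points, d))
        path[0] = start
        path[-1] = end
        path[1:-1] = z.reshape(n_points - 2, d)
        return path

    def fun(z):
        a, g = fw_action_gradient(unpack(z), times, dd, reg)
        return a, g[1:-1].ravel()

    bounds = None
    if dd.lower is not None:
        lo = np.tile(dd.lower, n_points - 2)
        hi = np.tile(dd.upper, n_points - 2)
        bounds = list(zip(lo, hi))
    res = minimize(fun, pack(x_init), jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10})
    return unpack(res.x), times, float(res.fun), res


def minimize_action(
    dd: DriftDiffusion,
    start: np.ndarray,
    end: np.ndarray,
    n_points: int = 64,
    total_time: float | None = None,
    t_range: tuple[float, float] = (2.0, 2000.0),
    reg: float = 1e-10,
    maxiter: int = 600,
) -> MAPResult:
    """Minimum-action path between two fixed points.

    With ``total_time=None`` the transit time is optimised as well, by a
    golden-section search on log T (the action is unimodal in T in practice:
    too-short paths pay for speed, too-long paths pay for loitering only at
    the endpoints once the path passes near the saddle).
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    if start.shape != (dd.dim,) or end.shape != (dd.dim,):
        raise ValueError("endpoint dimension mismatch")
    if np.allclose(start, end):
        times = np.linspace(0.0, 1.0, n_points)
        path = np.tile(start, (n_points, 1))
        return MAPResult(path=path, times=times, action=0.0, converged=True,
                         total_time=1.0, diagnostics={"note": "coincident endpoints"})

    straight = start[None, :] + np.linspace(0, 1, n_points)[:, None] * (end - start)[None, :]
    if dd.lower is not None:
        straight = np.clip(straight, dd.lower, dd.upper)

    cache: dict[float, tuple] = {}

    warm = {"path": straight}

    def eval_T(T):
        Tq = float(T)
        if Tq in cache:
            return cache[Tq][2]
        path, times, a, res = _minimize_fixed_T(dd, start, end, Tq, n_points, warm["path"], reg, maxiter)
        cache[Tq] = (path, times, a, res)
        warm["path"] = path
        return a

    if total_time is not None:
        eval_T(total_time)
        path, times, a, res = cache[float(total_time)]
        ok = bool(res.success or res.status == 1)
        return MAPResult(path=path, times=times, action=a, converged=ok,
                         total_time=float(total_time),
                         diagnostics={"nit": res.nit, "message": str(res.message)})

    # golden section on log T
    lo, hi = np.log(t_range[0]), np.log(t_range[1])
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - gr * (hi - lo)
    x2 = lo + gr * (hi - lo)
    f1, f2 = eval_T(np.exp(x1)), eval_T(np.exp(x2))
    for _ in range(18):
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - gr * (hi - lo)
            f1 = eval_T(np.exp(x1))
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + gr * (hi - lo)
            f2 = eval_T(np.exp(x2))
    Tbest = float(np.exp(x1 if f1 <= f2 else x2))
    path, times, a, res = cache[Tbest]
    ok = bool(res.success or res.status == 1)
    return MAPResult(path=path, times=times, action=a, converged=ok, total_time=Tbest,
                     diagnostics={"nit": res.nit, "message": str(res.message),
                                  "n_T_evals": len(cache)})


def er_minimum_action(params: ERParams, direction: str = "open", **kwargs) -> MAPResult:
    """Minimum action of the closed->open ('open') or open->closed ('close')
    switch of one ER system, between its mean-field attractors."""
    from .er_model import find_er_attractors

    att = find_er_attractors(params)
    if att.shape[0] < 2:
        raise ValueError("ER system is not bistable")
    closed, opened = att[0], att[-1]
    dd = er_drift_diffusion(params)
    if direction == "open":
        return minimize_action(dd, closed, opened, **kwargs)
    if direction == "close":
        return minimize_action(dd, opened, closed, **kwargs)
    raise ValueError("direction must be 'open' or 'close'")


# ---------------------------------------------------------------------------
# prefactor estimation
# ---------------------------------------------------------------------------

@dataclass
class SwitchingEstimate:
    """Exponential switching law tau_s = C * exp(Y * S) fitted from simulation."""

    S: float                  # slope of ln tau on Y
    C: float                  # prefactor (time units)
    se_S: float
    se_lnC: float
    Y_values: np.ndarray
    tau_values: np.ndarray

    def tau_s(self, Y: float) -> float:
        return self.C * np.exp(Y * self.S)


def estimate_prefactor(
    params: ERParams,
    Y_values,
    n_events: int = 20,
    seed: int = 0,
    direction: str = "open",
    t_max_per_passage: float = 1e6,
) -> SwitchingEstimate:
    """Fit ln tau(Y) = ln C + S * Y from direct SSA switching at small sizes.

    The ER system is rescaled to each Y along the fixed-macroscopic-law
    family (`er_params_at_size`); the slope cross-checks the minimised
    action, the intercept supplies the prefactor C.
    """
    Y_values = np.asarray(list(Y_values), dtype=int)
    if Y_values.size < 3:
        raise ValueError("need at least 3 system sizes to regress")
    seeds = spawn_seeds(seed, Y_values.size)
    taus = []
    for Y, s in zip(Y_values, seeds):
        p = er_params_at_size(params, int(Y))
        # nearest-count 85%/15% bands: size-consistent relative thresholds
        tt = estimate_transition_times(p, n_events=n_events, seed=int(s),
                                       t_max_per_passage=t_max_per_passage,
                                       open_fraction=0.85, closed_fraction=0.15)
        tau = tt.tau_open if direction == "open" else tt.tau_close
        if not np.isfinite(tau):
            raise RuntimeError(f"no switching observed at Y={Y} within budget")
        taus.append(tau)
    taus = np.asarray(taus)
    X = np.stack([np.ones_like(Y_values, dtype=float), Y_values.astype(float)], axis=1)
    y = np.log(taus)
    coef, res_, rank_, sv_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(Y_values.size - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return SwitchingEstimate(
        S=float(coef[1]), C=float(np.exp(coef[0])),
        se_S=float(np.sqrt(cov[1, 1])), se_lnC=float(np.sqrt(cov[0, 0])),
        Y_values=Y_values, tau_values=taus,
    )
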