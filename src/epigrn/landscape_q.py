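"""Reprogramming probability Q of a DERS-PERS epigenetic landscape pair.

A pluripotency-locked landscape has the differentiation gene's ER system
closed and the pluripotency gene's open (D- P+).  Remodelling to the
differentiation-primed configuration D+ P- proceeds by one switch of each
system, along two routes: P closes first (D- P+ -> D- P- -> D+ P-) or D opens
first (D- P+ -> D+ P+ -> D+ P-).  Holding times in each ER state are
exponential with means tau1+/- (DERS closed->open / open->closed) and tau2+/-
(PERS analogues); the two systems evolve independently, a simultaneous switch
is neglected, and a route is abandoned if the intermediate state reverts
before completing (no back-switching).  The waiting-time density of the
direct transition is then a normalised two-route competition mixture,

    P(tau) = Z^{-1} (P1(tau) + P2(tau)),

each route density being a competition-weighted convolution of two
exponentials, with Z fixed by normalisation (equivalently: the density of the
arrival time conditioned on a direct route).  Q(tau_P) is its integral over
(0, tau_P]; pairs with Q >= T (default T = 0.7) are differentiation-primed,
the rest pluripotency-locked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SwitchRates",
    "QResult",
    "transition_pdf",
    "q_probability",
    "q_mc_oracle",
    "q_mc_full_ctmc",
    "classify_pairs",
    "PRIMED_THRESHOLD",
]

PRIMED_THRESHOLD = 0.7


@dataclass(frozen=True)
class SwitchRates:
    """Mean ER switching times of one DERS-PERS pair (all positive, finite)."""

    tau1_plus: float    # DERS closed -> open
    tau1_minus: float   # DERS open -> closed
    tau2_plus: float    # PERS closed -> open
    tau2_minus: float   # PERS open -> closed

    def __post_init__(self):
        for name in ("tau1_plus", "tau1_minus", "tau2_plus", "tau2_minus"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def rates(self):
        """(r1p, r1m, r2p, r2m): the four exponential switching rates."""
        return (1.0 / self.tau1_plus, 1.0 / self.tau1_minus,
                1.0 / self.tau2_plus, 1.0 / self.tau2_minus)


def _dexp(a: float, b: float, t: np.ndarray) -> np.ndarray:
    """(exp(-a t) - exp(-b t)) / (b - a), stable through b -> a.

    Symmetric in (a, b); the smaller exponent is factored out so the
    expression never overflows."""
    t = np.asarray(t, dtype=float)
    lo, hi = (a, b) if a <= b else (b, a)
    d = hi - lo
    x = d * t
    small = np.abs(x) < 1e-7
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp(-lo * t) * np.where(
            small,
            t * (1.0 - x / 2.0 + x * x / 6.0),
            (-np.expm1(-x)) / max(d, 1e-300),
        )
    return out


def _int_dexp(a: float, b: float, T: np.ndarray) -> np.ndarray:
    """int_0^T _dexp(a, b, t) dt, stable through b -> a."""
    T = np.asarray(T, dtype=float)

    def F(r):  # int_0^T exp(-r t) dt
        return np.where(T == np.inf, 1.0 / r, -np.expm1(-r * np.minimum(T, 1e306)) / r)

    if abs(b - a) > 1e-9 * max(a, b):
        return (F(a) - F(b)) / (b - a)
    # limit: int t exp(-a t) = (1 - (1 + aT) exp(-aT)) / a^2
    with np.errstate(over="ignore"):
        val = (1.0 - (1.0 + a * np.minimum(T, 1e306)) * np.exp(-a * np.minimum(T, 1e306))) / a**2
    return np.where(T == np.inf, 1.0 / a**2, val)


def _route_params(rates: SwitchRates):
    r1p, r1m, r2p, r2m = rates.rates
    # route 1: P closes first (against D opening), then D opens (against P reopening)
    a1, b1 = r1p + r2p, r1p + r2m
    # route 2: D opens first, then P closes (against D reclosing)
    a2, b2 = r1m + r2m, r1p + r2m
    amp = r1p * r2m
    return amp, (a1, b1), (a2, b2)


def transition_pdf(tau, rates: SwitchRates):
    """Normalised waiting-time density of the D- P+ -> D+ P- transition."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    amp, (a1, b1), (a2, b2) = _route_params(rates)
    Z = amp * (_int_dexp(a1, b1, np.inf) + _int_dexp(a2, b2, np.inf))
    dens = amp * (_dexp(a1, b1, tau) + _dexp(a2, b2, tau)) / Z
    return dens if dens.shape else float(dens)


def route_densities(tau, rates: SwitchRates):
    """Unnormalised sub-densities (P1, P2) of the two reprogramming routes."""
    tau = np.asarray(tau, dtype=float)
    amp, (a1, b1), (a2, b2) = _route_params(rates)
    return amp * _dexp(a1, b1, tau), amp * _dexp(a2, b2, tau)


@dataclass(frozen=True)
class QResult:
    """Reprogramming probability over a horizon, with its classification."""

    q: float
    tau_P: float
    method: str                      # 'closed_form' or 'monte_carlo'
    se: float | None = None
    threshold: float = PRIMED_THRESHOLD

    def __post_init__(self):
        if not -1e-12 <= self.q <= 1 + 1e-12:
            raise ValueError(f"Q out of [0, 1]: {self.q}")
        object.__setattr__(self, "q", float(min(max(self.q, 0.0), 1.0)))

    @property
    def classification(self) -> str:
        return "primed" if self.q >= self.threshold else "locked"


def q_probability(rates: SwitchRates, tau_P: float, threshold: float = PRIMED_THRESHOLD) -> QResult:
    """Closed-form Q(tau_P): the integral of `transition_pdf` over (0, tau_P].

    Monotone non-decreasing in tau_P, Q(0) = 0, Q(inf) = 1.
    """
    if tau_P < 0:
        raise ValueError("tau_P must be non-negative")
    amp, (a1, b1), (a2, b2) = _route_params(rates)
    Z = _int_dexp(a1, b1, np.inf) + _int_dexp(a2, b2, np.inf)
    q = float((_int_dexp(a1, b1, tau_P) + _int_dexp(a2, b2, tau_P)) / Z)
    return QResult(q=q, tau_P=float(tau_P), method="closed_form", threshold=threshold)


def q_mc_oracle(
    rates: SwitchRates,
    tau_P: float,
    n_runs: int = 100_000,
    seed: int = 0,
    threshold: float = PRIMED_THRESHOLD,
) -> QResult:
    """Monte-Carlo oracle for Q: independent two-state ER switches, restricted
    to direct routes (a single switch of each system, no back-switching).

    Stage 1 is the competition between the DERS opening and the PERS closing;
    stage 2 the completing switch in competition with the intermediate state's
    reversion.  Runs whose intermediate reverts are not direct and are
    excluded (Q conditions on direct remodelling, matching the closed form's
    normalisation).  Binomial standard error reported.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    r1p, r1m, r2p, r2m = rates.rates
    rng = np.random.default_rng(seed)
    t1 = rng.exponential(1.0 / (r1p + r2m), n_runs)
    d_first = rng.random(n_runs) < r1p / (r1p + r2m)
    # stage 2 competition: completing rate vs reversion rate
    comp = np.where(d_first, r2m, r1p)
    back = np.where(d_first, r1m, r2p)
    t2 = rng.exponential(1.0, n_runs) / (comp + back)
    direct = rng.random(n_runs) < comp / (comp + back)
    n_direct = int(direct.sum())
    if n_direct == 0:
        return QResult(q=0.0, tau_P=float(tau_P), method="monte_carlo", se=np.nan, threshold=threshold)
    arrival = t1[direct] + t2[direct]
    q = float(np.mean(arrival <= tau_P))
    se = float(np.sqrt(max(q * (1 - q), 1e-12) / n_direct))
    return QResult(q=q, tau_P=float(tau_P), method="monte_carlo", se=se, threshold=threshold)


def q_mc_full_ctmc(
    rates: SwitchRates,
    tau_P: float,
    n_runs: int = 100_000,
    seed: int = 0,
    threshold: float = PRIMED_THRESHOLD,
    max_flips: int = 100_000,
) -> QResult:
    """Secondary oracle: full 4-state first-passage WITH back-switching.

    Each ER system keeps flipping with its exponential holding times; the
    first arrival of the joint state at (D open, P closed) counts regardless
    of the route.  Deviations from the direct-route Q are expected and
    quantify the weight of indirect paths.
    """
    r1p, r1m, r2p, r2m = rates.rates
    rng = np.random.default_rng(seed)
    d_open = np.zeros(n_runs, dtype=bool)
    p_open = np.ones(n_runs, dtype=bool)
    t = np.zeros(n_runs)
    arrived = np.zeros(n_runs, dtype=bool)
    for _ in range(max_flips):
        active = ~arrived & (t <= tau_P)
        if not active.any():
            break
        rd = np.where(d_open, r1m, r1p)
        rp = np.where(p_open, r2m, r2p)
        tot = rd + rp
        t[active] += rng.exponential(1.0, int(active.sum())) / tot[active]
        flip_d = rng.random(n_runs) < rd / tot
        d_open = np.where(active & flip_d, ~d_open, d_open)
        p_open = np.where(active & ~flip_d, ~p_open, p_open)
        arrived |= active & d_open & ~p_open & (t <= tau_P)
    q = float(np.mean(arrived))
    se = float(np.sqrt(max(q * (1 - q), 1e-12) / n_runs))
    return QResult(q=q, tau_P=float(tau_P), method="monte_carlo", se=se, threshold=threshold)


def classify_pairs(
    ders_times: np.ndarray,
    pers_times: np.ndarray,
    threshold: float = PRIMED_THRESHOLD,
    tau_P: float | None = None,
) -> pd.DataFrame:
    """Q for every DERS x PERS pair of measured transition times.

    ``ders_times`` and ``pers_times`` are (n, 2) arrays of (tau+, tau-).
    The horizon defaults to the DERS-ensemble mean closed->open time.
    Pairs with non-finite times are skipped and reported with NaN Q.
    """
    ders_times = np.atleast_2d(np.asarray(ders_times, dtype=float))
    pers_times = np.atleast_2d(np.asarray(pers_times, dtype=float))
    finite_d = np.isfinite(ders_times).all(axis=1)
    if tau_P is None:
        if not finite_d.any():
            raise ValueError("no finite DERS opening times to set the horizon")
        tau_P = float(np.mean(ders_times[finite_d, 0]))
    rows = []
    for i, (t1p, t1m) in enumerate(ders_times):
        for j, (t2p, t2m) in enumerate(pers_times):
            if not all(np.isfinite([t1p, t1m, t2p, t2m])) or min(t1p, t1m, t2p, t2m) <= 0:
                rows.append((i, j, np.nan, "skipped"))
                continue
            res = q_probability(SwitchRates(t1p, t1m, t2p, t2m), tau_P, threshold)
            rows.append((i, j, res.q, res.classification))
    return pd.DataFrame(rows, columns=["ders_id", "pers_id", "Q", "classification"])
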