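"""Multiscale hybrid (piecewise-deterministic Markov) simulator.

The coupled ER-GRN model separates scales: TF monomers (scale S) outnumber
promoter binding sites (E), and chromatin modification sites (Y) outnumber
the histone-modifying enzymes (Z).  Exploiting S >> E and Y >> Z:

* bound-promoter counts and enzyme-substrate complexes are *fast* variables,
  sampled from their quasi-steady-state (QSSA) stationary laws conditioned on
  the slow state -- a product-form multinomial over promoter occupancies and
  binomial laws for the HDM.M / HDAC.A complexes;
* the slow ER site counts follow a Markov jump process whose six effective
  channels (un/recruited methylation and acetylation, enzymatic de-
  methylation and deacetylation) are simulated exactly by thinning a
  constant-bound Poisson proposal (complexes resampled at every proposal);
* TF monomer concentrations x_i follow an ODE between stochastic events,
  with sampled occupancies entering the synthesis and binding-loss terms and
  promoter accessibility gated by eta_i = H(y_i3 - y0).

Because regulation is one-way (chromatin gates transcription; TFs do not
modify chromatin), the per-gene ER jump processes can be generated first and
the GRN integrated through the resulting eta(t) signal; this is an exact
scheduler for the coupled PDMP.  The module also hosts the intervention
experiments: reprogramming strategies on blue-cluster DERSs and scans over
HDM/HDAC abundance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from . import er_model
from .er_model import ERParams, classify_regime, find_er_attractors
from .grn_model import GRNParams, find_steady_states
from .ssa import (DifferentiationCriterion, default_differentiation_criterion,
                  estimate_transition_times, first_dwell_time, spawn_seeds)

__all__ = [
    "HybridConfig",
    "HybridResult",
    "qssa_sample_promoters",
    "qssa_sample_complexes",
    "promoter_occupancy_pmf",
    "hybrid_run",
    "hybrid_differentiation_time",
    "reprogram_strategy",
    "hme_scan",
]


@dataclass(frozen=True)
class HybridConfig:
    """Numerical knobs of the hybrid scheme.

    ``resample_dt``: interval at which fast promoter occupancies are redrawn
    between ER events; it must not exceed the occupancy correlation time
    (of order E / (delta S)), otherwise the frozen samples inject excess
    low-frequency noise into the monomer dynamics -- `for_params` picks a
    safe value.  ``dt_ode``: RK4 step of the monomer ODE; ``epsilon``: the
    scale-separation bookkeeping parameter of the time-rescaled Poisson
    representation (kept explicit for sensitivity studies; the thinning
    scheduler is exact for any positive value, which rescales the slow-channel
    clock).
    """

    resample_dt: float = 0.02
    dt_ode: float = 0.02
    epsilon: float = 1.0
    max_er_events: int = 5_000_000
    check_scales: bool = True

    def __post_init__(self):
        if self.epsilon <= 0 or self.resample_dt <= 0 or self.dt_ode <= 0:
            raise ValueError("epsilon, resample_dt and dt_ode must be positive")

    @staticmethod
    def for_params(grn_params: GRNParams, safety: float = 2.0, **over) -> "HybridConfig":
        """Config with the resample interval tied to the promoter kinetics."""
        d_max = float(np.max(grn_params.d)) if np.max(grn_params.d) > 0 else 10.0
        dt = min(0.1, 1.0 / (safety * d_max))
        kw = dict(resample_dt=dt, dt_ode=min(0.02, dt / 2))
        kw.update(over)
        return HybridConfig(**kw)


def _warn_scales(er_params: list[ERParams], grn_params: GRNParams):
    Y = min(p.n_sites for p in er_params)
    Z = max(max(p.e_hdm, p.e_hdac) for p in er_params)
    if not (grn_params.S > grn_params.E):
        warnings.warn("scale assumption S >> E violated", stacklevel=3)
    if not (Y > Z):
        warnings.warn("scale assumption Y >> Z violated", stacklevel=3)


# ---------------------------------------------------------------------------
# QSSA samplers for the fast variables
# ---------------------------------------------------------------------------

def promoter_occupancy_pmf(
    x: np.ndarray, params: GRNParams, eta: np.ndarray, promoter: int, max_states: int = 20_000
):
    """Stationary law of promoter ``promoter``'s occupancy vector at fixed x.

    The binding/unbinding chain of dimers over the e_i exposed sites is
    reversible with product-form stationary distribution

        pi(n) propto  e! / (n_1! ... n_N! (e - sum n)!)  prod_j rho_j^{n_j},

    rho_j = eta_i k_ij x_j^2 (x in monomer-scale units, k = beta/delta).
    Returns (list of occupancy tuples, probabilities).
    """
    n = params.n_genes
    e_i = int(round(params.e[promoter]))
    x = np.asarray(x, dtype=float)
    rho = float(eta[promoter]) * params.k[promoter] * x**2
    states = [s for s in itertools.product(range(e_i + 1), repeat=n) if sum(s) <= e_i]
    if len(states) > max_states:
        raise ValueError(
            f"promoter occupancy state space has {len(states)} states; raise max_states"
        )
    w = np.empty(len(states))
    for si, s in enumerate(states):
        free = e_i - sum(s)
        coef = math.factorial(e_i) / (math.prod(math.factorial(v) for v in s) * math.factorial(free))
        w[si] = coef * math.prod(r**v for r, v in zip(rho, s))
    w /= w.sum()
    return states, w


def qssa_sample_promoters(
    x: np.ndarray, params: GRNParams, eta: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw the (n_genes, n_genes) bound-site matrix from the QSSA law.

    Row i is promoter i's occupancy by each dimer species; a closed promoter
    (eta_i = 0) is surely empty.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_genes
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        if eta[i] == 0:
            continue
        states, w = promoter_occupancy_pmf(x, params, eta, i)
        out[i] = states[rng.choice(len(states), p=w)]
    return out


def complex_count_pmf(n_enz: int, n_sub: int, kappa: float, r_exit: float) -> np.ndarray:
    """Stationary law of the enzyme-substrate complex count.

    Birth rate (n_enz - y)(n_sub - y) kappa, death r_exit * y, support
    0..min(n_enz, n_sub): the detailed-balance weights are enumerated exactly.
    Substrate depletion (complexed sites being unavailable) is built in; for
    n_sub >> n_enz the law approaches Binomial(n_enz, g/(g + r)) with
    g = kappa * n_sub, the Briggs-Haldane occupancy.
    """
    nmax = max(min(int(n_enz), int(np.floor(n_sub))), 0)
    w = np.zeros(nmax + 1)
    w[0] = 1.0
    if kappa > 0:
        for y in range(nmax):
            w[y + 1] = w[y] * (n_enz - y) * (n_sub - y) * kappa / (r_exit * (y + 1))
    return w / w.sum()


def qssa_sample_complexes(
    y_slow: np.ndarray, params: ERParams, seed: int | np.random.Generator
) -> tuple[int, int]:
    """Draw (Y5, Y7) enzyme-complex counts from their stationary QSSA laws.

    ``y_slow`` holds total mark counts, (M, A) or (M, U, A).  The HDM.M count
    is drawn first; the HDAC.A chain's recruitment then uses the free
    methylated count.  Supports are respected by construction (Y5 <= e_HDM,
    Y5 <= M; analogously for Y7).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = params.c
    y1 = int(y_slow[0])
    y3 = int(y_slow[-1]) if len(y_slow) == 2 else int(y_slow[2])
    r5 = c[1] + c[2] + c[4] + c[5]
    r7 = c[9] + c[10] + c[12] + c[13]
    # self-consistent means: each chain's recruitment reads the other's free marks
    m5 = m7 = 0.0
    for _ in range(8):
        pmf5 = complex_count_pmf(params.e_hdm, y1, c[0] + c[3] * max(y3 - m7, 0.0), r5)
        m5 = float(pmf5 @ np.arange(pmf5.size))
        pmf7 = complex_count_pmf(params.e_hdac, y3, c[8] + c[11] * max(y1 - m5, 0.0), r7)
        m7 = float(pmf7 @ np.arange(pmf7.size))
    y5 = int(rng.choice(pmf5.size, p=pmf5))
    pmf7 = complex_count_pmf(params.e_hdac, y3, c[8] + c[11] * max(y1 - y5, 0.0), r7)
    y7 = int(rng.choice(pmf7.size, p=pmf7))
    return y5, y7


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _complex_weights(n_enz, n_sub, kappa, r_exit, w):
    """Detailed-balance weights of the enzyme-substrate binding chain.

    Birth rate (n_enz - y)(n_sub - y) kappa, death rate r_exit * y, support
    y = 0..min(n_enz, floor(n_sub)).  Substrate depletion (a complexed site
    is unavailable) is built in; it matters at the default scales where Y/Z
    is only 3.  Returns (nmax, total weight); weights land in ``w``.
    """
    nmax = min(n_enz, int(np.floor(n_sub)))
    if nmax < 0:
        nmax = 0
    w[0] = 1.0
    tot = 1.0
    for y in range(nmax):
        if kappa <= 0.0:
            w[y + 1] = 0.0
        else:
            w[y + 1] = w[y] * (n_enz - y) * (n_sub - y) * kappa / (r_exit * (y + 1))
        tot += w[y + 1]
    return nmax, tot


@njit(cache=True)
def _complex_mean(n_enz, n_sub, kappa, r_exit, w):
    nmax, tot = _complex_weights(n_enz, n_sub, kappa, r_exit, w)
    m = 0.0
    for y in range(1, nmax + 1):
        m += y * w[y]
    return m / tot


@njit(cache=True)
def _sample_complex_count(n_enz, n_sub, kappa, r_exit, w):
    nmax, tot = _complex_weights(n_enz, n_sub, kappa, r_exit, w)
    u = np.random.random() * tot
    acc = 0.0
    for y in range(nmax + 1):
        acc += w[y]
        if acc >= u:
            return y
    return nmax


@njit(cache=True)
def _er_slow_kernel(c, Y, e_hdm, e_hdac, y1_0, y3_0, t_max, epsilon, max_events, seed):
    """Slow ER jump process over total mark counts (M, A) by exact thinning.

    The slow state counts marks whether free or enzyme-bound; complex counts
    are redrawn from their depletion-corrected stationary laws at every
    proposed event and the channel propensities use the resulting *free*
    counts.  The proposal bound replaces complexes by their maxima, so
    thinning is exact.  Returns event times, total M, total A and free A
    (the observable gating promoter accessibility) after each event.
    """
    np.random.seed(seed)
    r_exit5 = c[1] + c[2] + c[4] + c[5]
    r_exit7 = c[9] + c[10] + c[12] + c[13]
    k_dem = (c[2] + c[5]) / epsilon
    k_dea = (c[10] + c[13]) / epsilon
    times = np.empty(max_events)
    y1s = np.empty(max_events, np.int64)
    y3s = np.empty(max_events, np.int64)
    y3f = np.empty(max_events, np.int64)
    y1 = y1_0
    y3 = y3_0
    t = 0.0
    n = 0
    a = np.empty(6)
    wbuf = np.empty(max(e_hdm, e_hdac) + 1)
    while n < max_events:
        y2 = Y - y1 - y3
        lam = (c[6] + c[7] * y1) * y2 / epsilon + (c[14] + c[15] * y3) * y2 / epsilon \
            + k_dem * min(e_hdm, y1) + k_dea * min(e_hdac, y3)
        if lam <= 0.0:
            break
        t_prop = t + np.random.exponential(1.0 / lam)
        if t_prop > t_max:
            break
        t = t_prop
        # self-consistent cross-recruitment (each chain reads the other's free marks)
        m5 = 0.0
        m7 = 0.0
        for _ in range(6):
            af = y3 - m7 if y3 - m7 > 0.0 else 0.0
            m5 = _complex_mean(e_hdm, float(y1), c[0] + c[3] * af, r_exit5, wbuf)
            mf = y1 - m5 if y1 - m5 > 0.0 else 0.0
            m7 = _complex_mean(e_hdac, float(y3), c[8] + c[11] * mf, r_exit7, wbuf)
        af = y3 - m7 if y3 - m7 > 0.0 else 0.0
        y5 = _sample_complex_count(e_hdm, float(y1), c[0] + c[3] * af, r_exit5, wbuf)
        mf = float(y1 - y5)
        y7 = _sample_complex_count(e_hdac, float(y3), c[8] + c[11] * mf, r_exit7, wbuf)
        m_free = y1 - y5
        a_free = y3 - y7
        a[0] = c[6] * y2 / epsilon            # unrecruited methylation  U -> M
        a[1] = c[7] * m_free * y2 / epsilon   # recruited methylation
        a[2] = k_dem * y5                     # demethylation            M -> U
        a[3] = c[14] * y2 / epsilon           # unrecruited acetylation  U -> A
        a[4] = c[15] * a_free * y2 / epsilon  # recruited acetylation
        a[5] = k_dea * y7                     # deacetylation            A -> U
        atot = a[0] + a[1] + a[2] + a[3] + a[4] + a[5]
        u = np.random.random() * lam
        if u >= atot:
            continue  # thinned proposal
        acc = 0.0
        k = 0
        for k in range(6):
            acc += a[k]
            if acc >= u:
                break
        if k <= 1:
            y1 += 1
        elif k == 2:
            y1 -= 1
            y5 -= 1
        elif k <= 4:
            y3 += 1
        else:
            y3 -= 1
            y7 -= 1
        times[n] = t
        y1s[n] = y1
        y3s[n] = y3
        y3f[n] = y3 - y7
        n += 1
    return times[:n].copy(), y1s[:n].copy(), y3s[:n].copy(), y3f[:n].copy()


@njit(cache=True)
def _sample_occupancy_2g(e_i, rho1, rho2):
    """Draw (n1, n2) from the product-form promoter law for two dimer species."""
    total = 0.0
    # weights over n1 + n2 <= e_i
    w = np.zeros((e_i + 1, e_i + 1))
    for n1 in range(e_i + 1):
        for n2 in range(e_i + 1 - n1):
            coef = 1.0
            # multinomial coefficient e!/(n1! n2! free!)
            # computed iteratively to stay numba-friendly
            num = 1.0
            for v in range(e_i, e_i - n1 - n2, -1):
                num *= v
            den = 1.0
            for v in range(2, n1 + 1):
                den *= v
            for v in range(2, n2 + 1):
                den *= v
            coef = num / den
            w[n1, n2] = coef * rho1**n1 * rho2**n2
            total += w[n1, n2]
    u = np.random.random() * total
    acc = 0.0
    for n1 in range(e_i + 1):
        for n2 in range(e_i + 1 - n1):
            acc += w[n1, n2]
            if acc >= u:
                return n1, n2
    return 0, 0


@njit(cache=True)
def _grn_rhs_2g(x, occ, eta, R, w1, w2, beta, delta, e, E):
    """Reduced monomer ODE right-hand side with sampled occupancy (2 genes)."""
    out = np.empty(2)
    for i in range(2):
        val = R[i] + w1[i] * (occ[i, i] / E) - w2[i] * x[i]
        for j in range(2):
            free_j = (e[j] - occ[j, 0] - occ[j, 1]) / E
            val -= 2.0 * (beta[j, i] * eta[j] * free_j * x[i] * x[i] - delta[j, i] * occ[j, i] / E)
        out[i] = val
    return out


@njit(cache=True)
def _grn_pdmp_kernel(
    eta_times, eta_vals,               # (K,), (K, 2): eta from eta_times[k] onwards
    R, w1, w2, beta, delta, kmat, e, E,
    x0, sample_grid, resample_dt, dt_ode, seed,
):
    np.random.seed(seed)
    T = sample_grid.size
    xs = np.empty((T, 2))
    occs = np.zeros((T, 2, 2))
    x = x0.copy()
    t = 0.0
    k_eta = 0
    si = 0
    n_resamples = 0
    occ = np.zeros((2, 2))
    t_end = sample_grid[T - 1]
    while True:
        # record samples due at the current time (state *before* advancing)
        while si < T and sample_grid[si] <= t + 1e-12:
            xs[si, 0] = x[0]
            xs[si, 1] = x[1]
            occs[si, 0, 0] = occ[0, 0]
            occs[si, 0, 1] = occ[0, 1]
            occs[si, 1, 0] = occ[1, 0]
            occs[si, 1, 1] = occ[1, 1]
            si += 1
        if si >= T or t >= t_end:
            break
        # advance eta segment
        while k_eta + 1 < eta_times.size and eta_times[k_eta + 1] <= t:
            k_eta += 1
        eta = eta_vals[k_eta]
        # resample occupancies
        for i in range(2):
            if eta[i] == 0.0:
                occ[i, 0] = 0.0
                occ[i, 1] = 0.0
            else:
                rho1 = kmat[i, 0] * x[0] * x[0]
                rho2 = kmat[i, 1] * x[1] * x[1]
                n1, n2 = _sample_occupancy_2g(int(e[i]), rho1, rho2)
                occ[i, 0] = n1
                occ[i, 1] = n2
        n_resamples += 1
        # integrate to the next resample point / eta switch / sample / end
        t_next = t + resample_dt
        if k_eta + 1 < eta_times.size and eta_times[k_eta + 1] < t_next:
            t_next = eta_times[k_eta + 1]
        if si < T and sample_grid[si] < t_next:
            t_next = sample_grid[si]
        if t_next > t_end:
            t_next = t_end
        seg = t_next - t
        if seg <= 0.0:
            t = t_next + 1e-12
            continue
        n_steps = max(1, int(np.ceil(seg / dt_ode)))
        h = seg / n_steps
        for _ in range(n_steps):
            k1 = _grn_rhs_2g(x, occ, eta, R, w1, w2, beta, delta, e, E)
            x1 = x + 0.5 * h * k1
            k2 = _grn_rhs_2g(x1, occ, eta, R, w1, w2, beta, delta, e, E)
            x2 = x + 0.5 * h * k2
            k3 = _grn_rhs_2g(x2, occ, eta, R, w1, w2, beta, delta, e, E)
            x3 = x + h * k3
            k4 = _grn_rhs_2g(x3, occ, eta, R, w1, w2, beta, delta, e, E)
            for i in range(2):
                x[i] += (h / 6.0) * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i])
                if x[i] < 0.0:
                    x[i] = 0.0
        t = t_next
    return xs, occs, n_resamples


# ---------------------------------------------------------------------------
# the hybrid run
# ---------------------------------------------------------------------------

@dataclass
class HybridResult:
    """Sampled hybrid trajectory of the coupled system."""

    times: np.ndarray            # sample grid
    x: np.ndarray                # (T, 2) monomer concentrations (units of S)
    eta: np.ndarray              # (T, 2) open/closed indicators
    acetyl: np.ndarray           # (T, 2) total acetylated-site counts
    methyl: np.ndarray           # (T, 2) total methylated-site counts
    n_er_events: int
    n_resamples: int
    seed: int

    @property
    def n_stochastic_events(self) -> int:
        return self.n_er_events + self.n_resamples


def _eta_signal(er_params, times_list, y3_list, y3_init, t_max):
    """Merge per-gene acetylation jump processes into a joint eta(t) staircase."""
    n = len(er_params)
    thresholds = [p.y0 * p.n_sites for p in er_params]
    events = [(0.0, -1, 0)]
    for g in range(n):
        for t, y3 in zip(times_list[g], y3_list[g]):
            events.append((float(t), g, int(y3)))
    events.sort()
    y3_now = list(y3_init)
    ts, etas, y3s = [], [], []
    for t, g, y3 in events:
        if g >= 0:
            y3_now[g] = y3
        eta = tuple(1.0 if y3_now[i] >= thresholds[i] else 0.0 for i in range(n))
        if ts and ts[-1] == t:
            etas[-1] = eta
            y3s[-1] = tuple(y3_now)
        else:
            ts.append(t)
            etas.append(eta)
            y3s.append(tuple(y3_now))
    return np.asarray(ts), np.asarray(etas, dtype=float), np.asarray(y3s, dtype=float)


def hybrid_run(
    er_params: list[ERParams],
    grn_params: GRNParams,
    t_max: float,
    seed: int,
    config: HybridConfig | None = None,
    er_init: list[np.ndarray] | None = None,
    x_init: np.ndarray | None = None,
    sample_dt: float = 0.5,
) -> HybridResult:
    """Simulate the reduced coupled model (two genes) up to ``t_max``.

    ``er_init`` holds per-gene slow fractions (m, a); the default is the
    pluripotency-locked landscape (gene-1 ER closed, gene-2 ER open) with the
    GRN at its PSS.  The same seed reproduces the trajectory exactly.
    """
    config = config or HybridConfig()
    if grn_params.n_genes != 2:
        raise NotImplementedError("the hybrid integrator is implemented for two genes")
    if len(er_params) != 2:
        raise er_model.ConfigurationError("need one ER system per gene")
    if config.check_scales:
        _warn_scales(er_params, grn_params)

    seeds = spawn_seeds(seed, 3)
    if er_init is None:
        att1 = find_er_attractors(er_params[0])
        att2 = find_er_attractors(er_params[1])
        er_init = [att1[0], att2[-1]]   # gene 1 closed, gene 2 open
    if x_init is None:
        pss = [s for s in find_steady_states(grn_params, np.array([0.0, 1.0]))
               if s.stable and s.label == "PSS"]
        x_init = pss[0].q if pss else np.zeros(2)

    times_list, y1_list, y3_list = [], [], []
    y1_init, y3_init = [], []
    n_er_events = 0
    for g in range(2):
        p = er_params[g]
        y1_0 = int(round(er_init[g][0] * p.n_sites))
        y3_0 = int(round(er_init[g][1] * p.n_sites))
        ts, y1s, y3s, y3fs = _er_slow_kernel(
            p.c, p.n_sites, int(p.e_hdm), int(p.e_hdac),
            y1_0, y3_0, float(t_max), config.epsilon,
            config.max_er_events, int(seeds[g]),
        )
        times_list.append(ts)
        y1_list.append(y1s)
        y3_list.append(y3s)  # promoter accessibility reads total acetylation
        y1_init.append(y1_0)
        y3_init.append(y3_0)
        n_er_events += ts.size

    eta_t, eta_v, y3_v = _eta_signal(er_params, times_list, y3_list, y3_init, t_max)

    grid = np.arange(0.0, t_max + sample_dt / 2, sample_dt)
    xs, occs, n_resamples = _grn_pdmp_kernel(
        eta_t, eta_v,
        grn_params.R, grn_params.omega1, grn_params.omega2,
        grn_params.beta, grn_params.delta, grn_params.k,
        grn_params.e.astype(np.float64), float(grn_params.E),
        np.asarray(x_init, dtype=np.float64), grid,
        config.resample_dt, config.dt_ode, int(seeds[2]),
    )

    # eta and the slow mark counts resampled onto the grid
    idx = np.clip(np.searchsorted(eta_t, grid, side="right") - 1, 0, len(eta_t) - 1)
    methyl = np.empty((grid.size, 2))
    for g in range(2):
        series = np.concatenate([[y1_init[g]], y1_list[g]])
        tser = np.concatenate([[0.0], times_list[g]])
        gi = np.clip(np.searchsorted(tser, grid, side="right") - 1, 0, len(tser) - 1)
        methyl[:, g] = series[gi]
    return HybridResult(
        times=grid, x=xs, eta=eta_v[idx], acetyl=y3_v[idx], methyl=methyl,
        n_er_events=n_er_events, n_resamples=int(n_resamples), seed=int(seed),
    )


def hybrid_differentiation_time(
    er_params: list[ERParams],
    grn_params: GRNParams,
    seed: int,
    criterion: DifferentiationCriterion | None = None,
    t_max: float = 2000.0,
    config: HybridConfig | None = None,
    sample_dt: float = 0.5,
):
    """One tau_D sample from the hybrid scheme (pluripotency-locked start).

    The criterion thresholds are expressed in monomer counts; the hybrid
    x is in units of S, so they are divided by S.  Returns
    (tau_D, censored, n_stochastic_events).
    """
    if criterion is None:
        criterion = default_differentiation_criterion(grn_params)
    # chunked simulation: the slow state is Markov, so restarting each chunk
    # from the carried (M, A, x) state with a fresh stream is exact
    chunk_t = min(t_max, max(500.0, 40.0 * criterion.dwell, t_max / 25.0))
    n_chunks = int(np.ceil(t_max / chunk_t))
    seeds = spawn_seeds(seed, n_chunks)
    er_state = None
    x_state = None
    t0 = 0.0
    times_all: list[np.ndarray] = []
    ok_all: list[np.ndarray] = []
    n_events = 0
    for ci in range(n_chunks):
        t1 = min(t0 + chunk_t, t_max)
        res = hybrid_run(er_params, grn_params, t1 - t0, int(seeds[ci]), config,
                         er_init=er_state, x_init=x_state, sample_dt=sample_dt)
        n_events += res.n_stochastic_events
        ok = (res.x[:, 0] * grn_params.S >= criterion.x1_min) \
            & (res.x[:, 1] * grn_params.S <= criterion.x2_max)
        times_all.append(res.times + t0)
        ok_all.append(ok)
        tau = first_dwell_time(np.concatenate(times_all), np.concatenate(ok_all), criterion.dwell)
        if tau is not None:
            return tau, False, n_events
        # carry the slow state: total-mark fractions and monomer levels
        er_state = [
            np.array([res.methyl[-1, g], res.acetyl[-1, g]]) / er_params[g].n_sites
            for g in range(len(er_params))
        ]
        x_state = res.x[-1]
        t0 = t1
    return float(t_max), True, n_events


# ---------------------------------------------------------------------------
# intervention experiments
# ---------------------------------------------------------------------------

def reprogram_strategy(
    params: ERParams,
    strategy: str,
    factor: float = 4.0,
    cluster: str | None = None,
    measure: bool = False,
    seed: int = 0,
    n_events: int = 10,
) -> dict:
    """Kinetic intervention unlocking a pluripotency-locked DERS.

    ``two_step``: divide the unrecruited-deacetylation catalysis constant
    (channel 11) by ``factor``, then multiply the unrecruited-demethylation
    catalysis constant (channel 3) by ``factor``; ``one_step``: only the
    channel-3 increase.  Factor 1 returns the parameters unchanged.  With
    ``measure=True`` the modified system's (tau+, tau-) are re-measured by
    SSA.  The modified system is flagged when it is no longer bistable.
    """
    if strategy not in ("two_step", "one_step"):
        raise ValueError("strategy must be 'two_step' or 'one_step'")
    if cluster is not None and cluster != "blue":
        warnings.warn(f"reprogramming strategies target blue-cluster DERSs, got {cluster!r}")
    steps = {3: factor} if strategy == "one_step" else {11: 1.0 / factor, 3: factor}
    new = params.scaled(steps)
    out = {"params": new, "strategy": strategy, "factor": factor}
    try:
        out["regime"] = classify_regime(new)
    except er_model.NumericalFailureError:
        out["regime"] = "undetermined"
    out["bistable"] = out["regime"] == "bistable"
    if measure and out["bistable"]:
        tt = estimate_transition_times(new, n_events=n_events, seed=seed)
        out["times"] = tt
        out["tau_open"], out["tau_close"] = tt.tau_open, tt.tau_close
    return out


def hme_scan(
    ders_params: ERParams,
    pers_params: ERParams,
    grn_params: GRNParams,
    grid: list[tuple[float, float]],
    n_runs: int,
    seed: int,
    t_max: float = 2000.0,
    criterion: DifferentiationCriterion | None = None,
    config: HybridConfig | None = None,
    scale_both: bool = True,
):
    """Median/IQR of tau_D per (e_HDM, e_HDAC) condition (hybrid runs).

    The enzyme counts are applied to both genes' ER systems when
    ``scale_both``; the baseline (Z, Z) point must be part of the grid.
    Censored runs are counted separately and never enter the statistics.
    """
    import pandas as pd

    Z = ders_params.enzyme_scale
    if not any(int(a) == Z and int(b) == Z for a, b in grid):
        raise ValueError("the baseline point (Z, Z) must be included in the grid")
    if criterion is None:
        criterion = default_differentiation_criterion(grn_params)
    rows = []
    seeds = spawn_seeds(seed, len(grid))
    for (e_hdm, e_hdac), s in zip(grid, seeds):
        dp = ders_params.with_enzymes(int(e_hdm), int(e_hdac))
        pp = pers_params.with_enzymes(int(e_hdm), int(e_hdac)) if scale_both else pers_params
        run_seeds = spawn_seeds(int(s), n_runs)
        taus, censored = [], 0
        for rs in run_seeds:
            tau, cens, _ = hybrid_differentiation_time(
                [dp, pp], grn_params, int(rs), criterion, t_max, config,
            )
            if cens:
                censored += 1
            else:
                taus.append(tau)
        taus = np.asarray(taus)
        rows.append({
            "e_hdm": int(e_hdm), "e_hdac": int(e_hdac),
            "n": int(taus.size), "n_censored": censored,
            "median": float(np.median(taus)) if taus.size else np.nan,
            "iqr_low": float(np.percentile(taus, 25)) if taus.size else np.nan,
            "iqr_high": float(np.percentile(taus, 75)) if taus.size else np.nan,
        })
    return pd.DataFrame(rows)
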