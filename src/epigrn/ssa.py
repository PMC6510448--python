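"""Exact stochastic simulation (Gillespie) for declarative reaction networks.

A `Network` is a purely declarative object: stoichiometry matrix, mass-action
factor lists (propensity = c_k * product of factor-species counts), and
optional threshold gates (a channel is switched off while a gated species sits
below its threshold -- used for the epigenetic open/closed indicator eta).
The inner loops are numba-compiled; every public entry point is reproducible
given its seed.

This module also builds the *full* coupled ER-GRN reference model (16 ER
channels per gene plus the promoter-binding GRN channels, with binding gated
by the live acetylation state) and provides the transition-time and
differentiation-time measurements used as ground truth elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import er_model
from .er_model import ERParams, ReactionTable, default_table
from .grn_model import GRNParams

__all__ = [
    "Network",
    "Trajectory",
    "TransitionTimes",
    "gillespie_run",
    "sample_trajectory",
    "first_passage",
    "er_network",
    "er_initial_state",
    "estimate_transition_times",
    "CoupledModel",
    "coupled_full_model",
    "coupled_initial_state",
    "DifferentiationCriterion",
    "default_differentiation_criterion",
    "measure_differentiation_time",
    "first_dwell_time",
    "spawn_seeds",
]


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> 1


@dataclass(frozen=True)
class Network:
    """Declarative mass-action reaction network."""

    species: tuple[str, ...]
    stoich: np.ndarray       # (n_channels, n_species) int64
    factors: np.ndarray      # (n_channels, max_order) int64, -1 padded
    c: np.ndarray            # (n_channels,) float64
    gate_idx: np.ndarray | None = None
    gate_thresh: np.ndarray | None = None
    gate_idx2: np.ndarray | None = None  # optional second species summed into the gate
    conservation: tuple = ()  # ((coef_vector, total), ...)

    def __post_init__(self):
        C = self.stoich.shape[0]
        object.__setattr__(self, "stoich", np.ascontiguousarray(self.stoich, dtype=np.int64))
        object.__setattr__(self, "factors", np.ascontiguousarray(self.factors, dtype=np.int64))
        object.__setattr__(self, "c", np.ascontiguousarray(self.c, dtype=np.float64))
        gi = self.gate_idx if self.gate_idx is not None else -np.ones(C, dtype=np.int64)
        gt = self.gate_thresh if self.gate_thresh is not None else np.zeros(C)
        gi2 = self.gate_idx2 if self.gate_idx2 is not None else -np.ones(C, dtype=np.int64)
        object.__setattr__(self, "gate_idx", np.ascontiguousarray(gi, dtype=np.int64))
        object.__setattr__(self, "gate_thresh", np.ascontiguousarray(gt, dtype=np.float64))
        object.__setattr__(self, "gate_idx2", np.ascontiguousarray(gi2, dtype=np.int64))
        if np.any(self.c < 0):
            raise ValueError("rate constants must be non-negative")
        reps = np.zeros_like(self.factors)
        for j in range(self.factors.shape[1]):
            reps[:, j] = (self.factors[:, :j] == self.factors[:, j : j + 1]).sum(axis=1)
        object.__setattr__(self, "_factor_reps", np.ascontiguousarray(reps, dtype=np.int64))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_channels(self) -> int:
        return self.stoich.shape[0]

    def propensities(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("negative copy numbers")
        a = self.c.copy()
        for j in range(self.factors.shape[1]):
            col = self.factors[:, j]
            live = col >= 0
            reps = (self.factors[:, :j] == col[:, None]).sum(axis=1)
            f = np.maximum(x[col[live]] - reps[live], 0.0)
            a[live] *= f
        gated = self.gate_idx >= 0
        if gated.any():
            gv = x[np.maximum(self.gate_idx, 0)]
            gv = gv + np.where(self.gate_idx2 >= 0, x[np.maximum(self.gate_idx2, 0)], 0.0)
            a[gated & (gv < self.gate_thresh)] = 0.0
        return a

    def check_conservation(self, states: np.ndarray) -> None:
        states = np.atleast_2d(states)
        for coef, total in self.conservation:
            got = states @ np.asarray(coef, dtype=float)
            if not np.allclose(got, total):
                raise er_model.InvalidStateError(
                    f"conservation law violated: expected {total}, got {got[np.argmax(np.abs(got - total))]}"
                )


@dataclass(frozen=True)
class Trajectory:
    """Event-resolved SSA output (times strictly increasing)."""

    times: np.ndarray
    states: np.ndarray       # (n_events, n_species), state *after* each event
    channels: np.ndarray
    seed: int
    t_final: float
    state_final: np.ndarray
    initial_state: np.ndarray


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _propensity_sum(x, c, factors, freps, gate_idx, gate_idx2, gate_thresh, a):
    atot = 0.0
    for k in range(c.size):
        ak = c[k]
        for j in range(factors.shape[1]):
            idx = factors[k, j]
            if idx >= 0:
                # falling factorial for repeated factor species (e.g. dimers)
                f = x[idx] - freps[k, j]
                ak *= f if f > 0.0 else 0.0
        if gate_idx[k] >= 0:
            gv = x[gate_idx[k]]
            if gate_idx2[k] >= 0:
                gv += x[gate_idx2[k]]
            if gv < gate_thresh[k]:
                ak = 0.0
        if ak < 0.0:
            raise ValueError("negative propensity encountered")
        a[k] = ak
        atot += ak
    return atot


@njit(cache=True)
def _pick_channel(a, atot):
    r = np.random.random() * atot
    acc = 0.0
    k = 0
    for k in range(a.size):
        acc += a[k]
        if acc >= r:
            break
    return k


@njit(cache=True)
def _run_events(stoich, factors, freps, c, gate_idx, gate_idx2, gate_thresh, x0, t_max, max_events, seed):
    np.random.seed(seed)
    S = x0.size
    x = x0.astype(np.float64)
    a = np.empty(c.size)
    times = np.empty(max_events)
    chans = np.empty(max_events, np.int64)
    states = np.empty((max_events, S))
    t = 0.0
    n = 0
    while n < max_events:
        atot = _propensity_sum(x, c, factors, freps, gate_idx, gate_idx2, gate_thresh, a)
        if atot <= 0.0:
            break
        t_next = t + np.random.exponential(1.0 / atot)
        if t_next > t_max:
            t = t_max
            break
        t = t_next
        k = _pick_channel(a, atot)
        for s in range(S):
            x[s] += stoich[k, s]
        times[n] = t
        chans[n] = k
        for s in range(S):
            states[n, s] = x[s]
        n += 1
    return times[:n].copy(), chans[:n].copy(), states[:n].copy(), x, t


@njit(cache=True)
def _run_sampled(stoich, factors, freps, c, gate_idx, gate_idx2, gate_thresh, x0, sample_times, max_events, seed):
    np.random.seed(seed)
    S = x0.size
    x = x0.astype(np.float64)
    a = np.empty(c.size)
    T = sample_times.size
    out = np.empty((T, S))
    t = 0.0
    si = 0
    n = 0
    complete = True
    while si < T:
        atot = _propensity_sum(x, c, factors, freps, gate_idx, gate_idx2, gate_thresh, a)
        if atot <= 0.0:
            for i in range(si, T):
                for s in range(S):
                    out[i, s] = x[s]
            si = T
            break
        t_next = t + np.random.exponential(1.0 / atot)
        while si < T and sample_times[si] < t_next:
            for s in range(S):
                out[si, s] = x[s]
            si += 1
        if si >= T:
            break
        t = t_next
        k = _pick_channel(a, atot)
        for s in range(S):
            x[s] += stoich[k, s]
        n += 1
        if n >= max_events:
            complete = False
            for i in range(si, T):
                for s in range(S):
                    out[i, s] = np.nan
            break
    return out, complete, n


@njit(cache=True)
def _run_until(stoich, factors, freps, c, gate_idx, gate_idx2, gate_thresh, x0, watch, watch2, lo, hi, t_max, max_events, seed):
    """Run until x[watch] >= hi (reached=+1) or x[watch] <= lo (reached=-1).

    reached = 0 on timeout/budget, -2 on absorbing state."""
    np.random.seed(seed)
    S = x0.size
    x = x0.astype(np.float64)
    a = np.empty(c.size)
    t = 0.0
    n = 0
    reached = 0
    while True:
        wv = x[watch]
        if watch2 >= 0:
            wv += x[watch2]
        if wv >= hi:
            reached = 1
            break
        if wv <= lo:
            reached = -1
            break
        atot = _propensity_sum(x, c, factors, freps, gate_idx, gate_idx2, gate_thresh, a)
        if atot <= 0.0:
            reached = -2
            break
        t_next = t + np.random.exponential(1.0 / atot)
        if t_next > t_max:
            t = t_max
            break
        t = t_next
        k = _pick_channel(a, atot)
        for s in range(S):
            x[s] += stoich[k, s]
        n += 1
        if n >= max_events:
            break
    return t, x, n, reached


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------

def gillespie_run(
    network: Network,
    x0: np.ndarray,
    t_max: float,
    seed: int,
    max_events: int = 1_000_000,
    check_conservation: bool = True,
) -> Trajectory:
    """Statistically exact SSA with full event recording.

    Ends early when the total propensity reaches zero (absorbing state).
    Two runs with the same seed produce identical trajectories.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    x0 = np.asarray(x0, dtype=np.float64)
    if np.any(x0 < 0):
        raise ValueError("negative initial copy numbers")
    times, chans, states, xf, tf = _run_events(
        network.stoich, network.factors, network._factor_reps, network.c,
        network.gate_idx, network.gate_idx2, network.gate_thresh,
        x0, float(t_max), int(max_events), int(seed),
    )
    if check_conservation and network.conservation:
        network.check_conservation(states if len(states) else x0[None, :])
    return Trajectory(
        times=times, states=states, channels=chans, seed=int(seed),
        t_final=tf, state_final=xf, initial_state=x0,
    )


def sample_trajectory(
    network: Network,
    x0: np.ndarray,
    sample_times: np.ndarray,
    seed: int,
    max_events: int = 50_000_000,
):
    """States at the given (ascending) sample times.

    Returns (states, complete, n_events); ``complete`` is False when the
    event budget ran out (remaining rows are NaN)."""
    st = np.ascontiguousarray(sample_times, dtype=np.float64)
    out, complete, n = _run_sampled(
        network.stoich, network.factors, network._factor_reps, network.c,
        network.gate_idx, network.gate_idx2, network.gate_thresh,
        np.asarray(x0, dtype=np.float64), st, int(max_events), int(seed),
    )
    return out, bool(complete), int(n)


def first_passage(
    network: Network,
    x0: np.ndarray,
    watch: int,
    lo: float,
    hi: float,
    t_max: float,
    seed: int,
    max_events: int = 50_000_000,
    watch2: int = -1,
):
    """First time the watched level leaves the open interval (lo, hi).

    The level is x[watch], plus x[watch2] when watch2 >= 0 (composite
    observables such as total acetylation, free plus enzyme-bound).  Returns
    (t, final_state, n_events, reached) with reached in {+1: hit hi, -1: hit
    lo, 0: budget/timeout, -2: absorbed}.
    """
    return _run_until(
        network.stoich, network.factors, network._factor_reps, network.c,
        network.gate_idx, network.gate_idx2, network.gate_thresh,
        np.asarray(x0, dtype=np.float64), int(watch), int(watch2), float(lo), float(hi),
        float(t_max), int(max_events), int(seed),
    )


# ---------------------------------------------------------------------------
# ER-specific builders and measurements
# ---------------------------------------------------------------------------

def er_network(params: ERParams, table: ReactionTable | None = None) -> Network:
    if table is None:
        table = default_table()
    site = np.zeros(7)
    site[[er_model.M, er_model.U, er_model.A, er_model.C_HDM, er_model.C_HDAC]] = 1
    hdm = np.zeros(7)
    hdm[[er_model.HDM, er_model.C_HDM]] = 1
    hdac = np.zeros(7)
    hdac[[er_model.HDAC, er_model.C_HDAC]] = 1
    return Network(
        species=("M", "U", "A", "HDM", "C_HDM", "HDAC", "C_HDAC"),
        stoich=table.stoich,
        factors=table.factors,
        c=params.c,
        conservation=(
            (site, float(params.n_sites)),
            (hdm, float(params.e_hdm)),
            (hdac, float(params.e_hdac)),
        ),
    )


def er_initial_state(params: ERParams, ma: np.ndarray) -> np.ndarray:
    """Integer ER state nearest the slow fractions (m, a), enzymes free."""
    y = np.zeros(7, dtype=np.int64)
    y[er_model.M] = int(round(ma[0] * params.n_sites))
    y[er_model.A] = int(round(ma[1] * params.n_sites))
    y[er_model.U] = params.n_sites - y[er_model.M] - y[er_model.A]
    y[er_model.HDM] = params.e_hdm
    y[er_model.HDAC] = params.e_hdac
    if y[er_model.U] < 0:
        raise er_model.InvalidStateError("fractions exceed the site budget")
    return y


def _acetyl_thresholds(params: ERParams, open_fraction=None, closed_fraction=None):
    """Counts bounding the open and closed acetylation bands.

    Default: the strict over-90% / under-10% rule (Y3 >= floor(0.9 Y) + 1,
    Y3 <= ceil(0.1 Y) - 1).  Explicit fractions use nearest-count rounding
    instead, which keeps the *relative* band position consistent across
    system sizes (needed when comparing switching times along a size family;
    the strict rule's quantisation is severe at small Y)."""
    if open_fraction is None and closed_fraction is None:
        hi = np.floor(er_model.OPEN_FRACTION * params.n_sites) + 1
        lo = np.ceil(er_model.CLOSED_FRACTION * params.n_sites) - 1
        return lo, hi
    fo = er_model.OPEN_FRACTION if open_fraction is None else open_fraction
    fc = er_model.CLOSED_FRACTION if closed_fraction is None else closed_fraction
    return float(np.round(fc * params.n_sites)), float(np.round(fo * params.n_sites))


@dataclass
class TransitionTimes:
    """First-passage statistics between the closed and open acetylation bands."""

    tau_open: float              # mean closed -> open waiting time (tau+)
    tau_close: float             # mean open -> closed waiting time (tau-)
    samples_open: np.ndarray
    samples_close: np.ndarray
    se_open: float
    se_close: float
    rare_open: bool = False      # no crossing observed within budget
    rare_close: bool = False
    lower_bound_open: float = 0.0
    lower_bound_close: float = 0.0

    @property
    def n_open(self) -> int:
        return self.samples_open.size

    @property
    def n_close(self) -> int:
        return self.samples_close.size


def estimate_transition_times(
    er_params: ERParams,
    n_events: int = 25,
    seed: int = 0,
    t_max_per_passage: float = 1e6,
    max_events_per_passage: int = 20_000_000,
    table: ReactionTable | None = None,
    open_fraction: float | None = None,
    closed_fraction: float | None = None,
) -> TransitionTimes:
    """Alternating first-passage times between the 10% / 90% acetylation bands.

    The walker starts at the closed mean-field attractor; each closed->open
    crossing yields a tau+ sample and each open->closed return a tau- sample.
    A direction with no crossing inside the budget is flagged rare and carries
    the accumulated waiting time as a lower bound instead of an estimate.
    """
    net = er_network(er_params, table)
    attractors = er_model.find_er_attractors(er_params)
    closed_ma = attractors[0]
    open_ma = attractors[-1]
    lo, hi = _acetyl_thresholds(er_params, open_fraction, closed_fraction)

    seeds = spawn_seeds(seed, 4 * n_events + 8)
    x = er_initial_state(er_params, closed_ma).astype(np.float64)
    going_up = True
    ups: list[float] = []
    downs: list[float] = []
    lb_up = 0.0
    lb_down = 0.0
    si = 0
    while (len(ups) < n_events or len(downs) < n_events) and si < seeds.size:
        watch_lo = -1.0 if going_up else lo
        watch_hi = hi if going_up else float(er_params.n_sites) + 1
        t, x, n, reached = first_passage(
            net, x, er_model.A, watch_lo, watch_hi,
            t_max_per_passage, int(seeds[si]), max_events_per_passage,
            watch2=er_model.C_HDAC,
        )
        si += 1
        if going_up:
            if reached == 1:
                ups.append(t)
                going_up = False
            else:
                lb_up += t
                # restart from the attractor; direction unchanged
                x = er_initial_state(er_params, closed_ma).astype(np.float64)
                if len(ups) == 0 and si >= 4:
                    break
        else:
            if reached == -1:
                downs.append(t)
                going_up = True
            else:
                lb_down += t
                x = er_initial_state(er_params, open_ma).astype(np.float64)
                if len(downs) == 0 and si >= 8:
                    break

    ups_a = np.asarray(ups)
    downs_a = np.asarray(downs)
    return TransitionTimes(
        tau_open=float(ups_a.mean()) if ups_a.size else np.nan,
        tau_close=float(downs_a.mean()) if downs_a.size else np.nan,
        samples_open=ups_a,
        samples_close=downs_a,
        se_open=float(ups_a.std(ddof=1) / np.sqrt(ups_a.size)) if ups_a.size > 1 else np.nan,
        se_close=float(downs_a.std(ddof=1) / np.sqrt(downs_a.size)) if downs_a.size > 1 else np.nan,
        rare_open=ups_a.size == 0,
        rare_close=downs_a.size == 0,
        lower_bound_open=lb_up,
        lower_bound_close=lb_down,
    )


# ---------------------------------------------------------------------------
# the coupled ER-GRN reference model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoupledModel:
    """Joint network of per-gene ER systems and the stochastic GRN.

    Index bookkeeping: gene g's ER species occupy slots [7g, 7g+7); monomers,
    free promoter sites and bound sites follow.  The GRN binding channels are
    gated on the live acetylation count of the target promoter's ER system
    (eta_j = H(Y_j3 - y0 * n_sites)).
    """

    network: Network
    er_params: tuple[ERParams, ...]
    grn_params: GRNParams
    x_index: np.ndarray        # monomer slot per gene
    free_index: np.ndarray     # free promoter-site slot per gene
    bound_index: np.ndarray    # (n, n) bound-site slots
    acetyl_index: np.ndarray   # Y3 slot per gene


def coupled_full_model(
    er_params: list[ERParams],
    grn_params: GRNParams,
    table: ReactionTable | None = None,
) -> CoupledModel:
    if table is None:
        table = default_table()
    n = grn_params.n_genes
    if len(er_params) != n:
        raise er_model.ConfigurationError(
            f"need one ER system per gene: got {len(er_params)} for {n} genes"
        )
    er_names = ("M", "U", "A", "HDM", "C_HDM", "HDAC", "C_HDAC")
    species: list[str] = []
    for g in range(n):
        species += [f"{s}_{g + 1}" for s in er_names]
    base_x = len(species)
    species += [f"X_{i + 1}" for i in range(n)]
    base_f = len(species)
    species += [f"F_{i + 1}" for i in range(n)]
    base_b = len(species)
    for i in range(n):
        species += [f"X_{i + 1}{j + 1}" for j in range(n)]
    S = len(species)

    x_index = base_x + np.arange(n)
    free_index = base_f + np.arange(n)
    bound_index = base_b + np.arange(n * n).reshape(n, n)
    acetyl_index = 7 * np.arange(n) + er_model.A

    stoich_rows = []
    factor_rows = []
    c_list = []
    gate_i = []
    gate_t = []
    gate_i2 = []

    def add(stoich_pairs, facs, rate, gate=(-1, 0.0, -1)):
        row = np.zeros(S, dtype=np.int64)
        for idx, d in stoich_pairs:
            row[idx] += d
        frow = -np.ones(3, dtype=np.int64)
        for j, idx in enumerate(facs):
            frow[j] = idx
        stoich_rows.append(row)
        factor_rows.append(frow)
        c_list.append(rate)
        gate_i.append(gate[0])
        gate_t.append(gate[1])
        gate_i2.append(gate[2])

    # per-gene ER channels
    for g in range(n):
        off = 7 * g
        for k in range(16):
            pairs = [(off + s, int(table.stoich[k, s])) for s in range(7) if table.stoich[k, s] != 0]
            facs = [off + int(f) for f in table.factors[k] if f >= 0]
            add(pairs, facs, float(er_params[g].c[k]))

    # GRN channels (same ordering as grn_model.grn_propensities)
    for i in range(n):
        add([(x_index[i], 1)], [], float(grn_params.basal_rate[i]))                      # basal
    for i in range(n):
        add([(x_index[i], 1)], [bound_index[i, i]], float(grn_params.k1[i]))             # synthesis
    for i in range(n):
        add([(x_index[i], -1)], [x_index[i]], float(grn_params.k2[i]))                   # degradation
    for i in range(n):
        for j in range(n):
            add(
                [(free_index[i], -1), (bound_index[i, j], 1), (x_index[j], -2)],
                [free_index[i], x_index[j], x_index[j]],
                float(grn_params.b[i, j]),
                # eta_i reads total acetylation: free plus HDAC-complexed sites
                gate=(int(acetyl_index[i]), er_params[i].y0 * er_params[i].n_sites,
                      int(7 * i + er_model.C_HDAC)),
            )
    for i in range(n):
        for j in range(n):
            add(
                [(free_index[i], 1), (bound_index[i, j], -1), (x_index[j], 2)],
                [bound_index[i, j]],
                float(grn_params.d[i, j]),
            )

    conservation = []
    for g in range(n):
        off = 7 * g
        site = np.zeros(S)
        site[[off + er_model.M, off + er_model.U, off + er_model.A,
              off + er_model.C_HDM, off + er_model.C_HDAC]] = 1
        hdmv = np.zeros(S)
        hdmv[[off + er_model.HDM, off + er_model.C_HDM]] = 1
        hdacv = np.zeros(S)
        hdacv[[off + er_model.HDAC, off + er_model.C_HDAC]] = 1
        conservation += [
            (site, float(er_params[g].n_sites)),
            (hdmv, float(er_params[g].e_hdm)),
            (hdacv, float(er_params[g].e_hdac)),
        ]
        prom = np.zeros(S)
        prom[free_index[g]] = 1
        prom[bound_index[g]] = 1
        conservation.append((prom, float(grn_params.e[g])))

    net = Network(
        species=tuple(species),
        stoich=np.array(stoich_rows),
        factors=np.array(factor_rows),
        c=np.array(c_list),
        gate_idx=np.array(gate_i, dtype=np.int64),
        gate_thresh=np.array(gate_t),
        gate_idx2=np.array(gate_i2, dtype=np.int64),
        conservation=tuple(conservation),
    )
    return CoupledModel(
        network=net,
        er_params=tuple(er_params),
        grn_params=grn_params,
        x_index=x_index,
        free_index=free_index,
        bound_index=bound_index,
        acetyl_index=acetyl_index,
    )


def coupled_initial_state(
    model: CoupledModel,
    er_ma: list[np.ndarray],
    x: np.ndarray,
    bound: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble a joint state from per-gene slow fractions and monomer counts."""
    n = model.grn_params.n_genes
    S = model.network.n_species
    state = np.zeros(S, dtype=np.float64)
    for g in range(n):
        state[7 * g : 7 * g + 7] = er_initial_state(model.er_params[g], er_ma[g])
    state[model.x_index] = np.round(np.asarray(x, dtype=float))
    b = np.zeros((n, n)) if bound is None else np.asarray(bound, dtype=float)
    state[model.bound_index.ravel()] = b.ravel()
    state[model.free_index] = model.grn_params.e - b.sum(axis=1)
    if np.any(state[model.free_index] < 0):
        raise er_model.InvalidStateError("promoter occupancy exceeds exposed sites")
    return state


# ---------------------------------------------------------------------------
# differentiation-time measurement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentiationCriterion:
    """Basin-entry rule for 'the cell has differentiated': the gene-1 monomer
    count exceeds ``x1_min`` while the gene-2 count stays below ``x2_max``,
    sustained for ``dwell`` time units."""

    x1_min: float
    x2_max: float
    dwell: float = 5.0


def default_differentiation_criterion(grn_params: GRNParams, dwell: float = 5.0) -> DifferentiationCriterion:
    """Thresholds from the reduced model: half the DSS level of gene 1 (at
    accessibility (1, 0)) and a tenth of the PSS level of gene 2 (at (0, 1))."""
    from .grn_model import find_steady_states

    dss = [s for s in find_steady_states(grn_params, np.array([1.0, 0.0])) if s.stable and s.label == "DSS"]
    pss = [s for s in find_steady_states(grn_params, np.array([0.0, 1.0])) if s.stable and s.label == "PSS"]
    if not dss or not pss:
        raise er_model.ConfigurationError("GRN parameters do not exhibit the DSS/PSS pair")
    q1_dss = dss[0].q[0]
    q2_pss = pss[0].q[1]
    return DifferentiationCriterion(
        x1_min=0.5 * grn_params.S * q1_dss,
        x2_max=0.1 * grn_params.S * q2_pss,
        dwell=dwell,
    )


def first_dwell_time(times: np.ndarray, ok: np.ndarray, dwell: float):
    """Earliest t such that ``ok`` holds continuously on [t, t + dwell].

    ``ok`` is evaluated on the (piecewise-constant) sample grid ``times``.
    Returns None if no sustained window exists.
    """
    times = np.asarray(times, dtype=float)
    ok = np.asarray(ok, dtype=bool)
    start = None
    for i in range(ok.size):
        if ok[i]:
            if start is None:
                start = times[i]
            if times[i] - start >= dwell:
                return float(start)
        else:
            start = None
    if start is not None and times[-1] - start >= dwell:
        return float(start)
    return None


def measure_differentiation_time(
    model: CoupledModel,
    seed: int,
    criterion: DifferentiationCriterion | None = None,
    t_max: float = 2000.0,
    sample_dt: float = 0.5,
    max_events: int = 200_000_000,
):
    """One differentiation-time sample tau_D from the full coupled SSA.

    Starts pluripotency-locked: gene-1 ER at its closed attractor, gene-2 ER
    at its open attractor, GRN at the PSS.  Returns (tau_D, censored, n_events);
    censored runs carry tau_D = t_max and must never be averaged in.
    """
    if criterion is None:
        criterion = default_differentiation_criterion(model.grn_params)
    from .grn_model import find_steady_states

    n = model.grn_params.n_genes
    closed_ma = er_model.find_er_attractors(model.er_params[0])[0]
    open_ma = er_model.find_er_attractors(model.er_params[1])[-1]
    pss = [s for s in find_steady_states(model.grn_params, np.array([0.0, 1.0])) if s.stable and s.label == "PSS"]
    if not pss:
        raise er_model.ConfigurationError("no PSS at accessibility (0, 1)")
    x0 = coupled_initial_state(
        model,
        [closed_ma, open_ma] + [closed_ma] * (n - 2),
        model.grn_params.S * pss[0].q,
    )
    # simulate in chunks so runs can stop as soon as the dwell is observed
    chunk_t = max(20.0 * criterion.dwell, 50.0 * sample_dt)
    n_chunks = int(np.ceil(t_max / chunk_t))
    seeds = spawn_seeds(seed, n_chunks)
    all_times: list[np.ndarray] = []
    all_ok: list[np.ndarray] = []
    n_events = 0
    state = x0
    t0 = 0.0
    for ci in range(n_chunks):
        t1 = min(t0 + chunk_t, t_max)
        grid = np.arange(t0, t1 + sample_dt / 2, sample_dt)
        rel = grid - t0
        states, complete, ne = sample_trajectory(model.network, state, rel, int(seeds[ci]), max_events)
        n_events += ne
        x1 = states[:, model.x_index[0]]
        x2 = states[:, model.x_index[1]]
        valid = ~np.isnan(x1)
        all_times.append(grid[valid])
        all_ok.append((x1 >= criterion.x1_min)[valid] & (x2 <= criterion.x2_max)[valid])
        times_cat = np.concatenate(all_times)
        ok_cat = np.concatenate(all_ok)
        tau = first_dwell_time(times_cat, ok_cat, criterion.dwell)
        if tau is not None:
            return tau, False, n_events
        if not complete or not valid.all():
            break
        state = states[-1]
        t0 = t1
    times_cat = np.concatenate(all_times)
    return float(times_cat[-1]) if times_cat.size else 0.0, True, n_events
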