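"""Gene-regulatory-network submodel: reduced dynamics and phase diagram.

The GRN couples ``n_genes`` self-activating genes that inhibit each other
competitively: homodimers of protein j bind the promoter of gene i (rate
``b_ij``), occupying binding sites that the gene's own activator then cannot
use.  In the reduced (quasi-steady-state) description the generalized protein
coordinates q_i follow

    dq_i/dtau = R_i + (p_inf_i/p) * omega_i1 * k_ii q_i^2 / (1 + sum_j k_ij q_j^2)
                - omega_i2 q_i,          k_ij = beta_ij / delta_ij,

where the promoter-accessibility fraction ``p_inf_i/p = e_i/E`` is the handle
through which epigenetic regulation acts: 0 for a silenced promoter, order one
for an open one.  For two genes the stable steady states are classified as
PSS (pluripotency: gene 2 on, gene 1 off), DSS (differentiation: mirrored) and
USS (undecided: both off), and scanning the accessibility pair maps out the
mono-, bi- and tristability regions of the cell-fate landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRNParams",
    "SteadyState",
    "default_grn_params",
    "reduced_rhs",
    "reduced_jacobian",
    "find_steady_states",
    "region_label",
    "grn_phase_diagram",
    "grn_propensities",
    "GRNState",
]


@dataclass(frozen=True)
class GRNParams:
    """Rescaled and raw rates of the N-gene competitive-inhibition GRN.

    The rescaled rates (R, omega1, omega2, beta, delta) define the reduced
    dynamics; the raw stochastic rates follow from the molecular scales
    S (monomer copy numbers) and E (promoter binding sites):

        basal rate  R_i * S          synthesis  k_i1 = omega_i1 * S / E
        degradation k_i2 = omega_i2  binding    b_ij = beta_ij / (S * E)
        unbinding   d_ij = delta_ij * S / E

    so that for large S the mean dynamics of x_i = X_i/S reproduce the
    reduced equations.  ``e`` holds the exposed binding sites per promoter.
    """

    R: np.ndarray
    omega1: np.ndarray
    omega2: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    S: float = 100.0
    E: int = 3
    e: np.ndarray | None = None

    def __post_init__(self):
        R = np.atleast_1d(np.asarray(self.R, dtype=float))
        n = R.size
        object.__setattr__(self, "R", R)
        for name in ("omega1", "omega2"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (n,)).copy()
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, v)
        for name in ("beta", "delta"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if np.any(mat < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, mat)
        e = np.full(n, self.E, dtype=float) if self.e is None else np.asarray(self.e, dtype=float)
        if np.any(e < 0) or np.any(e > self.E):
            raise ValueError("exposed sites must satisfy 0 <= e_i <= E")
        object.__setattr__(self, "e", e)

    @property
    def n_genes(self) -> int:
        return self.R.size

    @property
    def k(self) -> np.ndarray:
        """Binding/unbinding ratio matrix k_ij = beta_ij / delta_ij."""
        return np.where(self.delta > 0, self.beta / np.where(self.delta > 0, self.delta, 1.0), 0.0)

    # raw stochastic rates
    @property
    def basal_rate(self) -> np.ndarray:
        return self.R * self.S

    @property
    def k1(self) -> np.ndarray:
        return self.omega1 * self.S / self.E

    @property
    def k2(self) -> np.ndarray:
        return self.omega2

    @property
    def b(self) -> np.ndarray:
        return self.beta / (self.S * self.E)

    @property
    def d(self) -> np.ndarray:
        return self.delta * self.S / self.E


def default_grn_params(**over) -> GRNParams:
    """Two-gene defaults: strong self-activation (omega_11 = omega_21 = 4),
    symmetric competitive inhibition, small basal leak."""
    kw = dict(
        R=np.array([0.02, 0.02]),
        omega1=np.array([4.0, 4.0]),
        omega2=np.array([1.0, 1.0]),
        beta=np.array([[4.0, 2.0], [2.0, 4.0]]),
        delta=np.ones((2, 2)),
        S=100.0,
        E=3,
    )
    kw.update(over)
    return GRNParams(**kw)


# ---------------------------------------------------------------------------
# reduced dynamics
# ---------------------------------------------------------------------------

def reduced_rhs(q: np.ndarray, params: GRNParams, pfrac: np.ndarray) -> np.ndarray:
    """dq/dtau of the reduced GRN flow.  Vectorised over leading axes of q.

    ``pfrac`` (promoter accessibility, p_inf_i/p) may be a single vector or
    broadcastable to q's shape.
    """
    q = np.asarray(q, dtype=float)
    pf = np.broadcast_to(np.asarray(pfrac, dtype=float), q.shape)
    k = params.k
    q2 = q**2
    denom = 1.0 + q2 @ k.T  # denom_i = 1 + sum_j k_ij q_j^2
    act = params.omega1 * np.diagonal(k) * q2 / denom
    return params.R + pf * act - params.omega2 * q


def reduced_jacobian(q: np.ndarray, params: GRNParams, pfrac: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of `reduced_rhs`, shape (..., n, n)."""
    q = np.asarray(q, dtype=float)
    pf = np.broadcast_to(np.asarray(pfrac, dtype=float), q.shape)
    k = params.k
    n = params.n_genes
    q2 = q**2
    denom = 1.0 + q2 @ k.T
    kd = np.diagonal(k)
    core = pf * params.omega1 * kd  # (..., n)
    jac = np.zeros(q.shape + (n,))
    # d/dq_l [q_i^2 / D_i] = 2 q_i delta_il / D_i - q_i^2 * 2 k_il q_l / D_i^2
    for l in range(n):
        jac[..., l] = core * (-q2 * 2.0 * k[:, l][None, ...] * q[..., l : l + 1] / denom**2)
    for i in range(n):
        jac[..., i, i] += core[..., i] * 2.0 * q[..., i] / denom[..., i] - params.omega2[i]
    return jac


@dataclass(frozen=True)
class SteadyState:
    q: np.ndarray
    stable: bool
    label: str


_SS_CACHE: dict = {}


def _newton_polish(points: np.ndarray, params: GRNParams, pf: np.ndarray, n_iter: int = 80):
    """Newton iteration on a batch of starting points (vectorised).

    Converged points are frozen; steps are clipped to a trust radius so
    divergent starts stall harmlessly (they fail the residual filter and are
    dropped by the caller).
    """
    shape = points.shape[:-1]
    x = points.reshape(-1, points.shape[-1]).copy()
    pf_flat = np.broadcast_to(pf, points.shape).reshape(-1, points.shape[-1])
    f = reduced_rhs(x, params, pf_flat)
    active = np.ones(x.shape[0], dtype=bool)
    trust = 1.0 + np.abs(x).max()
    for _ in range(n_iter):
        active = np.abs(f).max(axis=-1) > 1e-12
        if not active.any():
            break
        xa = x[active]
        pa = pf_flat[active]
        fa = f[active]
        jac = reduced_jacobian(xa, params, pa)
        try:
            step = np.linalg.solve(jac, fa[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = fa / np.maximum(np.abs(np.diagonal(jac, axis1=-2, axis2=-1)), 1e-12)
        norm = np.linalg.norm(step, axis=-1, keepdims=True)
        step = np.where(norm > trust, step * trust / np.maximum(norm, 1e-300), step)
        xa = np.clip(xa - step, 0.0, None)
        x[active] = xa
        f[active] = reduced_rhs(xa, params, pa)
    return x.reshape(points.shape), f.reshape(points.shape)


def classify_steady_state(q: np.ndarray, on_threshold: float = 0.5) -> str:
    """Label a two-gene state by which genes are 'on' (q >= on_threshold).

    Gene 1 promotes differentiation, gene 2 pluripotency: (off, on) -> PSS,
    (on, off) -> DSS, (off, off) -> USS, (on, on) -> other.
    """
    q = np.asarray(q)
    if q.shape[-1] != 2:
        return "other"
    on = q >= on_threshold
    if not on[0] and on[1]:
        return "PSS"
    if on[0] and not on[1]:
        return "DSS"
    if not on[0] and not on[1]:
        return "USS"
    return "other"


def find_steady_states(
    params: GRNParams,
    pfrac: np.ndarray,
    n_starts: int = 9,
    on_threshold: float = 0.5,
    merge_tol: float = 1e-6,
) -> list[SteadyState]:
    """All steady states of the reduced flow at one accessibility pair.

    Multistart damped Newton from an ``n_starts``-per-axis grid over
    [0, q_max_i], with q_max_i = (R_i + pf_i omega_i1)/omega_i2 an invariant
    bound on the flow.  Roots are merged within ``merge_tol`` and classified
    by linear stability; non-converged starts are dropped (their residual
    stays visibly non-zero, never silently mislabelled).
    """
    pf = np.asarray(pfrac, dtype=float)
    key = (params.R.tobytes(), params.omega1.tobytes(), params.omega2.tobytes(),
           params.beta.tobytes(), params.delta.tobytes(), pf.tobytes(),
           n_starts, on_threshold, merge_tol)
    hit = _SS_CACHE.get(key)
    if hit is not None:
        return list(hit)
    n = params.n_genes
    qmax = (params.R + pf * params.omega1) / np.maximum(params.omega2, 1e-12)
    axes = [np.linspace(0.0, qmax[i] * 1.05 + 1e-6, n_starts) for i in range(n)]
    mesh = np.meshgrid(*axes, indexing="ij")
    starts = np.stack([g.ravel() for g in mesh], axis=-1)
    x, f = _newton_polish(starts, params, pf)
    ok = np.abs(f).max(axis=-1) < 1e-9
    roots: list[np.ndarray] = []
    for p in x[ok]:
        if not any(np.linalg.norm(p - r) <= merge_tol * max(1.0, np.linalg.norm(r)) for r in roots):
            roots.append(p)
    out = []
    for r in roots:
        jac = reduced_jacobian(r, params, pf)
        eig = np.linalg.eigvals(jac)
        stable = bool(np.all(np.real(eig) < -1e-10))
        out.append(SteadyState(q=r, stable=stable, label=classify_steady_state(r, on_threshold)))
    if len(_SS_CACHE) > 4096:
        _SS_CACHE.clear()
    _SS_CACHE[key] = tuple(out)
    return out


_REGION_ORDER = "PUD"


def region_label(states: list[SteadyState]) -> str:
    """Canonical region name from the set of stable-state labels, e.g. 'PU'."""
    present = {s.label[0] for s in states if s.stable and s.label != "other"}
    extra = "O" if any(s.stable and s.label == "other" for s in states) else ""
    name = "".join(ch for ch in _REGION_ORDER if ch in present) + extra
    return name or "none"


def grn_phase_diagram(
    params: GRNParams,
    pfrac1_grid: np.ndarray,
    pfrac2_grid: np.ndarray,
    n_starts: int = 7,
    on_threshold: float = 0.5,
) -> np.ndarray:
    """Region label per (pfrac1, pfrac2) cell, vectorised over the grid.

    Runs the multistart Newton for all cells simultaneously; each cell's
    region is the set of stable-state labels present ('U', 'PU', 'PUD', ...).
    Cells where no start converges are labelled 'undetermined'.
    """
    g1 = np.asarray(pfrac1_grid, dtype=float)
    g2 = np.asarray(pfrac2_grid, dtype=float)
    if np.any(g1 < 0) or np.any(g2 < 0):
        raise ValueError("accessibility grids must be non-negative")
    p1, p2 = np.meshgrid(g1, g2, indexing="ij")
    cells = np.stack([p1.ravel(), p2.ravel()], axis=-1)  # (C, 2)
    n_cells = cells.shape[0]

    qmax = (params.R + cells * params.omega1) / params.omega2  # (C, 2)
    frac = np.linspace(0.0, 1.05, n_starts)
    s1, s2 = np.meshgrid(frac, frac, indexing="ij")
    unit = np.stack([s1.ravel(), s2.ravel()], axis=-1)  # (K, 2)
    starts = unit[None, :, :] * (qmax[:, None, :] + 1e-6)  # (C, K, 2)
    pf = np.broadcast_to(cells[:, None, :], starts.shape)

    x, f = _newton_polish(starts, params, pf)
    ok = np.abs(f).max(axis=-1) < 1e-9

    jac = reduced_jacobian(x, params, pf)
    tr = np.trace(jac, axis1=-2, axis2=-1)
    det = np.linalg.det(jac)
    stable = (tr < -1e-10) & (det > 1e-12)

    on = x >= on_threshold
    code = np.where(on[..., 0], 2, 0) + np.where(on[..., 1], 1, 0)  # 0=U, 1=P, 2=D, 3=both

    labels = np.empty(n_cells, dtype=object)
    letters = {0: "U", 1: "P", 2: "D", 3: "O"}
    for i in range(n_cells):
        sel = ok[i] & stable[i]
        if not sel.any():
            labels[i] = "undetermined"
            continue
        present = {letters[int(cd)] for cd in code[i][sel]}
        labels[i] = "".join(ch for ch in _REGION_ORDER if ch in present) + ("O" if "O" in present else "")
    return labels.reshape(g1.size, g2.size)


# ---------------------------------------------------------------------------
# stochastic GRN propensities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GRNState:
    """Copy numbers of the stochastic GRN: monomers X_i and bound promoter
    sites X_ij (promoter of gene i occupied by a dimer of protein j)."""

    x: np.ndarray
    bound: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=np.int64))
        object.__setattr__(self, "bound", np.asarray(self.bound, dtype=np.int64))


def grn_propensities(state: GRNState, params: GRNParams, eta: np.ndarray) -> np.ndarray:
    """Reaction rates of the stochastic GRN given open/closed indicators.

    Channel order: basal production (n), synthesis from bound own-promoter
    sites (n), degradation (n), dimer binding j -> promoter i gated by eta_i
    (n*n, row-major over (i, j)), unbinding of X_ij (n*n).
    """
    n = params.n_genes
    x = np.asarray(state.x, dtype=float)
    bound = np.asarray(state.bound, dtype=float)
    if np.any(x < 0) or np.any(bound < 0):
        raise ValueError("negative copy numbers")
    free = params.e - bound.sum(axis=1)
    if np.any(free < 0):
        raise ValueError("promoter occupancy exceeds exposed sites")
    eta = np.asarray(eta, dtype=float)
    a = np.empty(3 * n + 2 * n * n)
    a[:n] = params.basal_rate
    a[n : 2 * n] = params.k1 * np.diagonal(bound)
    a[2 * n : 3 * n] = params.k2 * x
    # dimerisation folded into binding: falling factorial X(X-1) per dimer
    bind = params.b * eta[:, None] * free[:, None] * (x * np.maximum(x - 1, 0))[None, :]
    a[3 * n : 3 * n + n * n] = bind.ravel()
    a[3 * n + n * n :] = (params.d * bound).ravel()
    return a
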