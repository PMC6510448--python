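"""Per-gene stochastic epigenetic-regulation (ER) network and its mean-field limit.

The ER state of one gene is a vector of seven copy numbers: methylated (M),
unmodified (U) and acetylated (A) chromatin sites, free and substrate-bound
histone demethylase (HDM) and histone deacetylase (HDAC).  Sixteen mass-action
channels implement enzymatic removal of marks (Michaelis-Menten triplets, both
unrecruited and recruited by the opposing mark) and non-enzymatic addition of
marks (unrecruited and recruited).  Mutual reinforcement -- M marks promoting
methylation and deacetylation, A marks promoting acetylation and demethylation
-- makes the network bistable for suitable rate constants, with a predominantly
acetylated *open* state and a predominantly methylated *closed* (silenced)
state.

The mean-field limit used for regime classification and phase diagrams treats
the site fractions (m, u, a) as slow variables and eliminates the enzymes via
the Briggs-Haldane quasi-steady state (valid when sites greatly outnumber
enzymes, Y >> Z).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "ERParams",
    "ReactionTable",
    "default_table",
    "er_propensities",
    "er_meanfield_rhs",
    "reduced_meanfield_rhs",
    "find_er_attractors",
    "classify_regime",
    "hme_phase_diagram",
    "classify_er_state",
    "closed_state",
    "open_state",
    "validate_er_state",
    "InvalidStateError",
    "ConfigurationError",
    "NumericalFailureError",
]

N_CHANNELS = 16
N_SPECIES = 7

# species indices
M, U, A, HDM, C_HDM, HDAC, C_HDAC = range(7)

OPEN_FRACTION = 0.9   # acetylation fraction above which a state counts as open
CLOSED_FRACTION = 0.1  # ... below which it counts as closed


class InvalidStateError(ValueError):
    """A copy-number vector violates non-negativity or conservation."""


class ConfigurationError(ValueError):
    """Parameters and reaction table are mutually inconsistent."""


class NumericalFailureError(RuntimeError):
    """Fixed-point search failed to converge; diagnostics in args."""


@dataclass(frozen=True)
class ERParams:
    """Rate constants and molecular scales of one gene's ER system.

    Parameters
    ----------
    c : 16 non-negative mass-action rate constants (dimensionless), indexed
        as in the default reaction table.
    n_sites : total number of chromatin modification sites (scale Y).
    e_hdm, e_hdac : total HDM / HDAC enzyme copy numbers.
    enzyme_scale : reference enzyme count Z (the e_HDM = e_HDAC = Z baseline).
    y0 : acetylation-fraction threshold for the open/closed indicator eta.
    """

    c: np.ndarray
    n_sites: int = 15
    e_hdm: int = 5
    e_hdac: int = 5
    enzyme_scale: int = 5
    y0: float = 0.5

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "c", c)
        if c.shape != (N_CHANNELS,):
            raise ConfigurationError(f"expected {N_CHANNELS} rate constants, got {c.shape}")
        if np.any(c < 0):
            raise ConfigurationError("rate constants must be non-negative")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.e_hdm < 0 or self.e_hdac < 0:
            raise ConfigurationError("enzyme counts must be >= 0")
        if not 0.0 < self.y0 < 1.0:
            raise ConfigurationError("y0 must lie strictly between 0 and 1")

    def with_enzymes(self, e_hdm: int, e_hdac: int) -> "ERParams":
        return replace(self, e_hdm=int(e_hdm), e_hdac=int(e_hdac))

    def scaled(self, channel_factors: dict[int, float]) -> "ERParams":
        """Return params with 1-based channels scaled by the given factors."""
        c = self.c.copy()
        for ch, f in channel_factors.items():
            if not 1 <= ch <= N_CHANNELS:
                raise ConfigurationError(f"channel index {ch} out of range")
            c[ch - 1] *= f
        return replace(self, c=c)


@dataclass(frozen=True)
class ReactionTable:
    """Declarative 16-channel reaction table over the 7 ER species."""

    stoich: np.ndarray            # (16, 7) int
    factors: np.ndarray           # (16, 3) int, species indices, -1 = unused
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.stoich.shape != (N_CHANNELS, N_SPECIES):
            raise ConfigurationError("stoichiometry must be 16 x 7")
        self._check_conservation()

    def _check_conservation(self):
        site_mask = np.zeros(N_SPECIES)
        site_mask[[M, U, A, C_HDM, C_HDAC]] = 1
        hdm_mask = np.zeros(N_SPECIES)
        hdm_mask[[HDM, C_HDM]] = 1
        hdac_mask = np.zeros(N_SPECIES)
        hdac_mask[[HDAC, C_HDAC]] = 1
        for name, mask in [("sites", site_mask), ("HDM", hdm_mask), ("HDAC", hdac_mask)]:
            bad = np.nonzero(self.stoich @ mask)[0]
            if bad.size:
                raise ConfigurationError(
                    f"channel(s) {[int(b) + 1 for b in bad]} violate the {name} conservation law"
                )


def _load_table_dict(raw: dict) -> ReactionTable:
    species = list(raw["species"])
    idx = {s: i for i, s in enumerate(species)}
    channels = raw["channels"]
    if len(channels) != N_CHANNELS:
        raise ConfigurationError(f"expected {N_CHANNELS} channels, got {len(channels)}")
    stoich = np.zeros((N_CHANNELS, N_SPECIES), dtype=np.int64)
    factors = -np.ones((N_CHANNELS, 3), dtype=np.int64)
    labels = []
    for k, ch in enumerate(channels):
        for sp, d in ch["stoich"].items():
            stoich[k, idx[sp]] = d
        facs = ch["factors"]
        if len(facs) > 3:
            raise ConfigurationError("at most 3 factor species per channel")
        for j, sp in enumerate(facs):
            factors[k, j] = idx[sp]
        labels.append(ch.get("label", f"channel {k + 1}"))
    return ReactionTable(stoich=stoich, factors=factors, labels=tuple(labels))


def load_table(path) -> ReactionTable:
    with open(path) as fh:
        return _load_table_dict(yaml.safe_load(fh))


_DEFAULT_TABLE: ReactionTable | None = None


def default_table() -> ReactionTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = importlib.resources.files("epigrn.data").joinpath("er_reactions.yaml")
        _DEFAULT_TABLE = _load_table_dict(yaml.safe_load(ref.read_text()))
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# stochastic states and propensities
# ---------------------------------------------------------------------------

def closed_state(params: ERParams) -> np.ndarray:
    """Fully methylated state with all enzymes free."""
    y = np.zeros(N_SPECIES, dtype=np.int64)
    y[M] = params.n_sites
    y[HDM] = params.e_hdm
    y[HDAC] = params.e_hdac
    return y


def open_state(params: ERParams) -> np.ndarray:
    """Fully acetylated state with all enzymes free."""
    y = np.zeros(N_SPECIES, dtype=np.int64)
    y[A] = params.n_sites
    y[HDM] = params.e_hdm
    y[HDAC] = params.e_hdac
    return y


def validate_er_state(state: np.ndarray, params: ERParams) -> None:
    y = np.asarray(state)
    if y.shape != (N_SPECIES,):
        raise InvalidStateError(f"ER state must have {N_SPECIES} entries")
    if np.any(y < 0):
        raise InvalidStateError("negative copy numbers")
    if y[M] + y[U] + y[A] + y[C_HDM] + y[C_HDAC] != params.n_sites:
        raise InvalidStateError("site conservation violated")
    if y[HDM] + y[C_HDM] != params.e_hdm:
        raise InvalidStateError("HDM conservation violated")
    if y[HDAC] + y[C_HDAC] != params.e_hdac:
        raise InvalidStateError("HDAC conservation violated")


def er_propensities(state: np.ndarray, params: ERParams, table: ReactionTable | None = None) -> np.ndarray:
    """Mass-action propensities a_k = c_k * prod of factor-species counts."""
    if table is None:
        table = default_table()
    y = np.asarray(state, dtype=float)
    if y.shape != (N_SPECIES,):
        raise InvalidStateError(f"ER state must have {N_SPECIES} entries")
    if np.any(y < 0):
        raise InvalidStateError("negative copy numbers")
    a = params.c.copy()
    for j in range(table.factors.shape[1]):
        col = table.factors[:, j]
        live = col >= 0
        a[live] *= y[col[live]]
    return a


def classify_er_state(state: np.ndarray, params: ERParams) -> str:
    """Open / closed / intermediate by the 90% / 10% acetylation rule.

    The acetylation level counts all acetylated sites, free or bound in an
    HDAC complex (a complexed site is still acetylated)."""
    frac = (state[A] + state[C_HDAC]) / params.n_sites
    if frac > OPEN_FRACTION:
        return "open"
    if frac < CLOSED_FRACTION:
        return "closed"
    return "intermediate"


# ---------------------------------------------------------------------------
# mean-field limit (Briggs-Haldane QSSA over the enzymes)
# ---------------------------------------------------------------------------

def _qssa_complexes(m: float, a: float, params: ERParams):
    """Quasi-steady-state HDM.M and HDAC.A complex counts at site fractions (m, a)."""
    c = params.c
    Y = params.n_sites
    g = (c[0] + c[3] * a * Y) * m * Y            # HDM binding propensity per free enzyme
    r = c[1] + c[2] + c[4] + c[5]                # HDM complex exit rate
    y5 = params.e_hdm * g / (g + r) if g + r > 0 else 0.0
    h = (c[8] + c[11] * m * Y) * a * Y           # HDAC binding propensity per free enzyme
    s = c[9] + c[10] + c[12] + c[13]             # HDAC complex exit rate
    y7 = params.e_hdac * h / (h + s) if h + s > 0 else 0.0
    return y5, y7


def reduced_meanfield_rhs(ma: np.ndarray, params: ERParams) -> np.ndarray:
    """Reduced mean-field flow on the independent slow fractions (m, a).

    Vectorised: `ma` may be (..., 2).  The unmodified fraction is
    u = 1 - m - a; enzyme complexes sit at their Briggs-Haldane values.
    """
    ma = np.asarray(ma, dtype=float)
    m = ma[..., 0]
    a = ma[..., 1]
    u = 1.0 - m - a
    c = params.c
    Y = params.n_sites
    g = (c[0] + c[3] * a * Y) * m * Y
    r = c[1] + c[2] + c[4] + c[5]
    y5 = np.where(g + r > 0, params.e_hdm * g / np.maximum(g + r, 1e-300), 0.0)
    h = (c[8] + c[11] * m * Y) * a * Y
    s = c[9] + c[10] + c[12] + c[13]
    y7 = np.where(h + s > 0, params.e_hdac * h / np.maximum(h + s, 1e-300), 0.0)
    dm = (c[6] + c[7] * m * Y) * u - (c[2] + c[5]) * y5 / Y
    da = (c[14] + c[15] * a * Y) * u - (c[10] + c[13]) * y7 / Y
    return np.stack([dm, da], axis=-1)


def er_meanfield_rhs(mua: np.ndarray, params: ERParams) -> np.ndarray:
    """Mean-field time derivatives of the slow site fractions (m, u, a).

    The complexed fraction is implicit (O(Z/Y)); the induced dynamics
    conserve m + u + a exactly.
    """
    mua = np.asarray(mua, dtype=float)
    if np.any(mua < -1e-12) or np.sum(mua) > 1 + 1e-9:
        raise InvalidStateError("fractions must be non-negative with m+u+a <= 1")
    m, u, a = mua
    c = params.c
    Y = params.n_sites
    y5, y7 = _qssa_complexes(m, a, params)
    dm = (c[6] + c[7] * m * Y) * u - (c[2] + c[5]) * y5 / Y
    da = (c[14] + c[15] * a * Y) * u - (c[10] + c[13]) * y7 / Y
    return np.array([dm, -dm - da, da])


def _project_simplex(ma: np.ndarray) -> np.ndarray:
    ma = np.clip(ma, 0.0, 1.0)
    tot = ma.sum(axis=-1)
    over = tot > 1.0
    if np.any(over):
        ma[over] /= tot[over][..., None]
    return ma


_ATTRACTOR_CACHE: dict = {}


def _params_key(params: ERParams):
    return (params.c.tobytes(), params.n_sites, float(params.e_hdm),
            float(params.e_hdac), params.y0)


def find_er_attractors(
    params: ERParams,
    n_grid: int = 11,
    t_relax: float = 400.0,
    dt: float = 0.05,
    tol: float = 1e-9,
    merge_tol: float = 1e-6,
) -> np.ndarray:
    """Stable fixed points (m*, a*) of the reduced mean-field flow.

    Relaxes an ``n_grid x n_grid`` lattice of initial fractions under RK4,
    then polishes converged points with Newton and merges duplicates within
    ``merge_tol`` relative distance.  Results are memoised per parameter set
    (the computation is deterministic).
    """
    key = _params_key(params) + (n_grid, t_relax, dt, tol, merge_tol)
    hit = _ATTRACTOR_CACHE.get(key)
    if hit is not None:
        return hit.copy()
    grid = np.linspace(0.0, 1.0, n_grid)
    mm, aa = np.meshgrid(grid, grid)
    pts = np.stack([mm.ravel(), aa.ravel()], axis=-1)
    pts = _project_simplex(pts)

    x = pts.copy()
    n_steps = int(t_relax / dt)
    chunk = 200
    for start in range(0, n_steps, chunk):
        for _ in range(min(chunk, n_steps - start)):
            k1 = reduced_meanfield_rhs(x, params)
            k2 = reduced_meanfield_rhs(_project_simplex(x + 0.5 * dt * k1), params)
            k3 = reduced_meanfield_rhs(_project_simplex(x + 0.5 * dt * k2), params)
            k4 = reduced_meanfield_rhs(_project_simplex(x + dt * k3), params)
            x = _project_simplex(x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4))
        speed = np.abs(reduced_meanfield_rhs(x, params)).max()
        if speed < tol:
            break

    resid = np.abs(reduced_meanfield_rhs(x, params)).max(axis=-1)
    x = x[resid < 1e-5]
    if x.shape[0] == 0:
        raise NumericalFailureError(
            "no initial condition relaxed to a fixed point", {"max_residual": float(resid.min())}
        )

    # merge, then Newton-polish representatives
    points: list[np.ndarray] = []
    for p in x:
        if not any(np.linalg.norm(p - q) <= merge_tol * max(1.0, np.linalg.norm(q)) + 1e-8 for q in points):
            points.append(p)
    polished = []
    from scipy.optimize import root

    for p in points:
        sol = root(lambda v: reduced_meanfield_rhs(v, params), p, tol=1e-12)
        q = sol.x if sol.success else p
        if _is_stable(q, params) and not any(
            np.linalg.norm(q - w) <= merge_tol * max(1.0, np.linalg.norm(w)) for w in polished
        ):
            polished.append(q)
    if not polished:
        raise NumericalFailureError("fixed-point polishing lost all candidates", {})
    order = np.argsort([p[1] for p in polished])  # ascending acetylation
    out = np.array([polished[i] for i in order])
    if len(_ATTRACTOR_CACHE) > 4096:
        _ATTRACTOR_CACHE.clear()
    _ATTRACTOR_CACHE[key] = out
    return out.copy()


def _is_stable(ma: np.ndarray, params: ERParams, eps: float = 1e-7) -> bool:
    jac = np.empty((2, 2))
    for j in range(2):
        dp = np.zeros(2)
        dp[j] = eps
        jac[:, j] = (reduced_meanfield_rhs(ma + dp, params) - reduced_meanfield_rhs(ma - dp, params)) / (2 * eps)
    return bool(np.all(np.real(np.linalg.eigvals(jac)) < 1e-8))


def classify_regime(params: ERParams, **kwargs) -> str:
    """Classify the mean-field ER regime as 'closed', 'bistable' or 'open'."""
    attr = find_er_attractors(params, **kwargs)
    if attr.shape[0] >= 2:
        return "bistable"
    return "open" if attr[0, 1] >= params.y0 else "closed"


def hme_phase_diagram(
    params: ERParams,
    hdm_grid: np.ndarray,
    hdac_grid: np.ndarray,
    **kwargs,
):
    """Regime label per (e_HDM, e_HDAC) grid point.

    Returns an (len(hdm_grid), len(hdac_grid)) array of labels in
    {'closed', 'bistable', 'open', 'undetermined'}.  Enzyme totals enter
    the mean-field limit through the QSSA complex levels only, so the
    diagram is deterministic given the rate constants.
    """
    hdm_grid = np.asarray(hdm_grid, dtype=float)
    hdac_grid = np.asarray(hdac_grid, dtype=float)
    if np.any(hdm_grid < 0) or np.any(hdac_grid < 0):
        raise ConfigurationError("enzyme grids must be non-negative")
    out = np.empty((hdm_grid.size, hdac_grid.size), dtype=object)
    for i, e1 in enumerate(hdm_grid):
        for j, e2 in enumerate(hdac_grid):
            p = replace(params, e_hdm=e1, e_hdac=e2)
            try:
                out[i, j] = classify_regime(p, **kwargs)
            except NumericalFailureError:
                out[i, j] = "undetermined"
    return out
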