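"""Heterogeneous ER-system ensembles: ABC generation, clustering, sensitivity.

Cell-to-cell variability in the co-factors of histone-modifying enzymes is
represented by an ensemble of rate-constant vectors {c_j} compatible with a
common set of reference trajectories ("raw data"): 10 stochastic realisations
of the acetylation level observed at 25 time points, summarised per time
point by the mean and standard deviation over realisations.  An ABC rejection
sampler draws candidate rate vectors from independent log-uniform priors,
re-simulates the observation protocol and accepts a candidate when both
summary statistics stay within prescribed tolerances of the reference at
every time point.

Bistable members are characterised by their mean transition times (tau+,
tau-) and the differentiation-gene ensemble is partitioned by k-means (k = 3)
in the (log10 tau+, log10 tau-) plane into the fast-opening/slow-closing
(red), slow-opening/fast-closing (blue) and slow-both (green) clusters.
Two-sample Kolmogorov-Smirnov comparisons of per-parameter marginals between
subensembles identify the rate constants that drive a given behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .er_model import ERParams, classify_regime, find_er_attractors, NumericalFailureError
from .ssa import TransitionTimes, er_initial_state, er_network, estimate_transition_times, sample_trajectory, spawn_seeds
from . import er_model

__all__ = [
    "RawData",
    "SummaryStats",
    "EnsembleRecord",
    "generate_raw_data",
    "summary_stats",
    "default_prior_ranges",
    "abc_rejection",
    "measure_ensemble_times",
    "kmeans_clusters",
    "ks_compare",
    "sensitivity_report",
    "empirical_cdf",
]


@dataclass(frozen=True)
class RawData:
    """Reference acetylation trajectories: (n_realisations, n_timepoints)."""

    levels: np.ndarray
    times: np.ndarray
    params: ERParams
    seed: int
    role: str  # 'ders' (near the open attractor) or 'pers' (near the closed)

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "levels", lv)
        if lv.ndim != 2 or lv.shape[1] != np.asarray(self.times).size:
            raise ValueError("levels must be (n_realisations, n_timepoints)")


@dataclass(frozen=True)
class SummaryStats:
    """Per-time-point mean and standard deviation over realisations."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("standard deviations must be non-negative")


@dataclass
class EnsembleRecord:
    """One accepted parameter set with its measured behaviour."""

    c: np.ndarray
    role: str
    regime: str = "unknown"
    times: TransitionTimes | None = None
    cluster: str = "none"


def _observation_grid(n_timepoints: int, t_end: float) -> np.ndarray:
    return np.linspace(t_end / n_timepoints, t_end, n_timepoints)


def _simulate_protocol(
    params: ERParams,
    x0: np.ndarray,
    seed: int,
    n_realisations: int,
    times: np.ndarray,
    max_events: int = 2_000_000,
) -> np.ndarray:
    net = er_network(params)
    seeds = spawn_seeds(seed, n_realisations)
    out = np.empty((n_realisations, times.size))
    for i, s in enumerate(seeds):
        states, complete, _ = sample_trajectory(net, x0, times, int(s), max_events)
        # acetylation level: free plus enzyme-bound acetylated sites
        out[i] = states[:, er_model.A] + states[:, er_model.C_HDAC]
    return out


def generate_raw_data(
    params: ERParams,
    role: str,
    seed: int,
    n_realisations: int = 10,
    n_timepoints: int = 25,
    t_end: float = 25.0,
) -> RawData:
    """Synthetic reference trajectories for one ER system.

    The landscape is poised for differentiation: a 'ders' system starts at its
    open mean-field attractor, a 'pers' system at its closed one.  Refuses
    parameters that are not bistable (the ensemble analysis presumes both
    attractors exist).
    """
    if role not in ("ders", "pers"):
        raise ValueError("role must be 'ders' or 'pers'")
    regime = classify_regime(params)
    if regime != "bistable":
        raise ValueError(f"reference parameters must be bistable, got {regime}")
    att = find_er_attractors(params)
    ma = att[-1] if role == "ders" else att[0]
    x0 = er_initial_state(params, ma)
    times = _observation_grid(n_timepoints, t_end)
    levels = _simulate_protocol(params, x0.astype(float), seed, n_realisations, times)
    return RawData(levels=levels, times=times, params=params, seed=seed, role=role)


def summary_stats(data: np.ndarray | RawData) -> SummaryStats:
    levels = data.levels if isinstance(data, RawData) else np.asarray(data, dtype=float)
    return SummaryStats(mean=levels.mean(axis=0), sd=levels.std(axis=0))


def default_prior_ranges(reference_c: np.ndarray, spread: float = 100.0) -> np.ndarray:
    """Independent log-uniform prior bounds: reference x [1/spread, spread]."""
    c = np.asarray(reference_c, dtype=float)
    return np.stack([c / spread, c * spread], axis=1)


def abc_rejection(
    raw: RawData,
    prior_ranges: np.ndarray,
    n_accept: int,
    seed: int,
    eps_mean: float | None = None,
    eps_sd: float | None = None,
    max_candidates: int = 2_000_000,
    probe: int = 2000,
    min_rate: float = 1e-6,
) -> tuple[list[EnsembleRecord], dict]:
    """ABC rejection sampler against the raw-data summary statistics.

    Candidates c ~ prod_j LogUniform(prior_ranges[j]) are re-simulated under
    the raw data's observation protocol (same initial state, grid and number
    of realisations) and accepted when

        max_t |mean_cand - mean_raw| <= eps_mean  and
        max_t |sd_cand   - sd_raw|   <= eps_sd.

    Default tolerances are 0.1 * n_sites and 0.15 * n_sites.  Aborts with
    tolerance advice if the acceptance rate over a probe batch falls below
    ``min_rate``.  Returns (records, provenance dict with acceptance rate).
    """
    if n_accept < 1:
        raise ValueError("n_accept must be >= 1")
    pr = np.asarray(prior_ranges, dtype=float)
    if pr.shape != (16, 2) or np.any(pr <= 0):
        raise ValueError("prior_ranges must be (16, 2) and positive")
    Y = raw.params.n_sites
    eps_mean = 0.1 * Y if eps_mean is None else eps_mean
    eps_sd = 0.15 * Y if eps_sd is None else eps_sd
    target = summary_stats(raw)
    att = find_er_attractors(raw.params)
    ma = att[-1] if raw.role == "ders" else att[0]
    x0 = er_initial_state(raw.params, ma).astype(float)

    rng = np.random.default_rng(seed)
    log_lo, log_hi = np.log(pr[:, 0]), np.log(pr[:, 1])
    accepted: list[EnsembleRecord] = []
    n_tried = 0
    while len(accepted) < n_accept:
        if n_tried >= max_candidates:
            raise RuntimeError(
                f"candidate budget exhausted: {len(accepted)}/{n_accept} accepted "
                f"after {n_tried} draws; widen tolerances or narrow the prior"
            )
        c = np.exp(rng.uniform(log_lo, log_hi))
        cand_seed = int(rng.integers(0, 2**31 - 1))
        p = replace(raw.params, c=c)
        levels = _simulate_protocol(p, x0, cand_seed, raw.levels.shape[0], raw.times)
        ss = summary_stats(levels)
        n_tried += 1
        if (np.max(np.abs(ss.mean - target.mean)) <= eps_mean
                and np.max(np.abs(ss.sd - target.sd)) <= eps_sd):
            accepted.append(EnsembleRecord(c=c, role=raw.role))
        if n_tried == probe and len(accepted) / probe < min_rate:
            raise RuntimeError(
                f"acceptance rate below {min_rate} over {probe} probes; "
                "widen eps_mean/eps_sd or narrow the prior ranges"
            )
    prov = {
        "n_tried": n_tried,
        "acceptance_rate": len(accepted) / n_tried,
        "eps_mean": eps_mean,
        "eps_sd": eps_sd,
        "seed": seed,
    }
    return accepted, prov


def measure_ensemble_times(
    records: list[EnsembleRecord],
    template: ERParams,
    seed: int,
    n_events: int = 10,
    t_max_per_passage: float = 3e4,
    max_events_per_passage: int = 5_000_000,
) -> list[EnsembleRecord]:
    """Classify each record's regime and measure (tau+, tau-) for bistable ones.

    Non-bistable records are retained and flagged; they carry no times and are
    excluded from clustering downstream.
    """
    seeds = spawn_seeds(seed, len(records))
    for rec, s in zip(records, seeds):
        p = replace(template, c=rec.c)
        try:
            rec.regime = classify_regime(p)
        except NumericalFailureError:
            rec.regime = "undetermined"
            continue
        if rec.regime != "bistable":
            continue
        rec.times = estimate_transition_times(
            p, n_events=n_events, seed=int(s),
            t_max_per_passage=t_max_per_passage,
            max_events_per_passage=max_events_per_passage,
        )
    return records


_CLUSTER_NAMES = ("red", "blue", "green")


def kmeans_clusters(
    records: list[EnsembleRecord],
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> list[EnsembleRecord]:
    """k-means on standardised (log10 tau+, log10 tau-) over bistable records.

    Cluster naming follows the centroid geometry: red has the smallest
    opening time tau+; of the remaining clusters, blue has the smallest
    closing time tau- and green the largest (slow in both directions).
    """
    usable = [r for r in records
              if r.times is not None and np.isfinite(r.times.tau_open) and np.isfinite(r.times.tau_close)]
    if k > len(usable):
        raise ValueError(f"k={k} exceeds the {len(usable)} records with finite times")
    X = np.log10([[r.times.tau_open, r.times.tau_close] for r in usable])
    mu, sig = X.mean(axis=0), np.maximum(X.std(axis=0), 1e-12)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit((X - mu) / sig)
    centroids = km.cluster_centers_ * sig + mu  # back to log10 time units
    order = {}
    if k == 3:
        red = int(np.argmin(centroids[:, 0]))
        rest = [i for i in range(3) if i != red]
        blue = rest[int(np.argmin(centroids[rest, 1]))]
        green = [i for i in rest if i != blue][0]
        order = {red: "red", blue: "blue", green: "green"}
    else:
        order = {i: f"cluster{i}" for i in range(k)}
    for r, lab in zip(usable, km.labels_):
        r.cluster = order[int(lab)]
    return records


def cluster_centroids(records: list[EnsembleRecord]) -> pd.DataFrame:
    """Median (tau+, tau-) per named cluster."""
    rows = []
    for name in sorted({r.cluster for r in records if r.cluster != "none"}):
        sel = [r for r in records if r.cluster == name]
        rows.append((
            name,
            float(np.median([r.times.tau_open for r in sel])),
            float(np.median([r.times.tau_close for r in sel])),
            len(sel),
        ))
    return pd.DataFrame(rows, columns=["cluster", "tau_open", "tau_close", "n"])


def ks_compare(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size == b.size and np.allclose(np.sort(a), np.sort(b)):
        return 0.0, 1.0
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


def empirical_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted support and empirical CDF heights (for export/plotting)."""
    x = np.sort(np.asarray(values, dtype=float))
    return x, np.arange(1, x.size + 1) / x.size


def sensitivity_report(
    c_matrix: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Pairwise KS comparison of every rate constant between subensembles.

    ``c_matrix`` is (n_records, 16); ``groups`` labels each record.  For each
    unordered pair of groups and each parameter: KS D, raw p-value, the
    direction of the first group's bias ('larger'/'smaller' by median
    difference) and significance at ``alpha``.  Raw p-values are reported; a
    Benjamini-Hochberg adjusted column can be added but is off by default.
    """
    c_matrix = np.asarray(c_matrix, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    rows = []
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            ga, gb = names[ai], names[bi]
            A = c_matrix[groups == ga]
            B = c_matrix[groups == gb]
            for j in range(c_matrix.shape[1]):
                D, p = ks_compare(A[:, j], B[:, j])
                dmed = float(np.median(A[:, j]) - np.median(B[:, j]))
                rows.append({
                    "group_a": ga, "group_b": gb, "parameter": f"c{j + 1}",
                    "D": D, "p_value": p,
                    "bias_a": "larger" if dmed > 0 else ("smaller" if dmed < 0 else "equal"),
                    "significant": p < alpha,
                })
    out = pd.DataFrame(rows)
    if benjamini_hochberg and len(out):
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(adj)
        q[order] = np.minimum(adj, 1.0)
        out["p_bh"] = q
    return out
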