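"""Frequentist baseline: ITPC tables, Wilcoxon signed-rank comparisons and
cluster-based permutation testing over electrodes.

This is the pipeline the Bayesian model is compared against: per-cell ITPC,
electrode-averaged per-participant traces, paired signed-rank tests with a
Hodges-Lehmann confidence interval, and a Maris-Oostenveld style max-mass
cluster permutation test controlling the family-wise error over electrodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

from .model import PhaseDataset

__all__ = [
    "ItpcTable",
    "WilcoxonResult",
    "ClusterResult",
    "itpc_table",
    "electrode_condition_difference",
    "wilcoxon_signed_rank",
    "signed_rank_null_distribution",
    "cluster_permutation_test",
    "knn_adjacency",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ITPC tables
# ---------------------------------------------------------------------------

@dataclass
class ItpcTable:
    """ITPC per (participant, condition, electrode) plus electrode averages.

    ``values`` is (P, C, E) with NaN for cells that had no trials;
    ``electrode_mean`` is the per-(participant, condition) arithmetic mean
    over electrodes with data.
    """

    values: np.ndarray
    electrode_mean: np.ndarray
    condition_labels: tuple[str, ...]
    electrode_labels: tuple[str, ...]

    def condition_index(self, label) -> int:
        if isinstance(label, (int, np.integer)):
            return int(label)
        return self.condition_labels.index(label)


def itpc_table(data: PhaseDataset) -> ItpcTable:
    """Per-cell inter-trial phase coherence |mean_k exp(i theta_pcek)|.

    Empty cells are excluded (NaN) with a logged warning; the electrode
    average ignores them.
    """
    z = np.where(data.mask, np.exp(1j * np.nan_to_num(data.phases)), 0.0)
    counts = data.mask.sum(axis=-1)
    n_empty = int(np.sum(counts == 0))
    if n_empty:
        log.warning("itpc_table: %d empty cells excluded", n_empty)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.abs(z.sum(axis=-1)) / counts
    values = np.where(counts > 0, values, np.nan)
    values = np.minimum(values, 1.0)
    with np.errstate(invalid="ignore"):
        electrode_mean = np.nanmean(values, axis=-1)
    return ItpcTable(values=values, electrode_mean=electrode_mean,
                     condition_labels=data.layout.condition_labels,
                     electrode_labels=data.layout.electrode_labels)


def electrode_condition_difference(table: ItpcTable, c1, c2,
                                   center: bool = False) -> np.ndarray:
    """Participant-averaged ITPC difference per electrode,
    <R(p, c1, e) - R(p, c2, e)>_p.

    ``center=True`` subtracts the across-electrode mean — the convention used
    in topographic difference maps, since the ITPC's upward bias shifts all
    electrodes together.
    """
    i1, i2 = table.condition_index(c1), table.condition_index(c2)
    diff = np.nanmean(table.values[:, i1, :] - table.values[:, i2, :], axis=0)
    if center:
        diff = diff - np.mean(diff)
    return diff


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with Hodges-Lehmann interval
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float           # W+ (sum of positive ranks)
    p_value: float
    n: int                     # non-zero differences used
    n_zero: int                # zero differences dropped
    estimate: float            # Hodges-Lehmann location (median Walsh average)
    ci_low: float
    ci_high: float
    ci_level: float
    alternative: str
    method: str                # "exact" or "approx"


@lru_cache(maxsize=None)
def signed_rank_null_distribution(n: int) -> np.ndarray:
    """Null pmf of W+ over 0..n(n+1)/2 by polynomial convolution (exact)."""
    counts = np.ones(1)
    for r in range(1, n + 1):
        new = np.zeros(counts.size + r)
        new[:counts.size] += counts
        new[r:] += counts
        counts = new
    return counts / counts.sum()


def _signed_rank_critical(n: int, alpha: float) -> int:
    """Largest k with P(W+ <= k) <= alpha/2 under the null (exact for
    n <= 150, normal approximation above); returns -1 if none."""
    if n <= 150:
        cdf = np.cumsum(signed_rank_null_distribution(n))
        ks = np.nonzero(cdf <= alpha / 2.0 + 1e-12)[0]
        return int(ks[-1]) if ks.size else -1
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return int(np.floor(mean + sd * sps.norm.ppf(alpha / 2.0)))


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided",
                         ci_level: float = 0.95) -> WilcoxonResult:
    """Paired signed-rank test with a Hodges-Lehmann confidence interval.

    Zero differences are dropped (signed-rank convention) and counted.  The
    p-value is exact (full enumeration of sign assignments) for n <= 25
    without ties, and a normal approximation with continuity correction
    otherwise.  The location estimate is the median of the Walsh averages
    (w_i + w_j)/2, i <= j, with the CI endpoints taken at the exact
    signed-rank critical values.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    n_zero = int(np.sum(d == 0.0))
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        log.warning("wilcoxon_signed_rank: only %d non-zero differences", n)
    if n_zero:
        log.info("wilcoxon_signed_rank: dropped %d zero differences", n_zero)

    ranks = sps.rankdata(np.abs(d))
    has_ties = np.unique(np.abs(d)).size != n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative=alternative, method=method,
                      correction=(method == "approx"))
    w_plus = float(np.sum(ranks[d > 0.0]))

    walsh = np.sort(np.add.outer(d, d)[np.triu_indices(n)] / 2.0)
    m = walsh.size
    alpha = 1.0 - ci_level
    k = _signed_rank_critical(n, alpha)
    if k < 0:
        ci_low, ci_high = -np.inf, np.inf
    else:
        ci_low = float(walsh[k])          # k+1-th smallest, 0-indexed
        ci_high = float(walsh[m - 1 - k])
    return WilcoxonResult(
        statistic=w_plus, p_value=float(res.pvalue), n=n, n_zero=n_zero,
        estimate=float(np.median(walsh)), ci_low=ci_low, ci_high=ci_high,
        ci_level=ci_level, alternative=alternative, method=method)


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    clusters: list[tuple[int, ...]]   # electrode indices per cluster
    cluster_mass: np.ndarray          # signed summed statistic per cluster
    p_values: np.ndarray              # permutation p per cluster
    n_permutations: int
    statistic: np.ndarray             # per-electrode paired statistic
    threshold: float                  # |stat| forming threshold
    seed: int | None

    def significant(self, alpha: float = 0.05) -> list[tuple[int, ...]]:
        return [c for c, p in zip(self.clusters, self.p_values) if p < alpha]


def knn_adjacency(coords: np.ndarray, k: int = 4) -> np.ndarray:
    """Symmetric k-nearest-neighbour adjacency from 2-D montage coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of electrodes")
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    nearest = np.argsort(d2, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    adj[rows, nearest.ravel()] = True
    return adj | adj.T


def _edge_list(adjacency: np.ndarray) -> np.ndarray:
    i, j = np.nonzero(np.triu(adjacency, k=1))
    return np.column_stack([i, j])


def _clusters_from_mask(mask: np.ndarray, edges: np.ndarray
                        ) -> list[np.ndarray]:
    """Connected components of the supra-threshold electrode subgraph
    (union-find over the precomputed edge list; called once per permutation,
    so it avoids any per-call sparse-matrix construction)."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    parent = {int(i): int(i) for i in idx}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    keep = mask[edges[:, 0]] & mask[edges[:, 1]]
    for a, b in edges[keep]:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in idx:
        groups.setdefault(find(int(i)), []).append(int(i))
    return [np.asarray(g) for g in groups.values()]


def _paired_stats(diffs: np.ndarray, signs: np.ndarray, stat: str,
                  ranks: np.ndarray | None = None) -> np.ndarray:
    """Per-electrode paired statistic for each sign-flip row.

    ``diffs`` is (P, E), ``signs`` is (B, P); returns (B, E)."""
    P = diffs.shape[0]
    if stat == "t":
        m = signs @ diffs / P
        ss = np.sum(diffs * diffs, axis=0) / P      # invariant to sign flips
        var = (ss - m * m) * P / (P - 1)
        var = np.maximum(var, 1e-300)
        return m / np.sqrt(var / P)
    # signed-rank z statistic
    pos = signs > 0
    w_plus = pos.astype(float) @ ranks              # (B, E)
    mean = P * (P + 1) / 4.0
    sd = np.sqrt(P * (P + 1) * (2 * P + 1) / 24.0)
    return (w_plus - mean) / sd


def cluster_permutation_test(table: ItpcTable, c1, c2,
                             adjacency: np.ndarray, *,
                             threshold_p: float = 0.05,
                             n_permutations: int = 1000,
                             seed: int | None = None,
                             stat: str = "t") -> ClusterResult:
    """Cluster-based permutation test of a paired condition difference.

    Per-electrode paired statistics (t by default, signed-rank z optionally)
    are thresholded at the two-sided ``threshold_p`` forming level; connected
    supra-threshold electrodes of the same sign form clusters whose mass is
    the summed statistic.  The null distribution of the maximal absolute
    cluster mass is built by randomly swapping the condition labels within
    participants (sign flips of the paired differences), and each observed
    cluster receives p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 500:
        raise ValueError("n_permutations must be at least 500")
    if stat not in ("t", "wilcoxon"):
        raise ValueError(f"unknown statistic {stat!r}")
    adjacency = np.asarray(adjacency, dtype=bool)
    E = table.values.shape[2]
    if adjacency.shape != (E, E):
        raise ValueError("adjacency must be E x E")
    n_comp, _ = connected_components(sparse.csr_matrix(adjacency),
                                     directed=False)
    if n_comp != 1:
        raise ValueError("adjacency graph must cover all electrodes in one "
                         "connected component")

    i1, i2 = table.condition_index(c1), table.condition_index(c2)
    diffs = table.values[:, i1, :] - table.values[:, i2, :]
    if np.any(~np.isfinite(diffs)):
        raise ValueError("cluster test requires complete (P, E) differences")
    P = diffs.shape[0]
    ranks = sps.rankdata(np.abs(diffs), axis=0) if stat == "wilcoxon" else None

    if stat == "t":
        crit = sps.t.ppf(1.0 - threshold_p / 2.0, df=P - 1)
    else:
        crit = sps.norm.ppf(1.0 - threshold_p / 2.0)

    edges = _edge_list(adjacency)
    obs = _paired_stats(diffs, np.ones((1, P)), stat, ranks)[0]
    clusters: list[np.ndarray] = []
    for sign in (1.0, -1.0):
        clusters.extend(_clusters_from_mask(sign * obs > crit, edges))
    masses = np.array([obs[c].sum() for c in clusters])

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, P))
    stats_perm = _paired_stats(diffs, signs, stat, ranks)
    null_max = np.zeros(n_permutations)
    for b in range(n_permutations):
        row = stats_perm[b]
        best = 0.0
        for sign in (1.0, -1.0):
            for comp in _clusters_from_mask(sign * row > crit, edges):
                best = max(best, abs(row[comp].sum()))
        null_max[b] = best

    p_values = np.array([
        (1.0 + np.sum(null_max >= abs(m))) / (1.0 + n_permutations)
        for m in masses])
    order = np.argsort(p_values) if masses.size else np.array([], dtype=int)
    return ClusterResult(
        clusters=[tuple(int(i) for i in clusters[j]) for j in order],
        cluster_mass=masses[order], p_values=p_values[order],
        n_permutations=n_permutations, statistic=obs, threshold=float(crit),
        seed=seed)
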