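"""Hierarchical consensus clustering, model-order selection, and partition
comparison.

Consensus clustering repeatedly clusters random subsamples of the patients
and records, for every pair, the fraction of co-sampled runs in which the two
patients landed in the same cluster.  A stable cluster number k yields a
near-binary consensus matrix; the empirical CDF of the consensus entries,
its area, the relative area increase from k-1 to k (delta-area), and the
proportion of ambiguous clustering (PAC — entries away from 0 and 1) are the
standard model-order diagnostics.  The inner clusterer is agglomerative with
Ward linkage on Euclidean distance; the final partition at each k clusters
the dissimilarity 1 - consensus with average linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import comb


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]  # k -> n x n consensus matrix
    assignments: dict[int, np.ndarray]  # k -> labels 1..k
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    chosen_k: int = 0
    n_resamples: int = 0
    item_fraction: float = 0.8
    notes: list[str] = field(default_factory=list)


def _upper_entries(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(m, k=1)
    return m[iu]


def _cdf_area(entries: np.ndarray) -> float:
    """Area under the empirical CDF of consensus entries over [0, 1]."""
    x = np.sort(entries)
    n = x.size
    # stepwise CDF: integral = sum over sorted points of (x_{i+1}-x_i) * F(x_i),
    # plus the tail up to 1
    xs = np.concatenate([[0.0], x, [1.0]])
    F = np.concatenate([[0.0], (np.arange(1, n + 1)) / n, [1.0]])
    return float(np.sum(np.diff(xs) * F[:-1]))


def pac_score(m: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal consensus
    entries strictly inside (lower, upper)."""
    e = _upper_entries(m)
    return float(np.mean((e > lower) & (e < upper)))


def consensus_cluster(
    X: np.ndarray,
    k_range: range | list[int] = range(2, 9),
    n_resamples: int = 500,
    item_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Resampled hierarchical consensus clustering over a range of k.

    For each k, ``n_resamples`` subsamples of ``ceil(item_fraction * n)``
    patients (without replacement) are Ward-clustered and cut at k; the
    consensus matrix divides pairwise co-clustering counts by co-sampling
    counts.  The final assignment at each k comes from average-linkage
    clustering of 1 - consensus.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    n = X.shape[0]
    ks = list(k_range)
    if n <= max(ks):
        raise ValueError("need more patients than the largest k")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    m_sub = int(np.ceil(item_fraction * n))

    result = ConsensusResult(
        k_range=ks,
        consensus={},
        assignments={},
        cdf_area={},
        delta_area={},
        pac={},
        n_resamples=n_resamples,
        item_fraction=item_fraction,
    )

    # one shared subsample sequence across k keeps co-sampling counts common
    subsamples = [rng.choice(n, size=m_sub, replace=False) for _ in range(n_resamples)]
    co_sampled = np.zeros((n, n))
    for idx in subsamples:
        co_sampled[np.ix_(idx, idx)] += 1
    if np.any(_upper_entries(co_sampled) == 0):
        raise ValueError(
            "some patient pair was never co-sampled; increase n_resamples"
        )

    sub_links = [linkage(X[idx], method="ward") for idx in subsamples]
    for k in ks:
        co_cluster = np.zeros((n, n))
        for idx, Z in zip(subsamples, sub_links):
            labels = fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_cluster[np.ix_(idx, idx)] += same
        consensus = co_cluster / co_sampled
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        result.consensus[k] = consensus

        diss = 1.0 - consensus
        np.fill_diagonal(diss, 0.0)
        Zf = linkage(squareform(diss, checks=False), method="average")
        result.assignments[k] = fcluster(Zf, t=k, criterion="maxclust")
        result.cdf_area[k] = _cdf_area(_upper_entries(consensus))
        result.pac[k] = pac_score(consensus)

    for i, k in enumerate(ks):
        if i == 0:
            result.delta_area[k] = result.cdf_area[k]
        else:
            prev = result.cdf_area[ks[i - 1]]
            result.delta_area[k] = (
                (result.cdf_area[k] - prev) / prev if prev > 0 else 0.0
            )
    result.chosen_k = select_k(result)
    return result


def select_k(result: ConsensusResult) -> int:
    """k minimizing the proportion of ambiguous clustering (PAC), ties broken
    by the larger consensus-CDF delta-area, then by the smaller k.

    PAC minimization is preferred over maximizing the delta-area because the
    delta-area of the smallest k is its raw CDF area (there is no smaller k
    to difference against), which dominates the curve whenever k_min is even
    moderately stable and systematically under-selects k; both statistics are
    retained in the result for inspection.  Degenerate diagnostics (every k
    equally stable, e.g. identical rows) fall back to the smallest k with a
    warning.
    """
    ks = result.k_range
    pacs = np.array([result.pac[k] for k in ks])
    deltas = np.array([result.delta_area[k] for k in ks])
    if len(ks) > 1 and np.allclose(pacs, pacs[0]) and np.allclose(deltas, deltas[0]):
        warnings.warn("degenerate consensus diagnostics; returning k_min")
        return ks[0]
    best = pacs.min()
    tied = [k for k, p in zip(ks, pacs) if np.isclose(p, best, atol=1e-12)]
    tied.sort(key=lambda k: (-result.delta_area[k], k))
    return tied[0]


def merge_small_clusters(
    assignments: np.ndarray,
    consensus: np.ndarray,
    min_frac: float = 0.05,
    manual_map: dict[int, int] | None = None,
) -> tuple[np.ndarray, dict[int, int]]:
    """Merge under-populated clusters to obtain balanced categories.

    With ``manual_map`` (original label -> merged label) the mapping is
    applied verbatim; it must cover every label present.  Otherwise each
    cluster holding fewer than ``min_frac`` of the patients is absorbed into
    the cluster with the highest mean pairwise consensus to it.  Returns the
    merged labels and the merge map actually applied.
    """
    labels = np.asarray(assignments)
    present = np.unique(labels)
    if manual_map is not None:
        missing = set(present) - set(manual_map)
        if missing:
            raise ValueError(f"manual_map does not cover labels {sorted(missing)}")
        merged = np.array([manual_map[l] for l in labels])
        return merged, dict(manual_map)

    n = labels.size
    merge_map = {int(l): int(l) for l in present}
    sizes = {int(l): int(np.sum(labels == l)) for l in present}
    # absorb smallest first; recompute after each merge
    while True:
        small = [l for l, s in sizes.items() if s < min_frac * n]
        if not small or len(sizes) == 1:
            break
        l = min(small, key=lambda c: (sizes[c], c))
        members = np.flatnonzero(np.isin(labels, [k for k, v in merge_map.items() if v == l]))
        best_target, best_score = None, -np.inf
        for t in sizes:
            if t == l:
                continue
            t_members = np.flatnonzero(
                np.isin(labels, [k for k, v in merge_map.items() if v == t])
            )
            score = float(consensus[np.ix_(members, t_members)].mean())
            if score > best_score:
                best_target, best_score = t, score
        sizes[best_target] += sizes.pop(l)
        for k, v in merge_map.items():
            if v == l:
                merge_map[k] = best_target
    merged = np.array([merge_map[int(l)] for l in labels])
    return merged, merge_map


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two partitions of the same items.

    ARI = (sum_ij C(n_ij,2) - E) / (0.5 [sum_i C(a_i,2) + sum_j C(b_j,2)] - E)
    with E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2); 1 for identical
    partitions, ~0 for independent ones.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same items")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_ij = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-one-cluster etc.)
        return 1.0 if np.array_equal(ai, bi) or sum_ij == max_index else 0.0
    return float((sum_ij - expected) / (max_index - expected))
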