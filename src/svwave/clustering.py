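"""DTW K-Means over compressed profiles and clustering validation.

K-Means under dynamic time warping uses DTW-barycenter averaging (DBA)
for the centroid update: each member series is aligned to the current
barycenter along its optimal warping path and the barycenter point is
replaced by the mean of the values aligned to it. Both the reassignment
and the DBA update are non-increasing in the within-cluster sum of
squared DTW distances, which the implementation asserts every iteration.

The consistency experiment re-runs the clustering on random subsets with
(a) a different seed and (b) the uncompressed signal, measuring in each
case the fraction of profiles that keep their cluster assignment (up to
label permutation), and compares the two agreement distributions with a
one-sided two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import ks_2samp
from sklearn.metrics import silhouette_score

from .config import PipelineConfig
from .signal_prep import dtw_distances_to, normalize, pool_average

_MONOTONE_TOL = 1e-8


@dataclass
class ClusterModel:
    k: int
    barycenters: List[np.ndarray]
    labels: np.ndarray
    inertia: float

    def shares(self) -> np.ndarray:
        """Fraction of profiles per cluster label."""
        counts = np.bincount(self.labels, minlength=self.k)
        return counts / max(1, self.labels.size)


def _dtw_to_centers(
    X: np.ndarray, centers: Sequence[np.ndarray], radius: Optional[int]
) -> np.ndarray:
    d = np.empty((X.shape[0], len(centers)))
    for ci, c in enumerate(centers):
        d[:, ci] = dtw_distances_to(X, c, radius)
    return d


def _kmeanspp_init(
    X: np.ndarray, k: int, rng: np.random.Generator, radius: Optional[int]
) -> List[np.ndarray]:
    """k-means++-style seeding on DTW distances."""
    n = X.shape[0]
    first = int(rng.integers(n))
    centers = [X[first].copy()]
    d2 = dtw_distances_to(X, centers[0], radius) ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers.append(X[idx].copy())
        d2 = np.minimum(d2, dtw_distances_to(X, centers[-1], radius) ** 2)
    return centers


def _dba_update(
    members: np.ndarray, center: np.ndarray, radius: Optional[int]
) -> np.ndarray:
    """One DBA step: average member values aligned to each center point."""
    from .signal_prep import _dtw_backtrace, _dtw_cost_matrix

    sums = np.zeros_like(center)
    counts = np.zeros(center.size)
    r = -1 if radius is None else int(radius)
    c = np.ascontiguousarray(center, dtype=np.float64)
    for series in members:
        s = np.ascontiguousarray(series, dtype=np.float64)
        pi, pj = _dtw_backtrace(_dtw_cost_matrix(c, s, r))
        np.add.at(sums, pi, s[pj])
        np.add.at(counts, pi, 1)
    counts[counts == 0] = 1
    return sums / counts


def kmeans_dtw(
    profiles: Sequence[Sequence[float]],
    k: int,
    seed: int,
    n_restarts: int = 10,
    max_iter: int = 30,
    radius: Optional[int] = None,
) -> ClusterModel:
    """DTW-barycenter K-Means, deterministic given ``seed``.

    Runs ``n_restarts`` k-means++-seeded replicates and keeps the one
    with the lowest inertia (sum of squared DTW distances to the
    assigned barycenter).
    """
    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} profiles, got {n}")
    rng = np.random.default_rng(seed)
    best: Optional[ClusterModel] = None
    for _ in range(n_restarts):
        centers = _kmeanspp_init(X, k, rng, radius)
        prev_inertia = np.inf
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            d = _dtw_to_centers(X, centers, radius)
            labels = d.argmin(axis=1)
            inertia = float((d.min(axis=1) ** 2).sum())
            assert inertia <= prev_inertia + _MONOTONE_TOL, (
                "DTW K-Means objective increased"
            )
            if prev_inertia - inertia < 1e-9:
                prev_inertia = inertia
                break
            prev_inertia = inertia
            for ci in range(k):
                members = X[labels == ci]
                if members.size:
                    centers[ci] = _dba_update(members, centers[ci], radius)
        d = _dtw_to_centers(X, centers, radius)
        labels = d.argmin(axis=1)
        inertia = float((d.min(axis=1) ** 2).sum())
        model = ClusterModel(k=k, barycenters=list(centers), labels=labels, inertia=inertia)
        if best is None or model.inertia < best.inertia:
            best = model
    assert best is not None
    return best


def dtw_distance_matrix(
    X: np.ndarray, radius: Optional[int] = None
) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n - 1):
        D[i, i + 1 :] = D[i + 1 :, i] = dtw_distances_to(X[i + 1 :], X[i], radius)
    return D


def silhouette_dtw(
    X: np.ndarray, labels: np.ndarray, radius: Optional[int] = None
) -> float:
    """Mean silhouette under DTW distance (precomputed matrix)."""
    D = dtw_distance_matrix(X, radius)
    return float(silhouette_score(D, labels, metric="precomputed"))


def estimate_k(
    profiles: Sequence[Sequence[float]],
    candidate_ks: Sequence[int],
    runs: int,
    seed: int,
    subsample_size: Optional[int] = None,
    radius: Optional[int] = None,
) -> int:
    """Pick k by mean silhouette over bootstrap subsamples (no replacement).

    Each run draws a subsample, clusters it at every candidate k, and
    scores the partition with the DTW silhouette; the k with the highest
    mean silhouette across runs wins.
    """
    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if subsample_size is None:
        subsample_size = min(n, 50)
    if subsample_size > n:
        raise ValueError("subsample_size exceeds pool size")
    if max(candidate_ks) >= subsample_size:
        raise ValueError("subsample too small for the largest candidate k")
    rng = np.random.default_rng(seed)
    scores: Dict[int, List[float]] = {k: [] for k in candidate_ks}
    for _ in range(runs):
        idx = rng.choice(n, size=subsample_size, replace=False)
        sub = X[idx]
        run_seed = int(rng.integers(2**31 - 1))
        for k in candidate_ks:
            model = kmeans_dtw(sub, k, seed=run_seed, n_restarts=3, radius=radius)
            if len(np.unique(model.labels)) < 2:
                scores[k].append(-1.0)
            else:
                scores[k].append(silhouette_dtw(sub, model.labels, radius))
    means = {k: float(np.mean(v)) for k, v in scores.items()}
    return max(sorted(candidate_ks), key=lambda k: means[k])


def label_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Max over label permutations of the co-assignment fraction.

    Solved as a maximum-weight matching on the contingency table, so it
    is permutation-invariant and symmetric in its arguments.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("label vectors differ in length")
    ka, kb = a.max() + 1, b.max() + 1
    contingency = np.zeros((ka, kb))
    for x, y in zip(a, b):
        contingency[x, y] += 1
    rows, cols = linear_sum_assignment(-contingency)
    return float(contingency[rows, cols].sum() / a.size)


def consistency_validation(
    profile_pool: Sequence[Sequence[float]],
    repeats: int,
    subset_size: int,
    pool_window: int,
    seed: int,
    k: int = 2,
    radius: Optional[int] = None,
    kmeans_restarts: int = 3,
) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Compression-consistency experiment.

    Per repeat, on a random subset of raw profiles: C0 clusters the
    compressed+normalized subset with seed A, C1 with seed B, C2 the
    uncompressed+normalized subset with seed A. Returns the seed-effect
    agreement distribution (C0 vs C1), the compression-effect
    distribution (C0 vs C2), and the one-sided two-sample KS comparison
    (H1: compression-effect agreements stochastically larger).
    """
    X = np.asarray(profile_pool, dtype=float)
    n = X.shape[0]
    if subset_size > n:
        raise ValueError("subset_size exceeds pool size")
    rng = np.random.default_rng(seed)
    seed_effect = np.empty(repeats)
    comp_effect = np.empty(repeats)
    for r in range(repeats):
        idx = rng.choice(n, size=subset_size, replace=False)
        raw = X[idx]
        compressed = np.stack([pool_average(p, pool_window) for p in raw])
        comp_norm = np.stack([normalize(p) for p in compressed])
        raw_norm = np.stack([normalize(p) for p in raw])
        seed_a = int(rng.integers(2**31 - 1))
        seed_b = int(rng.integers(2**31 - 1))
        c0 = kmeans_dtw(comp_norm, k, seed_a, n_restarts=kmeans_restarts, radius=radius)
        c1 = kmeans_dtw(comp_norm, k, seed_b, n_restarts=kmeans_restarts, radius=radius)
        c2 = kmeans_dtw(raw_norm, k, seed_a, n_restarts=kmeans_restarts, radius=radius)
        seed_effect[r] = label_agreement(c0.labels, c1.labels)
        comp_effect[r] = label_agreement(c0.labels, c2.labels)
    ks = ks_2samp(comp_effect, seed_effect, alternative="less")
    return seed_effect, comp_effect, float(ks.statistic), float(ks.pvalue)


def write_consistency_report(
    seed_effect: np.ndarray,
    comp_effect: np.ndarray,
    ks_statistic: float,
    p_value: float,
    out_prefix: str,
) -> None:
    """TSV of the two agreement distributions plus a histogram figure."""
    import pandas as pd

    df = pd.DataFrame(
        {"seed_effect": seed_effect, "compression_effect": comp_effect}
    )
    df.to_csv(out_prefix + ".tsv", sep="\t", index=False)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0.5, 1.0, 21)
    ax.hist(seed_effect, bins=bins, alpha=0.6, label="seed effect (C0 vs C1)")
    ax.hist(comp_effect, bins=bins, alpha=0.6, label="compression effect (C0 vs C2)")
    ax.set_xlabel("agreement (fraction of co-assigned profiles)")
    ax.set_ylabel("runs")
    ax.set_title(f"KS = {ks_statistic:.3f}, p = {p_value:.3g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_prefix + ".png", dpi=120)
    plt.close(fig)
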