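"""Motif discovery: reference-point pruned neighbour search, bootstrapping,
and iterative motif merging.

The neighbour search linearizes the SAX segment space against two fixed
reference words — the SAX transforms of sine and cosine sampled on
[0, pi/2] — and only evaluates the full SAX distance for pairs whose 1D
projections onto *both* reference axes are close. Because the SAX
MINDIST assigns distance zero to adjacent symbols it is not a metric, so
the projection filter carries an analytically derived slack term that
makes the pruning exactly lossless: the similarity groups are identical
to brute-force all-pairs grouping, just cheaper to obtain.

Groups are formed by single linkage over verified pairs within ``eps``
and ranked by size (prominence), ties broken by tighter mean intra-group
distance. Discovery is bootstrapped over random profile subsets; each
subset is clustered (DTW K-Means, k=2), discovery restricted to the
dominant cluster when it holds more than the representative share (66%),
and the per-subset top representatives are iteratively merged — closest
pair first, support-weighted symbol averaging — into the predominant
motif per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .clustering import ClusterModel, kmeans_dtw
from .config import PipelineConfig
from .signal_prep import (
    SAXWord,
    Segment,
    normalize,
    pool_average,
    sax_breakpoints,
    sax_cell_table,
    sax_mindist,
    sax_transform,
    segment_sliding,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------- reference nodes


@dataclass(frozen=True)
class ReferenceNodes:
    r_sin: SAXWord
    r_cos: SAXWord


def make_references(seg_len: int, alphabet_size: int) -> ReferenceNodes:
    """SAX transforms of sin and cos sampled at seg_len points on [0, pi/2].

    Each curve is z-normalized before discretisation; the construction is
    fully deterministic, so the reference axes are identical across runs.
    """
    if seg_len < 2:
        raise ValueError("seg_len must be >= 2")
    t = np.linspace(0.0, np.pi / 2, seg_len)
    r_sin = sax_transform(normalize(np.sin(t)), alphabet_size)
    r_cos = sax_transform(normalize(np.cos(t)), alphabet_size)
    return ReferenceNodes(r_sin=r_sin, r_cos=r_cos)


# ------------------------------------------------------------ group search


@dataclass
class SimilarityGroup:
    members: List[Segment]
    representative: SAXWord
    rank: int
    mean_distance: float = 0.0

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SearchStats:
    """Bookkeeping for the pruning efficiency claim."""

    n_segments: int = 0
    n_pairs_total: int = 0
    n_pairs_evaluated: int = 0


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _mindist_to_reference(
    symbols: np.ndarray, ref: np.ndarray, table: np.ndarray, scale: float
) -> np.ndarray:
    cells = table[symbols, ref[None, :]]
    return scale * np.sqrt((cells**2).sum(axis=1))


def pruning_slack(alphabet_size: int, original_length: int) -> float:
    """Valid filter slack: sqrt(n) times the widest interior symbol cell.

    If mindist(x, y) <= eps then the reference projections differ by at
    most eps + this slack (interval-distance bound; positions pairing the
    two opposite extreme symbols are excluded by the caller's guard).
    """
    bps = sax_breakpoints(alphabet_size)
    widths = np.diff(bps)
    return float(np.sqrt(original_length) * widths.max()) if widths.size else 0.0


def _filter_guard(alphabet_size: int, original_length: int, seg_len: int) -> float:
    """Smallest mindist a pair with opposite extreme symbols can have."""
    bps = sax_breakpoints(alphabet_size)
    cross = bps[-1] - bps[0]
    return float(np.sqrt(original_length / seg_len) * cross)


def knn_search_modified(
    segments: Sequence[Segment],
    refs: ReferenceNodes,
    eps: float,
    original_length: int,
    return_stats: bool = False,
):
    """Group SAX segments into ranked similarity groups.

    Candidate pairs are those close on both reference axes (within
    ``eps`` plus the lossless slack); only candidates get an exact SAX
    distance evaluation, and pairs within ``eps`` are merged by single
    linkage. Output is identical to brute-force all-pairs grouping.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    segs = list(segments)
    n = len(segs)
    stats = SearchStats(n_segments=n, n_pairs_total=n * (n - 1) // 2)
    if n == 0:
        return ([], stats) if return_stats else []
    alphabet = segs[0].word.alphabet_size
    w = len(segs[0])
    for s in segs:
        if len(s) != w or s.word.alphabet_size != alphabet:
            raise ValueError("segments differ in length or alphabet")

    table = sax_cell_table(alphabet)
    sq_table = table**2
    scale = np.sqrt(original_length / w)
    symbols = np.array([s.word.symbols for s in segs], dtype=np.intp)
    ref_sin = np.array(refs.r_sin.symbols, dtype=np.intp)
    ref_cos = np.array(refs.r_cos.symbols, dtype=np.intp)
    if len(refs.r_sin) != w or refs.r_sin.alphabet_size != alphabet:
        raise ValueError("reference nodes incompatible with segments")
    S = _mindist_to_reference(symbols, ref_sin, table, scale)
    C = _mindist_to_reference(symbols, ref_cos, table, scale)

    use_filter = eps < _filter_guard(alphabet, original_length, w)
    slack = pruning_slack(alphabet, original_length)
    thr = eps + slack

    uf = _UnionFind(n)
    order = np.argsort(S, kind="stable")
    S_sorted = S[order]
    # sweep in S-order; only pairs within thr on the S axis can be candidates
    for a in range(n):
        i = order[a]
        b_hi = np.searchsorted(S_sorted, S_sorted[a] + thr, side="right")
        js = order[a + 1 : b_hi]
        if use_filter and js.size:
            js = js[np.abs(C[js] - C[i]) <= thr]
        if not js.size:
            continue
        d2 = (sq_table[symbols[i][None, :], symbols[js]]).sum(axis=1)
        d = scale * np.sqrt(d2)
        stats.n_pairs_evaluated += int(js.size)
        for j in js[d <= eps]:
            uf.union(i, int(j))
    if not use_filter:
        logger.debug("eps %.3g at or above filter guard; pruning disabled", eps)

    roots: Dict[int, List[int]] = {}
    for i in range(n):
        roots.setdefault(uf.find(i), []).append(i)

    groups: List[SimilarityGroup] = []
    # medoid / mean-distance on a deterministic subsample for huge groups;
    # only affects tie-breaking and the reported representative, not membership
    medoid_cap = 400
    for members_idx in roots.values():
        midx = np.array(members_idx, dtype=np.intp)
        if midx.size == 1:
            rep = segs[int(midx[0])].word
            mean_d = 0.0
        else:
            pick = midx
            if midx.size > medoid_cap:
                stride = int(np.ceil(midx.size / medoid_cap))
                pick = midx[::stride]
            sub = symbols[pick]
            sq = np.zeros((pick.size, pick.size))
            for col in range(w):
                c = sub[:, col]
                sq += sq_table[c[:, None], c[None, :]]
            dmat = scale * np.sqrt(sq)
            mean_rows = dmat.sum(axis=1) / (pick.size - 1)
            rep = segs[int(pick[int(mean_rows.argmin())])].word
            mean_d = float(dmat[np.triu_indices(pick.size, 1)].mean())
        groups.append(
            SimilarityGroup(
                members=[segs[int(i)] for i in midx],
                representative=rep,
                rank=0,
                mean_distance=mean_d,
            )
        )
    groups.sort(key=lambda g: (-g.size, g.mean_distance))
    for r, g in enumerate(groups):
        g.rank = r
    return (groups, stats) if return_stats else groups


# --------------------------------------------------------- cluster scoping


def select_cluster_scope(model: ClusterModel, threshold_share: float = 66.0) -> Set[int]:
    """Restrict discovery to the dominant cluster only when it holds
    strictly more than ``threshold_share`` percent of profiles."""
    shares = model.shares() * 100.0
    top = int(shares.argmax())
    if shares[top] > threshold_share:
        return {top}
    return set(range(model.k))


# ------------------------------------------------------------ bootstrapping


@dataclass
class MotifCandidate:
    sax: SAXWord
    cluster: int
    support: int = 1
    bp_offset: float = 0.0  # breakpoint position within the segment (pooled pts)


@dataclass
class Motif:
    """Predominant SAX motif for one (svtype, side, genotype, cluster)."""

    sax: SAXWord
    support: int
    svtype: str = ""
    side: str = ""
    genotype: str = ""
    cluster: int = 0
    bp_offset: int = 0
    convincing: bool = True


def calibrate_eps(
    segments: Sequence[Segment],
    original_length: int,
    percentile: float = 5.0,
    max_sample: int = 400,
    seed: int = 0,
) -> float:
    """eps default: the 5th percentile of pairwise SAX distances on a
    calibration sample of segments."""
    rng = np.random.default_rng(seed)
    segs = list(segments)
    if len(segs) > max_sample:
        idx = rng.choice(len(segs), size=max_sample, replace=False)
        segs = [segs[int(i)] for i in idx]
    symbols = np.array([s.word.symbols for s in segs], dtype=np.intp)
    alphabet = segs[0].word.alphabet_size
    w = symbols.shape[1]
    sq_table = sax_cell_table(alphabet) ** 2
    n = symbols.shape[0]
    sq = np.zeros((n, n))
    for col in range(w):
        c = symbols[:, col]
        sq += sq_table[c[:, None], c[None, :]]
    d = np.sqrt(original_length / w) * np.sqrt(sq[np.triu_indices(n, 1)])
    return float(np.percentile(d, percentile))


@dataclass
class BootstrapResult:
    """Per-canonical-cluster candidate lists plus the eps actually used."""

    candidates: Dict[int, List[MotifCandidate]] = field(default_factory=dict)
    eps: float = 0.0


def bootstrap_discover(
    profiles: Sequence[Sequence[float]],
    config: PipelineConfig,
    seed: int,
    sample_stats: Optional[Sequence[Tuple[float, float]]] = None,
) -> BootstrapResult:
    """Bootstrap motif discovery over one (svtype, side, genotype) pool.

    Each of ``config.n_bootstrap`` subsets of ``config.bootstrap_size``
    profiles (without replacement when the pool allows, else with
    replacement) runs pool -> normalize -> DTW K-Means (k=2) -> cluster
    scoping -> SAX -> sliding segmentation -> pruned neighbour search,
    and emits the top-ranked group representative per in-scope cluster.
    Cluster ids are canonicalised by size (0 = larger cluster) so that
    candidates from different subsets can be merged per cluster.
    """
    X = np.asarray(profiles, dtype=float)
    if X.size == 0:
        raise ValueError("empty profile pool")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    refs = make_references(config.seg_len, config.alphabet_size)
    original_length = config.seg_len * config.pool_window
    replace = n < config.bootstrap_size
    if replace:
        logger.warning(
            "pool of %d profiles smaller than bootstrap_size=%d; "
            "sampling with replacement",
            n,
            config.bootstrap_size,
        )
    eps = config.eps
    candidates: Dict[int, List[MotifCandidate]] = {}
    for _ in range(config.n_bootstrap):
        idx = rng.choice(n, size=config.bootstrap_size, replace=replace)
        pooled = np.stack([pool_average(X[i], config.pool_window) for i in idx])
        if sample_stats is not None and config.normalize_mode == "sample":
            norm = np.stack(
                [normalize(pooled[a], sample_stats[int(i)]) for a, i in enumerate(idx)]
            )
        else:
            norm = np.stack([normalize(p) for p in pooled])
        model = kmeans_dtw(
            norm,
            config.k_clusters,
            seed=int(rng.integers(2**31 - 1)),
            n_restarts=config.kmeans_restarts,
            max_iter=config.kmeans_max_iter,
            radius=config.sakoe_chiba_radius,
        )
        scope = select_cluster_scope(model, config.representative_share)
        # canonical ids: order clusters by decreasing size
        size_order = np.argsort(-np.bincount(model.labels, minlength=model.k), kind="stable")
        canon = {int(orig): rank for rank, orig in enumerate(size_order)}
        for orig_cluster in scope:
            members = norm[model.labels == orig_cluster]
            segments: List[Segment] = []
            for p_i, prof in enumerate(members):
                word = sax_transform(prof, config.alphabet_size)
                segments.extend(
                    segment_sliding(word, config.seg_len, config.seg_step, profile_index=p_i)
                )
            if not segments:
                continue
            if eps is None:
                eps = calibrate_eps(
                    segments, original_length, seed=int(rng.integers(2**31 - 1))
                )
                logger.info("calibrated eps = %.4f", eps)
            groups = knn_search_modified(segments, refs, eps, original_length)
            if not groups:
                continue
            top = groups[0]
            center = config.word_length // 2  # breakpoint index in pooled units
            offsets = [center - m.offset for m in top.members]
            candidates.setdefault(canon[orig_cluster], []).append(
                MotifCandidate(
                    sax=top.representative,
                    cluster=canon[orig_cluster],
                    support=1,
                    bp_offset=float(np.median(offsets)),
                )
            )
    return BootstrapResult(candidates=candidates, eps=0.0 if eps is None else eps)


# ----------------------------------------------------------------- merging


def merge_motifs(
    candidates: Sequence[MotifCandidate],
    merge_eps: float,
    original_length: int,
) -> Motif:
    """Iteratively merge bootstrap candidates into the predominant motif.

    While any two family representatives are within ``merge_eps`` in SAX
    distance, the closest pair is merged; the merged representative is
    the per-position support-weighted mean of symbol indices, rounded
    half-to-even. The representative of the largest family wins; its
    support is the sum of member supports.
    """
    if not candidates:
        raise ValueError("no candidates to merge")
    fams: List[Dict] = [
        {
            "symbols": np.asarray(c.sax.symbols, dtype=float),
            "support": c.support,
            "bp_offset": c.bp_offset,
            "alphabet": c.sax.alphabet_size,
        }
        for c in candidates
    ]

    def dist(f1: Dict, f2: Dict) -> float:
        a = SAXWord(tuple(int(round(s)) for s in f1["symbols"]), f1["alphabet"])
        b = SAXWord(tuple(int(round(s)) for s in f2["symbols"]), f2["alphabet"])
        return sax_mindist(a, b, original_length)

    while len(fams) > 1:
        best = None
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                d = dist(fams[i], fams[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        assert best is not None
        d, i, j = best
        if d > merge_eps:
            break
        wi, wj = fams[i]["support"], fams[j]["support"]
        merged = {
            "symbols": (fams[i]["symbols"] * wi + fams[j]["symbols"] * wj) / (wi + wj),
            "support": wi + wj,
            "bp_offset": (fams[i]["bp_offset"] * wi + fams[j]["bp_offset"] * wj)
            / (wi + wj),
            "alphabet": fams[i]["alphabet"],
        }
        fams = [f for a, f in enumerate(fams) if a not in (i, j)] + [merged]

    top = max(fams, key=lambda f: f["support"])
    symbols = tuple(
        int(np.clip(np.round(s), 0, top["alphabet"] - 1)) for s in top["symbols"]
    )
    return Motif(
        sax=SAXWord(symbols, top["alphabet"]),
        support=int(top["support"]),
        bp_offset=int(round(top["bp_offset"])),
    )


def write_motif_files(motifs: Sequence[Motif], prefix: str, config: PipelineConfig) -> None:
    """One record per (svtype, side, genotype, cluster): TSV + JSON with the
    base-N SAX string and the parameters needed to reuse the motif."""
    import json

    rows = []
    for m in motifs:
        rows.append(
            {
                "svtype": m.svtype,
                "side": m.side,
                "genotype": m.genotype,
                "cluster": m.cluster,
                "sax": m.sax.to_string(),
                "alphabet_size": m.sax.alphabet_size,
                "seg_len": len(m.sax),
                "support": m.support,
                "bp_offset": m.bp_offset,
                "convincing": m.convincing,
            }
        )
    header = list(rows[0].keys()) if rows else [
        "svtype", "side", "genotype", "cluster", "sax", "alphabet_size",
        "seg_len", "support", "bp_offset", "convincing",
    ]
    with open(prefix + ".tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[h]) for h in header) + "\n")
    payload = {
        "parameters": {
            "alphabet_size": config.alphabet_size,
            "seg_len": config.seg_len,
            "pool_window": config.pool_window,
            "half_width": config.half_width,
        },
        "motifs": rows,
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_motif_json(path) -> Tuple[List[Motif], Dict]:
    """Load motifs and their generation parameters from a JSON motif file."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    motifs = []
    for r in payload["motifs"]:
        motifs.append(
            Motif(
                sax=SAXWord.from_string(r["sax"], r["alphabet_size"]),
                support=r["support"],
                svtype=r["svtype"],
                side=r["side"],
                genotype=r["genotype"],
                cluster=r["cluster"],
                bp_offset=r["bp_offset"],
                convincing=bool(r["convincing"]),
            )
        )
    return motifs, payload["parameters"]


def discover_predominant_motifs(
    profiles: Sequence[Sequence[float]],
    config: PipelineConfig,
    seed: int,
    svtype: str = "",
    side: str = "",
    genotype: str = "",
    sample_stats: Optional[Sequence[Tuple[float, float]]] = None,
) -> List[Motif]:
    """Full discovery for one combination: bootstrap, then merge per cluster.

    A motif is flagged unconvincing when its merged family absorbed less
    than ``config.support_floor`` percent of that cluster's bootstrap
    candidates (the insertion-class outcome: the waveform carries no
    reproducible pattern).
    """
    result = bootstrap_discover(profiles, config, seed, sample_stats)
    original_length = config.seg_len * config.pool_window
    # merge_eps defaults to the (possibly run-time calibrated) grouping eps
    merge_eps = config.merge_eps if config.merge_eps is not None else result.eps
    motifs: List[Motif] = []
    for cluster_id in sorted(result.candidates):
        cands = result.candidates[cluster_id]
        motif = merge_motifs(cands, merge_eps, original_length)
        motif.svtype, motif.side, motif.genotype = svtype, side, genotype
        motif.cluster = cluster_id
        share = 100.0 * motif.support / len(cands)
        motif.convincing = share >= config.support_floor
        motifs.append(motif)
    return motifs
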