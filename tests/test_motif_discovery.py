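"""Reference nodes, pruned neighbour search, scoping, bootstrapping, merging."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from svwave.clustering import ClusterModel
from svwave.config import PipelineConfig
from svwave.fixtures import planted_motif_dataset, step_template
from svwave.motif_discovery import (
    MotifCandidate,
    bootstrap_discover,
    calibrate_eps,
    knn_search_modified,
    make_references,
    merge_motifs,
    select_cluster_scope,
)
from svwave.signal_prep import (
    SAXWord,
    Segment,
    normalize,
    pairwise_mindist,
    sax_transform,
    segment_sliding,
)


class TestReferences:
    def test_sine_non_decreasing_cosine_non_increasing(self):
        refs = make_references(32, 24)
        s, c = refs.r_sin.symbols, refs.r_cos.symbols
        assert all(a <= b for a, b in zip(s, s[1:]))
        assert all(a >= b for a, b in zip(c, c[1:]))

    def test_sin_is_reversed_cos(self):
        # sin(t) = cos(pi/2 - t): on symmetric sampling the words mirror
        refs = make_references(32, 24)
        assert refs.r_sin.symbols == tuple(reversed(refs.r_cos.symbols))

    def test_deterministic(self):
        a = make_references(32, 24)
        b = make_references(32, 24)
        assert a.r_sin.symbols == b.r_sin.symbols
        assert a.r_cos.symbols == b.r_cos.symbols


def _random_segments(n, seed, seg_len=16, alphabet=12):
    """Segments cut from SAX words of random-walk profiles."""
    rng = np.random.default_rng(seed)
    segs = []
    i = 0
    while len(segs) < n:
        prof = np.cumsum(rng.normal(size=2 * seg_len))
        word = sax_transform(normalize(prof), alphabet)
        segs.extend(segment_sliding(word, seg_len, seg_len // 2, profile_index=i))
        i += 1
    return segs[:n]


def _bruteforce_partition(segments, eps, original_length):
    """Independent oracle: full pairwise matrix + connected components."""
    sym = np.array([s.word.symbols for s in segments])
    D = pairwise_mindist(sym, segments[0].word.alphabet_size, original_length)
    n = len(segments)
    adj = sp.csr_matrix((D <= eps) & ~np.eye(n, dtype=bool))
    _, labels = connected_components(adj, directed=False)
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}


def _partition_of(groups, segments):
    index = {id(s): i for i, s in enumerate(segments)}
    return {frozenset(index[id(m)] for m in g.members) for g in groups}


class TestKNNSearch:
    def test_identical_segments_one_group(self):
        seg = Segment(SAXWord((3,) * 16, 12), 0, 0)
        segs = [Segment(seg.word, i, 0) for i in range(10)]
        refs = make_references(16, 12)
        groups = knn_search_modified(segs, refs, eps=0.5, original_length=16)
        assert len(groups) == 1
        assert groups[0].size == 10

    def test_eps_zero_far_segments_are_singletons(self):
        words = [(0,) * 16, (4,) * 16, (8,) * 16, (11,) * 16]
        segs = [Segment(SAXWord(w, 12), i, 0) for i, w in enumerate(words)]
        refs = make_references(16, 12)
        groups = knn_search_modified(segs, refs, eps=0.0, original_length=16)
        assert len(groups) == 4
        assert all(g.size == 1 for g in groups)

    def test_negative_eps_rejected(self):
        refs = make_references(16, 12)
        with pytest.raises(ValueError):
            knn_search_modified([], refs, eps=-1.0, original_length=16)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_grouping(self, seed):
        """Pruned search produces exactly the brute-force partition."""
        segs = _random_segments(120, seed)
        eps = calibrate_eps(segs, 32, percentile=10.0, seed=seed)
        refs = make_references(16, 12)
        groups = knn_search_modified(segs, refs, eps, original_length=32)
        assert _partition_of(groups, segs) == _bruteforce_partition(segs, eps, 32)

    def test_prunes_on_dispersed_data(self):
        """Level-separated constant words: strictly fewer evaluations than
        all pairs, with the partition still exact."""
        words = [(lvl,) * 16 for lvl in range(12) for _ in range(6)]
        segs = [Segment(SAXWord(w, 12), i, 0) for i, w in enumerate(words)]
        refs = make_references(16, 12)
        groups, stats = knn_search_modified(
            segs, refs, eps=0.1, original_length=256, return_stats=True
        )
        assert stats.n_pairs_evaluated < stats.n_pairs_total
        assert _partition_of(groups, segs) == _bruteforce_partition(segs, 0.1, 256)

    def test_ranking_by_size(self):
        words = [(3,) * 16] * 5 + [(9,) * 16] * 3
        segs = [Segment(SAXWord(w, 12), i, 0) for i, w in enumerate(words)]
        refs = make_references(16, 12)
        groups = knn_search_modified(segs, refs, eps=0.2, original_length=16)
        assert [g.size for g in groups] == [5, 3]
        assert [g.rank for g in groups] == [0, 1]


class TestClusterScope:
    def _model(self, n_top, n_other):
        labels = np.array([0] * n_top + [1] * n_other)
        return ClusterModel(k=2, barycenters=[np.zeros(2)] * 2, labels=labels, inertia=0)

    def test_dominant_cluster_only(self):
        assert select_cluster_scope(self._model(70, 30)) == {0}

    def test_even_split_keeps_both(self):
        assert select_cluster_scope(self._model(50, 50)) == {0, 1}

    def test_boundary_share_keeps_both(self):
        # exactly 66% is not "more than 66%"
        assert select_cluster_scope(self._model(66, 34)) == {0, 1}

    def test_just_above_boundary_restricts(self):
        assert select_cluster_scope(self._model(67, 33)) == {0}


class TestMerge:
    def test_identical_candidates(self):
        w = SAXWord((5,) * 8, 12)
        cands = [MotifCandidate(sax=w, cluster=0) for _ in range(4)]
        motif = merge_motifs(cands, merge_eps=0.1, original_length=8)
        assert motif.sax.symbols == w.symbols
        assert motif.support == 4

    def test_adjacent_symbol_average(self):
        # one differing adjacent position (MINDIST 0): merged, averaged
        a = SAXWord((5, 5, 5, 5), 12)
        b = SAXWord((5, 5, 5, 6), 12)
        motif = merge_motifs(
            [MotifCandidate(a, 0), MotifCandidate(b, 0)],
            merge_eps=0.0,
            original_length=4,
        )
        assert motif.support == 2
        # mean index 5.5, half-to-even rounding -> 6
        assert motif.sax.symbols == (5, 5, 5, 6)

    def test_no_merge_when_far(self):
        a = MotifCandidate(SAXWord((0,) * 4, 12), 0, support=3)
        b = MotifCandidate(SAXWord((11,) * 4, 12), 0, support=1)
        motif = merge_motifs([a, b], merge_eps=0.0, original_length=4)
        assert motif.sax.symbols == (0, 0, 0, 0)
        assert motif.support == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_motifs([], 0.0, 4)


class TestBootstrap:
    def test_identical_pool_gives_identical_representatives(self):
        cfg = PipelineConfig(
            n_bootstrap=3, bootstrap_size=24, kmeans_restarts=2,
            normalize_mode="profile",
        )
        pool = planted_motif_dataset(step_template(), 30, noise_sd=0.0, seed=0)
        result = bootstrap_discover(pool, cfg, seed=1)
        words = {
            c.sax.symbols for cands in result.candidates.values() for c in cands
        }
        assert len(words) == 1

    def test_deterministic_given_seed(self, del_template_pool):
        cfg = PipelineConfig(
            n_bootstrap=2, bootstrap_size=40, kmeans_restarts=2,
            normalize_mode="profile",
        )
        r1 = bootstrap_discover(del_template_pool, cfg, seed=9)
        r2 = bootstrap_discover(del_template_pool, cfg, seed=9)
        assert r1.eps == r2.eps
        for cl in r1.candidates:
            w1 = [c.sax.symbols for c in r1.candidates[cl]]
            w2 = [c.sax.symbols for c in r2.candidates[cl]]
            assert w1 == w2

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_discover(np.empty((0, 512)), PipelineConfig(), seed=0)
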