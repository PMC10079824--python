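"""Signal transformations: pooling, z-normalization, SAX, MINDIST, DTW.

The motif pipeline pushes each 512 bp depth profile through average
pooling (8 bp windows -> 64 points), z-normalization, and SAX
discretisation over a 24-symbol alphabet. Because pooling already plays
the role of the piecewise-aggregate step, SAX here maps one pooled point
to one symbol (PAA factor 1), so the SAX word has the pooled length.

Symbol cells are the standard-normal quantile cells: with breakpoints
``beta_k = Phi^-1(k / a)`` for ``k = 1..a-1``, symbol ``s`` covers
``[beta_s, beta_{s+1})`` (left-closed, so a value exactly on a boundary
takes the upper cell; a constant zero series maps to symbol ``a // 2``).

MINDIST is the SAX lower bound on the Euclidean distance of the original
series: ``sqrt(n / w) * sqrt(sum cell(a_i, b_i)^2)`` where the cell
distance is zero for identical or adjacent symbols and otherwise the gap
between the nearer cell edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.stats import norm


# ---------------------------------------------------------------- pooling


def pool_average(values: Sequence[float], window: int) -> np.ndarray:
    """Mean-pool in fixed windows; a ragged tail is averaged over its length."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return np.empty(0)
    n_full = n // window
    out = np.empty(int(np.ceil(n / window)))
    if n_full:
        out[:n_full] = x[: n_full * window].reshape(n_full, window).mean(axis=1)
    if n % window:
        out[n_full] = x[n_full * window :].mean()
    return out


def normalize(
    profile: Sequence[float],
    sample_stats: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Scale to zero mean and unit variance.

    With ``sample_stats=(mean, sd)`` the sample-level moments are used
    (the whole-sample normalization mode); otherwise the profile's own
    mean and population (ddof=0) standard deviation. A constant profile
    in per-profile mode maps to all zeros.
    """
    x = np.asarray(profile, dtype=float)
    if sample_stats is not None:
        mean, sd = sample_stats
        if sd <= 0:
            raise ValueError("sample sd must be positive")
    else:
        mean = x.mean() if x.size else 0.0
        sd = x.std()
        if sd == 0:
            return np.zeros_like(x)
    return (x - mean) / sd


# -------------------------------------------------------------------- SAX


def sax_breakpoints(alphabet_size: int) -> np.ndarray:
    """Interior standard-normal quantiles beta_1..beta_{a-1}."""
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be >= 2")
    ks = np.arange(1, alphabet_size) / alphabet_size
    return norm.ppf(ks)


@dataclass(frozen=True)
class SAXWord:
    """Symbol sequence over a finite alphabet; symbols in [0, alphabet_size)."""

    symbols: tuple
    alphabet_size: int

    def __post_init__(self) -> None:
        if any(not 0 <= s < self.alphabet_size for s in self.symbols):
            raise ValueError("symbol outside alphabet")

    def __len__(self) -> int:
        return len(self.symbols)

    def to_string(self) -> str:
        """Base-N serialisation, one character per symbol (0-9a-...)."""
        digits = "0123456789abcdefghijklmnopqrstuvwxyz"
        if self.alphabet_size > len(digits):
            raise ValueError("alphabet too large for string serialisation")
        return "".join(digits[s] for s in self.symbols)

    @classmethod
    def from_string(cls, text: str, alphabet_size: int) -> "SAXWord":
        digits = "0123456789abcdefghijklmnopqrstuvwxyz"
        return cls(tuple(digits.index(c) for c in text), alphabet_size)


def sax_transform(values: Sequence[float], alphabet_size: int) -> SAXWord:
    """Discretise a z-normalized series, one symbol per input point."""
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("NaN in SAX input")
    bps = sax_breakpoints(alphabet_size)
    symbols = np.searchsorted(bps, x, side="right")
    return SAXWord(tuple(int(s) for s in symbols), alphabet_size)


def sax_cell_table(alphabet_size: int) -> np.ndarray:
    """(a, a) lookup of cell distances: 0 for |r-c|<=1, else edge gap."""
    bps = sax_breakpoints(alphabet_size)
    a = alphabet_size
    table = np.zeros((a, a))
    for r in range(a):
        for c in range(r + 2, a):
            # gap between upper edge of cell r and lower edge of cell c
            table[r, c] = table[c, r] = bps[c - 1] - bps[r]
    return table


def sax_mindist(a: SAXWord, b: SAXWord, original_length: int) -> float:
    """SAX MINDIST; zero between identical or symbol-adjacent words."""
    if len(a) != len(b):
        raise ValueError("SAX words differ in length")
    if a.alphabet_size != b.alphabet_size:
        raise ValueError("SAX words differ in alphabet")
    table = sax_cell_table(a.alphabet_size)
    cells = table[np.array(a.symbols), np.array(b.symbols)]
    w = len(a)
    return float(np.sqrt(original_length / w) * np.sqrt((cells**2).sum()))


def pairwise_mindist(
    symbol_matrix: np.ndarray, alphabet_size: int, original_length: int
) -> np.ndarray:
    """Full pairwise MINDIST matrix for an (n, w) array of symbol rows."""
    table = sax_cell_table(alphabet_size)
    n, w = symbol_matrix.shape
    sq = np.zeros((n, n))
    for j in range(w):
        col = symbol_matrix[:, j]
        sq += table[col[:, None], col[None, :]] ** 2
    return np.sqrt(original_length / w) * np.sqrt(sq)


# ----------------------------------------------------------- segmentation


@dataclass(frozen=True)
class Segment:
    """A seg_len-symbol slice of a SAX word, with its origin recorded."""

    word: SAXWord
    profile_index: int
    offset: int

    def __len__(self) -> int:
        return len(self.word)


def segment_sliding(
    word: SAXWord, seg_len: int, step: int = 1, profile_index: int = 0
) -> List[Segment]:
    """Overlapping sliding segmentation of a SAX word."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if seg_len > len(word):
        return []
    segments = []
    for off in range(0, len(word) - seg_len + 1, step):
        sub = SAXWord(word.symbols[off : off + seg_len], word.alphabet_size)
        segments.append(Segment(word=sub, profile_index=profile_index, offset=off))
    return segments


# -------------------------------------------------------------------- DTW


@njit(cache=True)
def _dtw_cost_matrix(x, y, radius):  # pragma: no cover - numba
    n, m = x.shape[0], y.shape[0]
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        if radius >= 0:
            jlo = max(1, i - radius)
            jhi = min(m, i + radius)
        else:
            jlo, jhi = 1, m
        for j in range(jlo, jhi + 1):
            d = (x[i - 1] - y[j - 1]) ** 2
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = d + best
    return D


def dtw_distance(
    x: Sequence[float], y: Sequence[float], radius: Optional[int] = None
) -> float:
    """Classic DTW: sqrt of the minimal cumulative squared cost over
    monotone, endpoint-anchored warping paths. ``radius`` enables a
    Sakoe-Chiba band (None = unconstrained)."""
    xa = np.ascontiguousarray(x, dtype=np.float64)
    ya = np.ascontiguousarray(y, dtype=np.float64)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    r = -1 if radius is None else int(radius)
    D = _dtw_cost_matrix(xa, ya, r)
    return float(np.sqrt(D[xa.size, ya.size]))


@njit(cache=True)
def _dtw_dist_batch(X, c, radius):  # pragma: no cover - numba
    n_series = X.shape[0]
    out = np.empty(n_series)
    for s in range(n_series):
        D = _dtw_cost_matrix(X[s], c, radius)
        out[s] = np.sqrt(D[X.shape[1], c.shape[0]])
    return out


def dtw_distances_to(
    X: np.ndarray, center: np.ndarray, radius: Optional[int] = None
) -> np.ndarray:
    """DTW distance from every row of ``X`` to ``center`` (batch kernel)."""
    Xa = np.ascontiguousarray(X, dtype=np.float64)
    ca = np.ascontiguousarray(center, dtype=np.float64)
    r = -1 if radius is None else int(radius)
    return _dtw_dist_batch(Xa, ca, r)


@njit(cache=True)
def _dtw_backtrace(D):  # pragma: no cover - numba
    n = D.shape[0] - 1
    m = D.shape[1] - 1
    max_len = n + m
    pi = np.empty(max_len, dtype=np.int64)
    pj = np.empty(max_len, dtype=np.int64)
    i, j = n, m
    k = 0
    pi[k] = i - 1
    pj[k] = j - 1
    while i > 1 or j > 1:
        best = D[i - 1, j - 1]
        bi, bj = i - 1, j - 1
        if D[i - 1, j] < best:
            best = D[i - 1, j]
            bi, bj = i - 1, j
        if D[i, j - 1] < best:
            bi, bj = i, j - 1
        i, j = bi, bj
        k += 1
        pi[k] = i - 1
        pj[k] = j - 1
    return pi[: k + 1][::-1].copy(), pj[: k + 1][::-1].copy()


def dtw_path(
    x: Sequence[float], y: Sequence[float], radius: Optional[int] = None
) -> List[Tuple[int, int]]:
    """Optimal warping path as (i, j) index pairs, for barycenter updates."""
    xa = np.ascontiguousarray(x, dtype=np.float64)
    ya = np.ascontiguousarray(y, dtype=np.float64)
    r = -1 if radius is None else int(radius)
    D = _dtw_cost_matrix(xa, ya, r)
    pi, pj = _dtw_backtrace(D)
    return list(zip(pi.tolist(), pj.tolist()))
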