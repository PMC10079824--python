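"""Motif scanning: locate stored SAX motifs in new depth-of-coverage signal.

A scan window runs through the same representation pipeline as discovery
(average pooling, z-normalization, SAX) and every seg_len-symbol offset
is scored by SAX distance to the motif word. Scores are invariant to
uniform scaling of the raw signal because normalization absorbs scale.
The default score threshold is motif-specific, calibrated as the 1st
percentile of scores observed on motif-free synthetic coverage.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .bcov_io import BcovIndex, CoverageTrack, read_bcov
from .config import PipelineConfig
from .motif_discovery import Motif
from .signal_prep import normalize, pool_average, sax_mindist, sax_transform

logger = logging.getLogger(__name__)


def scan_profile(
    profile: Sequence[float],
    motif: Motif,
    config: PipelineConfig,
    threshold: Optional[float] = None,
) -> List[Tuple[int, float]]:
    """Score every segment offset of one profile against a motif.

    Returns (pooled offset, score) pairs with score <= threshold, sorted
    by score ascending; ``threshold=None`` returns all offsets scored.
    Offsets are in pooled units (multiply by ``config.pool_window`` for bp).
    """
    x = np.asarray(profile, dtype=float)
    seg_len = len(motif.sax)
    if x.size < seg_len * config.pool_window:
        logger.warning("profile shorter than one motif instance; no hits")
        return []
    pooled = pool_average(x, config.pool_window)
    word = sax_transform(normalize(pooled), config.alphabet_size)
    original_length = seg_len * config.pool_window
    hits = []
    for off in range(0, len(word) - seg_len + 1):
        sub = type(word)(word.symbols[off : off + seg_len], word.alphabet_size)
        score = sax_mindist(sub, motif.sax, original_length)
        if threshold is None or score <= threshold:
            hits.append((off, score))
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def calibrate_scan_threshold(
    motif: Motif,
    config: PipelineConfig,
    seed: int = 0,
    n_profiles: int = 100,
    mean_coverage: float = 30.0,
    percentile: float = 1.0,
) -> float:
    """Motif-specific threshold: low percentile of scores on motif-free
    Poisson coverage at the given mean depth."""
    rng = np.random.default_rng(seed)
    scores: List[float] = []
    for _ in range(n_profiles):
        flat = rng.poisson(mean_coverage, size=config.profile_length)
        scores.extend(s for _, s in scan_profile(flat, motif, config, threshold=None))
    return float(np.percentile(scores, percentile))


def scan_track(
    bcov: Union[str, Path, CoverageTrack],
    motifs: Sequence[Motif],
    config: PipelineConfig,
    stride: int = 256,
    thresholds: Optional[Sequence[float]] = None,
    contigs: Optional[Iterable[str]] = None,
    seed: int = 0,
    merge: bool = True,
) -> pd.DataFrame:
    """Scan tiled windows of a coverage track for all motifs.

    Windows of ``config.profile_length`` bp are taken every ``stride``
    bp; hits are reported as BED-like rows (contig, 0-based half-open
    start/end of the matched segment, motif id, score, and the predicted
    1-based breakpoint position from the motif's breakpoint offset).
    Overlapping hits of the same motif keep only the best score.
    """
    if isinstance(bcov, CoverageTrack):
        tracks = {bcov.contig: bcov}
    else:
        index = BcovIndex.read(str(bcov) + ".idx")
        names = [n for n, _, _ in index.entries]
        if contigs is not None:
            wanted = set(contigs)
            missing = wanted - set(names)
            if missing:
                raise KeyError(f"contigs not in BCOV index: {sorted(missing)}")
            names = [n for n in names if n in wanted]
        tracks = {name: read_bcov(bcov, name) for name in names}

    if thresholds is None:
        thresholds = [
            m_thr
            if (m_thr := config.scan_threshold) is not None
            else calibrate_scan_threshold(m, config, seed=seed)
            for m in motifs
        ]
    rows = []
    window = config.profile_length
    seg_bp = {i: len(m.sax) * config.pool_window for i, m in enumerate(motifs)}
    for contig, track in tracks.items():
        n = len(track)
        for w0 in range(0, max(1, n - window + 1), stride):
            chunk = np.asarray(track.depths[w0 : w0 + window])
            if chunk.size < window:
                break
            for mi, motif in enumerate(motifs):
                for off, score in scan_profile(chunk, motif, config, thresholds[mi]):
                    g_start = w0 + off * config.pool_window  # 0-based
                    rows.append(
                        {
                            "contig": contig,
                            "start": g_start,
                            "end": g_start + seg_bp[mi],
                            "motif": mi,
                            "score": score,
                            "bp_pos": g_start + motif.bp_offset * config.pool_window + 1,
                        }
                    )
    df = pd.DataFrame(
        rows, columns=["contig", "start", "end", "motif", "score", "bp_pos"]
    )
    if df.empty or not merge:
        return df.sort_values(["contig", "start"], kind="stable").reset_index(drop=True)
    return _merge_hits(df)


def _merge_hits(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping same-motif hits to the minimum-score one."""
    kept = []
    for (_, _), group in df.groupby(["contig", "motif"], sort=True):
        group = group.sort_values(["score", "start"], kind="stable")
        taken: List[Tuple[int, int]] = []
        for _, row in group.iterrows():
            if any(row.start < e and row.end > s for s, e in taken):
                continue
            taken.append((row.start, row.end))
            kept.append(row)
    out = pd.DataFrame(kept).sort_values(["contig", "start"], kind="stable")
    return out.reset_index(drop=True)


def write_hits_bed(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """BED-like TSV: contig, start, end (0-based half-open), motif id, score."""
    df.to_csv(path, sep="\t", index=False)
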