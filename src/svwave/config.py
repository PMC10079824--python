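"""Pipeline configuration: every numeric constant of the method in one place.

The defaults encode the study conditions: a ±256 bp window around each
breakpoint (profile length 512), a 20 bp minimum SV length, 8 bp average
pooling, a 24-symbol SAX alphabet, 32-point sliding segments, two DTW
K-Means clusters with a 66% representative-cluster rule, 360 bootstrap
subsets of 960 profiles each for motif discovery, and 80 repeats of the
compression-consistency experiment on subsets of 100 profiles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional


@dataclass
class PipelineConfig:
    """All tunable parameters of the breakpoint-waveform pipeline.

    Parameters
    ----------
    half_width
        Half-width of the breakpoint window in bp; profiles span
        ``2 * half_width`` positions centred on the breakpoint.
    min_sv_len
        Variants shorter than this (bp) are discarded outright.
    pool_window
        Average-pooling window (bp) used to compress profiles.
    alphabet_size
        Number of SAX symbols.
    seg_len
        Length of sliding SAX segments, in pooled data points.
    seg_step
        Stride of the sliding segmentation, in pooled data points.
    k_clusters
        Number of DTW K-Means clusters per profile subset.
    representative_share
        Percentage threshold: if the larger cluster holds strictly more
        than this share of profiles, motif discovery is restricted to it.
    n_bootstrap, bootstrap_size
        Number of bootstrap subsets and profiles per subset for motif
        discovery.
    consistency_repeats, consistency_subset
        Repeats and subset size of the compression-consistency experiment.
    eps, merge_eps
        SAX-distance neighbourhood threshold for similarity grouping and
        for motif merging. ``None`` means calibrate at run time (5th
        percentile of pairwise segment distances).
    scan_threshold
        Score cut-off for motif scanning; ``None`` means calibrate on
        motif-free coverage.
    support_floor
        Minimum share of bootstrap candidates the predominant motif must
        absorb to be reported as convincing.
    kmeans_restarts, kmeans_max_iter
        DTW K-Means initialisation restarts and iteration cap.
    sakoe_chiba_radius
        Optional DTW warping-window constraint (pooled points); ``None``
        disables the band.
    normalize_mode
        ``"sample"`` uses per-sample coverage moments when available,
        ``"profile"`` always uses the profile's own moments.
    seed
        Base seed for all stochastic steps.
    """

    half_width: int = 256
    min_sv_len: int = 20
    pool_window: int = 8
    alphabet_size: int = 24
    seg_len: int = 32
    seg_step: int = 1
    k_clusters: int = 2
    representative_share: float = 66.0
    n_bootstrap: int = 360
    bootstrap_size: int = 960
    consistency_repeats: int = 80
    consistency_subset: int = 100
    eps: Optional[float] = None
    merge_eps: Optional[float] = None
    scan_threshold: Optional[float] = None
    support_floor: float = 10.0
    kmeans_restarts: int = 10
    kmeans_max_iter: int = 30
    sakoe_chiba_radius: Optional[int] = None
    normalize_mode: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if (2 * self.half_width) % self.pool_window != 0:
            raise ValueError("2*half_width must be divisible by pool_window")
        if self.seg_len > (2 * self.half_width) // self.pool_window:
            raise ValueError("seg_len exceeds the pooled profile length")
        if not 0 < self.representative_share < 100:
            raise ValueError("representative_share must be in (0, 100)")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if self.normalize_mode not in ("sample", "profile"):
            raise ValueError("normalize_mode must be 'sample' or 'profile'")

    @property
    def profile_length(self) -> int:
        return 2 * self.half_width

    @property
    def word_length(self) -> int:
        """Length of the pooled (and SAX-transformed) profile."""
        return self.profile_length // self.pool_window

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))
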