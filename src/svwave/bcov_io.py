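"""BCOV: a lossless binary per-base coverage format.

One little-endian unsigned 16-bit integer per genomic position, written
sequentially with no header — the file is exactly ``2 * n_positions``
bytes, so any window can be read with a single O(1) seek. Depth values
above 65535 are clamped to 65535 (the largest value two bytes can hold).

Multi-contig layout: all contigs share one payload stream; a plain-text
sidecar index (``<path>.idx``, tab-separated ``contig  byte_offset
n_positions`` lines) records where each contig starts. Coordinates in the
slicing API are 1-based; a window of half-width ``w`` centred at position
``p`` covers ``[p - w, p + w - 1]`` — ``2w`` values with the breakpoint at
0-based offset ``w`` inside the window.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Dict, Iterable, List, Tuple, Union

import numpy as np

BCOV_DTYPE = np.dtype("<u2")
MAX_DEPTH = 65535  # 2**16 - 1


class BcovFormatError(ValueError):
    """Malformed BCOV payload, index or coverage input."""


class WindowOutOfBounds(ValueError):
    """Requested window extends past a contig end; callers drop such loci."""


@dataclass
class CoverageTrack:
    """Dense per-base read depth for one contig (explicit zeros included)."""

    contig: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1:
            raise BcovFormatError("depths must be one-dimensional")
        if self.depths.size and np.issubdtype(self.depths.dtype, np.floating):
            raise BcovFormatError("depths must be integers")

    def __len__(self) -> int:
        return int(self.depths.size)


@dataclass
class BcovIndex:
    """Sidecar index: (contig, byte offset into the payload, n positions)."""

    entries: List[Tuple[str, int, int]] = field(default_factory=list)

    def offset_of(self, contig: str) -> Tuple[int, int]:
        for name, off, n in self.entries:
            if name == contig:
                return off, n
        raise KeyError(f"contig {contig!r} not in BCOV index")

    def __contains__(self, contig: str) -> bool:
        return any(name == contig for name, _, _ in self.entries)

    @property
    def payload_size(self) -> int:
        return sum(2 * n for _, _, n in self.entries)

    def validate(self) -> None:
        prev_end = 0
        for name, off, n in self.entries:
            if off % 2 != 0:
                raise BcovFormatError(f"odd byte offset for {name!r}")
            if off < prev_end:
                raise BcovFormatError("index entries overlap or are unsorted")
            prev_end = off + 2 * n

    def write(self, path: Union[str, Path]) -> None:
        lines = [f"{name}\t{off}\t{n}" for name, off, n in self.entries]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    @classmethod
    def read(cls, path: Union[str, Path]) -> "BcovIndex":
        entries = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            name, off, n = line.split("\t")
            entries.append((name, int(off), int(n)))
        idx = cls(entries)
        idx.validate()
        return idx


def encode_bcov(track: CoverageTrack, sink: BinaryIO) -> int:
    """Write one track as sequential little-endian u16; returns bytes written.

    Negative depths are rejected; depths above 65535 are clamped.
    """
    depths = np.asarray(track.depths, dtype=np.int64)
    if depths.size and depths.min() < 0:
        raise BcovFormatError("negative depth in coverage track")
    clamped = np.minimum(depths, MAX_DEPTH).astype(BCOV_DTYPE)
    payload = clamped.tobytes()
    sink.write(payload)
    return len(payload)


def decode_bcov(
    source: Union[BinaryIO, bytes], index: BcovIndex, contig: str
) -> CoverageTrack:
    """Exact inverse of :func:`encode_bcov` for in-range depths."""
    off, n = index.offset_of(contig)
    if isinstance(source, (bytes, bytearray)):
        payload = bytes(source[off : off + 2 * n])
    else:
        source.seek(off)
        payload = source.read(2 * n)
    if len(payload) % 2 != 0 or len(payload) != 2 * n:
        raise BcovFormatError(
            f"payload for {contig!r} has {len(payload)} bytes, expected {2 * n}"
        )
    depths = np.frombuffer(payload, dtype=BCOV_DTYPE).astype(np.int64)
    return CoverageTrack(contig=contig, depths=depths)


def write_bcov(
    tracks: Iterable[CoverageTrack], path: Union[str, Path]
) -> BcovIndex:
    """Write tracks to ``path`` and the index to ``path + '.idx'``."""
    path = Path(path)
    entries: List[Tuple[str, int, int]] = []
    with open(path, "wb") as fh:
        offset = 0
        for track in tracks:
            n = len(track)
            encode_bcov(track, fh)
            entries.append((track.contig, offset, n))
            offset += 2 * n
    index = BcovIndex(entries)
    index.write(str(path) + ".idx")
    return index


def read_bcov(path: Union[str, Path], contig: str) -> CoverageTrack:
    index = BcovIndex.read(str(path) + ".idx")
    with open(path, "rb") as fh:
        return decode_bcov(fh, index, contig)


def _window_bounds(center: int, half_width: int) -> Tuple[int, int]:
    # 1-based [center - w, center + w - 1]  ->  0-based half-open
    return center - half_width - 1, center + half_width - 1


def slice_window(
    source: Union[CoverageTrack, str, Path],
    contig: str,
    center: int,
    half_width: int,
) -> np.ndarray:
    """Depth vector of length ``2*half_width`` around a 1-based position.

    ``source`` is either an in-memory :class:`CoverageTrack` or a path to
    a BCOV file (its ``.idx`` sidecar must exist). Windows extending past
    either contig end raise :class:`WindowOutOfBounds` rather than pad.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    lo, hi = _window_bounds(center, half_width)
    if isinstance(source, CoverageTrack):
        if source.contig != contig:
            raise KeyError(f"track is {source.contig!r}, requested {contig!r}")
        n = len(source)
        if lo < 0 or hi > n:
            raise WindowOutOfBounds(
                f"window [{lo}, {hi}) outside contig of length {n}"
            )
        return np.asarray(source.depths[lo:hi], dtype=np.int64)
    path = Path(source)
    index = BcovIndex.read(str(path) + ".idx")
    off, n = index.offset_of(contig)
    if lo < 0 or hi > n:
        raise WindowOutOfBounds(
            f"window [{lo}, {hi}) outside contig of length {n}"
        )
    with open(path, "rb") as fh:
        fh.seek(off + 2 * lo)
        payload = fh.read(2 * (hi - lo))
    return np.frombuffer(payload, dtype=BCOV_DTYPE).astype(np.int64)


def bedgraph_to_bcov(
    bedgraph: Union[str, Path, io.TextIOBase, Iterable[str]],
    contig_lengths: Dict[str, int],
) -> Dict[str, CoverageTrack]:
    """Expand a per-base bedGraph (0-based half-open) into dense tracks.

    Positions not covered by any interval are explicit zeros. Intervals
    must not overlap and must not extend past the declared contig length.
    """
    if isinstance(bedgraph, (str, Path)):
        lines: Iterable[str] = Path(bedgraph).read_text().splitlines()
    elif isinstance(bedgraph, io.TextIOBase):
        lines = bedgraph.read().splitlines()
    else:
        lines = bedgraph

    tracks = {
        name: np.zeros(length, dtype=np.int64)
        for name, length in contig_lengths.items()
    }
    covered = {
        name: np.zeros(ln, dtype=bool) for name, ln in contig_lengths.items()
    }
    for line in lines:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise BcovFormatError(f"bad bedGraph line: {line!r}")
        name, start, end, value = fields[0], int(fields[1]), int(fields[2]), fields[3]
        if name not in tracks:
            raise BcovFormatError(f"contig {name!r} not in contig_lengths")
        if end > contig_lengths[name] or start < 0 or end < start:
            raise BcovFormatError(f"interval out of bounds: {line!r}")
        if covered[name][start:end].any():
            raise BcovFormatError(f"overlapping bedGraph intervals at {line!r}")
        covered[name][start:end] = True
        tracks[name][start:end] = int(round(float(value)))
    return {
        name: CoverageTrack(contig=name, depths=depths)
        for name, depths in tracks.items()
    }
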