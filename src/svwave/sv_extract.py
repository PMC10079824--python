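"""Structural-variant parsing, breakpoint derivation and profile extraction.

Variants are kept only when their FILTER is exactly PASS and their length
(end − start + 1) is at least the minimum SV length (20 bp by default;
insertions are exempt, having no reference length). Breakpoint loci
follow the class taxonomy: interval SVs at least as long as the window
yield a left (L) locus at the start and a right (R) locus at the end;
insertions yield a single breakpoint (BP) at the start; interval SVs
shorter than the window but at least the minimum length are "special"
(spSV) with one window centred on the variant midpoint — except
copy-number calls, which never produce spSV loci.

Profiles are extracted for carrier samples only (hom-alt or het; a
per-sample FT field, when present, must also be PASS), and windows that
run off the contig or are entirely zero coverage are dropped.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .bcov_io import CoverageTrack, WindowOutOfBounds, slice_window
from .config import PipelineConfig

logger = logging.getLogger(__name__)

SVTYPES = ("DEL", "DUP", "INS", "INV", "CNV_GAIN", "CNV_LOSS")
CNV_TYPES = ("CNV_GAIN", "CNV_LOSS")


class Genotype(str, Enum):
    HOM_ALT = "HOM_ALT"
    HET = "HET"
    OTHER = "OTHER"


class Side(str, Enum):
    L = "L"
    R = "R"
    BP = "BP"
    SPSV = "spSV"


@dataclass
class VariantRecord:
    contig: str
    start: int  # 1-based
    end: int  # 1-based, == start for INS
    svtype: str
    filter: frozenset = frozenset({"PASS"})
    genotype_by_sample: Dict[str, Genotype] = field(default_factory=dict)
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.svtype == "INS" and self.end != self.start:
            raise ValueError("INS records must have end == start")
        if self.end < self.start:
            raise ValueError("end < start")
        self.filter = frozenset(self.filter)

    @property
    def length(self) -> int:
        """Interval length, end − start + 1 (1 for insertions)."""
        return self.end - self.start + 1

    def carriers(self) -> Dict[str, Genotype]:
        return {
            s: g
            for s, g in self.genotype_by_sample.items()
            if g in (Genotype.HOM_ALT, Genotype.HET)
        }


@dataclass
class BreakpointLocus:
    variant: VariantRecord
    side: Side
    position: int  # 1-based


@dataclass
class DOCProfile:
    values: np.ndarray
    sample: str
    locus: BreakpointLocus
    genotype: Genotype


def classify_gt(alleles: Sequence[Optional[int]]) -> Genotype:
    """GT 1/1 -> HOM_ALT, 0/1 or 1/0 -> HET, anything else OTHER."""
    if len(alleles) != 2 or any(a is None for a in alleles):
        return Genotype.OTHER
    pair = tuple(sorted(alleles))
    if pair == (1, 1):
        return Genotype.HOM_ALT
    if pair == (0, 1):
        return Genotype.HET
    return Genotype.OTHER


_SVTYPE_ALIASES = {
    "DEL": "DEL",
    "DUP": "DUP",
    "INS": "INS",
    "INV": "INV",
    "CNV_GAIN": "CNV_GAIN",
    "CNV_LOSS": "CNV_LOSS",
    "GAIN": "CNV_GAIN",
    "LOSS": "CNV_LOSS",
}


def parse_vcf(path: Union[str, Path]) -> List[VariantRecord]:
    """Read SV records (SVTYPE, END, FILTER, GT, optional FT) with pysam.

    Records without a recognisable SVTYPE are skipped with a warning.
    A per-sample FT other than PASS demotes that sample to OTHER.
    """
    import pysam

    records: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            if svtype is None or str(svtype).upper() not in _SVTYPE_ALIASES:
                logger.warning(
                    "skipping record %s:%d — missing or unknown SVTYPE %r",
                    rec.chrom,
                    rec.pos,
                    svtype,
                )
                continue
            svtype = _SVTYPE_ALIASES[str(svtype).upper()]
            if svtype == "INS":
                end = rec.pos
            else:
                end = int(rec.info.get("END", rec.stop))
            genotypes: Dict[str, Genotype] = {}
            for sample_name, call in rec.samples.items():
                gt = classify_gt(call.get("GT") or ())
                ft = call.get("FT")
                if ft is not None and str(ft) not in ("PASS", "."):
                    gt = Genotype.OTHER
                genotypes[sample_name] = gt
            filters = frozenset(rec.filter.keys()) or frozenset({"PASS"})
            records.append(
                VariantRecord(
                    contig=rec.chrom,
                    start=rec.pos,
                    end=end,
                    svtype=svtype,
                    filter=filters,
                    genotype_by_sample=genotypes,
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}:{svtype}",
                )
            )
    return records


def filter_variants(
    records: Iterable[VariantRecord], config: PipelineConfig
) -> List[VariantRecord]:
    """Keep records whose FILTER is exactly {PASS} and whose length is at
    least ``config.min_sv_len`` (insertions exempt). Idempotent."""
    kept = []
    for rec in records:
        if rec.filter != frozenset({"PASS"}):
            continue
        if rec.svtype != "INS" and rec.length < config.min_sv_len:
            continue
        kept.append(rec)
    return kept


def derive_loci(
    record: VariantRecord, config: PipelineConfig
) -> List[BreakpointLocus]:
    """Typed breakpoint loci for one filtered record.

    INS -> one BP locus at start. Interval SVs of at least the window
    size -> L at start and R at end. Shorter interval SVs (>= min length)
    are spSV with one locus at the midpoint — but copy-number classes
    never yield spSV loci.
    """
    window = config.profile_length
    if record.svtype == "INS":
        return [BreakpointLocus(record, Side.BP, record.start)]
    if record.length >= window:
        return [
            BreakpointLocus(record, Side.L, record.start),
            BreakpointLocus(record, Side.R, record.end),
        ]
    if record.length >= config.min_sv_len:
        if record.svtype in CNV_TYPES:
            return []
        mid = (record.start + record.end) // 2
        return [BreakpointLocus(record, Side.SPSV, mid)]
    return []


CoverageSource = Union[CoverageTrack, str, Path, Dict[str, CoverageTrack]]


def _window_for(
    coverage: CoverageSource, contig: str, center: int, half_width: int
) -> np.ndarray:
    if isinstance(coverage, dict):
        coverage = coverage[contig]
    return slice_window(coverage, contig, center, half_width)


def extract_profiles(
    loci: Iterable[BreakpointLocus],
    coverage_by_sample: Dict[str, CoverageSource],
    config: PipelineConfig,
) -> List[DOCProfile]:
    """One profile per (locus, carrier sample).

    Samples with genotype OTHER are excluded. Windows that run off the
    contig are dropped, as are all-zero windows (the mechanism behind
    left/right count imbalance at variant edges). Samples without
    coverage are skipped with a warning.
    """
    profiles: List[DOCProfile] = []
    for locus in loci:
        for sample, gt in locus.variant.carriers().items():
            cov = coverage_by_sample.get(sample)
            if cov is None:
                logger.warning("no coverage for sample %s; skipped", sample)
                continue
            try:
                values = _window_for(
                    cov, locus.variant.contig, locus.position, config.half_width
                )
            except (WindowOutOfBounds, KeyError):
                continue
            if not values.any():
                continue
            profiles.append(
                DOCProfile(values=values, sample=sample, locus=locus, genotype=gt)
            )
    return profiles


# ----------------------------------------------------------- profile store

_SCHEMA = """
CREATE TABLE IF NOT EXISTS sample (
    id TEXT PRIMARY KEY,
    population TEXT,
    sex TEXT,
    mean_coverage REAL,
    sd_coverage REAL,
    bcov_path TEXT
);
CREATE TABLE IF NOT EXISTS variant (
    id TEXT PRIMARY KEY,
    contig TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    svtype TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS breakpoint (
    id INTEGER PRIMARY KEY,
    variant_id TEXT NOT NULL REFERENCES variant(id),
    side TEXT NOT NULL,
    position INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS profile (
    id INTEGER PRIMARY KEY,
    sample_id TEXT NOT NULL REFERENCES sample(id),
    breakpoint_id INTEGER NOT NULL REFERENCES breakpoint(id),
    genotype TEXT NOT NULL,
    values_blob BLOB NOT NULL
);
CREATE TABLE IF NOT EXISTS motif (
    id INTEGER PRIMARY KEY,
    svtype TEXT NOT NULL,
    side TEXT NOT NULL,
    genotype TEXT NOT NULL,
    cluster INTEGER NOT NULL,
    sax_word TEXT NOT NULL,
    alphabet_size INTEGER NOT NULL,
    support INTEGER NOT NULL,
    bp_offset INTEGER NOT NULL DEFAULT 0,
    convincing INTEGER NOT NULL DEFAULT 1
);
CREATE INDEX IF NOT EXISTS idx_bp_pos ON breakpoint(position);
CREATE INDEX IF NOT EXISTS idx_variant_region ON variant(contig, start, end);
"""


class ProfileStore:
    """Single-file relational store for samples, variants, breakpoints,
    profiles and motifs; queryable by coordinate, SV class, genotype and
    breakpoint type."""

    def __init__(self, path: Union[str, Path] = ":memory:") -> None:
        self.conn = sqlite3.connect(str(path))
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "ProfileStore":
        return self

    def __exit__(self, *exc) -> None:
        self.conn.commit()
        self.close()

    def add_sample(
        self,
        sample_id: str,
        population: str = "",
        sex: str = "",
        mean_coverage: float = 0.0,
        sd_coverage: float = 0.0,
        bcov_path: str = "",
    ) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO sample VALUES (?,?,?,?,?,?)",
            (sample_id, population, sex, mean_coverage, sd_coverage, bcov_path),
        )

    def add_profiles(self, profiles: Iterable[DOCProfile]) -> int:
        """Insert profiles with their variants and breakpoints; returns count."""
        n = 0
        bp_cache: Dict[Tuple[str, str, int], int] = {}
        for p in profiles:
            # bare sample row when no metadata was registered beforehand
            self.conn.execute(
                "INSERT OR IGNORE INTO sample (id) VALUES (?)", (p.sample,)
            )
            var = p.locus.variant
            self.conn.execute(
                "INSERT OR IGNORE INTO variant VALUES (?,?,?,?,?)",
                (var.variant_id, var.contig, var.start, var.end, var.svtype),
            )
            key = (var.variant_id, p.locus.side.value, p.locus.position)
            if key not in bp_cache:
                cur = self.conn.execute(
                    "SELECT id FROM breakpoint WHERE variant_id=? AND side=? AND position=?",
                    key,
                )
                row = cur.fetchone()
                if row is None:
                    cur = self.conn.execute(
                        "INSERT INTO breakpoint (variant_id, side, position) VALUES (?,?,?)",
                        key,
                    )
                    bp_cache[key] = cur.lastrowid
                else:
                    bp_cache[key] = row[0]
            blob = np.asarray(p.values, dtype="<u2").tobytes()
            self.conn.execute(
                "INSERT INTO profile (sample_id, breakpoint_id, genotype, values_blob)"
                " VALUES (?,?,?,?)",
                (p.sample, bp_cache[key], p.genotype.value, blob),
            )
            n += 1
        self.conn.commit()
        return n

    def add_motifs(self, motifs: Iterable) -> int:
        n = 0
        for m in motifs:
            self.conn.execute(
                "INSERT INTO motif (svtype, side, genotype, cluster, sax_word,"
                " alphabet_size, support, bp_offset, convincing)"
                " VALUES (?,?,?,?,?,?,?,?,?)",
                (
                    m.svtype,
                    m.side,
                    m.genotype,
                    m.cluster,
                    m.sax.to_string(),
                    m.sax.alphabet_size,
                    m.support,
                    m.bp_offset,
                    int(m.convincing),
                ),
            )
            n += 1
        self.conn.commit()
        return n

    def query_profiles(
        self,
        svtype: Optional[str] = None,
        side: Optional[str] = None,
        genotype: Optional[str] = None,
        region: Optional[Tuple[str, int, int]] = None,
    ) -> List[Tuple[str, str, str, str, int, np.ndarray]]:
        """Rows of (sample, svtype, side, genotype, position, values)."""
        sql = (
            "SELECT p.sample_id, v.svtype, b.side, p.genotype, b.position,"
            " p.values_blob FROM profile p"
            " JOIN breakpoint b ON p.breakpoint_id = b.id"
            " JOIN variant v ON b.variant_id = v.id WHERE 1=1"
        )
        args: List = []
        if svtype is not None:
            sql += " AND v.svtype = ?"
            args.append(svtype)
        if side is not None:
            sql += " AND b.side = ?"
            args.append(side)
        if genotype is not None:
            sql += " AND p.genotype = ?"
            args.append(genotype)
        if region is not None:
            contig, lo, hi = region
            sql += " AND v.contig = ? AND b.position BETWEEN ? AND ?"
            args.extend([contig, lo, hi])
        rows = []
        for s, svt, sd, gt, pos, blob in self.conn.execute(sql, args):
            values = np.frombuffer(blob, dtype="<u2").astype(np.int64)
            rows.append((s, svt, sd, gt, pos, values))
        return rows


def populate_store(
    store: ProfileStore,
    profiles: Iterable[DOCProfile],
    samples_metadata: Optional[Dict[str, Dict]] = None,
    motifs: Iterable = (),
) -> Tuple[int, int]:
    """Fill a store from extraction output; returns (n_profiles, n_motifs)."""
    if samples_metadata:
        for sid, meta in samples_metadata.items():
            store.add_sample(sid, **meta)
    n_p = store.add_profiles(profiles)
    n_m = store.add_motifs(motifs)
    return n_p, n_m
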