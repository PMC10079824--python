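"""Synthetic coverage and profile generators.

The generators emulate the structure of short-read whole-genome coverage
around structural variants at roughly 30x mean depth: a Poisson (or
optionally negative-binomial, i.e. overdispersed) baseline whose rate is
scaled inside each planted event by a genotype-dependent copy factor —
deletions 0x (hom) / 0.5x (het), duplications and copy-number gains 2x /
1.5x, copy-number losses like deletions. Inversions keep 1x copy number
but receive a synthetic breakpoint-local dip (a linear ramp over a 50 bp
shoulder) standing in for alignment edge artifacts; insertions keep 1x
with a narrow synthetic dip at the single breakpoint. Matching VCF
records (PASS, per-sample GT) are emitted alongside each track.

These are idealised signals: real coverage adds GC bias, mappability
dropouts, and caller-imprecise breakpoints, none of which is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .bcov_io import CoverageTrack, write_bcov
from .sv_extract import Genotype, VariantRecord

COPY_FACTORS = {
    ("DEL", Genotype.HOM_ALT): 0.0,
    ("DEL", Genotype.HET): 0.5,
    ("CNV_LOSS", Genotype.HOM_ALT): 0.0,
    ("CNV_LOSS", Genotype.HET): 0.5,
    ("DUP", Genotype.HOM_ALT): 2.0,
    ("DUP", Genotype.HET): 1.5,
    ("CNV_GAIN", Genotype.HOM_ALT): 2.0,
    ("CNV_GAIN", Genotype.HET): 1.5,
    ("INV", Genotype.HOM_ALT): 1.0,
    ("INV", Genotype.HET): 1.0,
    ("INS", Genotype.HOM_ALT): 1.0,
    ("INS", Genotype.HET): 1.0,
}

INV_SHOULDER = 50  # bp ramp on each side of an inversion breakpoint
INS_DIP_WIDTH = 20  # bp of reduced depth around an insertion breakpoint
DIP_FACTOR = 0.5


@dataclass
class Event:
    svtype: str
    start: int  # 1-based
    length: int
    genotype: Genotype = Genotype.HOM_ALT

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class SimSpec:
    contig: str = "chr1"
    length: int = 100_000
    mean_coverage: float = 30.0
    events: List[Event] = field(default_factory=list)
    overdispersion: Optional[float] = None  # NB variance = mu + mu^2/r

    def __post_init__(self) -> None:
        spans = sorted((e.start, e.end) for e in self.events)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("events overlap")
        for e in self.events:
            if e.length < 1:
                raise ValueError("event length must be >= 1")
            if e.end > self.length:
                raise ValueError("event extends past contig end")


def _event_rate(spec: SimSpec) -> np.ndarray:
    """Expected depth per position after applying all planted events."""
    rate = np.full(spec.length, spec.mean_coverage, dtype=float)
    for ev in spec.events:
        factor = COPY_FACTORS[(ev.svtype, ev.genotype)]
        s0, e0 = ev.start - 1, ev.end  # 0-based half-open
        if ev.svtype == "INS":
            lo = max(0, s0 - INS_DIP_WIDTH // 2)
            hi = min(spec.length, s0 + INS_DIP_WIDTH // 2)
            rate[lo:hi] *= DIP_FACTOR
            continue
        rate[s0:e0] *= factor
        if ev.svtype == "INV":
            for bp in (s0, e0):
                lo = max(0, bp - INV_SHOULDER)
                hi = min(spec.length, bp + INV_SHOULDER)
                ramp = 1.0 - (1.0 - DIP_FACTOR) * (
                    1.0 - np.abs(np.arange(lo, hi) - bp) / INV_SHOULDER
                )
                rate[lo:hi] *= ramp
    return rate


def simulate_sample(
    spec: SimSpec, seed: int, sample_id: str = "S0"
) -> Tuple[CoverageTrack, List[VariantRecord], Tuple[float, float]]:
    """Draw one sample's coverage track plus its matching PASS VCF records.

    Returns (track, records, (mean, sd)) where the moments are the
    sample-level coverage statistics used by sample-mode normalization.
    """
    rng = np.random.default_rng(seed)
    rate = _event_rate(spec)
    if spec.overdispersion is None:
        depths = rng.poisson(rate)
    else:
        r = spec.overdispersion
        depths = rng.negative_binomial(r, r / (r + rate))
    track = CoverageTrack(contig=spec.contig, depths=depths.astype(np.int64))
    records = []
    for i, ev in enumerate(spec.events):
        end = ev.start if ev.svtype == "INS" else ev.end
        records.append(
            VariantRecord(
                contig=spec.contig,
                start=ev.start,
                end=end,
                svtype=ev.svtype,
                filter=frozenset({"PASS"}),
                genotype_by_sample={sample_id: ev.genotype},
                variant_id=f"{ev.svtype}_{i}",
            )
        )
    stats = (float(depths.mean()), float(depths.std()))
    return track, records, stats


def merge_variant_records(
    per_sample: Sequence[Sequence[VariantRecord]],
) -> List[VariantRecord]:
    """Merge identical loci across samples into multi-sample records."""
    merged: Dict[Tuple, VariantRecord] = {}
    for records in per_sample:
        for rec in records:
            key = (rec.contig, rec.start, rec.end, rec.svtype)
            if key not in merged:
                merged[key] = VariantRecord(
                    contig=rec.contig,
                    start=rec.start,
                    end=rec.end,
                    svtype=rec.svtype,
                    filter=rec.filter,
                    genotype_by_sample=dict(rec.genotype_by_sample),
                    variant_id=rec.variant_id,
                )
            else:
                merged[key].genotype_by_sample.update(rec.genotype_by_sample)
    return list(merged.values())


_GT_STRING = {Genotype.HOM_ALT: "1/1", Genotype.HET: "0/1", Genotype.OTHER: "0/0"}


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: Union[str, Path],
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write records as an uncompressed VCF 4.2 with SVTYPE/END and GT:FT."""
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in sorted({r.contig for r in records}):
            lines.append(f"##contig=<ID={name}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##FILTER=<ID=LowQual,Description="Low quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-sample filter">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for rec in sorted(records, key=lambda r: (r.contig, r.start)):
        filt = "PASS" if rec.filter == frozenset({"PASS"}) else ";".join(sorted(rec.filter))
        info = f"SVTYPE={rec.svtype};END={rec.end}"
        calls = []
        for s in samples:
            gt = rec.genotype_by_sample.get(s, Genotype.OTHER)
            calls.append(f"{_GT_STRING[gt]}:PASS")
        lines.append(
            f"{rec.contig}\t{rec.start}\t{rec.variant_id}\tN\t<{rec.svtype}>\t.\t"
            f"{filt}\t{info}\tGT:FT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sample_files(
    spec: SimSpec, seed: int, outdir: Union[str, Path], sample_id: str = "S0"
) -> Dict[str, Path]:
    """Emit bedGraph + BCOV + VCF + metadata TSV for one simulated sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    track, records, (mean, sd) = simulate_sample(spec, seed, sample_id)
    bcov_path = outdir / f"{sample_id}.bcov"
    write_bcov([track], bcov_path)
    bg_path = outdir / f"{sample_id}.bedGraph"
    with open(bg_path, "w") as fh:
        depths = track.depths
        run_start = 0
        for i in range(1, len(depths) + 1):
            if i == len(depths) or depths[i] != depths[run_start]:
                if depths[run_start] != 0:
                    fh.write(
                        f"{spec.contig}\t{run_start}\t{i}\t{depths[run_start]}\n"
                    )
                run_start = i
    vcf_path = outdir / f"{sample_id}.vcf"
    write_vcf(records, [sample_id], vcf_path, {spec.contig: spec.length})
    meta_path = outdir / f"{sample_id}.meta.tsv"
    meta_path.write_text(
        "sample\tpopulation\tsex\tmean_coverage\tsd_coverage\tbcov_path\n"
        f"{sample_id}\tSYNTH\tU\t{mean:.4f}\t{sd:.4f}\t{bcov_path}\n"
    )
    return {
        "bcov": bcov_path,
        "bedgraph": bg_path,
        "vcf": vcf_path,
        "meta": meta_path,
    }


# ------------------------------------------------------- profile templates


def step_template(seg_len: int = 32, direction: int = -1) -> np.ndarray:
    """Unit step at the segment centre: +0.5 then -0.5 (direction=-1)."""
    half = seg_len // 2
    t = np.empty(seg_len)
    t[:half] = 0.5 * -direction
    t[half:] = 0.5 * direction
    return t


def planted_motif_dataset(
    template: Sequence[float],
    n_profiles: int,
    noise_sd: float,
    seed: int,
    base: float = 30.0,
    amplitude: float = 20.0,
    profile_length: int = 512,
    pool_window: int = 8,
    shift_jitter: int = 0,
    stretch_jitter: float = 0.0,
) -> np.ndarray:
    """Profiles with the template embedded at the centre plus noise.

    The seg_len-point template is expanded to ``len(template) *
    pool_window`` bp, scaled by ``amplitude`` around ``base``, centred in
    a flat baseline, and Gaussian noise of ``noise_sd`` is added.
    Optional jitter shifts each instance by up to ``shift_jitter`` bp and
    stretches it by up to ±``stretch_jitter`` (fractional), emulating
    caller-imprecise and elastically deformed breakpoints.
    """
    tmpl = np.asarray(template, dtype=float)
    rng = np.random.default_rng(seed)
    profiles = np.empty((n_profiles, profile_length))
    span = tmpl.size * pool_window
    for i in range(n_profiles):
        stretch = 1.0 + (rng.uniform(-stretch_jitter, stretch_jitter) if stretch_jitter else 0.0)
        width = max(pool_window, int(round(span * stretch)))
        xs = np.linspace(0, tmpl.size - 1, width)
        expanded = np.interp(xs, np.arange(tmpl.size), tmpl)
        shift = int(rng.integers(-shift_jitter, shift_jitter + 1)) if shift_jitter else 0
        start = (profile_length - width) // 2 + shift
        start = int(np.clip(start, 0, profile_length - width))
        prof = np.full(profile_length, base)
        # continue the template's edge levels outside the embedded span
        prof[:start] = base + amplitude * expanded[0]
        prof[start + width :] = base + amplitude * expanded[-1]
        prof[start : start + width] = base + amplitude * expanded
        if noise_sd > 0:
            prof = prof + rng.normal(0, noise_sd, size=profile_length)
        profiles[i] = np.maximum(prof, 0.0)
    return profiles


def shape_pool(
    templates: Sequence[Sequence[float]],
    n_per_family: int,
    noise_sd: float,
    seed: int,
    **kwargs,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pool of profiles from several planted shape families, with labels."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for fi, tmpl in enumerate(templates):
        blocks.append(
            planted_motif_dataset(
                tmpl, n_per_family, noise_sd, seed=int(rng.integers(2**31 - 1)), **kwargs
            )
        )
        labels.extend([fi] * n_per_family)
    return np.vstack(blocks), np.array(labels)
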