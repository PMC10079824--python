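"""Orchestration of the two end-to-end workflows.

``run_build`` goes from coverage + SV calls to a populated profile store
and predominant motifs: convert/load coverage, filter variants, derive
typed breakpoint loci, extract carrier profiles, then bootstrap motif
discovery per (svtype, side, genotype) combination and merge. The
processing order over combinations is fixed (sorted), so motif files are
byte-identical across reruns with equal inputs, config and seed.

``run_scan`` takes a BCOV track and stored motifs and delegates to the
sliding-window scanner, after checking that the motifs were generated
under compatible parameters.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .bcov_io import CoverageTrack
from .motif_discovery import (
    Motif,
    discover_predominant_motifs,
    read_motif_json,
    write_motif_files,
)
from .motif_scan import scan_track
from .sv_extract import (
    DOCProfile,
    ProfileStore,
    VariantRecord,
    derive_loci,
    extract_profiles,
    filter_variants,
    parse_vcf,
    populate_store,
)

logger = logging.getLogger(__name__)

# minimum carrier profiles to attempt clustering + discovery for a combo
MIN_POOL = 10


def _combo_key(profile: DOCProfile, ignore_genotype: bool) -> Tuple[str, str, str]:
    gt = "ANY" if ignore_genotype else profile.genotype.value
    return (profile.locus.variant.svtype, profile.locus.side.value, gt)


def run_build(
    coverage_by_sample: Dict[str, Union[CoverageTrack, str, Path, Dict[str, CoverageTrack]]],
    variants: Union[str, Path, Sequence[VariantRecord]],
    config: PipelineConfig,
    metadata: Optional[Dict[str, Dict]] = None,
    store_path: Union[str, Path] = ":memory:",
    motif_prefix: Optional[str] = None,
    ignore_genotype: bool = False,
    sample_stats: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Tuple[ProfileStore, List[Motif], Dict]:
    """Full build: variants + coverage -> profile store + predominant motifs.

    ``variants`` is a VCF path or pre-parsed records. ``ignore_genotype``
    pools hom and het carriers, the remedy used when per-genotype pools
    are too thin to support a distinct motif. Returns the open store, the
    motif list and a run report (profile counts per combination, the
    config and the seed).
    """
    if isinstance(variants, (str, Path)):
        records = parse_vcf(variants)
    else:
        records = list(variants)
    records = filter_variants(records, config)
    loci = [locus for rec in records for locus in derive_loci(rec, config)]
    profiles = extract_profiles(loci, coverage_by_sample, config)

    pools: Dict[Tuple[str, str, str], List[DOCProfile]] = defaultdict(list)
    for p in profiles:
        pools[_combo_key(p, ignore_genotype)].append(p)

    rng = np.random.default_rng(config.seed)
    motifs: List[Motif] = []
    counts = {}
    for combo in sorted(pools):
        svtype, side, genotype = combo
        members = pools[combo]
        counts["/".join(combo)] = len(members)
        combo_seed = int(rng.integers(2**31 - 1))
        if len(members) < MIN_POOL:
            logger.warning(
                "combination %s has only %d profiles (<%d); motif discovery skipped",
                combo,
                len(members),
                MIN_POOL,
            )
            continue
        X = np.stack([m.values for m in members])
        stats = None
        if sample_stats is not None and config.normalize_mode == "sample":
            stats = [sample_stats[m.sample] for m in members]
        motifs.extend(
            discover_predominant_motifs(
                X,
                config,
                seed=combo_seed,
                svtype=svtype,
                side=side,
                genotype=genotype,
                sample_stats=stats,
            )
        )

    store = ProfileStore(store_path)
    populate_store(store, profiles, metadata, motifs)
    if motif_prefix is not None:
        write_motif_files(motifs, motif_prefix, config)
    report = {
        "n_variants": len(records),
        "n_loci": len(loci),
        "n_profiles": len(profiles),
        "profiles_per_combination": counts,
        "n_motifs": len(motifs),
        "seed": config.seed,
        "config": {
            "half_width": config.half_width,
            "pool_window": config.pool_window,
            "alphabet_size": config.alphabet_size,
            "seg_len": config.seg_len,
            "n_bootstrap": config.n_bootstrap,
            "bootstrap_size": config.bootstrap_size,
        },
    }
    if not records:
        logger.warning("no variants after filtering; store is empty")
    return store, motifs, report


def run_scan(
    bcov: Union[str, Path, CoverageTrack],
    motifs: Union[str, Path, Sequence[Motif]],
    config: PipelineConfig,
    stride: int = 256,
    threshold: Optional[float] = None,
    out_tsv: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Scan a coverage track for stored motifs; BED-like hit table out."""
    if isinstance(motifs, (str, Path)):
        motif_list, params = read_motif_json(motifs)
        for key in ("alphabet_size", "seg_len", "pool_window", "half_width"):
            if params[key] != getattr(config, key):
                raise ValueError(
                    f"motif file parameter mismatch: {key} is {params[key]} "
                    f"in the file but {getattr(config, key)} in the config"
                )
    else:
        motif_list = list(motifs)
    if not motif_list:
        raise ValueError("no motifs supplied")
    thresholds = None if threshold is None else [threshold] * len(motif_list)
    hits = scan_track(
        bcov, motif_list, config, stride=stride, thresholds=thresholds,
        seed=config.seed,
    )
    logger.info("scan produced %d merged hits", len(hits))
    if out_tsv is not None:
        hits.to_csv(out_tsv, sep="\t", index=False)
    return hits
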