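"""Variant filtering, breakpoint taxonomy, profile extraction, store."""

import numpy as np
import pytest

from svwave.bcov_io import CoverageTrack
from svwave.config import PipelineConfig
from svwave.fixtures import write_vcf
from svwave.sv_extract import (
    BreakpointLocus,
    DOCProfile,
    Genotype,
    ProfileStore,
    Side,
    VariantRecord,
    classify_gt,
    derive_loci,
    extract_profiles,
    filter_variants,
    parse_vcf,
    populate_store,
)

CFG = PipelineConfig()


def _rec(svtype="DEL", start=10_000, end=19_999, filt=("PASS",), gts=None):
    return VariantRecord(
        contig="chr1",
        start=start,
        end=start if svtype == "INS" else end,
        svtype=svtype,
        filter=frozenset(filt),
        genotype_by_sample=gts or {"S0": Genotype.HOM_ALT},
        variant_id=f"{svtype}_{start}",
    )


class TestFilter:
    def test_short_variant_dropped(self):
        assert filter_variants([_rec(start=100, end=109)], CFG) == []

    def test_exactly_min_length_retained(self):
        kept = filter_variants([_rec(start=100, end=119)], CFG)
        assert len(kept) == 1  # length 20 stays

    def test_non_pass_dropped(self):
        assert filter_variants([_rec(filt=("LowQual",))], CFG) == []
        assert filter_variants([_rec(filt=("PASS", "LowQual"))], CFG) == []

    def test_insertion_exempt_from_length(self):
        kept = filter_variants([_rec(svtype="INS", start=500)], CFG)
        assert len(kept) == 1

    def test_empty_input(self):
        assert filter_variants([], CFG) == []

    def test_idempotent(self):
        records = [
            _rec(),
            _rec(start=100, end=109),
            _rec(filt=("LowQual",)),
            _rec(svtype="INS", start=7),
        ]
        once = filter_variants(records, CFG)
        assert filter_variants(once, CFG) == once


class TestDeriveLoci:
    def test_insertion_single_breakpoint(self):
        loci = derive_loci(_rec(svtype="INS", start=1000), CFG)
        assert [(l.side, l.position) for l in loci] == [(Side.BP, 1000)]

    def test_long_interval_left_and_right(self):
        loci = derive_loci(_rec(start=10_000, end=19_999), CFG)
        assert [(l.side, l.position) for l in loci] == [
            (Side.L, 10_000),
            (Side.R, 19_999),
        ]

    def test_short_interval_is_spsv_at_midpoint(self):
        loci = derive_loci(_rec(start=1000, end=1099), CFG)
        assert [(l.side, l.position) for l in loci] == [(Side.SPSV, 1049)]

    def test_cnv_never_spsv(self):
        assert derive_loci(_rec(svtype="CNV_GAIN", start=1000, end=1099), CFG) == []
        assert derive_loci(_rec(svtype="CNV_LOSS", start=1000, end=1099), CFG) == []

    def test_cnv_long_interval_has_l_and_r(self):
        loci = derive_loci(_rec(svtype="CNV_LOSS", start=5000, end=9999), CFG)
        assert [l.side for l in loci] == [Side.L, Side.R]

    def test_window_boundary_is_spsv_below_512(self):
        assert derive_loci(_rec(start=1000, end=1510), CFG)[0].side == Side.SPSV
        assert derive_loci(_rec(start=1000, end=1511), CFG)[0].side == Side.L

    def test_left_right_balance(self):
        records = [_rec(start=s, end=s + 2000) for s in (10_000, 20_000, 40_000)]
        loci = [l for r in records for l in derive_loci(r, CFG)]
        sides = [l.side for l in loci]
        assert sides.count(Side.L) == sides.count(Side.R) == 3


class TestGenotypes:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            ((1, 1), Genotype.HOM_ALT),
            ((0, 1), Genotype.HET),
            ((1, 0), Genotype.HET),
            ((0, 0), Genotype.OTHER),
            ((None, None), Genotype.OTHER),
            ((1, 2), Genotype.OTHER),
        ],
    )
    def test_gt_classification(self, alleles, expected):
        assert classify_gt(alleles) == expected


class TestExtractProfiles:
    def _coverage(self, n=40_000, depth=30):
        return {
            s: CoverageTrack("chr1", np.full(n, depth, dtype=np.int64))
            for s in ("S0", "S1", "S2")
        }

    def test_one_profile_per_carrier(self):
        rec = _rec(
            gts={
                "S0": Genotype.HOM_ALT,
                "S1": Genotype.HET,
                "S2": Genotype.HOM_ALT,
            }
        )
        loci = [BreakpointLocus(rec, Side.L, rec.start)]
        profiles = extract_profiles(loci, self._coverage(), CFG)
        assert len(profiles) == 3
        assert all(p.values.size == 512 for p in profiles)

    def test_non_carriers_excluded(self):
        rec = _rec(gts={"S0": Genotype.OTHER, "S1": Genotype.HET})
        loci = [BreakpointLocus(rec, Side.L, rec.start)]
        assert {p.sample for p in extract_profiles(loci, self._coverage(), CFG)} == {
            "S1"
        }

    def test_window_off_contig_dropped(self):
        rec = _rec(start=100, end=5000)
        loci = [BreakpointLocus(rec, Side.L, 100)]
        assert extract_profiles(loci, self._coverage(), CFG) == []

    def test_all_zero_window_dropped(self):
        rec = _rec()
        loci = [BreakpointLocus(rec, Side.L, rec.start)]
        cov = {"S0": CoverageTrack("chr1", np.zeros(40_000, dtype=np.int64))}
        assert extract_profiles(loci, cov, CFG) == []

    def test_missing_coverage_skipped(self):
        rec = _rec(gts={"S0": Genotype.HOM_ALT, "missing": Genotype.HOM_ALT})
        loci = [BreakpointLocus(rec, Side.L, rec.start)]
        cov = {"S0": CoverageTrack("chr1", np.full(40_000, 30, dtype=np.int64))}
        assert {p.sample for p in extract_profiles(loci, cov, CFG)} == {"S0"}


class TestVCFRoundtrip:
    def test_parse_written_vcf(self, tmp_path):
        records = [
            _rec(gts={"S0": Genotype.HOM_ALT, "S1": Genotype.HET}),
            _rec(svtype="INS", start=5000, gts={"S0": Genotype.HET, "S1": Genotype.OTHER}),
            _rec(svtype="DUP", start=30_000, end=39_999, filt=("LowQual",)),
        ]
        path = tmp_path / "svs.vcf"
        write_vcf(records, ["S0", "S1"], path, {"chr1": 100_000})
        parsed = parse_vcf(path)
        assert len(parsed) == 3
        by_id = {r.variant_id: r for r in parsed}
        del0 = by_id["DEL_10000"]
        assert (del0.start, del0.end, del0.svtype) == (10_000, 19_999, "DEL")
        assert del0.genotype_by_sample == {
            "S0": Genotype.HOM_ALT,
            "S1": Genotype.HET,
        }
        assert by_id["INS_5000"].end == 5000
        assert by_id["DUP_30000"].filter == frozenset({"LowQual"})


class TestStore:
    def _profiles(self):
        rec = _rec(gts={"S0": Genotype.HOM_ALT})
        locus = BreakpointLocus(rec, Side.L, rec.start)
        return [
            DOCProfile(
                values=np.arange(512, dtype=np.int64) + i,
                sample="S0",
                locus=locus,
                genotype=Genotype.HOM_ALT,
            )
            for i in range(3)
        ]

    def test_insert_and_query_by_svtype(self):
        with ProfileStore() as store:
            store.add_sample("S0")
            populate_store(store, self._profiles())
            assert len(store.query_profiles(svtype="DEL")) == 3
            assert store.query_profiles(svtype="INV") == []

    def test_value_roundtrip(self):
        with ProfileStore() as store:
            store.add_sample("S0")
            store.add_profiles(self._profiles())
            rows = store.query_profiles(svtype="DEL")
            stored = sorted(tuple(r[5][:3]) for r in rows)
            assert stored == [(0, 1, 2), (1, 2, 3), (2, 3, 4)]

    def test_query_by_region(self):
        with ProfileStore() as store:
            store.add_sample("S0")
            store.add_profiles(self._profiles())
            assert len(store.query_profiles(region=("chr1", 9000, 11_000))) == 3
            assert store.query_profiles(region=("chr1", 900, 1100)) == []

    def test_foreign_key_enforced(self):
        import sqlite3

        with ProfileStore() as store:
            with pytest.raises(sqlite3.IntegrityError):
                store.conn.execute(
                    "INSERT INTO profile (sample_id, breakpoint_id, genotype,"
                    " values_blob) VALUES ('ghost', 1, 'HET', x'00')"
                )
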