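import random

import pytest

from editscan.detection import (
    call_genotype,
    classify_mismatch,
    detect_candidates,
    evaluate_criteria,
)
from editscan.types import (
    COMPLEMENT,
    DetectionParams,
    GenotypeStatus,
    MISMATCH_TYPES,
    SampleCall,
)

from conftest import make_record

PARAMS = DetectionParams()


class TestCallGenotype:
    @pytest.mark.parametrize(
        "dp,dv,expected",
        [
            (9, 0, GenotypeStatus.INSUFFICIENT_DEPTH),
            (10, 0, GenotypeStatus.HOM_REF),
            (20, 0, GenotypeStatus.HOM_REF),
            (20, 1, GenotypeStatus.HOM_REF),   # 19/20 = 0.95, inclusive
            (1000, 51, GenotypeStatus.HET),    # 949/1000 = 0.949 < 0.95
            (20, 10, GenotypeStatus.HET),
            (20, 19, GenotypeStatus.HOM_ALT),  # 19/20 = 0.95, inclusive
            (1000, 949, GenotypeStatus.HET),   # 0.949 just below the boundary
            (20, 20, GenotypeStatus.HOM_ALT),
        ],
    )
    def test_homozygosity_boundaries(self, dp, dv, expected):
        rec = make_record(ref="A", alts=("G",), dna=(dp, dv))
        call = call_genotype(SampleCall(dp, dv, 0), rec, PARAMS)
        assert call.status is expected

    def test_hom_allele_assignment(self):
        rec = make_record(ref="A", alts=("G",), dna=(20, 0))
        assert call_genotype(SampleCall(20, 0, 0), rec, PARAMS).dna_allele == "A"
        assert call_genotype(SampleCall(20, 20, 0), rec, PARAMS).dna_allele == "G"

    def test_indel_and_multiallelic_exclusions(self):
        indel = make_record(ref="A", alts=("AG",), dna=(20, 0), indel=True)
        assert (
            call_genotype(SampleCall(20, 0, 0), indel, PARAMS).status
            is GenotypeStatus.INDEL_EXCLUDED
        )
        multi = make_record(ref="A", alts=("G", "C"), dna=(20, 0))
        assert (
            call_genotype(SampleCall(20, 0, 0), multi, PARAMS).status
            is GenotypeStatus.MULTIALLELIC_EXCLUDED
        )

    def test_dv_exceeding_dp_is_data_error(self):
        rec = make_record(dna=(10, 11))
        with pytest.raises(ValueError, match="DV"):
            call_genotype(SampleCall(10, 11, 0), rec, PARAMS)

    def test_missing_dna_tags_insufficient(self):
        rec = make_record()
        call = call_genotype(SampleCall(None, None, None), rec, PARAMS)
        assert call.status is GenotypeStatus.INSUFFICIENT_DEPTH


class TestClassifyMismatch:
    @pytest.mark.parametrize(
        "dna,rna,strand,expected",
        [
            ("A", "G", "+", "A-to-G"),
            ("T", "C", "-", "A-to-G"),
            ("A", "G", "-", "T-to-C"),
            ("C", "T", "+", "C-to-T"),
            ("G", "A", "-", "C-to-T"),
        ],
    )
    def test_strand_typing(self, dna, rna, strand, expected):
        assert classify_mismatch(dna, rna, strand)[2] == expected

    def test_twelve_type_partition_is_exhaustive(self):
        seen = set()
        for dna in "ACGT":
            for rna in "ACGT":
                if dna == rna:
                    continue
                for strand in "+-":
                    seen.add(classify_mismatch(dna, rna, strand)[2])
        assert seen == set(MISMATCH_TYPES)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            classify_mismatch("A", "A", "+")
        with pytest.raises(ValueError):
            classify_mismatch("A", "N", "+")
        with pytest.raises(ValueError):
            classify_mismatch("A", "G", "x")


def _detect(plus=(), minus=(), tissues=("Liver",), params=PARAMS):
    return detect_candidates(iter(plus), iter(minus), list(tissues), params)


class TestDetectCandidates:
    def test_basic_hom_ref_candidate(self):
        rec = make_record(ref="A", alts=("G",), dna=(30, 0), tissues=[(30, 7, 3)])
        (c,) = _detect(plus=[rec])
        assert c.mismatch_type == "A-to-G"
        assert (c.rna_edited, c.rna_depth, c.strand) == (7, 30, "+")

    def test_minus_strand_t_to_c_reported_as_a_to_g(self):
        rec = make_record(ref="T", alts=("C",), dna=(30, 0), tissues=[(30, 6, 0)])
        (c,) = _detect(minus=[rec])
        assert c.mismatch_type == "A-to-G" and c.strand == "-"
        assert (c.dna_base, c.rna_base) == ("A", "G")
        assert (c.genomic_dna_base, c.genomic_rna_base) == ("T", "C")

    def test_hom_alt_edited_reads_are_reference_reads(self):
        # genotype G (alt), RNA shows the reference A: edited = dp - dv
        rec = make_record(ref="G", alts=("A",), dna=(40, 40), tissues=[(20, 12, 5)])
        (c,) = _detect(plus=[rec])
        assert (c.dna_base, c.rna_base) == ("A", "G")
        assert c.rna_edited == 8

    @pytest.mark.parametrize(
        "tissues,expect",
        [
            ([(30, 4, 3)], 0),   # criterion 4: fewer than 5 edited reads
            ([(30, 5, 3)], 1),
            ([(30, 7, 21)], 0),  # criterion 5: strand bias above 20
            ([(30, 7, 20)], 1),
        ],
    )
    def test_per_tissue_thresholds(self, tissues, expect):
        rec = make_record(ref="A", alts=("G",), dna=(30, 0), tissues=tissues)
        assert len(_detect(plus=[rec])) == expect

    def test_missing_tissue_tags_fail_closed(self):
        rec = make_record(ref="A", alts=("G",), dna=(30, 0))
        rec.samples[1] = SampleCall(dp=30, dv=None, sp=None)
        assert _detect(plus=[rec]) == []

    def test_per_tissue_independence_and_sorting(self):
        rec = make_record(
            ref="A", alts=("G",), dna=(30, 0),
            tissues=[(30, 7, 3), (30, 2, 3), (25, 6, 0)],
        )
        out = _detect(plus=[rec], tissues=("Liver", "Fat", "LD"))
        assert [c.tissue for c in out] == ["LD", "Liver"]

    def test_sample_count_mismatch_raises(self):
        rec = make_record(tissues=[(30, 7, 3), (30, 7, 3)])
        with pytest.raises(ValueError, match="samples"):
            _detect(plus=[rec], tissues=("Liver",))

    def test_same_position_both_strands_distinct(self):
        plus = make_record(ref="A", alts=("G",), dna=(30, 0), tissues=[(30, 7, 3)])
        minus = make_record(ref="T", alts=("C",), dna=(30, 0), tissues=[(30, 7, 3)])
        out = _detect(plus=[plus], minus=[minus])
        assert len(out) == 2
        assert {c.strand for c in out} == {"+", "-"}


def _random_records(rng, n=300):
    records = []
    for i in range(n):
        ref, alt = rng.sample("ACGT", 2)
        dp = rng.randint(5, 60)
        dv = rng.randint(0, dp)
        tissues = [
            (rng.randint(3, 60), 0, rng.randint(0, 40)) for _ in range(2)
        ]
        tissues = [
            (tdp, rng.randint(0, tdp), sp) for tdp, _, sp in tissues
        ]
        records.append(
            make_record(
                ref=ref, alts=(alt,), dna=(dp, dv), tissues=tissues,
                indel=rng.random() < 0.1, pos=1000 + i,
            )
        )
    return records


class TestDetectionProperties:
    def test_monotonicity_raising_thresholds_never_adds(self):
        rng = random.Random(11)
        records = _random_records(rng)
        base = set(
            (c.chrom, c.pos, c.strand, c.tissue)
            for c in _detect(plus=records, tissues=("A", "B"))
        )
        tighter = [
            DetectionParams(min_dna_depth=15),
            DetectionParams(homozygosity_fraction=0.99),
            DetectionParams(min_edited_reads=8),
            DetectionParams(max_strand_bias_phred=10),
        ]
        for params in tighter:
            got = set(
                (c.chrom, c.pos, c.strand, c.tissue)
                for c in _detect(plus=records, tissues=("A", "B"), params=params)
            )
            assert got <= base

    def test_strand_symmetry_under_complementation(self):
        rng = random.Random(12)
        records = _random_records(rng)
        flipped = []
        for r in records:
            f = make_record(
                ref=COMPLEMENT.get(r.ref_allele, r.ref_allele),
                alts=tuple(COMPLEMENT.get(a, a) for a in r.alt_alleles),
                dna=(r.samples[0].dp, r.samples[0].dv),
                tissues=[(s.dp, s.dv, s.sp) for s in r.samples[1:]],
                indel=r.is_indel, pos=r.pos,
            )
            flipped.append(f)
        fwd = _detect(plus=records, tissues=("A", "B"))
        rev = _detect(minus=flipped, tissues=("A", "B"))
        assert {(c.pos, c.mismatch_type, c.tissue) for c in fwd} == {
            (c.pos, c.mismatch_type, c.tissue) for c in rev
        }
        assert all(c.strand == "-" for c in rev)

    def test_emitted_candidates_satisfy_all_five_criteria(self, fixture_run):
        plus_index = {}
        from editscan.io_formats import VcfReader
        import os

        tissues = fixture_run["tissues"]
        for name in ("plus.vcf", "minus.vcf"):
            strand = "+" if name == "plus.vcf" else "-"
            for rec in VcfReader(os.path.join(fixture_run["dir"], name)):
                plus_index[(rec.chrom, rec.pos, strand)] = rec
        for c in fixture_run["candidates"]:
            rec = plus_index[(c.chrom, c.pos, c.strand)]
            crit = evaluate_criteria(rec, tissues.index(c.tissue), PARAMS)
            assert crit is not None and all(crit.values()), (c, crit)
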