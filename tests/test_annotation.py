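import random

import pytest

from editscan.annotation import (
    aa_change_table,
    categorize,
    find_containing,
    merge_vep,
    overlap_repeats,
    read_annotated,
    write_annotated,
)
from editscan.types import (
    AnnotatedCandidate,
    EditCandidate,
    RepeatInterval,
    VepRecord,
)


def _candidate(chrom="1", pos=1100, strand="+", tissue="Liver", **kw):
    defaults = dict(
        chrom=chrom, pos=pos, strand=strand, tissue=tissue, dna_base="A",
        rna_base="G", mismatch_type="A-to-G", dna_depth=30, rna_depth=40,
        rna_edited=8, sp=2, mq=50.0,
    )
    defaults.update(kw)
    return EditCandidate(**defaults)


def _iv(begin, end, chrom="1", name="Pre0_SS", cf="SINE/tRNA"):
    return RepeatInterval(
        chrom=chrom, begin=begin, end=end, strand="+",
        repeat_name=name, repeat_class_family=cf,
    )


def _vep(chrom="1", pos=1100, allele="G", consequence="intron_variant",
         gene="G1", feature="TX1", amino_acids=None, sift=None):
    return VepRecord(
        uploaded_variation=".", location=f"{chrom}:{pos}", allele=allele,
        gene=gene, feature=feature, consequence=consequence,
        protein_position=None, amino_acids=amino_acids, sift=sift,
    )


class TestOverlapRepeats:
    def test_containment_and_boundaries(self):
        repeats = {"1": [_iv(1000, 1246)]}
        inside, = overlap_repeats([_candidate(pos=1100)], repeats)
        assert inside.repeat == _iv(1000, 1246)
        before, = overlap_repeats([_candidate(pos=999)], repeats)
        assert before.repeat is None
        at_start, = overlap_repeats([_candidate(pos=1000)], repeats)
        assert at_start.repeat is not None
        at_end, = overlap_repeats([_candidate(pos=1246)], repeats)
        assert at_end.repeat is not None

    def test_nested_intervals_largest_begin_wins(self):
        repeats = {"1": [_iv(1000, 2000, name="outer"), _iv(1050, 1200, name="inner")]}
        hit, = overlap_repeats([_candidate(pos=1100)], repeats)
        assert hit.repeat.repeat_name == "inner"
        # position inside outer only
        hit2, = overlap_repeats([_candidate(pos=1500)], repeats)
        assert hit2.repeat.repeat_name == "outer"

    def test_unsorted_input_rejected(self):
        repeats = {"1": [_iv(2000, 3000), _iv(1000, 1500)]}
        with pytest.raises(ValueError, match="sorted"):
            overlap_repeats([_candidate()], repeats)

    def test_matches_naive_scan_on_random_instances(self):
        """Binary search + backward scan equals the naive containment scan."""
        rng = random.Random(42)
        for trial in range(120):
            n_iv = rng.randint(0, 50)
            intervals = []
            for _ in range(n_iv):
                b = rng.randint(1, 2000)
                # mix of short, nested and abutting spans
                e = b + rng.choice([0, 1, rng.randint(0, 40), rng.randint(0, 400)])
                intervals.append(_iv(b, e))
            intervals.sort(key=lambda iv: (iv.begin, iv.end))
            max_len = max((iv.end - iv.begin + 1 for iv in intervals), default=0)
            for _ in range(20):
                pos = rng.randint(1, 2200)
                got = find_containing(intervals, pos, max_len)
                best = None
                for iv in intervals:
                    if iv.contains(pos) and (best is None or iv.begin >= best.begin):
                        best = iv
                assert got == best, (trial, pos, intervals)

    def test_count_preserved(self):
        cands = [_candidate(pos=p) for p in (10, 1100, 5000)]
        out = overlap_repeats(cands, {"1": [_iv(1000, 1246)]})
        assert len(out) == len(cands)


class TestMergeVep:
    def test_category_priority_missense_over_intron(self):
        cand = AnnotatedCandidate(candidate=_candidate(pos=46041505, chrom="17"))
        rows = [
            _vep(chrom="17", pos=46041505, consequence="intron_variant",
                 feature="TX2"),
            _vep(chrom="17", pos=46041505, consequence="missense_variant",
                 feature="TX1", amino_acids="Y/C", sift="deleterious (0)"),
        ]
        (out,) = merge_vep([cand], rows)
        assert out.location_category == "missense"
        assert out.vep.amino_acids == "Y/C"
        assert out.vep.sift == "deleterious (0)"

    def test_compound_consequence_uses_priority(self):
        cand = AnnotatedCandidate(candidate=_candidate())
        (out,) = merge_vep(
            [cand], [_vep(consequence="intron_variant,NMD_transcript_variant")]
        )
        assert out.location_category == "intron"

    def test_allele_must_match(self):
        cand = AnnotatedCandidate(candidate=_candidate(strand="-"))
        # minus-strand A-to-G has genomic variant allele C
        (miss,) = merge_vep([cand], [_vep(allele="G")])
        assert miss.vep is None and miss.location_category == "other"
        (hit,) = merge_vep([cand], [_vep(allele="C")])
        assert hit.vep is not None

    def test_unmatched_keeps_other_and_count_preserved(self):
        cands = [AnnotatedCandidate(candidate=_candidate(pos=p)) for p in (1, 2, 3)]
        out = merge_vep(cands, [])
        assert len(out) == 3
        assert all(o.vep is None and o.location_category == "other" for o in out)

    def test_tie_break_by_gene_then_feature(self):
        cand = AnnotatedCandidate(candidate=_candidate())
        rows = [
            _vep(consequence="intron_variant", gene="B", feature="TX9"),
            _vep(consequence="intron_variant", gene="A", feature="TX2"),
            _vep(consequence="intron_variant", gene="A", feature="TX1"),
        ]
        (out,) = merge_vep([cand], rows)
        assert (out.vep.gene, out.vep.feature) == ("A", "TX1")

    def test_category_total_function(self):
        assert categorize(None) == "other"
        assert categorize(_vep(consequence="weird_new_term")) == "other"
        assert categorize(_vep(consequence="3_prime_UTR_variant")) == "three_prime_utr"
        assert categorize(_vep(consequence="stop_gained")) == "stop_or_start_altering"


class TestAaChangeTable:
    def test_tissues_aggregated_per_site(self):
        rows = [_vep(consequence="missense_variant", amino_acids="Y/C",
                     sift="deleterious (0)", gene="BLCAP")]
        cands = [
            AnnotatedCandidate(candidate=_candidate(tissue=t))
            for t in ("Liver", "Fat", "LD")
        ]
        merged = merge_vep(cands, rows)
        table = aa_change_table(merged)
        assert len(table) == 1
        assert table.iloc[0]["tissues"] == "Fat LD Liver"
        assert table.iloc[0]["amino_acids"] == "Y/C"

    def test_planted_missense_sites_counted(self):
        """34 missense among 49 coding sites gives a 34-row table."""
        rng = random.Random(5)
        cands, records = [], []
        for i in range(49):
            pos = 1000 + i
            missense = i < 34
            records.append(
                _vep(
                    pos=pos,
                    consequence=(
                        "missense_variant" if missense else "synonymous_variant"
                    ),
                    amino_acids="K/R" if missense else "K",
                    gene=f"G{i}",
                )
            )
            cands.append(
                AnnotatedCandidate(
                    candidate=_candidate(
                        pos=pos, tissue=rng.choice(["Liver", "Fat", "LD"])
                    )
                )
            )
        table = aa_change_table(merge_vep(cands, records))
        assert len(table) == 34

    def test_empty_input_gives_empty_table_with_header(self):
        table = aa_change_table([])
        assert list(table.columns) == [
            "position", "gene", "amino_acids", "sift", "tissues"
        ]
        assert len(table) == 0


class TestAnnotatedTableRoundTrip:
    def test_write_read_preserves_summary_columns(self, tmp_path):
        cands = [
            AnnotatedCandidate(
                candidate=_candidate(pos=1100),
                repeat=_iv(1000, 1246),
                vep=_vep(consequence="missense_variant", amino_acids="K/R"),
                location_category="missense",
            ),
            AnnotatedCandidate(candidate=_candidate(pos=5000)),
        ]
        path = tmp_path / "ann.tsv"
        write_annotated(path, cands)
        back = read_annotated(path)
        assert len(back) == 2
        assert back[0].candidate == cands[0].candidate
        assert back[0].repeat.repeat_name == "Pre0_SS"
        assert back[0].location_category == "missense"
        assert back[0].vep.amino_acids == "K/R"
        assert back[1].repeat is None and back[1].vep is None
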