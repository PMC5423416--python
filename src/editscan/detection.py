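"""Candidate RNA-editing site detection from paired strand-split VCFs.

A DNA->RNA mismatch at a locus is accepted as an editing candidate when
all five criteria hold: (1) the genomic-DNA genotype is homozygous by at
least the configured fraction of DNA reads, (2) at least ``min_dna_depth``
DNA reads determined the genotype, (3) the site is not an indel in any
sample, (4) at least ``min_edited_reads`` cDNA reads of the tissue differ
from the genotype call, and (5) the tissue's phred-scaled strand-bias
P-value does not exceed ``max_strand_bias_phred``.

Transcript strandedness comes from which VCF the record belongs to: the
plus-strand file holds pileups of plus-strand transcript alignments, so a
genomic A->G change is an A-to-G edit; on the minus-strand file both bases
are complemented into transcript space, turning genomic T->C into A-to-G.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional

from .types import (
    COMPLEMENT,
    DetectionParams,
    EditCandidate,
    GenotypeCall,
    GenotypeStatus,
    SampleCall,
    VcfSiteRecord,
    complement_base,
)

CANDIDATE_TABLE_COLUMNS = [
    "chrom", "pos", "strand", "tissue", "dna_base", "rna_base", "type",
    "dna_depth", "rna_depth", "rna_edited", "sp", "mq",
]

TABLE_SCHEMA_LINE = "# editscan-table v1"


def _non_missing_alts(record: VcfSiteRecord) -> list[str]:
    return [a for a in record.alt_alleles if a != "."]


def call_genotype(
    dna: SampleCall, record: VcfSiteRecord, params: DetectionParams
) -> GenotypeCall:
    """Call the genomic-DNA genotype at a site (criteria 1-3 plus ploidy guards).

    The call is homozygous-reference when at least ``homozygosity_fraction``
    of the DNA reads match the reference (boundary inclusive), homozygous-
    alternate symmetrically; anything between is heterozygous.
    """
    if dna.dp is None or dna.dv is None:
        return GenotypeCall(GenotypeStatus.INSUFFICIENT_DEPTH)
    if dna.dv > dna.dp:
        raise ValueError(
            f"{record.chrom}:{record.pos}: DV {dna.dv} exceeds DP {dna.dp}"
        )
    if dna.dp < params.min_dna_depth:
        return GenotypeCall(GenotypeStatus.INSUFFICIENT_DEPTH)
    if record.is_indel:
        return GenotypeCall(GenotypeStatus.INDEL_EXCLUDED)
    alts = _non_missing_alts(record)
    if len(alts) > 1:
        return GenotypeCall(GenotypeStatus.MULTIALLELIC_EXCLUDED)
    frac = params.homozygosity_fraction
    if (dna.dp - dna.dv) / dna.dp >= frac:
        return GenotypeCall(GenotypeStatus.HOM_REF, dna_allele=record.ref_allele)
    if alts and dna.dv / dna.dp >= frac:
        return GenotypeCall(GenotypeStatus.HOM_ALT, dna_allele=alts[0])
    return GenotypeCall(GenotypeStatus.HET)


def classify_mismatch(
    genomic_dna_base: str, genomic_rna_base: str, strand: str
) -> tuple[str, str, str]:
    """Map a genomic-base mismatch to transcript-strand space and type it.

    On '+' the mapping is the identity; on '-' both bases are complemented,
    so genomic T->C on a minus-strand transcript is reported as A-to-G.
    """
    if genomic_dna_base not in COMPLEMENT or genomic_rna_base not in COMPLEMENT:
        raise ValueError(
            f"non-canonical bases {genomic_dna_base!r}->{genomic_rna_base!r}"
        )
    if genomic_dna_base == genomic_rna_base:
        raise ValueError("bases must differ")
    if strand == "+":
        dna_b, rna_b = genomic_dna_base, genomic_rna_base
    elif strand == "-":
        dna_b = complement_base(genomic_dna_base)
        rna_b = complement_base(genomic_rna_base)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return dna_b, rna_b, f"{dna_b}-to-{rna_b}"


def _mismatch_alleles(
    genotype: GenotypeCall, record: VcfSiteRecord
) -> Optional[tuple[str, str]]:
    """Genomic (dna_base, rna_base) implied by the genotype, or None if no SNV."""
    alts = _non_missing_alts(record)
    if genotype.status is GenotypeStatus.HOM_REF:
        if len(alts) != 1 or len(alts[0]) != 1 or len(record.ref_allele) != 1:
            return None
        return record.ref_allele, alts[0]
    if genotype.status is GenotypeStatus.HOM_ALT:
        if len(record.ref_allele) != 1 or len(genotype.dna_allele) != 1:
            return None
        return genotype.dna_allele, record.ref_allele
    return None


def _edited_reads(genotype: GenotypeCall, call: SampleCall) -> int:
    # at hom-ref loci the "edited" reads are the non-reference reads (DV);
    # at hom-alt loci they are the reads matching the reference (DP - DV)
    if genotype.status is GenotypeStatus.HOM_REF:
        return call.dv
    return call.dp - call.dv


def evaluate_criteria(
    record: VcfSiteRecord, tissue_index: int, params: DetectionParams
) -> Optional[dict[int, bool]]:
    """Independently evaluate the five criteria for one tissue at one site.

    ``tissue_index`` is 0-based over the cDNA samples (record.samples[1:]).
    Returns a mapping criterion-number -> satisfied, or None when the
    tissue's tags are missing or the site is multiallelic (not assessable
    under any single criterion).
    """
    dna = record.samples[0]
    call = record.samples[1 + tissue_index]
    if None in (dna.dp, dna.dv, call.dp, call.dv, call.sp):
        return None
    if len(_non_missing_alts(record)) > 1:
        return None
    crit2 = dna.dp >= params.min_dna_depth
    crit3 = not record.is_indel
    frac = params.homozygosity_fraction
    hom_ref = dna.dp > 0 and (dna.dp - dna.dv) / dna.dp >= frac
    alts = _non_missing_alts(record)
    hom_alt = dna.dp > 0 and bool(alts) and dna.dv / dna.dp >= frac
    crit1 = hom_ref or hom_alt
    if hom_ref:
        edited = call.dv
    elif hom_alt:
        edited = call.dp - call.dv
    else:
        edited = call.dv  # conventional: non-reference reads
    crit4 = edited >= params.min_edited_reads
    crit5 = call.sp <= params.max_strand_bias_phred
    return {1: crit1, 2: crit2, 3: crit3, 4: crit4, 5: crit5}


def _detect_stream(
    records: Iterable[VcfSiteRecord],
    strand: str,
    tissue_labels: list[str],
    params: DetectionParams,
    stats: Counter,
) -> list[EditCandidate]:
    out: list[EditCandidate] = []
    for record in records:
        if len(record.samples) != 1 + len(tissue_labels):
            raise ValueError(
                f"{record.chrom}:{record.pos}: expected "
                f"{1 + len(tissue_labels)} samples, found {len(record.samples)}"
            )
        genotype = call_genotype(record.samples[0], record, params)
        if genotype.status is GenotypeStatus.INSUFFICIENT_DEPTH:
            stats["insufficient_depth"] += 1
            continue
        if genotype.status is GenotypeStatus.INDEL_EXCLUDED:
            stats["indel"] += 1
            continue
        if genotype.status is GenotypeStatus.MULTIALLELIC_EXCLUDED:
            stats["multiallelic"] += 1
            continue
        if genotype.status is GenotypeStatus.HET:
            stats["het"] += 1
            continue
        alleles = _mismatch_alleles(genotype, record)
        if alleles is None:
            stats["no_snv_mismatch"] += 1
            continue
        genomic_dna, genomic_rna = alleles
        for i, tissue in enumerate(tissue_labels):
            call = record.samples[1 + i]
            if call.dp is None or call.dv is None or call.sp is None:
                stats["missing_tags"] += 1
                continue
            edited = _edited_reads(genotype, call)
            if edited < params.min_edited_reads:
                stats["low_edited"] += 1
                continue
            if call.sp > params.max_strand_bias_phred:
                stats["strand_bias"] += 1
                continue
            dna_b, rna_b, mtype = classify_mismatch(genomic_dna, genomic_rna, strand)
            out.append(
                EditCandidate(
                    chrom=record.chrom, pos=record.pos, strand=strand,
                    tissue=tissue, dna_base=dna_b, rna_base=rna_b,
                    mismatch_type=mtype, dna_depth=record.samples[0].dp,
                    rna_depth=call.dp, rna_edited=edited, sp=call.sp,
                    mq=record.mq,
                )
            )
    return out


def detect_with_stats(
    plus_vcf: Iterable[VcfSiteRecord],
    minus_vcf: Iterable[VcfSiteRecord],
    tissue_labels: list[str],
    params: DetectionParams = DetectionParams(),
) -> tuple[list[EditCandidate], Counter]:
    """Run detection over both strand VCF streams; also return exclusion counts.

    Exclusion counters are keyed ``het`` (criterion 1), ``insufficient_depth``
    (criterion 2), ``indel`` (criterion 3), ``low_edited`` (criterion 4),
    ``strand_bias`` (criterion 5), plus ``multiallelic``, ``missing_tags``
    and ``no_snv_mismatch``.  Site-level keys count records; tissue-level
    keys (4, 5, missing_tags) count (site, tissue) pairs.
    """
    stats: Counter = Counter()
    candidates = _detect_stream(plus_vcf, "+", tissue_labels, params, stats)
    candidates += _detect_stream(minus_vcf, "-", tissue_labels, params, stats)
    candidates.sort(key=EditCandidate.sort_key)
    return candidates, stats


def detect_candidates(
    plus_vcf: Iterable[VcfSiteRecord],
    minus_vcf: Iterable[VcfSiteRecord],
    tissue_labels: list[str],
    params: DetectionParams = DetectionParams(),
) -> list[EditCandidate]:
    """As :func:`detect_with_stats`, returning the candidate list only."""
    return detect_with_stats(plus_vcf, minus_vcf, tissue_labels, params)[0]


# ---------------------------------------------------------------------------
# Candidate table I/O (tab-separated, schema-versioned)
# ---------------------------------------------------------------------------

def write_candidates(path, candidates: list[EditCandidate]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(TABLE_SCHEMA_LINE + " candidates\n")
        fh.write("\t".join(CANDIDATE_TABLE_COLUMNS) + "\n")
        for c in candidates:
            mq = "." if c.mq is None else f"{c.mq:g}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.tissue}\t{c.dna_base}\t"
                f"{c.rna_base}\t{c.mismatch_type}\t{c.dna_depth}\t{c.rna_depth}\t"
                f"{c.rna_edited}\t{c.sp}\t{mq}\n"
            )


def read_candidates(path) -> list[EditCandidate]:
    with open(path, "r", encoding="utf-8") as fh:
        schema = fh.readline().rstrip("\n")
        if not schema.startswith(TABLE_SCHEMA_LINE):
            raise ValueError(
                f"not an editscan table (expected {TABLE_SCHEMA_LINE!r} header, "
                f"got {schema[:40]!r})"
            )
        header = fh.readline().rstrip("\n").split("\t")
        if header != CANDIDATE_TABLE_COLUMNS:
            raise ValueError("candidate table schema mismatch")
        out = []
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                EditCandidate(
                    chrom=f[0], pos=int(f[1]), strand=f[2], tissue=f[3],
                    dna_base=f[4], rna_base=f[5], mismatch_type=f[6],
                    dna_depth=int(f[7]), rna_depth=int(f[8]),
                    rna_edited=int(f[9]), sp=int(f[10]),
                    mq=None if f[11] == "." else float(f[11]),
                )
            )
    return out
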