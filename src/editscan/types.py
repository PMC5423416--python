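"""Core domain types for DNA-vs-RNA mismatch detection.

The pipeline consumes multi-sample pileup VCFs (one genomic-DNA sample
followed by one cDNA sample per tissue), RepeatMasker ``.out`` annotation
and Variant Effect Predictor tabular output, and emits strand-resolved
editing candidates with repeat and consequence annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 12 ordered DNA->RNA substitution types, transcript-strand space.
MISMATCH_TYPES = tuple(
    f"{a}-to-{b}" for a in "ACGT" for b in "ACGT" if a != b
)

#: Genic location vocabulary used for consequence categorisation.
LOCATION_CATEGORIES = (
    "missense",
    "stop_or_start_altering",
    "synonymous",
    "three_prime_utr",
    "five_prime_utr",
    "intron",
    "non_coding_transcript",
    "upstream",
    "downstream",
    "intergenic",
    "other",
)


def complement_base(base: str) -> str:
    try:
        return COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"non-canonical base {base!r}") from None


_CHROM_NUM = re.compile(r"^(?:chr)?(\d+)$")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering: numeric contigs first in numeric order, then lexicographic."""
    m = _CHROM_NUM.match(chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class SampleCall:
    """Per-sample FORMAT values at one site.

    dp: total read depth; dv: high-quality non-reference read count
    (aggregate over alternate alleles, bcftools mpileup convention);
    sp: phred-scaled strand-bias P-value.  ``None`` marks a missing tag.
    """

    dp: Optional[int]
    dv: Optional[int]
    sp: Optional[int]


@dataclass
class VcfSiteRecord:
    """One parsed VCF data line, retaining raw columns for exact re-emission."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    is_indel: bool
    mq: Optional[float]
    samples: list[SampleCall]
    # raw columns preserved so the paired writer can round-trip byte-identically
    id_: str = "."
    qual: str = "."
    filter_: str = "."
    info: str = "."
    format_: str = ""
    sample_strings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RepeatInterval:
    """One RepeatMasker annotation row; 1-based, both ends inclusive."""

    chrom: str
    begin: int
    end: int
    strand: str
    repeat_name: str
    repeat_class_family: str

    def __post_init__(self):
        if self.begin > self.end:
            raise ValueError(f"interval begin {self.begin} > end {self.end}")

    @property
    def family(self) -> str:
        """Major class, e.g. 'SINE' from 'SINE/tRNA'."""
        return self.repeat_class_family.split("/", 1)[0]

    def contains(self, pos: int) -> bool:
        return self.begin <= pos <= self.end


@dataclass(frozen=True)
class VepRecord:
    """One Variant Effect Predictor default-output row."""

    uploaded_variation: str
    location: str
    allele: str
    gene: Optional[str]
    feature: Optional[str]
    consequence: str
    protein_position: Optional[int]
    amino_acids: Optional[str]
    sift: Optional[str]
    extra: str = "-"

    @property
    def chrom(self) -> str:
        return self.location.split(":", 1)[0]

    @property
    def pos(self) -> int:
        return int(self.location.split(":", 1)[1].split("-", 1)[0])

    @property
    def consequence_terms(self) -> tuple[str, ...]:
        return tuple(t.strip() for t in self.consequence.split(",") if t.strip())


@dataclass
class SamRecordView:
    """Text-level view of a SAM alignment line: mandatory columns plus tag triples."""

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    fields: list[str]          # all 11 mandatory columns, verbatim
    tags: list[tuple[str, str, str]]  # (TAG, TYPE, VALUE)

    def tag(self, name: str) -> Optional[tuple[str, str]]:
        for t, ty, v in self.tags:
            if t == name:
                return ty, v
        return None

    def to_line(self) -> str:
        return "\t".join(self.fields + [f"{t}:{ty}:{v}" for t, ty, v in self.tags])


@dataclass(frozen=True)
class DetectionParams:
    """The five filter thresholds of the candidate-site definition.

    min_dna_depth: minimum genomic-DNA reads to call the genotype (criterion 2).
    homozygosity_fraction: fraction of DNA reads that must agree for a
        homozygous call, boundary inclusive (criterion 1).
    min_edited_reads: minimum cDNA reads differing from the genotype call
        (criterion 4); also the k of the mapping-error binomial tail.
    max_strand_bias_phred: maximum phred-scaled strand-bias P-value of the
        supporting cDNA sample (criterion 5).
    Indels are always excluded (criterion 3).
    """

    min_dna_depth: int = 10
    homozygosity_fraction: float = 0.95
    min_edited_reads: int = 5
    max_strand_bias_phred: int = 20

    def __post_init__(self):
        if not (0.5 < self.homozygosity_fraction <= 1):
            raise ValueError("homozygosity_fraction must be in (0.5, 1]")
        if self.min_dna_depth < 1 or self.min_edited_reads < 1:
            raise ValueError("count thresholds must be >= 1")
        if self.max_strand_bias_phred < 0:
            raise ValueError("max_strand_bias_phred must be >= 0")


class GenotypeStatus(str, Enum):
    HOM_REF = "hom_ref"
    HOM_ALT = "hom_alt"
    HET = "het"
    INSUFFICIENT_DEPTH = "insufficient_depth"
    INDEL_EXCLUDED = "indel_excluded"
    MULTIALLELIC_EXCLUDED = "multiallelic_excluded"


@dataclass(frozen=True)
class GenotypeCall:
    status: GenotypeStatus
    dna_allele: Optional[str] = None

    def __post_init__(self):
        homo = self.status in (GenotypeStatus.HOM_REF, GenotypeStatus.HOM_ALT)
        if homo != (self.dna_allele is not None):
            raise ValueError("dna_allele present iff genotype is homozygous")


@dataclass(frozen=True)
class EditCandidate:
    """One accepted DNA->RNA mismatch in one tissue.

    Bases are reported in transcript-strand space: a genomic T->C change on
    a minus-strand transcript is an A-to-G candidate.  ``pos`` stays genomic.
    """

    chrom: str
    pos: int
    strand: str
    tissue: str
    dna_base: str
    rna_base: str
    mismatch_type: str
    dna_depth: int
    rna_depth: int
    rna_edited: int
    sp: int
    mq: Optional[float]

    @property
    def genomic_dna_base(self) -> str:
        return self.dna_base if self.strand == "+" else complement_base(self.dna_base)

    @property
    def genomic_rna_base(self) -> str:
        return self.rna_base if self.strand == "+" else complement_base(self.rna_base)

    def site_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos, self.strand, self.tissue)


@dataclass(frozen=True)
class AnnotatedCandidate:
    """An EditCandidate joined with repeat and consequence annotation."""

    candidate: EditCandidate
    repeat: Optional[RepeatInterval] = None
    vep: Optional[VepRecord] = None
    location_category: str = "other"

    def __getattr__(self, name):
        # delegate plain candidate fields so annotated candidates read like candidates
        return getattr(self.candidate, name)

    def with_vep(self, vep: Optional[VepRecord], category: str) -> "AnnotatedCandidate":
        return replace(self, vep=vep, location_category=category)
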