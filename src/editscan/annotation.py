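"""Merge candidates with RepeatMasker intervals and VEP consequences.

Repeat overlap uses per-chromosome binary search over interval starts with
a bounded backward scan, mirroring the classic sorted-interval containment
lookup; when several intervals contain a position the one with the largest
begin (the innermost start) wins.  VEP merging keys on (chrom, pos,
genomic variant allele) and keeps, per candidate, the single transcript
row with the highest-priority consequence.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from typing import Iterable, Optional

import pandas as pd

from .types import (
    AnnotatedCandidate,
    EditCandidate,
    RepeatInterval,
    VepRecord,
    chrom_sort_key,
)

# consequence term -> location category; higher in the list = higher priority
_TERM_CATEGORY: list[tuple[str, str]] = [
    ("missense_variant", "missense"),
    ("stop_gained", "stop_or_start_altering"),
    ("stop_lost", "stop_or_start_altering"),
    ("start_lost", "stop_or_start_altering"),
    ("start_retained_variant", "stop_or_start_altering"),
    ("stop_retained_variant", "synonymous"),
    ("synonymous_variant", "synonymous"),
    ("3_prime_UTR_variant", "three_prime_utr"),
    ("5_prime_UTR_variant", "five_prime_utr"),
    ("intron_variant", "intron"),
    ("non_coding_transcript_exon_variant", "non_coding_transcript"),
    ("non_coding_transcript_variant", "non_coding_transcript"),
    ("nc_transcript_variant", "non_coding_transcript"),
    ("upstream_gene_variant", "upstream"),
    ("downstream_gene_variant", "downstream"),
    ("intergenic_variant", "intergenic"),
]
_TERM_PRIORITY = {term: i for i, (term, _) in enumerate(_TERM_CATEGORY)}
_NO_MATCH = len(_TERM_CATEGORY)


def consequence_priority(record: VepRecord) -> int:
    """Rank of the record's best (lowest-index) recognised consequence term."""
    return min(
        (_TERM_PRIORITY.get(t, _NO_MATCH) for t in record.consequence_terms),
        default=_NO_MATCH,
    )


def categorize(record: Optional[VepRecord]) -> str:
    """Location category implied by a VEP record; 'other' when absent/unknown."""
    if record is None:
        return "other"
    best = consequence_priority(record)
    if best == _NO_MATCH:
        return "other"
    return _TERM_CATEGORY[best][1]


def _check_sorted(intervals: list[RepeatInterval]) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if b.begin < a.begin:
            raise ValueError(
                f"repeat intervals not sorted by begin near "
                f"{a.chrom}:{a.begin}/{b.begin}"
            )


def find_containing(
    intervals: list[RepeatInterval], pos: int, max_len: Optional[int] = None
) -> Optional[RepeatInterval]:
    """Largest-begin interval containing pos, via binary search + backward scan.

    ``intervals`` must be sorted ascending by begin.  The backward scan is
    bounded by the maximum interval length (precomputable by the caller),
    so nested or long-spanning earlier-starting intervals are still found.
    """
    if max_len is None:
        max_len = max((iv.end - iv.begin + 1 for iv in intervals), default=0)
    i = bisect_right(intervals, pos, key=lambda iv: iv.begin)
    # walk left from the last interval starting at or before pos; stop once
    # even the longest interval on this chrom could not reach pos
    j = i - 1
    while j >= 0 and intervals[j].begin > pos - max_len:
        if intervals[j].end >= pos:
            return intervals[j]
        j -= 1
    return None


def overlap_repeats(
    candidates: Iterable[EditCandidate],
    repeats: dict[str, list[RepeatInterval]],
) -> list[AnnotatedCandidate]:
    """Annotate each candidate with the repeat interval containing its position.

    Containment is purely positional (strand is ignored).  Candidates
    outside every interval get ``repeat=None``.  Raises if any per-chrom
    list is unsorted.
    """
    max_lens: dict[str, int] = {}
    for chrom, ivs in repeats.items():
        _check_sorted(ivs)
        max_lens[chrom] = max((iv.end - iv.begin + 1 for iv in ivs), default=0)
    out = []
    for c in candidates:
        cand = c.candidate if isinstance(c, AnnotatedCandidate) else c
        hit = find_containing(
            repeats.get(cand.chrom, []), cand.pos, max_lens.get(cand.chrom)
        )
        out.append(AnnotatedCandidate(candidate=cand, repeat=hit))
    return out


def merge_vep(
    candidates: Iterable[AnnotatedCandidate],
    vep_records: Iterable[VepRecord],
) -> list[AnnotatedCandidate]:
    """Join candidates with VEP rows on (chrom, pos, genomic variant allele).

    VEP emits one row per overlapping transcript; the row kept is the one
    with the highest-priority consequence, ties broken by gene then feature
    identifier.  Unmatched candidates keep ``vep=None`` and category
    'other'.  Candidate count is preserved.
    """
    by_key: dict[tuple[str, int, str], list[VepRecord]] = defaultdict(list)
    for r in vep_records:
        by_key[(r.chrom, r.pos, r.allele)].append(r)
    for rows in by_key.values():
        rows.sort(
            key=lambda r: (consequence_priority(r), r.gene or "", r.feature or "")
        )
    out = []
    for ac in candidates:
        if not isinstance(ac, AnnotatedCandidate):
            ac = AnnotatedCandidate(candidate=ac)
        rows = by_key.get((ac.chrom, ac.pos, ac.genomic_rna_base))
        best = rows[0] if rows else None
        out.append(ac.with_vep(best, categorize(best)))
    return out


def aa_change_table(candidates: Iterable[AnnotatedCandidate]) -> pd.DataFrame:
    """Amino-acid-change table: one row per coding-change site across tissues.

    Rows are (chrom, pos, strand) sites whose category is missense or
    stop/start-altering; the tissues column is the sorted, space-joined set
    of tissues carrying the candidate.  Ordered by (chrom, pos).
    """
    sites: dict[tuple[str, int, str], dict] = {}
    for ac in candidates:
        if ac.location_category not in ("missense", "stop_or_start_altering"):
            continue
        key = (ac.chrom, ac.pos, ac.strand)
        entry = sites.setdefault(
            key,
            {
                "position": f"{ac.chrom}:{ac.pos}",
                "gene": (ac.vep.gene if ac.vep else None) or "-",
                "amino_acids": (ac.vep.amino_acids if ac.vep else None) or "-",
                "sift": (ac.vep.sift if ac.vep else None) or "-",
                "tissues": set(),
            },
        )
        entry["tissues"].add(ac.tissue)
    rows = [
        {
            "position": e["position"],
            "gene": e["gene"],
            "amino_acids": e["amino_acids"],
            "sift": e["sift"],
            "tissues": " ".join(sorted(e["tissues"])),
        }
        for key, e in sorted(
            sites.items(), key=lambda kv: (chrom_sort_key(kv[0][0]), kv[0][1])
        )
    ]
    return pd.DataFrame(
        rows, columns=["position", "gene", "amino_acids", "sift", "tissues"]
    )


# ---------------------------------------------------------------------------
# Annotated table I/O (tab-separated, schema-versioned)
# ---------------------------------------------------------------------------

ANNOTATION_EXTRA_COLUMNS = [
    "repeat_name", "repeat_class_family", "gene", "consequence", "category",
    "amino_acids", "sift",
]


def write_annotated(path, annotated: list[AnnotatedCandidate]) -> None:
    from .detection import CANDIDATE_TABLE_COLUMNS, TABLE_SCHEMA_LINE

    def opt(x) -> str:
        return "." if x in (None, "") else str(x)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(TABLE_SCHEMA_LINE + " annotated\n")
        fh.write("\t".join(CANDIDATE_TABLE_COLUMNS + ANNOTATION_EXTRA_COLUMNS) + "\n")
        for a in annotated:
            c = a.candidate
            mq = "." if c.mq is None else f"{c.mq:g}"
            rep = a.repeat
            vep = a.vep
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.tissue}\t{c.dna_base}\t"
                f"{c.rna_base}\t{c.mismatch_type}\t{c.dna_depth}\t{c.rna_depth}\t"
                f"{c.rna_edited}\t{c.sp}\t{mq}\t"
                f"{opt(rep.repeat_name if rep else None)}\t"
                f"{opt(rep.repeat_class_family if rep else None)}\t"
                f"{opt(vep.gene if vep else None)}\t"
                f"{opt(vep.consequence if vep else None)}\t"
                f"{a.location_category}\t"
                f"{opt(vep.amino_acids if vep else None)}\t"
                f"{opt(vep.sift if vep else None)}\n"
            )


def read_annotated(path) -> list[AnnotatedCandidate]:
    """Read an annotated table back for summarisation.

    Repeat intervals and VEP records are reconstructed minimally (the
    columns the summaries use); interval bounds collapse to the candidate
    position.
    """
    from .detection import CANDIDATE_TABLE_COLUMNS, TABLE_SCHEMA_LINE

    with open(path, "r", encoding="utf-8") as fh:
        schema = fh.readline().rstrip("\n")
        if not schema.startswith(TABLE_SCHEMA_LINE):
            raise ValueError(f"not an editscan table: {schema[:40]!r}")
        header = fh.readline().rstrip("\n").split("\t")
        if header != CANDIDATE_TABLE_COLUMNS + ANNOTATION_EXTRA_COLUMNS:
            raise ValueError("annotated table schema mismatch")
        out = []
        for line in fh:
            f = line.rstrip("\n").split("\t")

            def opt(x: str):
                return None if x == "." else x

            cand = EditCandidate(
                chrom=f[0], pos=int(f[1]), strand=f[2], tissue=f[3],
                dna_base=f[4], rna_base=f[5], mismatch_type=f[6],
                dna_depth=int(f[7]), rna_depth=int(f[8]), rna_edited=int(f[9]),
                sp=int(f[10]), mq=None if f[11] == "." else float(f[11]),
            )
            repeat = None
            if opt(f[12]) is not None:
                repeat = RepeatInterval(
                    chrom=cand.chrom, begin=cand.pos, end=cand.pos,
                    strand="+", repeat_name=f[12], repeat_class_family=f[13],
                )
            vep = None
            if opt(f[15]) is not None:
                vep = VepRecord(
                    uploaded_variation=".",
                    location=f"{cand.chrom}:{cand.pos}",
                    allele=cand.genomic_rna_base, gene=opt(f[14]),
                    feature=None, consequence=f[15], protein_position=None,
                    amino_acids=opt(f[17]), sift=opt(f[18]),
                )
            out.append(
                AnnotatedCandidate(
                    candidate=cand, repeat=repeat, vep=vep,
                    location_category=f[16],
                )
            )
    return out
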