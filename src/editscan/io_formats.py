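"""Readers and writers for the pipeline's external text formats.

Four formats are touched: the samtools/bcftools mpileup VCF dialect (per
sample FORMAT tags DP, DV, SP and site INFO MQ / INDEL), RepeatMasker
``.out`` annotation, Variant Effect Predictor default input and tabular
output, and SAM text records for alignment-tag filtering.  All readers
accept gzip-compressed input transparently (detected by magic bytes, not
file name).  Readers keep the raw columns they parsed so the paired
writers can re-emit files byte-identically.
"""

from __future__ import annotations

import gzip
import io
import re
from typing import IO, Iterable, Iterator, Optional, Union

from .types import (
    EditCandidate,
    RepeatInterval,
    SamRecordView,
    SampleCall,
    VcfSiteRecord,
    VepRecord,
    chrom_sort_key,
)


class ParseError(ValueError):
    """Malformed input; the message names the offending line number."""


def _open_text(path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


# ---------------------------------------------------------------------------
# VCF (mpileup dialect)
# ---------------------------------------------------------------------------

def _parse_int(token: str) -> Optional[int]:
    if token in (".", ""):
        return None
    return int(token)


class VcfReader:
    """Streaming reader for an mpileup-dialect VCF.

    Iterating yields :class:`VcfSiteRecord` in file order; ``samples`` holds
    the header sample names (first is the genomic-DNA sample), and
    ``header_lines`` the verbatim header for round-trip re-emission.
    """

    def __init__(self, path):
        self.path = path
        self._fh = _open_text(path)
        self.header_lines: list[str] = []
        self.samples: list[str] = []
        self._lineno = 0
        for line in self._fh:
            self._lineno += 1
            line = line.rstrip("\n")
            self.header_lines.append(line)
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10 or cols[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                    "INFO", "FORMAT",
                ]:
                    raise ParseError(
                        f"line {self._lineno}: malformed #CHROM header"
                    )
                self.samples = cols[9:]
                break
            if not line.startswith("##"):
                raise ParseError(
                    f"line {self._lineno}: expected header line, got {line[:40]!r}"
                )
        else:
            raise ParseError("missing #CHROM header line")

    def __iter__(self) -> Iterator[VcfSiteRecord]:
        for line in self._fh:
            self._lineno += 1
            line = line.rstrip("\n")
            if not line:
                continue
            yield self._parse_line(line, self._lineno)
        self._fh.close()

    def _parse_line(self, line: str, lineno: int) -> VcfSiteRecord:
        cols = line.split("\t")
        if len(cols) != 9 + len(self.samples):
            raise ParseError(
                f"line {lineno}: expected {9 + len(self.samples)} columns, "
                f"got {len(cols)}"
            )
        chrom, pos_s, id_, ref, alt_s, qual, filt, info, format_ = cols[:9]
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer POS {pos_s!r}") from None
        if pos < 1 or not ref:
            raise ParseError(f"line {lineno}: invalid POS/REF")
        alts = [] if alt_s == "." else alt_s.split(",")

        info_fields = info.split(";")
        is_indel = "INDEL" in info_fields
        if len(ref) != 1 or any(len(a) != 1 for a in alts if a != "."):
            is_indel = True
        mq: Optional[float] = None
        for f in info_fields:
            if f.startswith("MQ="):
                try:
                    mq = float(f[3:])
                except ValueError:
                    raise ParseError(f"line {lineno}: bad MQ {f!r}") from None

        fmt_keys = format_.split(":")
        idx = {k: i for i, k in enumerate(fmt_keys)}
        calls = []
        for s in cols[9:]:
            parts = s.split(":")

            def get(key: str) -> Optional[int]:
                i = idx.get(key)
                if i is None or i >= len(parts):
                    return None
                try:
                    return _parse_int(parts[i])
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-integer {key} value {parts[i]!r}"
                    ) from None

            calls.append(SampleCall(dp=get("DP"), dv=get("DV"), sp=get("SP")))

        return VcfSiteRecord(
            chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=alts,
            is_indel=is_indel, mq=mq, samples=calls,
            id_=id_, qual=qual, filter_=filt, info=info,
            format_=format_, sample_strings=cols[9:],
        )


def read_vcf(path) -> Iterator[VcfSiteRecord]:
    """Stream VcfSiteRecord from a (possibly gzipped) VCF file."""
    return iter(VcfReader(path))


def vcf_sample_names(path) -> list[str]:
    return VcfReader(path).samples


def format_vcf_record(rec: VcfSiteRecord) -> str:
    alt = ",".join(rec.alt_alleles) if rec.alt_alleles else "."
    return "\t".join(
        [rec.chrom, str(rec.pos), rec.id_, rec.ref_allele, alt, rec.qual,
         rec.filter_, rec.info, rec.format_] + rec.sample_strings
    )


def write_vcf(path, header_lines: Iterable[str], records: Iterable[VcfSiteRecord]) -> None:
    """Paired writer: re-emits header and data lines verbatim from raw columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        for rec in records:
            fh.write(format_vcf_record(rec) + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER_LINES = 3


def read_repeatmasker(path) -> dict[str, list[RepeatInterval]]:
    """Parse a RepeatMasker ``.out`` file into per-chrom lists sorted by begin.

    Layout: three header lines, then whitespace-delimited columns
    (score, div, del, ins, query, begin, end, left, strand, name,
    class/family, ...).  A 'C' strand is normalised to '-'.
    """
    out: dict[str, list[RepeatInterval]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= _RM_HEADER_LINES or not line.strip():
                continue
            cols = line.split()
            if len(cols) < 11:
                raise ParseError(f"line {lineno}: expected >= 11 columns")
            chrom = cols[4]
            try:
                begin, end = int(cols[5]), int(cols[6])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-numeric begin/end {cols[5]!r}/{cols[6]!r}"
                ) from None
            strand = "-" if cols[8] == "C" else cols[8]
            out.setdefault(chrom, []).append(
                RepeatInterval(
                    chrom=chrom, begin=begin, end=end, strand=strand,
                    repeat_name=cols[9], repeat_class_family=cols[10],
                )
            )
    for ivs in out.values():
        ivs.sort(key=lambda iv: (iv.begin, iv.end))
    return out


def write_repeatmasker(path, intervals: Iterable[RepeatInterval]) -> None:
    """Emit intervals in RepeatMasker ``.out`` layout (synthetic score columns)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query        matching"
            "  repeat           position in repeat\n"
            "score  div. del. ins.  sequence  begin  end      (left)   repeat"
            "  class/family   begin  end    (left)  ID\n\n"
        )
        for iv in intervals:
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f"  225  10.0  0.0  0.0  {iv.chrom}  {iv.begin}  {iv.end}  (0)  "
                f"{strand}  {iv.repeat_name}  {iv.repeat_class_family}  1  "
                f"{iv.end - iv.begin + 1}  (0)  1\n"
            )


# ---------------------------------------------------------------------------
# Variant Effect Predictor default input / output
# ---------------------------------------------------------------------------

def write_vep_input(candidates: list[EditCandidate], path) -> None:
    """Write VEP default (whitespace-delimited, 1-based) input lines.

    One line per candidate: chrom, start, end (start = end = pos for SNVs),
    "ref/alt" in genomic-strand bases, and the transcript strand.  Output is
    deterministically ordered by (chrom, pos, strand).
    """
    ordered = sorted(
        candidates, key=lambda c: (chrom_sort_key(c.chrom), c.pos, c.strand)
    )
    with open(path, "w", encoding="utf-8") as fh:
        for c in ordered:
            fh.write(
                f"{c.chrom} {c.pos} {c.pos} "
                f"{c.genomic_dna_base}/{c.genomic_rna_base} {c.strand}\n"
            )


_VEP_COLUMNS = [
    "#Uploaded_variation", "Location", "Allele", "Gene", "Feature",
    "Feature_type", "Consequence", "cDNA_position", "CDS_position",
    "Protein_position", "Amino_acids", "Codons", "Existing_variation", "Extra",
]

_SIFT_RE = re.compile(r"SIFT=([A-Za-z_]+)\(([0-9.]+)\)")


def _sift_from_extra(extra: str) -> Optional[str]:
    m = _SIFT_RE.search(extra)
    if not m:
        return None
    return f"{m.group(1).replace('_', ' ')} ({m.group(2)})"


def read_vep_output(path) -> list[VepRecord]:
    """Parse VEP default tab-separated output; '-' fields are flagged missing."""
    records: list[VepRecord] = []
    header: Optional[list[str]] = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#"):
                header = line.split("\t")
                missing = [c for c in _VEP_COLUMNS[:7] if c not in header]
                if missing:
                    raise ParseError(
                        f"line {lineno}: missing mandatory columns {missing}"
                    )
                continue
            if header is None:
                raise ParseError(f"line {lineno}: data before #Uploaded_variation header")
            cols = line.split("\t")
            if len(cols) != len(header):
                raise ParseError(
                    f"line {lineno}: expected {len(header)} columns, got {len(cols)}"
                )
            row = dict(zip(header, cols))

            def opt(key: str) -> Optional[str]:
                v = row.get(key, "-")
                return None if v == "-" else v

            protein_position = opt("Protein_position")
            extra = row.get("Extra", "-")
            rec = VepRecord(
                uploaded_variation=row["#Uploaded_variation"],
                location=row["Location"],
                allele=row["Allele"],
                gene=opt("Gene"),
                feature=opt("Feature"),
                consequence=row["Consequence"],
                protein_position=(
                    int(protein_position) if protein_position else None
                ),
                amino_acids=opt("Amino_acids"),
                sift=_sift_from_extra(extra),
                extra=extra,
            )
            rec.pos  # validates the location string
            records.append(rec)
    return records


def write_vep_output(path, records: Iterable[VepRecord]) -> None:
    """Emit VEP default tab-separated output (paired with :func:`read_vep_output`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("## ENSEMBL VARIANT EFFECT PREDICTOR\n")
        fh.write("\t".join(_VEP_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join([
                    r.uploaded_variation, r.location, r.allele,
                    r.gene or "-", r.feature or "-", "Transcript",
                    r.consequence, "-", "-",
                    "-" if r.protein_position is None else str(r.protein_position),
                    r.amino_acids or "-", "-", "-", r.extra,
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# SAM text records: alignment tag filters
# ---------------------------------------------------------------------------

def parse_sam_record(line: str) -> SamRecordView:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 11:
        raise ParseError("SAM record has fewer than 11 mandatory columns")
    tags = []
    for t in cols[11:]:
        tag, typ, value = t.split(":", 2)
        tags.append((tag, typ, value))
    return SamRecordView(
        qname=cols[0], flag=int(cols[1]), rname=cols[2], pos=int(cols[3]),
        mapq=int(cols[4]), fields=cols[:11], tags=tags,
    )


SAM_FILTER_MODES = ("dna_unique", "cdna_unique_plus", "cdna_unique_minus")


def _keep_sam(rec: SamRecordView, mode: str) -> bool:
    if mode == "dna_unique":
        # multi-mapping DNA reads carry XS:i:<N> (alternative alignment count)
        return not any(t == "XS" and ty == "i" for t, ty, _ in rec.tags)
    nh = rec.tag("NH")
    xs = rec.tag("XS")
    unique = nh == ("i", "1")
    if mode == "cdna_unique_plus":
        return unique and xs == ("A", "+")
    if mode == "cdna_unique_minus":
        return unique and xs == ("A", "-")
    raise ValueError(f"unknown SAM filter mode {mode!r}")


def filter_sam_stream(
    records: Iterable[Union[str, SamRecordView]], mode: str
) -> Iterator[Union[str, SamRecordView]]:
    """Apply one of the three alignment-tag predicates to a SAM stream.

    ``dna_unique`` drops records carrying any integer XS tag (multi-mapped
    genomic reads); ``cdna_unique_plus``/``cdna_unique_minus`` keep uniquely
    mapped records (NH:i:1) assigned to the plus/minus transcript strand
    (XS:A:+ / XS:A:-).  Header lines (strings starting with '@') pass
    through untouched; plain strings are parsed on the fly and yielded as
    strings.
    """
    if mode not in SAM_FILTER_MODES:
        raise ValueError(f"unknown SAM filter mode {mode!r}")
    for item in records:
        if isinstance(item, str):
            if item.startswith("@"):
                yield item
                continue
            if _keep_sam(parse_sam_record(item), mode):
                yield item
        else:
            if _keep_sam(item, mode):
                yield item
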