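"""Mapping-error significance model for editing candidates.

Under the null of no RNA editing, apparent "edited" reads at a homozygous
locus arise from mis-mapped reads.  The site's phred-scaled mapping quality
MQ gives a per-read mis-mapping probability p = 10^(-MQ/10); the chance of
seeing at least k edited reads out of the tissue's depth N by mis-mapping
alone is then the binomial tail P(X >= k | N, p).  Sites whose tail
probability clears the Bonferroni-corrected level alpha/m (m = number of
queried cDNA positions) cannot be explained by mapping error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from scipy.stats import binom

from .detection import evaluate_criteria
from .types import DetectionParams, EditCandidate, VcfSiteRecord


def mapping_error_p(mq: float) -> float:
    """Per-read mapping-error probability from phred-scaled quality: 10^(-mq/10)."""
    if mq < 0:
        raise ValueError(f"mapping quality must be non-negative, got {mq}")
    return min(1.0, 10.0 ** (-mq / 10.0))


def binom_tail(n: int, k: int, p: float) -> float:
    """Exact upper-tail P(X >= k) for X ~ Binomial(n, p).

    Evaluated through the survival function (regularised incomplete beta),
    which keeps full relative precision for tiny tails where the printed
    complement form 1 - sum_{j<k} would cancel catastrophically.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 0 or k < 1:
        raise ValueError("need n >= 0 and k >= 1")
    if n < k:
        return 0.0
    return float(binom.sf(k - 1, n, p))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha/m."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


@dataclass(frozen=True)
class ScoredCandidate:
    """A candidate with its mapping-error assessment attached.

    ``scored`` is False when the site carried no MQ, in which case the
    probabilities are None and the candidate is retained unscored.
    """

    candidate: EditCandidate
    p_mapping_error: Optional[float]
    p_tail: Optional[float]
    passes_bonferroni: Optional[bool]
    scored: bool

    def __getattr__(self, name):
        return getattr(self.candidate, name)


def score_candidates(
    candidates: Iterable[EditCandidate],
    alpha: float = 0.05,
    m: int = 1,
    k: Optional[int] = None,
) -> list[ScoredCandidate]:
    """Attach p, the binomial tail and the Bonferroni verdict to each candidate.

    ``k`` defaults to the detection threshold of 5 edited reads so the model
    stays coupled to criterion 4.  The tail uses the candidate's cDNA depth
    as N and the site MQ carried from the VCF.
    """
    if k is None:
        k = DetectionParams().min_edited_reads
    threshold = bonferroni_threshold(alpha, m)
    out = []
    for c in candidates:
        if c.mq is None:
            out.append(ScoredCandidate(c, None, None, None, scored=False))
            continue
        p = mapping_error_p(c.mq)
        tail = binom_tail(c.rna_depth, k, p)
        out.append(ScoredCandidate(c, p, tail, tail <= threshold, scored=True))
    return out


def count_tests(
    records: Iterable[VcfSiteRecord],
    min_cdna_depth: int = 5,
    params: DetectionParams = DetectionParams(),
) -> int:
    """Count queried cDNA positions for the Bonferroni denominator m.

    A (site, tissue) pair is queried when the genomic genotype is homozygous
    (criteria 1-3 under ``params``) and the tissue's cDNA depth is at least
    ``min_cdna_depth``.  Feed records from both strand VCFs to count the
    whole transcriptome scan.
    """
    m = 0
    for record in records:
        n_tissues = len(record.samples) - 1
        for i in range(n_tissues):
            crit = evaluate_criteria(record, i, params)
            if crit is None or not (crit[1] and crit[2] and crit[3]):
                continue
            dp = record.samples[1 + i].dp
            if dp is not None and dp >= min_cdna_depth:
                m += 1
    return m


# ---------------------------------------------------------------------------
# Scored table I/O
# ---------------------------------------------------------------------------

SCORED_EXTRA_COLUMNS = ["p_mapping_error", "p_tail", "passes_bonferroni"]


def write_scored(path, scored: list[ScoredCandidate]) -> None:
    from .detection import CANDIDATE_TABLE_COLUMNS, TABLE_SCHEMA_LINE

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(TABLE_SCHEMA_LINE + " scored\n")
        fh.write("\t".join(CANDIDATE_TABLE_COLUMNS + SCORED_EXTRA_COLUMNS) + "\n")
        for s in scored:
            c = s.candidate
            mq = "." if c.mq is None else f"{c.mq:g}"
            p = "." if s.p_mapping_error is None else f"{s.p_mapping_error:.6e}"
            tail = "." if s.p_tail is None else f"{s.p_tail:.6e}"
            verdict = "." if s.passes_bonferroni is None else (
                "1" if s.passes_bonferroni else "0"
            )
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.tissue}\t{c.dna_base}\t"
                f"{c.rna_base}\t{c.mismatch_type}\t{c.dna_depth}\t{c.rna_depth}\t"
                f"{c.rna_edited}\t{c.sp}\t{mq}\t{p}\t{tail}\t{verdict}\n"
            )
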