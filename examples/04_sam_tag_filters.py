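"""Alignment-tag filtering that precedes variant calling.

Genomic DNA alignments are kept only if uniquely mapped (no integer XS
tag, which counts alternative alignments); cDNA alignments are kept if
uniquely mapped (NH:i:1) and are split by transcript strand using the
spliced-aligner XS:A:+ / XS:A:- strand tag.
"""

from editscan import filter_sam_stream

SAM = [
    "@HD\tVN:1.6",
    "read1\t0\t1\t100\t42\t50M\t*\t0\t0\tACGTA\tFFFFF\tAS:i:0",
    "read2\t0\t1\t200\t30\t50M\t*\t0\t0\tACGTA\tFFFFF\tAS:i:0\tXS:i:37",
    "read3\t0\t1\t300\t50\t50M\t*\t0\t0\tACGTA\tFFFFF\tNH:i:1\tXS:A:+",
    "read4\t0\t1\t400\t50\t50M\t*\t0\t0\tACGTA\tFFFFF\tNH:i:2\tXS:A:+",
    "read5\t16\t1\t500\t50\t50M\t*\t0\t0\tACGTA\tFFFFF\tNH:i:1\tXS:A:-",
]

for mode in ("dna_unique", "cdna_unique_plus", "cdna_unique_minus"):
    kept = [
        line.split("\t")[0]
        for line in filter_sam_stream(SAM, mode)
        if not line.startswith("@")
    ]
    print(f"{mode:18s} keeps: {kept}")
# read2 is dropped from the DNA stream (XS:i marks a multi-mapper); read3 and
# read5 are the uniquely mapped plus/minus-strand cDNA reads; read4 (NH:i:2)
# is never unique.
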