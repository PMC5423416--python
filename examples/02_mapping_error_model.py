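"""Assess whether apparent edits could be explained by mapping error.

Under the no-editing null, "edited" reads arise from mis-mapping with
per-read probability p = 10^(-MQ/10).  The binomial tail
P(X >= 5 | N, p) says how surprising 5 edited reads out of depth N are;
Bonferroni correction over the number of queried cDNA positions gives the
transcriptome-wide significance threshold.
"""

from editscan import binom_tail, bonferroni_threshold, mapping_error_p

mq, depth, k = 29, 13, 5
p = mapping_error_p(mq)
tail = binom_tail(depth, k, p)
threshold = bonferroni_threshold(alpha=0.05, m=189_638)

print(f"site MQ {mq}  ->  per-read mis-mapping probability p = {p:.4e}")
print(f"P(>= {k} edited reads | N={depth}, p) = {tail:.4e}")
print(f"Bonferroni threshold 0.05 / 189,638  = {threshold:.4e}")
print("significant (cannot be mapping error)?", tail <= threshold)
# A tail probability of ~4e-12 is far below the ~2.6e-7 threshold: even at
# this mediocre mapping quality, mis-mapping cannot plausibly produce five
# concordant edited reads, so the candidate stands.
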