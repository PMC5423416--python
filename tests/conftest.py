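import os

import pytest

from editscan.detection import detect_with_stats
from editscan.io_formats import VcfReader
from editscan.synthetic import SimulationConfig, generate_fixture
from editscan.types import SampleCall, VcfSiteRecord


def make_record(
    ref="A",
    alts=("G",),
    dna=(30, 0),
    tissues=((40, 10, 3),),
    indel=False,
    mq=40.0,
    chrom="1",
    pos=1000,
):
    """Build a minimal in-memory VCF record for detection tests."""
    samples = [SampleCall(dp=dna[0], dv=dna[1], sp=0)]
    samples += [SampleCall(dp=dp, dv=dv, sp=sp) for dp, dv, sp in tissues]
    return VcfSiteRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=list(alts),
        is_indel=indel, mq=mq, samples=samples,
    )


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """Seed-1 default fixture plus its detection output, shared across tests."""
    outdir = tmp_path_factory.mktemp("fixture")
    cfg = SimulationConfig(seed=1)
    truth = generate_fixture(cfg, outdir)
    plus = VcfReader(os.path.join(outdir, "plus.vcf"))
    minus = VcfReader(os.path.join(outdir, "minus.vcf"))
    candidates, stats = detect_with_stats(
        iter(plus), iter(minus), plus.samples[1:]
    )
    return {
        "dir": outdir,
        "config": cfg,
        "truth": truth,
        "candidates": candidates,
        "stats": stats,
        "tissues": plus.samples[1:],
    }
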