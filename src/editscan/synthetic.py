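"""Self-contained fixture generation with planted truth.

Generates the paired strand-split VCFs the detector consumes, together
with a matching RepeatMasker ``.out`` file, VEP tabular output and a
truth table.  Every planted edit satisfies all five detection criteria by
construction; every planted confounder fails exactly one designated
criterion (or is multiallelic, an exclusion outside the five).  All
randomness flows from one seed, and identical seeds give byte-identical
files.

The genome model is allele-level only: named contigs with positions laid
out on a 1 kb lattice so that planted repeat intervals (half-width
<= 300 bp) can never capture a neighbouring site by accident.  No
sequence is needed because detection operates on pileup alleles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import write_repeatmasker, write_vcf, write_vep_output
from .types import (
    EditCandidate,
    RepeatInterval,
    SampleCall,
    VcfSiteRecord,
    VepRecord,
    chrom_sort_key,
)

_CHROMS = tuple(str(i) for i in range(1, 19))

DEFAULT_TISSUES = ("Liver", "Fat", "LD")

#: (repeat_name, class/family, weight); shares are allocated exactly by
#: largest remainder, so the configured mix is reproduced without sampling noise.
DEFAULT_REPEAT_MIX = (
    ("Pre0_SS", "SINE/tRNA", 0.60),
    ("PRE-1a", "SINE/tRNA", 0.12),
    ("PRE-1b", "SINE/tRNA", 0.08),
    ("L1_SS", "LINE/L1", 0.12),
    ("LTR_SS", "LTR/ERVL", 0.05),
    ("tRNA-Glu", "tRNA", 0.03),
)

#: (location category, weight); 'other' sites receive no VEP row at all.
DEFAULT_CATEGORY_MIX = (
    ("intron", 0.46),
    ("three_prime_utr", 0.12),
    ("five_prime_utr", 0.03),
    ("missense", 0.05),
    ("synonymous", 0.03),
    ("non_coding_transcript", 0.05),
    ("upstream", 0.08),
    ("downstream", 0.08),
    ("intergenic", 0.05),
    ("other", 0.05),
)

_CATEGORY_TERM = {
    "intron": "intron_variant",
    "three_prime_utr": "3_prime_UTR_variant",
    "five_prime_utr": "5_prime_UTR_variant",
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
    "non_coding_transcript": "non_coding_transcript_variant",
    "upstream": "upstream_gene_variant",
    "downstream": "downstream_gene_variant",
    "intergenic": "intergenic_variant",
}

_AA_CHANGES = ("K/R", "Q/R", "I/V", "E/G", "Y/C", "S/G", "N/D", "T/A")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic run.

    Defaults emulate a three-tissue scan at the detection thresholds'
    scale: DNA depths straddle the 10-read genotype minimum comfortably,
    cDNA depths allow the 5-edited-read criterion, strand-bias values for
    honest sites sit in [0, 20] and for biased confounders in (20, 60],
    and 60% of planted edits fall inside repeat intervals.
    """

    seed: int = 1
    n_sites: int = 1000
    n_true_edits: int = 200
    tissue_count: int = 3
    dna_depth_range: tuple[int, int] = (10, 60)
    cdna_depth_range: tuple[int, int] = (8, 60)
    edit_fraction_range: tuple[float, float] = (0.1, 0.9)
    confounder_mix: tuple[tuple[str, float], ...] = (
        ("het", 0.06),
        ("low_depth", 0.06),
        ("indel", 0.06),
        ("low_edited", 0.06),
        ("strand_bias", 0.06),
        ("multiallelic", 0.06),
    )
    minus_strand_fraction: float = 0.5
    hom_alt_fraction: float = 0.2
    repeat_density: float = 0.6
    mq_range: tuple[int, int] = (20, 60)
    tissue_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.n_true_edits > self.n_sites:
            raise ValueError("n_true_edits must not exceed n_sites")
        if sum(w for _, w in self.confounder_mix) > 1:
            raise ValueError("confounder_mix proportions must sum to <= 1")
        total = self.n_true_edits + sum(
            int(round(w * self.n_sites)) for _, w in self.confounder_mix
        )
        if total > self.n_sites:
            raise ValueError("truths plus confounders exceed n_sites")

    @property
    def tissues(self) -> tuple[str, ...]:
        if self.tissue_labels is not None:
            return self.tissue_labels
        if self.tissue_count <= len(DEFAULT_TISSUES):
            return DEFAULT_TISSUES[: self.tissue_count]
        return DEFAULT_TISSUES + tuple(
            f"Tissue{i}" for i in range(len(DEFAULT_TISSUES), self.tissue_count)
        )


@dataclass(frozen=True)
class TruthEntry:
    """One planted per-tissue editing candidate."""

    chrom: str
    pos: int
    strand: str
    tissue: str
    mismatch_type: str
    rna_edited: int
    category: str
    repeat_name: Optional[str]

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.strand, self.tissue)


@dataclass(frozen=True)
class PlantedConfounder:
    """One planted failing site and the criterion it is built to violate.

    ``criterion`` is 'criterion1'..'criterion5' or 'multiallelic';
    ``tissue_dv`` records the cDNA edited-read counts used per tissue.
    """

    chrom: str
    pos: int
    strand: str
    criterion: str
    tissue_dv: tuple[int, ...]


@dataclass
class TruthSet:
    entries: list[TruthEntry]
    confounders: list[PlantedConfounder]

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {e.key() for e in self.entries}

    def sites(self) -> set[tuple[str, int, str]]:
        return {(e.chrom, e.pos, e.strand) for e in self.entries}

    def site_category(self) -> dict[tuple[str, int, str], str]:
        return {(e.chrom, e.pos, e.strand): e.category for e in self.entries}

    def confounder_at(self, chrom: str, pos: int) -> Optional[PlantedConfounder]:
        for c in self.confounders:
            if c.chrom == chrom and c.pos == pos:
                return c
        return None


@dataclass
class VerificationReport:
    """Truth-vs-detection comparison; both lists empty on a correct run."""

    missed: list[tuple[str, int, str, str]]
    spurious: list[tuple[tuple[str, int, str, str], str]]

    @property
    def ok(self) -> bool:
        return not self.missed and not self.spurious


def verify_truth(
    truth: TruthSet, detected: list[EditCandidate]
) -> VerificationReport:
    """Compare detection output with the planted truth, per (site, tissue).

    Spurious calls are tagged with the criterion their site was planted to
    fail, or 'unknown' when the site was not a planted confounder.
    """
    truth_keys = truth.keys()
    detected_keys = {(c.chrom, c.pos, c.strand, c.tissue) for c in detected}
    missed = sorted(truth_keys - detected_keys)
    spurious = []
    for key in sorted(detected_keys - truth_keys):
        conf = truth.confounder_at(key[0], key[1])
        spurious.append((key, conf.criterion if conf else "unknown"))
    return VerificationReport(missed=missed, spurious=spurious)


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

@dataclass
class _Site:
    chrom: str
    pos: int
    strand: str
    role: str
    ref: str
    alts: list[str]
    is_indel: bool
    mq: int
    dna: tuple[int, int]            # (dp, dv)
    tissues: list[tuple[int, int, int]]  # (dp, dv, sp) per tissue


def _largest_remainder(weights: list[float], n: int) -> list[int]:
    exact = [w * n for w in weights]
    counts = [int(x) for x in exact]
    rema = sorted(
        range(len(weights)), key=lambda i: (exact[i] - counts[i]), reverse=True
    )
    for i in rema[: n - sum(counts)]:
        counts[i] += 1
    return counts


def _hom_ref_dna(rng, cfg: SimulationConfig) -> tuple[int, int]:
    dp = int(rng.integers(cfg.dna_depth_range[0], cfg.dna_depth_range[1] + 1))
    dv = int(rng.integers(0, int(dp * 0.05) + 1))
    return dp, dv


def _edited_tissue(rng, cfg: SimulationConfig) -> tuple[int, int, int]:
    """cDNA (dp, edited, sp) satisfying criteria 4 and 5."""
    lo = max(cfg.cdna_depth_range[0], 5)
    dp = int(rng.integers(lo, cfg.cdna_depth_range[1] + 1))
    frac = rng.uniform(*cfg.edit_fraction_range)
    edited = min(dp, max(5, int(round(frac * dp))))
    sp = int(rng.integers(0, 21))
    return dp, edited, sp


def _unedited_tissue(rng, cfg: SimulationConfig) -> tuple[int, int, int]:
    """cDNA (dp, edited, sp) failing criterion 4 with margin (edited <= 3)."""
    dp = int(rng.integers(5, cfg.cdna_depth_range[1] + 1))
    edited = int(rng.integers(0, 4))
    sp = int(rng.integers(0, 21))
    return dp, edited, sp


def _random_snv(rng) -> tuple[str, str]:
    bases = "ACGT"
    ref = bases[int(rng.integers(0, 4))]
    alt = ref
    while alt == ref:
        alt = bases[int(rng.integers(0, 4))]
    return ref, alt


def _build_sites(cfg: SimulationConfig, rng) -> tuple[list[_Site], TruthSet]:
    n_tissues = cfg.tissue_count
    conf_counts = {
        name: int(round(w * cfg.n_sites)) for name, w in cfg.confounder_mix
    }
    roles = (
        ["truth"] * cfg.n_true_edits
        + [name for name, k in conf_counts.items() for _ in range(k)]
    )
    roles += ["clean"] * (cfg.n_sites - len(roles))

    # global slot lattice: slot -> (chrom, 1 kb window); sites sit in the
    # first 400 bp of their window, keeping any two sites >= 600 bp apart
    slots = rng.choice(np.arange(1, 2_000_000), size=cfg.n_sites, replace=False)
    offsets = rng.integers(0, 400, size=cfg.n_sites)

    sites: list[_Site] = []
    entries: list[TruthEntry] = []
    confounders: list[PlantedConfounder] = []

    for i, role in enumerate(roles):
        slot = int(slots[i])
        chrom = _CHROMS[slot % len(_CHROMS)]
        pos = (slot // len(_CHROMS) + 1) * 1000 + int(offsets[i])
        mq = int(rng.integers(cfg.mq_range[0], cfg.mq_range[1] + 1))
        strand = "-" if rng.random() < (
            cfg.minus_strand_fraction if role == "truth" else 0.5
        ) else "+"

        if role == "truth":
            # A-to-G on the transcript strand: genomic A->G on '+',
            # genomic T->C on '-'
            genomic_dna = "A" if strand == "+" else "T"
            genomic_rna = "G" if strand == "+" else "C"
            hom_alt = rng.random() < cfg.hom_alt_fraction
            dp = int(rng.integers(cfg.dna_depth_range[0], cfg.dna_depth_range[1] + 1))
            if hom_alt:
                ref, alts = genomic_rna, [genomic_dna]
                dv = dp - int(rng.integers(0, int(dp * 0.05) + 1))
            else:
                ref, alts = genomic_dna, [genomic_rna]
                dv = int(rng.integers(0, int(dp * 0.05) + 1))
            edited_mask = rng.random(n_tissues) < 0.6
            if not edited_mask.any():
                edited_mask[int(rng.integers(0, n_tissues))] = True
            tissues = []
            for t, label in enumerate(cfg.tissues):
                if edited_mask[t]:
                    tdp, edited, sp = _edited_tissue(rng, cfg)
                    entries.append(
                        TruthEntry(
                            chrom=chrom, pos=pos, strand=strand, tissue=label,
                            mismatch_type="A-to-G", rna_edited=edited,
                            category="other", repeat_name=None,
                        )
                    )
                else:
                    tdp, edited, sp = _unedited_tissue(rng, cfg)
                tdv = edited if not hom_alt else tdp - edited
                tissues.append((tdp, tdv, sp))
            sites.append(_Site(chrom, pos, strand, role, ref, alts, False,
                               mq, (dp, dv), tissues))
            continue

        if role == "het":
            ref, alt = _random_snv(rng)
            dp = int(rng.integers(cfg.dna_depth_range[0], cfg.dna_depth_range[1] + 1))
            dv = int(round(dp * rng.uniform(0.3, 0.7)))
            tissues = [
                (tdp, edited, sp)
                for tdp, edited, sp in (_edited_tissue(rng, cfg) for _ in range(n_tissues))
            ]
            site = _Site(chrom, pos, strand, role, ref, [alt], False,
                         mq, (dp, dv), tissues)
            crit = "criterion1"
        elif role == "low_depth":
            ref, alt = _random_snv(rng)
            dp = int(rng.integers(1, 10))
            tissues = [_edited_tissue(rng, cfg) for _ in range(n_tissues)]
            site = _Site(chrom, pos, strand, role, ref, [alt], False,
                         mq, (dp, 0), tissues)
            crit = "criterion2"
        elif role == "indel":
            dp, dv = _hom_ref_dna(rng, cfg)
            tissues = [_edited_tissue(rng, cfg) for _ in range(n_tissues)]
            site = _Site(chrom, pos, strand, role, "A", ["AG"], True,
                         mq, (dp, dv), tissues)
            crit = "criterion3"
        elif role == "low_edited":
            ref, alt = _random_snv(rng)
            dp, dv = _hom_ref_dna(rng, cfg)
            tissues = [
                (tdp, int(rng.integers(1, 5)), sp)
                for tdp, _, sp in (_unedited_tissue(rng, cfg) for _ in range(n_tissues))
            ]
            site = _Site(chrom, pos, strand, role, ref, [alt], False,
                         mq, (dp, dv), tissues)
            crit = "criterion4"
        elif role == "strand_bias":
            ref, alt = _random_snv(rng)
            dp, dv = _hom_ref_dna(rng, cfg)
            tissues = [
                (tdp, edited, int(rng.integers(21, 61)))
                for tdp, edited, _ in (_edited_tissue(rng, cfg) for _ in range(n_tissues))
            ]
            site = _Site(chrom, pos, strand, role, ref, [alt], False,
                         mq, (dp, dv), tissues)
            crit = "criterion5"
        elif role == "multiallelic":
            dp, dv = _hom_ref_dna(rng, cfg)
            tissues = [_edited_tissue(rng, cfg) for _ in range(n_tissues)]
            site = _Site(chrom, pos, strand, role, "A", ["G", "C"], False,
                         mq, (dp, dv), tissues)
            crit = "multiallelic"
        else:  # clean background site
            ref, alt = _random_snv(rng)
            dp, dv = _hom_ref_dna(rng, cfg)
            tissues = [
                (tdp, int(rng.integers(0, 3)), sp)
                for tdp, _, sp in (_unedited_tissue(rng, cfg) for _ in range(n_tissues))
            ]
            sites.append(_Site(chrom, pos, strand, role, ref, [alt], False,
                               mq, (dp, dv), tissues))
            continue

        sites.append(site)
        confounders.append(
            PlantedConfounder(
                chrom=chrom, pos=pos, strand=strand, criterion=crit,
                tissue_dv=tuple(tdv for _, tdv, _ in site.tissues),
            )
        )

    return sites, TruthSet(entries=entries, confounders=confounders)


def _assign_repeats(
    cfg: SimulationConfig, rng, truth: TruthSet
) -> tuple[list[RepeatInterval], dict[tuple[str, int, str], str]]:
    site_list = sorted(truth.sites(), key=lambda s: (chrom_sort_key(s[0]), s[1]))
    n_rep = int(round(cfg.repeat_density * len(site_list)))
    chosen_idx = rng.choice(len(site_list), size=n_rep, replace=False)
    chosen = [site_list[int(i)] for i in sorted(chosen_idx)]

    names = [(n, cf) for n, cf, _ in DEFAULT_REPEAT_MIX]
    counts = _largest_remainder([w for _, _, w in DEFAULT_REPEAT_MIX], n_rep)
    assigned = [names[i] for i, k in enumerate(counts) for _ in range(k)]
    order = rng.permutation(n_rep)

    intervals: list[RepeatInterval] = []
    site_repeat: dict[tuple[str, int, str], str] = {}
    for j, (chrom, pos, strand) in enumerate(chosen):
        name, class_family = assigned[int(order[j])]
        begin = pos - int(rng.integers(0, 300))
        end = pos + int(rng.integers(0, 300))
        intervals.append(
            RepeatInterval(
                chrom=chrom, begin=max(1, begin), end=end,
                strand="+" if rng.random() < 0.5 else "-",
                repeat_name=name, repeat_class_family=class_family,
            )
        )
        site_repeat[(chrom, pos, strand)] = name

    # decoy intervals in the uninhabited 600-800 bp band of random windows
    for _ in range(50):
        slot = int(rng.integers(1, 2_000_000))
        chrom = _CHROMS[slot % len(_CHROMS)]
        center = (slot // len(_CHROMS) + 1) * 1000 + 700
        half = int(rng.integers(10, 100))
        intervals.append(
            RepeatInterval(
                chrom=chrom, begin=max(1, center - half), end=center + half,
                strand="+", repeat_name="L1_SS", repeat_class_family="LINE/L1",
            )
        )
    intervals.sort(key=lambda iv: (chrom_sort_key(iv.chrom), iv.begin, iv.end))
    return intervals, site_repeat


def _assign_categories(
    cfg: SimulationConfig, rng, truth: TruthSet
) -> tuple[list[VepRecord], dict[tuple[str, int, str], str]]:
    site_list = sorted(truth.sites(), key=lambda s: (chrom_sort_key(s[0]), s[1]))
    cats = [c for c, _ in DEFAULT_CATEGORY_MIX]
    probs = np.array([w for _, w in DEFAULT_CATEGORY_MIX])
    draws = rng.choice(len(cats), size=len(site_list), p=probs / probs.sum())

    records: list[VepRecord] = []
    site_cat: dict[tuple[str, int, str], str] = {}
    for i, (chrom, pos, strand) in enumerate(site_list):
        category = cats[int(draws[i])]
        site_cat[(chrom, pos, strand)] = category
        if category == "other":
            continue  # deliberately left un-annotated
        allele = "G" if strand == "+" else "C"
        gene = f"GENE{i:04d}"
        feature = f"TX{i:04d}.1"
        uploaded = f"{chrom}_{pos}"
        if category == "missense":
            aa = _AA_CHANGES[int(rng.integers(0, len(_AA_CHANGES)))]
            sift_txt = (
                f"SIFT=deleterious({int(rng.integers(0, 5)) / 100})"
                if rng.random() < 0.4
                else f"SIFT=tolerated({int(rng.integers(5, 101)) / 100})"
            )
            records.append(
                VepRecord(
                    uploaded_variation=uploaded,
                    location=f"{chrom}:{pos}", allele=allele, gene=gene,
                    feature=feature, consequence="missense_variant",
                    protein_position=int(rng.integers(1, 500)),
                    amino_acids=aa,
                    sift=_sift_norm(sift_txt), extra=sift_txt,
                )
            )
        else:
            records.append(
                VepRecord(
                    uploaded_variation=uploaded,
                    location=f"{chrom}:{pos}", allele=allele, gene=gene,
                    feature=feature, consequence=_CATEGORY_TERM[category],
                    protein_position=None, amino_acids=None,
                    sift=None, extra="-",
                )
            )
        # a second, lower-priority transcript row for ~20% of genic sites
        if category not in ("intergenic",) and rng.random() < 0.2:
            records.append(
                VepRecord(
                    uploaded_variation=uploaded,
                    location=f"{chrom}:{pos}", allele=allele, gene=gene,
                    feature=f"TX{i:04d}.2", consequence="downstream_gene_variant",
                    protein_position=None, amino_acids=None,
                    sift=None, extra="-",
                )
            )
    return records, site_cat


def _sift_norm(extra: str) -> Optional[str]:
    from .io_formats import _sift_from_extra

    return _sift_from_extra(extra)


def _site_to_record(site: _Site) -> VcfSiteRecord:
    info = ("INDEL;" if site.is_indel else "") + f"MQ={site.mq}"
    fmt = "PL:DP:DV:SP"
    dna_dp, dna_dv = site.dna
    strings = [f"0,0,0:{dna_dp}:{dna_dv}:0"]
    calls = [SampleCall(dp=dna_dp, dv=dna_dv, sp=0)]
    for tdp, tdv, sp in site.tissues:
        strings.append(f"0,0,0:{tdp}:{tdv}:{sp}")
        calls.append(SampleCall(dp=tdp, dv=tdv, sp=sp))
    return VcfSiteRecord(
        chrom=site.chrom, pos=site.pos, ref_allele=site.ref,
        alt_alleles=list(site.alts), is_indel=site.is_indel,
        mq=float(site.mq), samples=calls,
        id_=".", qual="228", filter_=".", info=info,
        format_=fmt, sample_strings=strings,
    )


def _vcf_header(samples: list[str]) -> list[str]:
    return [
        "##fileformat=VCFv4.2",
        "##source=editscan-simulate",
        '##INFO=<ID=INDEL,Number=0,Type=Flag,Description="Indicates that the variant is an INDEL.">',
        '##INFO=<ID=MQ,Number=1,Type=Integer,Description="Root-mean-square mapping quality of covering reads">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="List of Phred-scaled genotype likelihoods">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Number of high-quality bases">',
        '##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Number of high-quality non-reference bases">',
        '##FORMAT=<ID=SP,Number=1,Type=Integer,Description="Phred-scaled strand bias P-value">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]


def generate_fixture(config: SimulationConfig, outdir) -> TruthSet:
    """Write plus.vcf, minus.vcf, repeats.out, vep_output.txt and truth tables.

    Returns the :class:`TruthSet`; rerunning with the same config yields
    byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sites, truth = _build_sites(config, rng)
    intervals, site_repeat = _assign_repeats(config, rng, truth)
    vep_records, site_cat = _assign_categories(config, rng, truth)

    # fold repeat and category assignments back into the truth entries
    truth.entries = [
        TruthEntry(
            chrom=e.chrom, pos=e.pos, strand=e.strand, tissue=e.tissue,
            mismatch_type=e.mismatch_type, rna_edited=e.rna_edited,
            category=site_cat[(e.chrom, e.pos, e.strand)],
            repeat_name=site_repeat.get((e.chrom, e.pos, e.strand)),
        )
        for e in truth.entries
    ]

    samples = ["DNA"] + list(config.tissues)
    for strand, fname in (("+", "plus.vcf"), ("-", "minus.vcf")):
        recs = [
            _site_to_record(s)
            for s in sorted(
                (s for s in sites if s.strand == strand),
                key=lambda s: (chrom_sort_key(s.chrom), s.pos),
            )
        ]
        write_vcf(os.path.join(outdir, fname), _vcf_header(samples), recs)

    write_repeatmasker(os.path.join(outdir, "repeats.out"), intervals)
    write_vep_output(os.path.join(outdir, "vep_output.txt"), vep_records)

    with open(os.path.join(outdir, "truth.tsv"), "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tstrand\ttissue\tmismatch_type\trna_edited\t"
                 "category\trepeat_name\n")
        for e in sorted(truth.entries, key=lambda e: (
            chrom_sort_key(e.chrom), e.pos, e.strand, e.tissue
        )):
            fh.write(
                f"{e.chrom}\t{e.pos}\t{e.strand}\t{e.tissue}\t"
                f"{e.mismatch_type}\t{e.rna_edited}\t{e.category}\t"
                f"{e.repeat_name or '.'}\n"
            )
    with open(os.path.join(outdir, "confounders.tsv"), "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tstrand\tcriterion\ttissue_dv\n")
        for c in sorted(truth.confounders, key=lambda c: (
            chrom_sort_key(c.chrom), c.pos
        )):
            dvs = ",".join(str(x) for x in c.tissue_dv)
            fh.write(f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.criterion}\t{dvs}\n")
    return truth


def read_truth(fixture_dir) -> TruthSet:
    """Load a fixture's truth.tsv and confounders.tsv back into a TruthSet."""
    entries: list[TruthEntry] = []
    with open(os.path.join(fixture_dir, "truth.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            entries.append(
                TruthEntry(
                    chrom=f[0], pos=int(f[1]), strand=f[2], tissue=f[3],
                    mismatch_type=f[4], rna_edited=int(f[5]), category=f[6],
                    repeat_name=None if f[7] == "." else f[7],
                )
            )
    confounders: list[PlantedConfounder] = []
    with open(os.path.join(fixture_dir, "confounders.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            confounders.append(
                PlantedConfounder(
                    chrom=f[0], pos=int(f[1]), strand=f[2], criterion=f[3],
                    tissue_dv=tuple(int(x) for x in f[4].split(",")),
                )
            )
    return TruthSet(entries=entries, confounders=confounders)
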