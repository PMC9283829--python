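"""Domain types and standard-format I/O for cfDNA-based fetal genotyping.

Genotypes are represented as tuples of allele indices over the locus's
(ref, alt) pair — ``(0, 0)`` hom-ref, ``(0, 1)`` het, ``(1, 1)`` hom-alt.
Phased genotypes are ordered ``(Hap I allele, Hap II allele)``; unphased
genotypes are stored sorted. Loci fall into four symbolic categories by
parental zygosity:

========  ======================  =====================
category  maternal                paternal
========  ======================  =====================
AAAA      homozygous              homozygous
AAAB      homozygous              heterozygous
ABAA      heterozygous            homozygous
ABAB      heterozygous            heterozygous
========  ======================  =====================

The labels are symbolic, not allele-literal: a homozygous-alt parent plays
the same role as a homozygous-ref one (the shared homozygous allele takes
the "A" role), and opposite-homozygous parents fall in the both-homozygous
class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

SNV = "SNV"
INDEL = "InDel"

CATEGORIES = ("AAAA", "AAAB", "ABAA", "ABAB")

#: method provenance values a FetalCall may carry
METHODS = ("bayes", "sprt", "closest1", "closest2", "unclassified")

Genotype = tuple[int, int]


def variant_class(ref: str, alt: str) -> str:
    """SNV if both alleles are single bases, InDel otherwise."""
    return SNV if len(ref) == 1 and len(alt) == 1 else INDEL


def is_het(gt: Genotype) -> bool:
    return gt[0] != gt[1]


def classify_locus(maternal_gt: Genotype, paternal_gt: Genotype) -> str:
    """Assign the four-way symbolic locus category from parental zygosity.

    Total on biallelic genotype pairs and invariant under a simultaneous
    ref/alt relabelling of both parents (only het/hom status matters).
    """
    m_het = is_het(maternal_gt)
    p_het = is_het(paternal_gt)
    if m_het and p_het:
        return "ABAB"
    if m_het:
        return "ABAA"
    if p_het:
        return "AAAB"
    return "AAAA"


@dataclass(slots=True)
class PlasmaCounts:
    """Per-allele cfDNA read counts at one locus (ref first, alt second)."""

    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    def count(self, allele: int) -> int:
        return self.alt_count if allele == 1 else self.ref_count


@dataclass(slots=True)
class LocusRecord:
    """One biallelic candidate site with parental genotype/phase/block info."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    maternal_gt: Genotype
    paternal_gt: Genotype
    maternal_phase: Optional[Genotype] = None  # (Hap I, Hap II) or None
    paternal_phase: Optional[Genotype] = None
    maternal_block: Optional[str] = None
    paternal_block: Optional[str] = None

    def __post_init__(self) -> None:
        for phase, gt, who in (
            (self.maternal_phase, self.maternal_gt, "maternal"),
            (self.paternal_phase, self.paternal_gt, "paternal"),
        ):
            if phase is not None and tuple(sorted(phase)) != tuple(sorted(gt)):
                raise ValueError(f"{who} phase {phase} is not a permutation of {gt}")

    @property
    def vclass(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def category(self) -> str:
        return classify_locus(self.maternal_gt, self.paternal_gt)

    def allele(self, idx: int) -> str:
        return self.alt if idx == 1 else self.ref


@dataclass(slots=True)
class HaplotypeBlock:
    """Contiguous phased parental segment; unit of SPRT accumulation."""

    parent: str  # "maternal" | "paternal"
    block_id: str
    chrom: str
    loci: list[LocusRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [l.pos for l in self.loci]
        if positions != sorted(positions):
            raise ValueError("block loci must be position-sorted")
        if any(l.chrom != self.chrom for l in self.loci):
            raise ValueError("block loci must share a chromosome")

    @property
    def span_bp(self) -> int:
        if not self.loci:
            return 0
        return self.loci[-1].pos - self.loci[0].pos + 1


@dataclass(slots=True)
class FetalCall:
    """Predicted fetal genotype with method provenance and confidence.

    ``maternal_allele`` / ``paternal_allele`` are filled when the two
    transmissions were resolved separately (haplotype paths); ``genotype``
    is None for unclassified loci.
    """

    locus: LocusRecord
    genotype: Optional[Genotype]
    method: str
    confidence: Optional[float] = None
    maternal_allele: Optional[int] = None
    paternal_allele: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.genotype is not None:
            self.genotype = tuple(sorted(self.genotype))  # type: ignore[assignment]


def group_blocks(records: Iterable[LocusRecord], parent: str) -> list[HaplotypeBlock]:
    """Group phased loci of one parent into HaplotypeBlocks (position-sorted)."""
    attr_block = f"{parent}_block"
    attr_phase = f"{parent}_phase"
    by_key: dict[tuple[str, str], list[LocusRecord]] = {}
    for rec in records:
        block = getattr(rec, attr_block)
        if block is None or getattr(rec, attr_phase) is None:
            continue
        by_key.setdefault((rec.chrom, block), []).append(rec)
    blocks = []
    for (chrom, block_id), loci in by_key.items():
        loci.sort(key=lambda r: r.pos)
        blocks.append(HaplotypeBlock(parent=parent, block_id=block_id, chrom=chrom, loci=loci))
    blocks.sort(key=lambda b: (b.chrom, b.loci[0].pos if b.loci else 0))
    return blocks


# ---------------------------------------------------------------------------
# VCF / TSV plumbing
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class ParentalSite:
    """Genotype/phase/block of one parent at one site, as read from a VCF."""

    gt: Genotype
    phase: Optional[Genotype]
    block: Optional[str]
    ref: str
    alt: str


@dataclass(slots=True)
class VcfFilterConfig:
    """Germline hygiene filters applied while reading parental VCFs.

    min_qual drops low-confidence records; depth bounds (from FORMAT/DP when
    present) drop poorly covered and likely-duplicated sites.
    """

    min_qual: float = 30.0
    min_depth: int = 10
    max_depth: Optional[int] = None  # e.g. 3x mean depth; None disables


def read_parental_vcf(
    path: str,
    parent: str,
    filters: VcfFilterConfig | None = None,
) -> tuple[dict[tuple[str, int], ParentalSite], dict[str, int]]:
    """Read a single-sample (optionally phased) parental VCF.

    Returns a map ``(chrom, pos) -> ParentalSite`` plus exclusion counters.
    Biallelic SNV/InDel records only; multiallelic and filtered records are
    dropped with counted reasons. Phased heterozygotes carry an ordered
    allele pair and a block id taken from the PS phase-set tag; unphased
    records are retained with phase absent (usable by the Bayesian engine
    only).
    """
    if parent not in ("maternal", "paternal"):
        raise ValueError("parent must be 'maternal' or 'paternal'")
    filters = filters or VcfFilterConfig()
    sites: dict[tuple[str, int], ParentalSite] = {}
    dropped = {"multiallelic": 0, "low_qual": 0, "depth": 0, "missing_gt": 0, "symbolic": 0}
    with pysam.VariantFile(path) as vcf:
        if len(vcf.header.samples) == 0:
            raise ValueError(f"{path}: VCF has no sample column")
        sample = vcf.header.samples[0]
        for rec in vcf:
            alts = rec.alts
            if alts is None or len(alts) != 1:
                dropped["multiallelic"] += 1
                continue
            alt = alts[0]
            if alt is None or not alt.isalpha():
                dropped["symbolic"] += 1
                continue
            if filters.min_qual and (rec.qual is not None) and rec.qual < filters.min_qual:
                dropped["low_qual"] += 1
                continue
            fmt = rec.samples[sample]
            gt_raw = fmt.get("GT")
            if gt_raw is None or len(gt_raw) != 2 or any(a is None for a in gt_raw):
                dropped["missing_gt"] += 1
                continue
            dp = fmt.get("DP")
            if dp is not None:
                if dp < filters.min_depth or (
                    filters.max_depth is not None and dp > filters.max_depth
                ):
                    dropped["depth"] += 1
                    continue
            phased = bool(fmt.phased)
            gt = tuple(sorted(int(a) for a in gt_raw))
            phase = None
            block = None
            if phased:
                phase = tuple(int(a) for a in gt_raw)
                ps = fmt.get("PS")
                block = str(ps) if ps is not None else None
                if block is None and gt[0] != gt[1]:
                    # phased het without a phase set is not anchorable
                    phase = None
            sites[(rec.chrom, rec.pos)] = ParentalSite(
                gt=gt, phase=phase, block=block, ref=rec.ref, alt=alt
            )
    n_drop = sum(dropped.values())
    if n_drop:
        logger.info("%s VCF %s: dropped %d records (%s)", parent, path, n_drop, dropped)
    return sites, dropped


def merge_parental_sites(
    maternal: Mapping[tuple[str, int], ParentalSite],
    paternal: Mapping[tuple[str, int], ParentalSite],
) -> list[LocusRecord]:
    """Join the two parental site maps into LocusRecords.

    A site missing from one parent's VCF is treated as homozygous-reference
    for that parent (standard single-sample VCF semantics). Sites whose alt
    alleles disagree between the parents are dropped.
    """
    records: list[LocusRecord] = []
    for key in sorted(set(maternal) | set(paternal), key=lambda k: (k[0], k[1])):
        m = maternal.get(key)
        p = paternal.get(key)
        ref = (m or p).ref  # type: ignore[union-attr]
        alt = (m or p).alt  # type: ignore[union-attr]
        if m is not None and p is not None and (m.ref != p.ref or m.alt != p.alt):
            continue
        records.append(
            LocusRecord(
                chrom=key[0],
                pos=key[1],
                ref=ref,
                alt=alt,
                maternal_gt=m.gt if m else (0, 0),
                paternal_gt=p.gt if p else (0, 0),
                maternal_phase=m.phase if m else None,
                paternal_phase=p.phase if p else None,
                maternal_block=m.block if m else None,
                paternal_block=p.block if p else None,
            )
        )
    return records


def _fetal_vcf_header(calls: Sequence[FetalCall], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##INFO=<ID=METHOD,Number=1,Type=String,'
        'Description="Engine that produced the call: bayes|sprt|closest1|closest2|unclassified">'
    )
    header.add_line(
        '##INFO=<ID=CONF,Number=1,Type=Float,'
        'Description="Posterior probability (bayes) or SPRT/imputation confidence">'
    )
    for chrom in dict.fromkeys(c.locus.chrom for c in calls):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_sample(sample)
    return header


def write_fetal_vcf(calls: Sequence[FetalCall], path: str, sample: str = "FETUS") -> None:
    """Write fetal genotype calls as a VCF 4.2 with METHOD/CONF INFO tags.

    Calls must be sorted by (chrom, pos); unclassified loci are emitted with
    a missing genotype.
    """
    keys = [(c.locus.chrom, c.locus.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos)")
    header = _fetal_vcf_header(calls, sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in calls:
            loc = call.locus
            rec = out.new_record(
                contig=loc.chrom,
                start=loc.pos - 1,
                alleles=(loc.ref, loc.alt),
            )
            rec.info["METHOD"] = call.method
            if call.confidence is not None:
                rec.info["CONF"] = float(call.confidence)
            if call.genotype is None:
                rec.samples[sample]["GT"] = (None, None)
            else:
                rec.samples[sample]["GT"] = tuple(call.genotype)
            out.write(rec)


def write_parental_vcf(
    records: Sequence[LocusRecord], parent: str, path: str, sample: str | None = None
) -> None:
    """Write one parent's genotypes (phased where available) as VCF 4.2."""
    sample = sample or parent.upper()
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_sample(sample)
    attr_gt = f"{parent}_gt"
    attr_phase = f"{parent}_phase"
    attr_block = f"{parent}_block"
    with pysam.VariantFile(path, "w", header=header) as out:
        for loc in records:
            gt = getattr(loc, attr_gt)
            phase = getattr(loc, attr_phase)
            block = getattr(loc, attr_block)
            rec = out.new_record(contig=loc.chrom, start=loc.pos - 1, alleles=(loc.ref, loc.alt))
            rec.qual = 60
            if phase is not None:
                rec.samples[sample]["GT"] = tuple(phase)
                rec.samples[sample].phased = True
                if block is not None:
                    rec.samples[sample]["PS"] = int(block)
            else:
                rec.samples[sample]["GT"] = tuple(gt)
            out.write(rec)


def read_truth_vcf(path: str) -> dict[tuple[str, int], Genotype]:
    """Read a truth (cord blood or simulated fetus) VCF into a genotype map."""
    truth: dict[tuple[str, int], Genotype] = {}
    with pysam.VariantFile(path) as vcf:
        sample = vcf.header.samples[0]
        for rec in vcf:
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            truth[(rec.chrom, rec.pos)] = tuple(sorted(int(a) for a in gt))
    return truth


COUNTS_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def read_counts_tsv(path: str) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def counts_map(df: "pandas.DataFrame") -> dict[tuple[str, int], PlasmaCounts]:  # noqa: F821
    return {
        (str(row.chrom), int(row.pos)): PlasmaCounts(int(row.ref_count), int(row.alt_count))
        for row in df.itertuples()
    }
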